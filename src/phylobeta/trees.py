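"""Tree arithmetic on dendropy trees.

Covers patristic distance matrices, ultrametricity checks, even-interpolation
node dating in the style of the BLADJ branch-adjustment algorithm, grafting
of species onto a genus/family backbone, and pruning to a species subset.

Trees are plain :class:`dendropy.Tree` objects; tips are taxa, internal node
labels carry calibration names.  Branch lengths and node ages are in Myr
throughout.  A dated tree is ultrametric: every tip sits at age 0 and a
node's age is its distance to any descendant tip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "PatristicMatrix",
    "read_newick",
    "write_newick",
    "tip_labels",
    "patristic_distances",
    "check_ultrametric",
    "node_ages",
    "bladj_adjust",
    "graft_taxa",
    "prune_to_species",
]


class TreeError(ValueError):
    pass


@dataclass
class PatristicMatrix:
    """Species-by-species path-length distances delta_ij (Myr).

    On an ultrametric tree ``delta_ij`` equals twice the age of the most
    recent common ancestor of i and j.
    """

    species: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise TreeError("distance matrix shape does not match species list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise TreeError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise TreeError("distance matrix diagonal is not zero")

    def reorder(self, species: list) -> "PatristicMatrix":
        """Submatrix/reordering for the given species (all must be present)."""
        idx = [self.species.index(sp) for sp in species]
        return PatristicMatrix(list(species), self.matrix[np.ix_(idx, idx)])


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick string; polytomies and labels preserved."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error classes
        raise TreeError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.label or (head.taxon.label if head.taxon else "<unnamed>")
            raise TreeError(f"missing branch length on edge above {name!r}")


def patristic_distances(tree: dendropy.Tree) -> PatristicMatrix:
    """Path-length (patristic) distances between all pairs of tips."""
    _require_branch_lengths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    leaves = list(tree.leaf_node_iter())
    taxa = [leaf.taxon for leaf in leaves]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return PatristicMatrix([t.label for t in taxa], mat)


class UltrametricityReport(NamedTuple):
    is_ultrametric: bool
    max_deviation: float
    depth: float


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> UltrametricityReport:
    """Check that all root-to-tip distances agree within ``rel_tol`` of depth."""
    _require_branch_lengths(tree)
    tree.calc_node_root_distances()
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    dev = depth - min(depths)
    return UltrametricityReport(dev <= rel_tol * max(depth, 1e-300), dev, depth)


def node_ages(tree: dendropy.Tree) -> dict:
    """Age of every node = max distance to a descendant tip (exact on
    ultrametric trees).  Keyed by node object."""
    _require_branch_lengths(tree)
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
    return ages


# ---------------------------------------------------------------------------
# BLADJ-style even-interpolation dating
# ---------------------------------------------------------------------------

def bladj_adjust(tree: dendropy.Tree, ages) -> dendropy.Tree:
    """Date a rooted topology by fixing constrained node ages and spacing
    unconstrained nodes evenly between their nearest dated neighbours.

    ``ages`` maps internal-node labels to ages (Myr); the root must be
    constrained.  Tips are pinned at age 0.  Unconstrained internal nodes are
    visited in preorder; each is dated by even interpolation along the chain
    from its nearest dated ancestor A to the oldest dated node or tip D
    reachable through it (ties broken by the fewest undated nodes in
    between, then lexicographically by label); anchoring on the oldest
    dated descendant guarantees no interpolated age ever drops below a
    constraint deeper in its subtree.  Branch lengths become parent age
    minus child age, so the result is ultrametric.

    The input tree is not modified; a dated clone is returned.
    """
    entries = ages.entries if hasattr(ages, "entries") else dict(ages)
    tree = tree.clone(depth=1)

    label_of = {}
    for node in tree.preorder_node_iter():
        label_of[node] = node.label or (node.taxon.label if node.taxon else None)

    known_labels = {label_of[n] for n in tree if label_of[n] is not None}
    missing = sorted(set(entries) - known_labels)
    if missing:
        raise TreeError(f"age constraints for unknown node labels: {missing}")

    age = {}
    for node in tree.preorder_node_iter():
        lab = label_of[node]
        if node.is_leaf():
            if lab in entries:
                raise TreeError(f"age constraint on tip {lab!r}")
            age[node] = 0.0
        elif lab in entries:
            age[node] = float(entries[lab])
    root = tree.seed_node
    if root not in age:
        raise TreeError("root node must carry an age constraint")

    # constraint consistency: no dated descendant older than a dated ancestor
    for node in tree.preorder_node_iter():
        if node is root or node not in age or node.is_leaf():
            continue
        anc = node.parent_node
        while anc is not None:
            if anc in age and age[anc] < age[node]:
                raise TreeError(
                    f"constraint inversion: descendant {label_of[node]!r} "
                    f"({age[node]}) older than ancestor {label_of[anc]!r} "
                    f"({age[anc]})"
                )
            anc = anc.parent_node

    def anchor_descendant(u):
        """BFS down from u through undated nodes; returns the dated node or
        tip with the oldest age (ties: fewest undated nodes strictly between
        u and it, then label)."""
        from collections import deque

        best = None  # ((-age, n_undated_between, label), node)
        queue = deque((ch, 0) for ch in u.child_nodes())
        while queue:
            node, undated_between = queue.popleft()
            if node in age:
                key = (-age[node], undated_between, label_of[node] or "")
                if best is None or key < best[0]:
                    best = (key, node)
            else:
                for ch in node.child_nodes():
                    queue.append((ch, undated_between + 1))
        return best[1]

    for u in tree.preorder_node_iter():
        if u in age or u.is_leaf():
            continue
        anc = u.parent_node
        while anc not in age:
            anc = anc.parent_node
        d = anchor_descendant(u)
        # chain of undated nodes from anc down to d, passing through u
        chain = []
        node = d.parent_node
        while node is not anc:
            chain.append(node)
            node = node.parent_node
        chain.reverse()
        k = len(chain)
        a_age, d_age = age[anc], age[d]
        for i, node in enumerate(chain, start=1):
            age[node] = a_age - i * (a_age - d_age) / (k + 1)

    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        length = age[node.parent_node] - age[node]
        if length < -1e-9:
            raise TreeError(
                f"negative branch above {label_of[node]!r}: {length}"
            )
        node.edge.length = max(length, 0.0)
    return tree


# ---------------------------------------------------------------------------
# Taxonomy grafting
# ---------------------------------------------------------------------------

def graft_taxa(backbone: dendropy.Tree, taxonomy, zero_terminal: bool = False):
    """Attach species tips onto a genus/family backbone.

    ``taxonomy`` maps species -> (genus, family).  A species is attached
    under its genus node when the backbone has one (a tip with that label is
    first converted to an internal node), otherwise under its family node,
    expanding polytomies.  By default new terminal branches extend to the
    present (length = age of the attachment node on a dated backbone), which
    preserves ultrametricity; ``zero_terminal=True`` attaches at distance 0
    instead.

    Returns ``(tree, report)`` where ``report`` maps species to the rank it
    was attached at ('genus' or 'family').  Species whose genus and family
    are both absent raise a :class:`TreeError` listing them.
    """
    tree = backbone.clone(depth=1)
    has_lengths = any(
        e.length is not None for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )
    ages = node_ages(tree) if has_lengths else None

    nodes_by_label = {}
    for node in tree.preorder_node_iter():
        lab = node.label or (node.taxon.label if node.taxon else None)
        if lab is not None:
            nodes_by_label.setdefault(lab, node)

    orphans, report = [], {}
    for species, (genus, family) in dict(taxonomy).items():
        if genus in nodes_by_label:
            target, rank = nodes_by_label[genus], "genus"
        elif family in nodes_by_label:
            target, rank = nodes_by_label[family], "family"
        else:
            orphans.append(species)
            continue
        if target.is_leaf():
            # promote the tip to an internal node named after its taxon
            target.label = target.taxon.label
            target.taxon = None
        length = None
        if ages is not None:
            length = 0.0 if zero_terminal else ages.get(target, 0.0)
        child = target.new_child(edge_length=length)
        child.taxon = tree.taxon_namespace.new_taxon(label=species)
        report[species] = rank
    if orphans:
        raise TreeError(
            f"species with neither genus nor family in backbone: {sorted(orphans)}"
        )
    return tree, report


def prune_to_species(tree: dendropy.Tree, species_set) -> dendropy.Tree:
    """Induced subtree on ``species_set``; unary nodes collapsed so patristic
    distances among retained tips are unchanged."""
    species_set = set(species_set)
    if not species_set:
        raise TreeError("cannot prune to an empty species set")
    tips = set(tip_labels(tree))
    unknown = sorted(species_set - tips)
    if unknown:
        raise TreeError(f"species not in tree: {unknown}")
    keep = [tx for tx in tree.taxon_namespace if tx.label in species_set]
    return tree.extract_tree_with_taxa(taxa=keep, suppress_unifurcations=True)
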