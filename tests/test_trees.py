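import itertools

import numpy as np
import pytest

from phylobeta import (
    AgeConstraintSet,
    TreeError,
    bladj_adjust,
    check_ultrametric,
    graft_taxa,
    node_ages,
    patristic_distances,
    prune_to_species,
    read_newick,
    simulate_tree,
    tip_labels,
    write_newick,
)


def test_read_newick_basics():
    t = read_newick("((a:1,b:1):1,c:2);")
    assert sorted(tip_labels(t)) == ["a", "b", "c"]
    assert sum(1 for _ in t.preorder_internal_node_iter()) == 2


def test_polytomy_preserved():
    t = read_newick("((a,b,c)G1,(d,e)G2)R;")
    sizes = sorted(len(n.child_nodes()) for n in t.preorder_internal_node_iter())
    assert sizes == [2, 2, 3]


@pytest.mark.parametrize("bad", ["((a:1,b:1:1,c:2);", "((a:1,a:1):1,c:2);"])
def test_parse_errors(bad):
    with pytest.raises(TreeError):
        read_newick(bad)


def test_newick_round_trip_isomorphic():
    for seed in range(5):
        t = simulate_tree(12, root_age=50.0, seed=seed)
        back = read_newick(write_newick(t))
        d1, d2 = patristic_distances(t), patristic_distances(back)
        assert set(d1.species) == set(d2.species)
        np.testing.assert_allclose(
            d2.reorder(d1.species).matrix, d1.matrix, rtol=1e-9)


def test_patristic_examples(caterpillar_delta):
    d = caterpillar_delta
    i = {sp: k for k, sp in enumerate(d.species)}
    assert d.matrix[i["a"], i["b"]] == 2
    assert d.matrix[i["a"], i["c"]] == 4
    assert d.matrix[i["b"], i["c"]] == 4


def test_patristic_star_tree():
    t = read_newick("(a:3,b:3,c:3,d:3);")
    d = patristic_distances(t)
    off = d.matrix[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 6.0)


def test_patristic_matches_graph_shortest_paths():
    """Independent oracle: Dijkstra on the tree graph (networkx)."""
    import networkx as nx

    tree = simulate_tree(20, root_age=80.0, seed=7)
    G = nx.Graph()
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            G.add_edge(id(node), id(ch), weight=ch.edge.length)
    leaves = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
    d = patristic_distances(tree)
    sp = d.species
    for a, b in itertools.combinations(range(len(sp)), 2):
        expect = nx.shortest_path_length(G, leaves[sp[a]], leaves[sp[b]],
                                         weight="weight")
        assert d.matrix[a, b] == pytest.approx(expect, rel=1e-9)


def test_four_point_condition_on_random_trees():
    rng = np.random.default_rng(0)
    for seed in range(3):
        d = patristic_distances(simulate_tree(12, 100.0, seed=seed)).matrix
        n = d.shape[0]
        for _ in range(50):
            i, j, k, l = rng.choice(n, size=4, replace=False)
            s = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l],
                        d[i, l] + d[j, k]])
            assert s[1] == pytest.approx(s[2], rel=1e-9)


def test_check_ultrametric_verdicts():
    assert check_ultrametric(read_newick("((a:1,b:1):1,c:2);")).is_ultrametric
    rep = check_ultrametric(read_newick("((a:1,b:2):1,c:2);"))
    assert not rep.is_ultrametric
    assert rep.max_deviation == pytest.approx(1.0)


def test_perturbation_flips_ultrametric_verdict():
    t = simulate_tree(10, 100.0, seed=3)
    assert check_ultrametric(t, rel_tol=1e-6).is_ultrametric
    leaf = next(t.leaf_node_iter())
    leaf.edge.length += 0.01  # > 1e-6 * 100
    assert not check_ultrametric(t, rel_tol=1e-6).is_ultrametric


# ---------------------------------------------------------------------------
# BLADJ dating
# ---------------------------------------------------------------------------

def test_bladj_chain_even_interpolation():
    t = read_newick("(((a)u2)u1)root;")
    dated = bladj_adjust(t, AgeConstraintSet({"root": 100.0}))
    ages = {(n.label or (n.taxon.label if n.taxon else None)): a
            for n, a in node_ages(dated).items()}
    assert ages["root"] == pytest.approx(100.0)
    assert ages["u1"] == pytest.approx(100 * 2 / 3, abs=1e-9)
    assert ages["u2"] == pytest.approx(100 / 3, abs=1e-9)
    assert ages["a"] == 0.0


def test_bladj_constraint_fidelity_and_ultrametric():
    t = read_newick("((a,b)m,(c,(d,e)x)y)root;")
    dated = bladj_adjust(t, AgeConstraintSet({"root": 100.0, "m": 50.0}))
    ages = {n.label: a for n, a in node_ages(dated).items() if n.label}
    assert ages["m"] == pytest.approx(50.0)
    assert check_ultrametric(dated).is_ultrametric


def test_bladj_errors():
    t = read_newick("((a,b)m,c)root;")
    with pytest.raises(TreeError, match="root"):
        bladj_adjust(t, AgeConstraintSet({"m": 10.0}))
    with pytest.raises(TreeError, match="inversion"):
        bladj_adjust(t, AgeConstraintSet({"root": 10.0, "m": 50.0}))
    with pytest.raises(TreeError, match="unknown"):
        bladj_adjust(t, AgeConstraintSet({"root": 10.0, "zz": 5.0}))


def _random_consistent_constraints(tree, rng, keep=0.4):
    """Constrain a random subset of internal nodes at their true ages."""
    ages = node_ages(tree)
    entries = {}
    for k, node in enumerate(tree.preorder_internal_node_iter()):
        node.label = f"n{k}"
        if node.parent_node is None or rng.random() < keep:
            entries[node.label] = ages[node]
    return AgeConstraintSet(entries)


def test_bladj_interpolated_ages_bounded_by_anchors():
    """Every interpolated age must lie strictly between the nearest
    constrained ancestor and the oldest constrained descendant (or 0)."""
    for seed in range(8):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(15, root_age=120.0, seed=seed)
        constraints = _random_consistent_constraints(tree, rng)
        dated = bladj_adjust(tree, constraints)
        assert check_ultrametric(dated).is_ultrametric
        ages = node_ages(dated)
        by_label = {n.label: ages[n] for n in dated.preorder_internal_node_iter()}
        for lab, age in constraints.entries.items():
            assert by_label[lab] == pytest.approx(age, abs=1e-9)
        for node in dated.preorder_internal_node_iter():
            if node.label in constraints.entries:
                continue
            anc = node.parent_node
            while anc.label not in constraints.entries:
                anc = anc.parent_node
            upper = constraints[anc.label]
            lower = 0.0
            stack = list(node.child_nodes())
            while stack:
                ch = stack.pop()
                if not ch.is_leaf() and ch.label in constraints.entries:
                    lower = max(lower, constraints[ch.label])
                else:
                    stack.extend(ch.child_nodes())
            assert lower < ages[node] < upper


def test_bladj_idempotent():
    tree = simulate_tree(10, root_age=90.0, seed=11)
    rng = np.random.default_rng(1)
    constraints = _random_consistent_constraints(tree, rng)
    dated = bladj_adjust(tree, constraints)
    full = AgeConstraintSet({
        n.label: a for n, a in node_ages(dated).items()
        if not n.is_leaf() and a > 0
    })
    redated = bladj_adjust(dated, full)
    for n1, n2 in zip(dated.preorder_node_iter(), redated.preorder_node_iter()):
        if n1.edge.length is not None:
            assert n2.edge.length == pytest.approx(n1.edge.length, abs=1e-9)


# ---------------------------------------------------------------------------
# grafting and pruning
# ---------------------------------------------------------------------------

def test_graft_congeners_under_genus_tip():
    backbone = read_newick("((GenA:10,GenB:10)F1:10,GenC:20)root;")
    tax = {"sp1": ("GenA", "F1"), "sp2": ("GenA", "F1")}
    tree, report = graft_taxa(backbone, tax)
    assert report == {"sp1": "genus", "sp2": "genus"}
    labels = tip_labels(tree)
    assert "sp1" in labels and "GenA" not in labels
    # genus tip is at age 0, so congeners coincide there
    d = patristic_distances(tree)
    i = {sp: k for k, sp in enumerate(d.species)}
    assert d.matrix[i["sp1"], i["sp2"]] == pytest.approx(0.0)


def test_graft_falls_back_to_family_polytomy():
    backbone = read_newick("((GenA:10,GenB:10)F1:10,GenC:20)root;")
    tree, report = graft_taxa(backbone, {"spX": ("GenZ", "F1")})
    assert report["spX"] == "family"
    # F1 is at age 10; extending to the present keeps the tree ultrametric
    assert check_ultrametric(tree).is_ultrametric
    with pytest.raises(TreeError, match="spY"):
        graft_taxa(backbone, {"spY": ("GenZ", "F9")})


def test_graft_zero_terminal_attaches_at_distance_zero():
    backbone = read_newick("((GenA:10,GenB:10)F1:10,GenC:20)root;")
    tree, _ = graft_taxa(backbone, {"spX": ("GenZ", "F1")}, zero_terminal=True)
    d = patristic_distances(tree)
    i = {sp: k for k, sp in enumerate(d.species)}
    assert d.matrix[i["spX"], i["GenA"]] == pytest.approx(10.0)


def test_graft_preserves_backbone_relationships():
    """New tips sit at their genus position: distances from a grafted
    species to untouched backbone tips equal the genus's distances."""
    backbone = simulate_tree(8, root_age=60.0, seed=5)
    before = patristic_distances(backbone)
    hosts = before.species[:4]
    untouched = before.species[4:]
    tax = {f"new{k}": (host, "nofam") for k, host in enumerate(hosts)}
    tree, _ = graft_taxa(backbone, tax)
    after = patristic_distances(tree)
    ib = {sp: k for k, sp in enumerate(before.species)}
    ia = {sp: k for k, sp in enumerate(after.species)}
    for k, host in enumerate(hosts):
        for other in untouched:
            assert after.matrix[ia[f"new{k}"], ia[other]] == pytest.approx(
                before.matrix[ib[host], ib[other]], abs=1e-9)
    assert check_ultrametric(tree).is_ultrametric


def test_prune_preserves_patristic_distances():
    t = read_newick("((a:1,b:1):1,c:2);")
    pruned = prune_to_species(t, {"a", "c"})
    d = patristic_distances(pruned)
    i = {sp: k for k, sp in enumerate(d.species)}
    assert d.matrix[i["a"], i["c"]] == pytest.approx(4.0)


def test_prune_random_submatrix_oracle():
    rng = np.random.default_rng(2)
    for seed in range(4):
        tree = simulate_tree(14, root_age=70.0, seed=seed)
        full = patristic_distances(tree)
        keep = list(rng.choice(full.species, size=6, replace=False))
        sub = patristic_distances(prune_to_species(tree, keep))
        np.testing.assert_allclose(sub.reorder(keep).matrix,
                                   full.reorder(keep).matrix, atol=1e-9)


def test_prune_errors():
    t = read_newick("((a:1,b:1):1,c:2);")
    with pytest.raises(TreeError):
        prune_to_species(t, set())
    with pytest.raises(TreeError, match="zz"):
        prune_to_species(t, {"a", "zz"})
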