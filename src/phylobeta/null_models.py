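"""Randomization schemes and permutation tests for community structure.

Three null models are provided:

``1-3x``
    Individuals are reshuffled among sites *within* each stratum (habitat
    type), holding every site's individual count and every species'
    within-stratum total fixed.  Tests taxonomic turnover (I_ST) between
    sites net of habitat composition.
``2-3x``
    Individuals are reshuffled among groups over the whole dataset, holding
    group sizes and species grand totals fixed.  Tests taxonomic turnover
    (I_ST) between habitats.
``1s``
    Species identities are shuffled across the tips of the phylogeny (a
    random bijection of species onto tip positions); the community matrix
    is untouched.  Tests phylogenetic structure (B_ST, Pi_ST, APD).

Community-randomizing models are biased for phylogenetic statistics (they
destroy species turnover, which B_ST is meant to be independent of), so
statistic/model pairings are enforced: I_ST only with 1-3x/2-3x, and
B_ST/Pi_ST/APD only with 1s.

P-values use the add-one rule ``p = (1 + b) / (R + 1)`` with ties counted
as at least as extreme, so the smallest attainable p at R = 999 is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import CommunityMatrix
from .partition import (
    PartitionError,
    PatristicMatrix,
    _canonical_statistic,
    apd,
    partition_diversity,
    statistic_value,
)

__all__ = [
    "PermutationReport",
    "permute_individuals_within_strata",
    "permute_individuals_among_groups",
    "permute_tips",
    "significance_test",
    "VALID_PAIRINGS",
]

VALID_PAIRINGS = {
    "I_ST": ("1-3x", "2-3x"),
    "B_ST": ("1s",),
    "Pi_ST": ("1s",),
    "APD": ("1s",),
}


@dataclass
class PermutationReport:
    statistic: str
    observed: float
    null_values: np.ndarray
    p_greater: float
    p_less: float
    p_two_sided: float
    model: str
    n_permutations: int
    seed: int
    alternative: str = "greater"

    @property
    def p_value(self) -> float:
        return {"greater": self.p_greater, "less": self.p_less,
                "two-sided": self.p_two_sided}[self.alternative]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["null_mean"] = float(np.mean(self.null_values))
        d["null_values"] = [float(v) for v in self.null_values]
        d["p_value"] = self.p_value
        return d


def _materialize(counts_row: np.ndarray) -> np.ndarray:
    """Expand a count vector into an explicit array of species indices."""
    return np.repeat(np.arange(counts_row.size), counts_row)


def _rebuild(labels: np.ndarray, sizes: np.ndarray, n_species: int) -> np.ndarray:
    """Split a label list by consecutive block sizes into a count matrix."""
    out = np.zeros((sizes.size, n_species), dtype=np.int64)
    start = 0
    for r, size in enumerate(sizes):
        out[r] = np.bincount(labels[start:start + size], minlength=n_species)
        start += size
    return out


def permute_individuals_within_strata(cm: CommunityMatrix, strata,
                                      rng: np.random.Generator) -> CommunityMatrix:
    """Model 1-3x draw: reshuffle individuals among sites within strata.

    ``strata`` maps site -> stratum.  Site sizes and per-stratum species
    totals are conserved exactly; a stratum containing a single site is a
    fixed block.
    """
    missing = [s for s in cm.sites if s not in strata]
    if missing:
        raise PartitionError(f"sites without stratum: {missing}")
    new_counts = np.zeros_like(cm.counts)
    site_index = {s: r for r, s in enumerate(cm.sites)}
    by_stratum: dict = {}
    for s in cm.sites:
        by_stratum.setdefault(strata[s], []).append(site_index[s])
    for rows in by_stratum.values():
        rows = np.array(rows)
        if rows.size == 1:
            new_counts[rows[0]] = cm.counts[rows[0]]
            continue
        labels = np.concatenate([_materialize(cm.counts[r]) for r in rows])
        rng.shuffle(labels)
        sizes = cm.counts[rows].sum(axis=1)
        new_counts[rows] = _rebuild(labels, sizes, cm.n_species)
    return CommunityMatrix(sites=list(cm.sites), species=list(cm.species),
                           counts=new_counts, habitat=dict(cm.habitat),
                           coords=dict(cm.coords))


def permute_individuals_among_groups(cm: CommunityMatrix, grouping,
                                     rng: np.random.Generator) -> CommunityMatrix:
    """Model 2-3x draw: reshuffle all individuals among groups.

    Group totals and species grand totals are conserved; within a group the
    reshuffled pool is spread over the group's sites preserving site sizes.
    ``grouping`` is as in :func:`phylobeta.partition.group_counts`.
    """
    from .partition import group_counts

    ids, _ = group_counts(cm, grouping)
    if len(ids) < 2:
        raise PartitionError("need at least 2 groups")
    # a single shuffle of the pooled labels, split consecutively by site,
    # realizes a uniform reassignment preserving all site (hence group) sizes
    labels = np.concatenate([_materialize(row) for row in cm.counts])
    rng.shuffle(labels)
    sizes = cm.site_sizes
    new_counts = _rebuild(labels, sizes, cm.n_species)
    return CommunityMatrix(sites=list(cm.sites), species=list(cm.species),
                           counts=new_counts, habitat=dict(cm.habitat),
                           coords=dict(cm.coords))


def permute_tips(delta: PatristicMatrix, rng: np.random.Generator,
                 pool=None) -> PatristicMatrix:
    """Model 1s draw: random bijection of species labels onto tip positions,
    i.e. a simultaneous row/column permutation of the distance matrix.

    ``pool`` restricts the shuffle to a subset of species (e.g. one clade);
    it must be exactly the species of ``delta``.
    """
    if pool is not None and set(pool) != set(delta.species):
        raise PartitionError(
            "permutation pool differs from the distance-matrix species set"
        )
    perm = rng.permutation(len(delta.species))
    return PatristicMatrix(list(delta.species),
                           delta.matrix[np.ix_(perm, perm)])


def _p_values(observed: float, null_values: np.ndarray):
    R = null_values.size
    b_ge = int(np.sum(null_values >= observed))
    b_le = int(np.sum(null_values <= observed))
    p_greater = (1 + b_ge) / (R + 1)
    p_less = (1 + b_le) / (R + 1)
    center = np.median(null_values)
    b_two = int(np.sum(np.abs(null_values - center) >= abs(observed - center)))
    p_two = (1 + b_two) / (R + 1)
    return p_greater, p_less, min(p_two, 1.0)


def significance_test(cm: CommunityMatrix, delta: PatristicMatrix,
                      grouping="site", statistic: str = "I_ST",
                      model: str = "1-3x", n_permutations: int = 999,
                      seed: int = 0, alternative: str = "greater",
                      strata=None, mode: str = "pairs") -> PermutationReport:
    """Permutation test of a differentiation statistic under a null model.

    Parameters
    ----------
    statistic : "I_ST" | "B_ST" | "Pi_ST" | "APD"
    model : "1-3x" | "2-3x" | "1s" — must match the statistic (see module
        docstring); invalid pairings are refused.
    strata : map site -> stratum for model 1-3x (defaults to the community's
        habitat labels).
    alternative : "greater" | "less" | "two-sided" — the headline p-value;
        all three are reported.
    """
    stat = statistic.upper() if statistic.upper() == "APD" \
        else _canonical_statistic(statistic)
    if model not in VALID_PAIRINGS.get(stat, ()):
        raise PartitionError(
            f"statistic {stat} cannot be tested under model {model}: "
            "community-randomizing models (3x) are biased for phylogenetic "
            "statistics, and tip shuffling (1s) leaves taxonomic turnover "
            f"unchanged; valid models for {stat}: {VALID_PAIRINGS[stat]}"
        )
    if n_permutations < 1:
        raise PartitionError("need at least one permutation")
    if alternative not in ("greater", "less", "two-sided"):
        raise PartitionError(f"unknown alternative {alternative!r}")

    rng = np.random.default_rng(seed)

    def evaluate(cm_k, delta_k):
        if stat == "APD":
            return apd(cm_k, delta_k).APD
        res = partition_diversity(cm_k, delta_k, grouping=grouping, mode=mode)
        return statistic_value(res, stat)

    observed = evaluate(cm, delta)
    null_values = np.empty(n_permutations)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # null draws only
        if model == "1-3x":
            strat = strata if strata is not None else \
                {s: h for s, h in zip(cm.sites, cm.habitat_vector())}
            for k in range(n_permutations):
                null_values[k] = evaluate(
                    permute_individuals_within_strata(cm, strat, rng), delta)
        elif model == "2-3x":
            for k in range(n_permutations):
                null_values[k] = evaluate(
                    permute_individuals_among_groups(cm, grouping, rng), delta)
        elif model == "1s":
            for k in range(n_permutations):
                null_values[k] = evaluate(cm, permute_tips(delta, rng))
        else:
            raise PartitionError(f"unknown model {model!r}")

    p_greater, p_less, p_two = _p_values(observed, null_values)
    return PermutationReport(
        statistic=stat, observed=observed, null_values=null_values,
        p_greater=p_greater, p_less=p_less, p_two_sided=p_two,
        model=model, n_permutations=n_permutations, seed=seed,
        alternative=alternative,
    )
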