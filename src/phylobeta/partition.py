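"""Rao quadratic-entropy partitioning of taxonomic and phylogenetic diversity.

Diversity is partitioned within and between groups of sites (transects,
habitats, or any user grouping) into eight quantities and four
differentiation coefficients:

========  ==================================================================
D_IS/D_IT  probability that two individuals belong to different species,
           within a group / between two groups (Simpson-Gini).
D_PS/D_PT  mean patristic distance between two individuals (Rao entropy,
           Myr); conspecific pairs contribute distance 0.
D_BS/D_BT  mean patristic distance between two NON-conspecific individuals
           (Myr).
Dlt_PS/PT  mean patristic distance between two distinct species on
           incidence (presence/absence) data (Myr).
========  ==================================================================

Each coefficient is the proportional excess of the between-group over the
within-group quantity, e.g. ``I_ST = (D_IT - D_IS) / D_IT``; ``B_ST`` and
``Pi_ST`` measure phylogenetic turnover independently of species turnover
(B_ST > 0: within-group phylogenetic clustering; B_ST < 0: overdispersion).

Within-group quantities average over groups with equal weight; between-group
quantities average over all unordered pairs of groups with equal weight.
The default "pairs" mode draws two *distinct* individuals without
replacement within a group; "frequency" mode draws with replacement (so two
groups of identical composition give exactly zero differentiation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np

from .io import CommunityMatrix
from .trees import PatristicMatrix

__all__ = [
    "PartitionResult",
    "ApdResult",
    "PartitionError",
    "group_counts",
    "partition_diversity",
    "assemble_coefficients",
    "pairwise_differentiation",
    "apd",
]

STATISTICS = ("I_ST", "P_ST", "B_ST", "Pi_ST")


class PartitionError(ValueError):
    pass


@dataclass
class PartitionResult:
    """The eight diversity quantities and four differentiation coefficients."""

    D_IS: float
    D_IT: float
    D_PS: float
    D_PT: float
    D_BS: float
    D_BT: float
    Delta_PS: float
    Delta_PT: float
    I_ST: float
    P_ST: float
    B_ST: float
    Pi_ST: float
    grouping: str = "custom"
    mode: str = "pairs"

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 4) -> dict:
        return {k: (round(v, ndigits) if isinstance(v, float) else v)
                for k, v in self.as_dict().items()}


@dataclass
class ApdResult:
    """Abundance Phylogenetic Deviation of the regional species pool.

    ``APD = 1 - weighted / unweighted`` where *weighted* is the regional
    abundance-weighted mean distance between non-conspecific individuals and
    *unweighted* the plain mean distance between distinct species.  APD > 0
    means abundant species are phylogenetically clustered; APD < 0 means
    they are overdispersed.
    """

    APD: float
    weighted_mean: float
    unweighted_mean: float


def group_counts(cm: CommunityMatrix, grouping):
    """Pool site counts into groups.

    ``grouping`` is ``"site"`` (each site its own group), ``"habitat"``
    (pool by habitat label), or a map site -> group id.  Returns
    ``(group_ids, counts)`` with counts of shape (n_groups, n_species).
    """
    if grouping in ("site", "transect", None):
        assign = {s: s for s in cm.sites}
    elif grouping == "habitat":
        assign = {s: h for s, h in zip(cm.sites, cm.habitat_vector())}
    else:
        assign = dict(grouping)
        missing = [s for s in cm.sites if s not in assign]
        if missing:
            raise PartitionError(f"sites without group assignment: {missing}")
    ids = list(dict.fromkeys(assign[s] for s in cm.sites))
    counts = np.zeros((len(ids), cm.n_species), dtype=np.int64)
    index = {g: k for k, g in enumerate(ids)}
    for r, s in enumerate(cm.sites):
        counts[index[assign[s]]] += cm.counts[r]
    return ids, counts


def _within_quantities(G: np.ndarray, delta: np.ndarray, mode: str):
    """Per-group D_I, D_P, D_B, Delta; D_B/Delta are NaN for monospecific
    groups."""
    n = G.sum(axis=1).astype(float)
    if mode == "pairs":
        if (n < 2).any():
            raise PartitionError(
                "pairs mode requires >= 2 individuals in every group"
            )
        same = (G * (G - 1)).sum(axis=1)
        pairs = n * (n - 1)
        D_I = 1.0 - same / pairs
        P_num = np.einsum("gi,ij,gj->g", G, delta, G)
        D_P = P_num / pairs
        b_pairs = n ** 2 - (G ** 2).sum(axis=1)  # ordered non-conspecific
    elif mode == "frequency":
        F = G / n[:, None]
        D_I = 1.0 - (F ** 2).sum(axis=1)
        P_num = np.einsum("gi,ij,gj->g", F, delta, F)
        D_P = P_num
        b_pairs = D_I.copy()
    else:
        raise PartitionError(f"unknown mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        D_B = np.where(b_pairs > 0, P_num / np.where(b_pairs > 0, b_pairs, 1.0),
                       np.nan)
    A = (G > 0).astype(float)
    s = A.sum(axis=1)
    d_num = np.einsum("gi,ij,gj->g", A, delta, A)
    with np.errstate(divide="ignore", invalid="ignore"):
        Delta = np.where(s > 1, d_num / np.where(s > 1, s * (s - 1), 1.0), np.nan)
    return D_I, D_P, D_B, Delta


def _between_matrices(G: np.ndarray, delta: np.ndarray):
    """Pairwise between-group D_I, D_P, D_B, Delta matrices (g, h)."""
    n = G.sum(axis=1).astype(float)
    F = G / n[:, None]
    ident = F @ F.T                       # P(same species), one from each
    D_I = 1.0 - ident
    D_P = F @ delta @ F.T
    with np.errstate(divide="ignore", invalid="ignore"):
        D_B = np.where(D_I > 0, D_P / np.where(D_I > 0, D_I, 1.0), np.nan)
    A = (G > 0).astype(float)
    shared = A @ A.T
    s = A.sum(axis=1)
    tot = np.outer(s, s) - shared          # ordered distinct-species pairs
    d_num = A @ delta @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        Delta = np.where(tot > 0, d_num / np.where(tot > 0, tot, 1.0), np.nan)
    return D_I, D_P, D_B, Delta


def _nanmean_strict(values, what, warn=True):
    values = np.asarray(values, dtype=float)
    bad = np.isnan(values)
    if bad.all():
        warnings.warn(f"{what} undefined for every group; flagged as NaN",
                      stacklevel=3)
        return float("nan")
    if bad.any() and warn:
        warnings.warn(
            f"{what} undefined for {int(bad.sum())} group(s) "
            "(monospecific); excluded from the within-group average",
            stacklevel=3,
        )
    return float(np.nanmean(values))


def partition_diversity(cm: CommunityMatrix, delta: PatristicMatrix,
                        grouping="site", mode: str = "pairs",
                        label: str | None = None) -> PartitionResult:
    """Partition taxonomic and phylogenetic diversity within/between groups.

    Parameters
    ----------
    cm : CommunityMatrix
    delta : PatristicMatrix
        Species distances; species set must equal the community's.
    grouping : "site" | "habitat" | mapping site -> group
    mode : "pairs" (two distinct individuals, default) or "frequency"
        (draws with replacement).

    Raises
    ------
    PartitionError
        Fewer than 2 groups, a group with < 2 individuals in pairs mode, or
        a quantity undefined for every group.
    """
    if set(cm.species) != set(delta.species):
        raise PartitionError("community and distance matrix species differ")
    d = delta.reorder(cm.species).matrix
    ids, G = group_counts(cm, grouping)
    if len(ids) < 2:
        raise PartitionError("need at least 2 groups")
    D_I, D_P, D_B, Delta = _within_quantities(G, d, mode)
    bI, bP, bB, bD = _between_matrices(G, d)
    iu = np.triu_indices(len(ids), k=1)

    D_IS = float(np.mean(D_I))
    D_PS = float(np.mean(D_P))
    D_BS = _nanmean_strict(D_B, "within-group D_B")
    Delta_PS = _nanmean_strict(Delta, "within-group Delta")
    D_IT = float(np.mean(bI[iu]))
    D_PT = float(np.mean(bP[iu]))
    D_BT = _nanmean_strict(bB[iu], "between-group D_B")
    Delta_PT = _nanmean_strict(bD[iu], "between-group Delta")

    return PartitionResult(
        D_IS=D_IS, D_IT=D_IT, D_PS=D_PS, D_PT=D_PT,
        D_BS=D_BS, D_BT=D_BT, Delta_PS=Delta_PS, Delta_PT=Delta_PT,
        I_ST=assemble_coefficients(D_IS, D_IT),
        P_ST=assemble_coefficients(D_PS, D_PT),
        B_ST=assemble_coefficients(D_BS, D_BT),
        Pi_ST=assemble_coefficients(Delta_PS, Delta_PT),
        grouping=label or (grouping if isinstance(grouping, str) else "custom"),
        mode=mode,
    )


def assemble_coefficients(d_within: float, d_total: float) -> float:
    """Differentiation coefficient ``(D_total - D_within) / D_total``.

    This is the beta/gamma share of diversity: I_ST, P_ST, B_ST and Pi_ST
    are all assembled this way from their within/total diversity pair.
    """
    if d_total == 0:
        raise PartitionError("total diversity is zero; coefficient undefined")
    return (d_total - d_within) / d_total


def statistic_value(result: PartitionResult, statistic: str) -> float:
    statistic = _canonical_statistic(statistic)
    return getattr(result, statistic)


def _canonical_statistic(statistic: str) -> str:
    aliases = {
        "ist": "I_ST", "i_st": "I_ST",
        "pst": "P_ST", "p_st": "P_ST",
        "bst": "B_ST", "b_st": "B_ST",
        "pist": "Pi_ST", "pi_st": "Pi_ST", "πst": "Pi_ST",
    }
    key = statistic.lower().replace("-", "_")
    if key not in aliases:
        raise PartitionError(f"unknown statistic {statistic!r}")
    return aliases[key]


def pairwise_differentiation(cm: CommunityMatrix, delta: PatristicMatrix,
                             grouping="site", statistic: str = "I_ST",
                             mode: str = "pairs"):
    """Group-by-group matrix of two-group differentiation coefficients.

    Entry (g, h) is the coefficient computed on the subset {g, h}: the
    within term averages the two groups, the between term is their pairwise
    quantity.  Returns ``(group_ids, matrix)``.
    """
    statistic = _canonical_statistic(statistic)
    if set(cm.species) != set(delta.species):
        raise PartitionError("community and distance matrix species differ")
    d = delta.reorder(cm.species).matrix
    ids, G = group_counts(cm, grouping)
    if len(ids) < 2:
        raise PartitionError("need at least 2 groups")
    D_I, D_P, D_B, Delta = _within_quantities(G, d, mode)
    bI, bP, bB, bD = _between_matrices(G, d)
    within = {"I_ST": D_I, "P_ST": D_P, "B_ST": D_B, "Pi_ST": Delta}[statistic]
    between = {"I_ST": bI, "P_ST": bP, "B_ST": bB, "Pi_ST": bD}[statistic]
    k = len(ids)
    out = np.zeros((k, k))
    for g, h in combinations(range(k), 2):
        w = np.nanmean([within[g], within[h]])
        t = between[g, h]
        if not np.isfinite(w) or not np.isfinite(t):
            out[g, h] = out[h, g] = np.nan
        else:
            out[g, h] = out[h, g] = assemble_coefficients(w, t)
    return ids, out


def apd(cm: CommunityMatrix, delta: PatristicMatrix) -> ApdResult:
    """Abundance Phylogenetic Deviation of the pooled regional sample.

    Compares the abundance-weighted mean distance between non-conspecific
    individuals, ``sum_{i!=j} p_i p_j delta_ij / sum_{i!=j} p_i p_j`` with
    regional relative abundances ``p_i``, to the unweighted mean distance
    between distinct species present in the pool.
    """
    if set(cm.species) != set(delta.species):
        raise PartitionError("community and distance matrix species differ")
    d = delta.reorder(cm.species).matrix
    x = cm.counts.sum(axis=0).astype(float)
    present = x > 0
    if present.sum() < 2:
        raise PartitionError("APD requires >= 2 species in the pool")
    x = x[present]
    d = d[np.ix_(present, present)]
    p = x / x.sum()
    w_num = p @ d @ p
    w_den = 1.0 - (p ** 2).sum()
    weighted = w_num / w_den
    k = len(p)
    unweighted = d.sum() / (k * (k - 1))
    return ApdResult(APD=1.0 - weighted / unweighted,
                     weighted_mean=weighted, unweighted_mean=unweighted)
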