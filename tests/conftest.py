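"""Shared fixtures and independent oracles.

The partition oracle recomputes every diversity quantity by expanding the
count table into an explicit list of individuals and enumerating pairs over
individual-level index arrays — a route deliberately different from the
count-level quadratic forms used by the implementation.
"""

import numpy as np
import pytest

from phylobeta import (
    CommunityMatrix,
    PatristicMatrix,
    patristic_distances,
    read_newick,
)


def make_cm(counts, habitat=None, coords=None, species=None, sites=None):
    counts = np.asarray(counts)
    sites = sites or [f"t{r + 1}" for r in range(counts.shape[0])]
    species = species or [f"sp{c + 1}" for c in range(counts.shape[1])]
    return CommunityMatrix(
        sites=sites, species=species, counts=counts,
        habitat=habitat or {s: "h1" for s in sites},
        coords=coords or {},
    )


def random_instance(rng, max_sites=6, max_species=10, max_total=200,
                    ultrametric=True):
    """Random community + random distance matrix for oracle comparisons.

    Every site gets at least 2 individuals and at least 2 species occur.
    """
    n_sites = rng.integers(2, max_sites + 1)
    n_species = rng.integers(2, max_species + 1)
    counts = rng.poisson(max_total / (n_sites * n_species),
                         size=(n_sites, n_species))
    counts[:, 0] += np.maximum(2 - counts.sum(axis=1), 0)  # n_s >= 2
    if (counts.sum(axis=0) > 0).sum() < 2:
        counts[0, 1] += 1
    if ultrametric:
        from phylobeta.simulate import simulate_tree

        tree = simulate_tree(n_species, root_age=100.0,
                             seed=int(rng.integers(2 ** 31)))
        delta = patristic_distances(tree)
        species = list(delta.species)
    else:
        half = np.triu(rng.uniform(1.0, 50.0, (n_species, n_species)), k=1)
        delta = PatristicMatrix(
            [f"sp{c + 1}" for c in range(n_species)], half + half.T)
        species = list(delta.species)
    cm = make_cm(counts, species=species)
    return cm, delta


# ---------------------------------------------------------------------------
# individual-level enumeration oracle
# ---------------------------------------------------------------------------

def _expand(row):
    return np.repeat(np.arange(row.size), row)


def oracle_partition(cm, delta, grouping="site", mode="pairs"):
    """All eight D/Delta quantities by exhaustive pair enumeration."""
    from phylobeta.partition import group_counts

    d = delta.reorder(cm.species).matrix
    _, G = group_counts(cm, grouping)
    inds = [_expand(row) for row in G]

    def within(ind):
        n = ind.size
        if mode == "pairs":
            M = d[np.ix_(ind, ind)]
            off = ~np.eye(n, dtype=bool)
            same = (ind[:, None] == ind[None, :]) & off
            D_I = float((off & ~same).sum()) / off.sum()
            D_P = M[off].mean()
            D_B = M[off & ~same].mean() if (off & ~same).any() else np.nan
        else:
            M = d[np.ix_(ind, ind)]
            allp = np.ones((n, n), dtype=bool)
            same = ind[:, None] == ind[None, :]
            D_I = float((~same).sum()) / allp.sum()
            D_P = M.mean()
            D_B = M[~same].mean() if (~same).any() else np.nan
        present = np.unique(ind)
        if present.size > 1:
            P = d[np.ix_(present, present)]
            Delta = P[~np.eye(present.size, dtype=bool)].mean()
        else:
            Delta = np.nan
        return D_I, D_P, D_B, Delta

    def between(ia, ib):
        M = d[np.ix_(ia, ib)]
        same = ia[:, None] == ib[None, :]
        D_I = float((~same).sum()) / same.size
        D_P = M.mean()
        D_B = M[~same].mean() if (~same).any() else np.nan
        pa, pb = np.unique(ia), np.unique(ib)
        P = d[np.ix_(pa, pb)]
        distinct = pa[:, None] != pb[None, :]
        Delta = P[distinct].mean() if distinct.any() else np.nan
        return D_I, D_P, D_B, Delta

    w = np.array([within(i) for i in inds])
    pairs = [(a, b) for a in range(len(inds)) for b in range(a + 1, len(inds))]
    b = np.array([between(inds[a], inds[c]) for a, c in pairs])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wm = np.nanmean(w, axis=0)
        bm = np.nanmean(b, axis=0)
    return {
        "D_IS": wm[0], "D_PS": wm[1], "D_BS": wm[2], "Delta_PS": wm[3],
        "D_IT": bm[0], "D_PT": bm[1], "D_BT": bm[2], "Delta_PT": bm[3],
    }


def oracle_apd(cm, delta):
    """APD by enumeration over the expanded regional individual list."""
    d = delta.reorder(cm.species).matrix
    ind = _expand(cm.counts.sum(axis=0))
    M = d[np.ix_(ind, ind)]
    same = ind[:, None] == ind[None, :]
    weighted = M[~same].mean()  # frequency weighting == pair enumeration
    # correction: APD weights are with replacement (p_i p_j), which equals
    # enumeration over ordered pairs of individuals including self-pairs of
    # the same species but excluding conspecific pairs -> same ratio
    present = np.unique(ind)
    P = d[np.ix_(present, present)]
    unweighted = P[~np.eye(present.size, dtype=bool)].mean()
    return 1.0 - weighted / unweighted


@pytest.fixture
def caterpillar_delta():
    tree = read_newick("((a:1,b:1):1,c:2);")
    return patristic_distances(tree)
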