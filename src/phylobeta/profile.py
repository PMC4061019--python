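"""Decomposition of diversity by divergence-time class.

For every pair of non-conspecific individuals, the divergence time of
their species is half the patristic distance (on a dated, ultrametric
tree).  The profile histograms these times separately for pairs drawn
within a group and for pairs straddling two groups; comparing the two
curves shows which depths of the phylogeny carry the between-group
turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityMatrix
from .partition import PartitionError, group_counts
from .trees import PatristicMatrix

__all__ = ["DivergenceProfile", "divergence_profile", "default_bins"]


@dataclass
class DivergenceProfile:
    bin_edges: np.ndarray
    freq_within: np.ndarray
    freq_between: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "freq_within": self.freq_within,
            "freq_between": self.freq_between,
        })


def default_bins(delta: PatristicMatrix, width: float = 20.0) -> np.ndarray:
    """Divergence-time classes of ``width`` Myr from 0 up to the root age."""
    root_age = float(delta.matrix.max()) / 2.0
    n = max(int(np.ceil(root_age / width)), 1)
    return np.arange(0.0, (n + 1) * width, width)


def divergence_profile(cm: CommunityMatrix, delta: PatristicMatrix,
                       grouping="site", bin_edges=None) -> DivergenceProfile:
    """Relative frequency of divergence times for non-conspecific pairs.

    Within: both individuals from the same group, pooled over groups.
    Between: individuals from two different groups, pooled over group pairs.
    Each histogram is normalized to sum to 1.
    """
    if set(cm.species) != set(delta.species):
        raise PartitionError("community and distance matrix species differ")
    d = delta.reorder(cm.species).matrix
    if bin_edges is None:
        bin_edges = default_bins(delta)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(bin_edges) <= 0).any():
        raise PartitionError("bin edges must be strictly increasing")
    _, G = group_counts(cm, grouping)
    Gf = G.astype(float)
    n_g = G.shape[0]
    iu = np.triu_indices(cm.n_species, k=1)
    times = (d / 2.0)[iu]

    # weight of species pair (i < j): number of unordered individual pairs
    within_w = (Gf.T @ Gf)[iu]            # sum_g x_gi * x_gj
    tot = Gf.sum(axis=0)
    total_w = np.outer(tot, tot)[iu]      # all cross-group + within pairs
    between_w = total_w - within_w if n_g > 1 else np.zeros_like(within_w)

    def hist(w):
        if w.sum() <= 0:
            raise PartitionError("no non-conspecific pairs to histogram")
        h, _ = np.histogram(times, bins=bin_edges, weights=w)
        return h / h.sum()

    return DivergenceProfile(
        bin_edges=bin_edges,
        freq_within=hist(within_w),
        freq_between=hist(between_w),
    )
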