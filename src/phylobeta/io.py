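"""Readers, writers and cross-file validation for community data.

The central container is :class:`CommunityMatrix`, a site-by-species table of
individual counts with optional per-site habitat labels and planar
coordinates.  All statistics downstream are defined over pairs of
individuals, so counts are required to be non-negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "AgeConstraintSet",
    "CommunityFormatError",
    "ValidationError",
    "read_community_table",
    "write_community_table",
    "read_site_metadata",
    "write_site_metadata",
    "read_age_constraints",
    "validate_against_tree",
]


class CommunityFormatError(ValueError):
    """A file could not be parsed into a valid community table."""


class ValidationError(ValueError):
    """Parsed inputs are mutually inconsistent or violate an invariant."""


@dataclass
class CommunityMatrix:
    """Site-by-species abundance counts with optional site metadata.

    Parameters
    ----------
    sites : list of str
        Ordered site identifiers (rows).
    species : list of str
        Ordered species identifiers (columns).
    counts : ndarray of shape (n_sites, n_species)
        Non-negative integer counts ``x[s, i]`` of individuals of species
        ``i`` recorded at site ``s``.
    habitat : dict, optional
        Map from site id to habitat label.
    coords : dict, optional
        Map from site id to ``(x, y)`` planar coordinates in km.
    """

    sites: list
    species: list
    counts: np.ndarray
    habitat: dict = field(default_factory=dict)
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.species)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        if len(set(self.sites)) != len(self.sites):
            raise ValidationError("duplicate site ids")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                bad = np.argwhere(self.counts != rounded)
                r, c = bad[0]
                raise CommunityFormatError(
                    f"non-integer count {self.counts[r, c]!r} for site "
                    f"{self.sites[r]!r}, species {self.species[c]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)
            r, c = bad[0]
            raise CommunityFormatError(
                f"negative count for site {self.sites[r]!r}, "
                f"species {self.species[c]!r}"
            )
        empty = np.flatnonzero(self.counts.sum(axis=1) < 1)
        if empty.size:
            names = [self.sites[i] for i in empty]
            raise ValidationError(f"sites with no individuals: {names}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def site_sizes(self) -> np.ndarray:
        """Number of individuals per site, ``n_s``."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Relative frequencies ``f[s, i] = x[s, i] / n_s``."""
        return self.counts / self.site_sizes[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sites, columns=self.species)

    def habitat_vector(self) -> list:
        missing = [s for s in self.sites if s not in self.habitat]
        if missing:
            raise ValidationError(f"sites without habitat label: {missing}")
        return [self.habitat[s] for s in self.sites]

    def coord_array(self) -> np.ndarray:
        missing = [s for s in self.sites if s not in self.coords]
        if missing:
            raise ValidationError(f"sites without coordinates: {missing}")
        return np.array([self.coords[s] for s in self.sites], dtype=float)

    def subset_species(self, keep: list) -> "CommunityMatrix":
        """Restrict to ``keep`` (order follows ``keep``), dropping empty sites."""
        idx = [self.species.index(sp) for sp in keep]
        sub = self.counts[:, idx]
        rows = np.flatnonzero(sub.sum(axis=1) >= 1)
        sites = [self.sites[r] for r in rows]
        return CommunityMatrix(
            sites=sites,
            species=list(keep),
            counts=sub[rows],
            habitat={s: self.habitat[s] for s in sites if s in self.habitat},
            coords={s: self.coords[s] for s in sites if s in self.coords},
        )


@dataclass
class AgeConstraintSet:
    """Fixed node ages (Myr) for dating, keyed by internal node label."""

    entries: dict

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if not v > 0}
        if bad:
            raise ValidationError(f"non-positive age constraints: {bad}")

    def __contains__(self, label):
        return label in self.entries

    def __getitem__(self, label):
        return self.entries[label]


def read_community_table(path, long_format: bool = False,
                         species_as_rows: bool = False) -> CommunityMatrix:
    """Read a site-by-species count table from TSV.

    Wide format (default): header row of species ids, first column site ids.
    Long format (``long_format=True``): three columns site / species / count;
    duplicate (site, species) rows are summed.  ``species_as_rows`` transposes
    a wide table whose rows are species.
    """
    if long_format:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 3:
            raise CommunityFormatError(
                "long format requires site, species, count columns"
            )
        df.columns = ["site", "species", "count", *df.columns[3:]]
        wide = (
            df.pivot_table(index="site", columns="species", values="count",
                           aggfunc="sum", fill_value=0)
        )
        # preserve first-appearance order
        site_order = list(dict.fromkeys(df["site"]))
        sp_order = list(dict.fromkeys(df["species"]))
        wide = wide.reindex(index=site_order, columns=sp_order, fill_value=0)
    else:
        wide = pd.read_csv(path, sep="\t", index_col=0)
        if species_as_rows:
            wide = wide.T
    values = wide.to_numpy()
    if values.dtype == object:
        raise CommunityFormatError("non-numeric cell in community table")
    return CommunityMatrix(
        sites=[str(s) for s in wide.index],
        species=[str(s) for s in wide.columns],
        counts=values,
    )


def write_community_table(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="site")


def read_site_metadata(path, sites=None):
    """Read per-site habitat labels and optional x/y coordinates (km).

    Returns ``(habitat, coords)`` dicts; ``coords`` is ``None`` when either
    coordinate column is absent.  When ``sites`` is given, every site must be
    present in the metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    if "site" not in df.columns or "habitat" not in df.columns:
        raise CommunityFormatError("metadata requires 'site' and 'habitat' columns")
    if sites is not None:
        missing = sorted(set(sites) - set(df["site"]))
        if missing:
            raise ValidationError(f"sites missing from metadata: {missing}")
    habitat = dict(zip(df["site"], df["habitat"]))
    coords = None
    if "x" in df.columns and "y" in df.columns:
        coords = {s: (float(x), float(y))
                  for s, x, y in zip(df["site"], df["x"], df["y"])}
    return habitat, coords


def write_site_metadata(cm: CommunityMatrix, path) -> None:
    rows = []
    for s in cm.sites:
        row = {"site": s, "habitat": cm.habitat.get(s, "")}
        if s in cm.coords:
            row["x"], row["y"] = cm.coords[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_age_constraints(path) -> AgeConstraintSet:
    """Read a two-column TSV ``node<TAB>age`` of node age constraints (Myr)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "age"],
                     dtype={"node": str}, comment="#")
    if df["node"].iloc[0].lower() == "node":  # tolerate a header row
        df = df.iloc[1:]
    return AgeConstraintSet({n: float(a) for n, a in zip(df["node"], df["age"])})


def validate_against_tree(cm: CommunityMatrix, tree) -> None:
    """Check that the community's species set equals the tree's tip set."""
    from . import trees

    tips = set(trees.tip_labels(tree))
    species = set(cm.species)
    if tips != species:
        only_cm = sorted(species - tips)
        only_tree = sorted(tips - species)
        raise ValidationError(
            "species sets differ between community table and tree; "
            f"only in table: {only_cm}; only in tree: {only_tree}"
        )
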