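"""Core data containers.

The containers mirror the objects of the mechanistic-statistical model:
a colony network (:class:`ColonyMap`), per-colony-year intrinsic growth
rates (:class:`GrowthForcing`), the dispersal parameter bundle
(:class:`Theta`), projected abundances (:class:`MetapopTrajectory`,
:class:`ClusterTrajectory`), fixed per-cluster allele frequencies
(:class:`ClusterAlleleFreqs`) and sampled diploid genotypes
(:class:`GenotypeDataset`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidForcingError

MISSING = -1  # internal genotype code for a missing call

EARTH_RADIUS_KM = 6371.0


class Behavior(str, enum.Enum):
    """Dispersal behavior: how departure and settlement use habitat quality.

    RANDOM        - random emigration (fixed per-region rate) and random settlement.
    SEMI_INFORMED - informed emigration (leave only where growth is negative)
                    but random settlement.
    INFORMED      - informed emigration and informed settlement (emigrants
                    settle at the best-growth colony in range).
    """

    RANDOM = "random"
    SEMI_INFORMED = "semi-informed"
    INFORMED = "informed"


def circular_distance_matrix(arc_km: np.ndarray, circumference_km: float) -> np.ndarray:
    """Pairwise shorter-arc distances between positions on a closed coastline."""
    arc = np.asarray(arc_km, dtype=float)
    diff = np.abs(arc[:, None] - arc[None, :])
    return np.minimum(diff, circumference_km - diff)


def haversine_distance_matrix(lon_deg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) on a sphere of radius 6371 km."""
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ColonyMap:
    """An ordered colony network with regions, capacities and distances.

    Parameters
    ----------
    ids
        Colony identifiers, one per colony, unique, order fixed.
    region
        Region label per colony (each colony belongs to exactly one region).
    K
        Carrying capacity (females) per colony, strictly positive.
    n0
        Initial abundance (females) per colony, non-negative.
    dist
        Symmetric pairwise distance matrix in km with zero diagonal.
    metric
        Name of the distance metric used to build ``dist``
        (``"circular"`` or ``"haversine"``).
    coords
        Optional per-colony coordinates: ``{"arc_km": ..., "circumference_km": ...}``
        for circular maps or ``{"lon": ..., "lat": ...}`` for geographic ones.
    """

    ids: list[str]
    region: np.ndarray
    K: np.ndarray
    n0: np.ndarray
    dist: np.ndarray
    metric: str = "circular"
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.region = np.asarray(self.region, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)
        self.dist = np.asarray(self.dist, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("colony ids must be unique")
        for name, arr in (("region", self.region), ("K", self.K), ("n0", self.n0)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per colony")
        if np.any(self.K <= 0):
            raise ValueError("carrying capacities must be strictly positive")
        if np.any(self.n0 < 0):
            raise ValueError("initial abundances must be non-negative")
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.dist), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        # region list in order of first appearance along the colony ordering
        seen: dict = {}
        for lab in self.region:
            seen.setdefault(lab, len(seen))
        self._regions = list(seen)
        self._region_idx = np.array([seen[lab] for lab in self.region], dtype=int)
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    @property
    def n_colonies(self) -> int:
        return len(self.ids)

    @property
    def regions(self) -> list:
        """Region labels in order of first appearance."""
        return list(self._regions)

    @property
    def n_regions(self) -> int:
        return len(self._regions)

    @property
    def region_index(self) -> np.ndarray:
        """Integer region index per colony (into :attr:`regions`)."""
        return self._region_idx

    def index(self, colony_id: str) -> int:
        return self._index[colony_id]

    def colonies_in_region(self, region) -> np.ndarray:
        return np.flatnonzero(self.region == region)


@dataclass
class GrowthForcing:
    """Per-colony, per-year intrinsic growth rates r_it plus the worst-case rate.

    ``rc_star`` is the lowest (most unfavourable) growth rate; the informed
    emigration rule scales habitat quality by the ratio r_it / rc_star, so
    ``rc_star`` must be negative.  By default it is the minimum of the matrix;
    it may be overridden with any value <= min(r) and < 0 (useful when a
    forcing contains no negative entry but a reference worst case is known).
    """

    years: np.ndarray
    r: np.ndarray  # shape (n_colonies, n_years)
    rc_star: float | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.years.ndim != 1 or self.r.ndim != 2:
            raise ValueError("years must be 1-D and r must be 2-D")
        if self.r.shape[1] != self.years.size:
            raise ValueError("r must have one column per year")
        if self.years.size == 0:
            raise ValueError("forcing must cover at least one year")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        rmin = float(self.r.min())
        if self.rc_star is None:
            if rmin >= 0:
                raise InvalidForcingError(
                    "cannot derive the worst-case growth rate: the forcing has no "
                    f"negative entry (min r = {rmin:g}); pass rc_star explicitly"
                )
            self.rc_star = rmin
        self.rc_star = float(self.rc_star)
        if self.rc_star >= 0:
            raise InvalidForcingError(
                f"worst-case growth rate must be negative, got {self.rc_star:g}"
            )
        if self.rc_star > rmin:
            raise InvalidForcingError(
                f"rc_star ({self.rc_star:g}) must not exceed min(r) ({rmin:g})"
            )
        self._year0 = int(self.years[0])

    @property
    def n_colonies(self) -> int:
        return self.r.shape[0]

    def covers(self, t0: int, t1: int) -> list[int]:
        """Return the years in [t0, t1) missing from the forcing."""
        return [t for t in range(t0, t1) if not (self.years[0] <= t <= self.years[-1])]

    def r_at(self, year: int) -> np.ndarray:
        """Growth-rate column for one year."""
        if not (self.years[0] <= year <= self.years[-1]):
            from .errors import ForcingGapError

            raise ForcingGapError([year])
        return self.r[:, year - self._year0]


@dataclass
class Theta:
    """The inferred parameter bundle.

    d
        Mean dispersal distance (km), the scale of the settlement kernel.
    pm
        Per-region emigration parameter in [0, 1]: the fixed emigration rate
        under random behavior, or the sensitivity to habitat degradation
        under informed emigration.
    mu_unknown
        For each genetically uncharacterized region, the shared initial
        cluster-proportion row (length-R simplex).
    behavior
        One of the three dispersal behaviors.
    """

    d: float
    pm: np.ndarray
    behavior: Behavior
    mu_unknown: dict = field(default_factory=dict)

    def __post_init__(self):
        self.d = float(self.d)
        self.pm = np.asarray(self.pm, dtype=float)
        self.behavior = Behavior(self.behavior)
        if self.d <= 0:
            raise ValueError("mean dispersal distance must be positive")
        if np.any((self.pm < 0) | (self.pm > 1)):
            raise ValueError("pm entries must lie in [0, 1]")
        clean = {}
        for reg, mu in self.mu_unknown.items():
            mu = np.asarray(mu, dtype=float)
            if np.any(mu < 0) or abs(mu.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"mu row for region {reg!r} must be a simplex vector"
                )
            clean[reg] = mu
        self.mu_unknown = clean


@dataclass
class MetapopTrajectory:
    """Deterministic projection output of the annual metapopulation update."""

    years: np.ndarray  # length T+1: state years t0 .. t1
    n: np.ndarray  # (n_colonies, T+1) abundances
    m: np.ndarray  # (n_colonies, T) realized emigration rates for step t -> t+1
    D: np.ndarray  # (T, n, n) applied dispersal matrices
    colony_ids: list[str]

    @property
    def total(self) -> np.ndarray:
        """Total metapopulation size per state year."""
        return self.n.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy colony x year abundance table."""
        n_col, n_t = self.n.shape
        return pd.DataFrame(
            {
                "colony_id": np.repeat(self.colony_ids, n_t),
                "year": np.tile(self.years, n_col),
                "n": self.n.ravel(),
            }
        )


@dataclass
class ClusterTrajectory:
    """Cluster-of-origin abundances nτʳ(t) and proportions μτr(t)."""

    years: np.ndarray  # length T+1
    nr: np.ndarray  # (n_colonies, R, T+1)
    colony_ids: list[str]
    clusters: list[str]

    def mu(self, eps: float = 0.0) -> np.ndarray:
        """Proportions μτr(t) = nτʳ(t)/nτ(t); NaN where the colony is empty."""
        tot = self.nr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.nr / np.where(tot > eps, tot, np.nan)
        return out


@dataclass
class ClusterAlleleFreqs:
    """Reference-allele frequencies per genetic cluster and locus.

    Frequencies are fixed over the sampling interval (the study window is
    shorter than two penguin generations).  Exact zeros encode private
    alleles; NaN marks a (cluster, locus) pair with no observations.
    """

    clusters: list[str]
    locus_ids: list[str]
    p: np.ndarray  # (R, n_loci) in [0, 1], NaN = unavailable

    def __post_init__(self):
        self.clusters = list(self.clusters)
        self.locus_ids = list(self.locus_ids)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.clusters), len(self.locus_ids)):
            raise ValueError("frequency matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = (self.p < 0) | (self.p > 1)
        if np.any(bad & ~np.isnan(self.p)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class GenotypeDataset:
    """Sampled diploid biallelic genotypes with colony / year provenance.

    ``codes`` stores reference-allele copy counts {0, 1, 2}; missing calls
    are stored as -1 (:data:`MISSING`).
    """

    individual_ids: list[str]
    colony_ids: np.ndarray  # (N,) colony id per individual
    years: np.ndarray  # (N,) sampling year per individual
    locus_ids: list[str]
    codes: np.ndarray  # (N, n_loci) int8

    def __post_init__(self):
        self.individual_ids = list(self.individual_ids)
        self.colony_ids = np.asarray(self.colony_ids, dtype=object)
        self.years = np.asarray(self.years, dtype=int)
        self.locus_ids = list(self.locus_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n = len(self.individual_ids)
        if self.codes.shape != (n, len(self.locus_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if self.colony_ids.shape != (n,) or self.years.shape != (n,):
            raise ValueError("provenance arrays must have one entry per individual")
        valid = np.isin(self.codes, [MISSING, 0, 1, 2])
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"genotype codes outside {{0,1,2,missing}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.codes != MISSING

    def het_counts(self) -> np.ndarray:
        """Number of heterozygous loci per individual (over observed loci)."""
        return (self.codes == 1).sum(axis=1)

    def sample_sizes(self) -> pd.DataFrame:
        """Per-(colony, year) sample sizes Gτ."""
        df = pd.DataFrame({"colony_id": self.colony_ids, "year": self.years})
        return (
            df.groupby(["colony_id", "year"], sort=True)
            .size()
            .rename("G")
            .reset_index()
        )

    def sampled_colonies(self) -> list[str]:
        seen: dict = {}
        for cid in self.colony_ids:
            seen.setdefault(cid, None)
        return list(seen)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            individual_ids=self.individual_ids,
            colony_ids=self.colony_ids,
            years=self.years,
            locus_ids=[self.locus_ids[i] for i in keep],
            codes=self.codes[:, keep],
        )
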