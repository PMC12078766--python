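"""Genetic-cluster dynamics and genotype likelihoods.

Each individual originates from one of R genetically differentiated
clusters with fixed biallelic allele frequencies.  Cluster-of-origin
abundances are advanced through time with the same reproduction and
dispersal operators as the total population (the markers are neutral, and
offspring inherit the mother's native cluster), which yields the mixture
proportions μτr(t) used by the sampling model.  Genotype probabilities
within a cluster assume Hardy-Weinberg and linkage equilibrium:

    P(G | cluster r) = prod_λ  p²,  2p(1-p)  or  (1-p)²

for reference-allele copy codes 2, 1, 0.  Private alleles (exact zero
frequencies) make some genotypes impossible under some clusters; the
log-probability is then -inf.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import logsumexp

from .dynamics import TRUNCATION_MULTIPLIER, _iterate
from .errors import NoLociSurviveError
from .types import (
    MISSING,
    ClusterAlleleFreqs,
    ClusterTrajectory,
    ColonyMap,
    GenotypeDataset,
    GrowthForcing,
    MetapopTrajectory,
    Theta,
)

logger = logging.getLogger(__name__)

#: Colonies with projected abundance below this are treated as extinct when
#: a sampling design point or genotyped individual falls on them.
EXTINCTION_THRESHOLD = 1e-9


def filter_snps(
    data: GenotypeDataset,
    min_presence: float = 0.8,
    require_all_colonies: bool = True,
    require_polymorphic: bool = True,
) -> GenotypeDataset:
    """Apply the SNP presence and polymorphism filters.

    A locus is retained when it is genotyped in at least one individual of
    every sampled colony, genotyped in at least ``min_presence`` (default
    80%) of the individuals within every colony, and polymorphic (both
    alleles observed) across the retained individuals.
    """
    if data.n_individuals == 0:
        raise ValueError("dataset contains no individuals")
    obs = data.observed
    keep = np.ones(data.n_loci, dtype=bool)
    for colony in data.sampled_colonies():
        rows = data.colony_ids == colony
        frac = obs[rows].mean(axis=0)
        if require_all_colonies:
            keep &= obs[rows].any(axis=0)
        keep &= frac >= min_presence
    if require_polymorphic:
        codes = data.codes
        ref = np.where(codes >= 0, codes, 0).sum(axis=0)
        alt = np.where(codes >= 0, 2 - codes, 0).sum(axis=0)
        keep &= (ref > 0) & (alt > 0)
    if not keep.any():
        raise NoLociSurviveError(
            "no loci survive the presence/polymorphism filters "
            f"(min_presence={min_presence})"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_snps: dropped %d of %d loci", dropped, data.n_loci)
    return data.subset_loci(keep)


def estimate_cluster_frequencies(
    data: GenotypeDataset,
    colony_to_cluster: dict,
    clusters: list[str] | None = None,
) -> ClusterAlleleFreqs:
    """Empirical reference-allele frequencies per cluster by allele counting.

    Missing genotypes are excluded from numerator and denominator; exact
    zeros are preserved (no pseudo-count), so private alleles stay private.
    A (cluster, locus) pair with no observation is flagged NaN.
    """
    for colony in data.sampled_colonies():
        if colony not in colony_to_cluster:
            raise KeyError(f"sampled colony {colony!r} has no cluster assignment")
    if clusters is None:
        seen: dict = {}
        for colony in data.sampled_colonies():
            seen.setdefault(colony_to_cluster[colony], None)
        clusters = list(seen)
    p = np.full((len(clusters), data.n_loci), np.nan)
    cluster_of_ind = np.array(
        [colony_to_cluster[c] for c in data.colony_ids], dtype=object
    )
    for k, cl in enumerate(clusters):
        rows = cluster_of_ind == cl
        if not rows.any():
            continue
        codes = data.codes[rows]
        obs = codes != MISSING
        n_obs = obs.sum(axis=0)
        ref = np.where(obs, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(n_obs > 0, ref / (2.0 * n_obs), np.nan)
    return ClusterAlleleFreqs(clusters=clusters, locus_ids=data.locus_ids, p=p)


def initial_mu(
    cmap: ColonyMap, theta: Theta, region_to_cluster: dict, clusters: list[str]
) -> np.ndarray:
    """Initial cluster-proportion matrix μ(0), one simplex row per colony.

    A colony in a genetically characterized region gets the indicator row of
    its region's cluster; colonies of an uncharacterized region share the
    estimated row from ``theta.mu_unknown``.
    """
    R = len(clusters)
    cluster_pos = {cl: k for k, cl in enumerate(clusters)}
    mu0 = np.zeros((cmap.n_colonies, R))
    for i, reg in enumerate(cmap.region):
        if reg in region_to_cluster:
            mu0[i, cluster_pos[region_to_cluster[reg]]] = 1.0
        elif reg in theta.mu_unknown:
            mu0[i] = theta.mu_unknown[reg]
        else:
            raise KeyError(
                f"region {reg!r} is neither mapped to a cluster nor estimated"
            )
    return mu0


def init_cluster_state(
    cmap: ColonyMap, theta: Theta, region_to_cluster: dict, clusters: list[str]
) -> np.ndarray:
    """Initial cluster-resolved abundances nτʳ(0) = μτr(0) nτ(0)."""
    return initial_mu(cmap, theta, region_to_cluster, clusters) * cmap.n0[:, None]


def project_clusters(
    cmap: ColonyMap,
    forcing: GrowthForcing,
    theta: Theta,
    t0: int,
    t1: int,
    region_to_cluster: dict,
    clusters: list[str],
    trunc: float = TRUNCATION_MULTIPLIER,
    store_matrices: bool = False,
) -> tuple[MetapopTrajectory, ClusterTrajectory]:
    """Joint projection of total and cluster-of-origin abundances."""
    nr0 = init_cluster_state(cmap, theta, region_to_cluster, clusters)
    traj, nr_hist = _iterate(
        cmap,
        forcing,
        theta,
        t0,
        t1,
        nr0=nr0,
        trunc=trunc,
        store_matrices=store_matrices,
    )
    ctraj = ClusterTrajectory(
        years=traj.years, nr=nr_hist, colony_ids=list(cmap.ids), clusters=list(clusters)
    )
    return traj, ctraj


def _hwe_log_tables(freqs: ClusterAlleleFreqs) -> np.ndarray:
    """Log genotype probabilities, shape (3, R, n_loci) indexed by code.

    NaN frequencies give NaN entries; callers must mask those loci out.
    """
    p = freqs.p
    with np.errstate(divide="ignore", invalid="ignore"):
        l0 = 2.0 * np.log1p(-p)
        l1 = np.log(2.0) + np.log(p) + np.log1p(-p)
        l2 = 2.0 * np.log(p)
    return np.stack([l0, l1, l2])


def genotype_log_prob(codes: np.ndarray, p_r: np.ndarray) -> float:
    """Log P(genotype | cluster) under HWE and linkage equilibrium.

    ``codes`` holds reference-allele copies {0, 1, 2} or -1 for missing;
    missing loci (and loci with NaN frequency) contribute nothing.  Returns
    -inf when an observed allele has frequency zero in the cluster.
    """
    codes = np.asarray(codes)
    p_r = np.asarray(p_r, dtype=float)
    if codes.shape != p_r.shape:
        raise ValueError("genotype and frequency vectors must align")
    bad = ~np.isin(codes, (MISSING, 0, 1, 2))
    if bad.any():
        raise ValueError(f"invalid genotype codes: {np.unique(codes[bad])}")
    obs = (codes != MISSING) & ~np.isnan(p_r)
    if not obs.any():
        return 0.0
    c = codes[obs]
    p = p_r[obs]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            c == 2,
            2.0 * np.log(p),
            np.where(c == 0, 2.0 * np.log1p(-p), np.log(2.0 * p * (1.0 - p))),
        )
    return float(terms.sum())


def cluster_loglik_matrix(
    data: GenotypeDataset, freqs: ClusterAlleleFreqs
) -> np.ndarray:
    """Per-individual, per-cluster genotype log-likelihoods, shape (N, R).

    This matrix depends only on the data and the fixed cluster frequencies,
    so it is computed once and reused across all parameter draws.
    """
    tables = _hwe_log_tables(freqs)  # (3, R, n_loci)
    N, R = data.n_individuals, freqs.n_clusters
    L = np.zeros((N, R))
    codes = data.codes
    for r in range(R):
        tab = tables[:, r, :]  # (3, n_loci)
        ok = ~np.isnan(freqs.p[r])
        vals = tab[np.clip(codes, 0, 2), np.arange(data.n_loci)[None, :]]
        use = (codes != MISSING) & ok[None, :]
        L[:, r] = np.where(use, vals, 0.0).sum(axis=1)
    return L


def mixture_log_prob(
    codes: np.ndarray, freqs: ClusterAlleleFreqs, mu: np.ndarray
) -> float:
    """Log probability of a genotype under the cluster mixture μτ·(t).

    Computed stably in log space; clusters with zero mixture weight are
    excluded, and the result is -inf only if every admissible cluster rules
    the genotype out.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or abs(mu.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must form a simplex")
    lps = np.array([genotype_log_prob(codes, freqs.p[r]) for r in range(freqs.n_clusters)])
    return _mixture_from_components(lps, mu)


def _mixture_from_components(lps: np.ndarray, mu: np.ndarray) -> float:
    keep = mu > 0
    if not keep.any() or np.all(np.isneginf(lps[keep])):
        return -np.inf
    return float(logsumexp(lps[keep], b=mu[keep]))


class LikelihoodEngine:
    """Precomputed structures for fast repeated likelihood evaluation.

    The genotype x cluster log-likelihood matrix and the (colony, year)
    grouping of individuals are fixed across parameter draws; only the
    projected mixture proportions change with Θ.
    """

    def __init__(
        self,
        data: GenotypeDataset,
        freqs: ClusterAlleleFreqs,
        cmap: ColonyMap,
        forcing: GrowthForcing,
        region_to_cluster: dict,
        t0: int | None = None,
        t1: int | None = None,
        trunc: float = TRUNCATION_MULTIPLIER,
    ):
        self.data = data
        self.freqs = freqs
        self.cmap = cmap
        self.forcing = forcing
        self.region_to_cluster = dict(region_to_cluster)
        self.trunc = trunc
        self.t0 = int(forcing.years[0]) if t0 is None else int(t0)
        self.t1 = (int(data.years.max()) if data.n_individuals else self.t0) if t1 is None else int(t1)
        if data.n_individuals:
            if int(data.years.max()) > self.t1 or int(data.years.min()) < self.t0:
                raise ValueError("sampled years fall outside the projection horizon")
        self.L = cluster_loglik_matrix(data, freqs)
        self.colony_idx = np.array([cmap.index(c) for c in data.colony_ids])
        self.year_idx = data.years - self.t0

    def log_likelihood(self, theta: Theta) -> float:
        """Log-likelihood of Θ: sum over individuals of mixture log-probabilities."""
        _, ctraj = project_clusters(
            self.cmap,
            self.forcing,
            theta,
            self.t0,
            self.t1,
            self.region_to_cluster,
            self.freqs.clusters,
            trunc=self.trunc,
            store_matrices=False,
        )
        nr_i = ctraj.nr[self.colony_idx, :, self.year_idx]  # (N, R)
        if not np.all(np.isfinite(nr_i)):
            # the deterministic dynamics diverged under this draw; treat the
            # draw as impossible rather than propagating non-finite values
            logger.debug("dynamics diverged under this draw; likelihood set to 0")
            return -np.inf
        tot_i = nr_i.sum(axis=1)
        if np.any(tot_i <= EXTINCTION_THRESHOLD):
            logger.debug("a sampled colony is extinct under this draw")
            return -np.inf
        with np.errstate(divide="ignore"):
            A = self.L + np.log(nr_i / tot_i[:, None])
        mx = A.max(axis=1)
        if np.any(np.isneginf(mx)):
            return -np.inf  # some genotype impossible under every admissible cluster
        lp = np.log(np.exp(A - mx[:, None]).sum(axis=1)) + mx
        return float(lp.sum())


def log_likelihood(
    theta: Theta,
    data: GenotypeDataset,
    freqs: ClusterAlleleFreqs,
    cmap: ColonyMap,
    forcing: GrowthForcing,
    region_to_cluster: dict,
    t0: int | None = None,
    t1: int | None = None,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> float:
    """Log-likelihood of the parameter bundle Θ given the genotype data.

    Projects the cluster dynamics once under Θ, then sums the mixture
    log-probability of every genotyped individual evaluated at the mixture
    proportions of its colony and sampling year.
    """
    engine = LikelihoodEngine(
        data, freqs, cmap, forcing, region_to_cluster, t0=t0, t1=t1, trunc=trunc
    )
    return engine.log_likelihood(theta)
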