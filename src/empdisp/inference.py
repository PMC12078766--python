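"""Posterior inference over the dispersal parameters Θ.

Plain prior importance sampling: draw M parameter bundles from the prior
(d uniform, pm uniform per region, each uncharacterized region's μ from a
flat Dirichlet), weight each draw by its likelihood (normalized with a
log-sum-exp shift), and summarize with weighted statistics.  Model
selection across the three dispersal behaviors uses the deviance
information criterion

    DIC = D̂ + V_D / 2,      D(Θ) = -2 log L(Θ),

with posterior mean D̂ and variance V_D estimated from the weighted
sample; lower is better.  Goodness of fit checks whether each observed
genotype lies in the Monte-Carlo 95% highest-probability region of the
fitted genotype mixture at its colony and year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TRUNCATION_MULTIPLIER, emigration_rate
from .errors import DegeneratePosteriorError
from .genetics import (
    LikelihoodEngine,
    _hwe_log_tables,
    _mixture_from_components,
    project_clusters,
)
from .types import (
    Behavior,
    ClusterAlleleFreqs,
    ColonyMap,
    GenotypeDataset,
    GrowthForcing,
    Theta,
)

logger = logging.getLogger(__name__)

ESS_WARN_THRESHOLD = 50.0


@dataclass
class PriorSpec:
    """Prior for the importance sampler.

    d is uniform on ``d_bounds`` (default 250-6,500 km, spanning plausible
    penguin movement scales), each per-region pm is uniform on
    ``pm_bounds`` (default [0, 1]), and each uncharacterized region's μ row
    is Dirichlet of order R with unit concentration.
    """

    n_regions: int
    n_clusters: int
    unknown_regions: tuple = ()
    d_bounds: tuple[float, float] = (250.0, 6500.0)
    pm_bounds: tuple[float, float] = (0.0, 1.0)
    M: int = 5000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.d_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("d bounds must be finite with lower < upper")
        lo, hi = self.pm_bounds
        if not (0 <= lo < hi <= 1):
            raise ValueError("pm bounds must satisfy 0 <= lower < upper <= 1")
        if self.M < 1:
            raise ValueError("need at least one draw")


def sample_prior(spec: PriorSpec, behavior: Behavior | str = Behavior.SEMI_INFORMED) -> list[Theta]:
    """M independent prior draws of Θ, deterministic given ``spec.seed``."""
    behavior = Behavior(behavior)
    rng = np.random.default_rng(spec.seed)
    d = rng.uniform(*spec.d_bounds, size=spec.M)
    pm = rng.uniform(*spec.pm_bounds, size=(spec.M, spec.n_regions))
    mus = {
        reg: rng.dirichlet(np.ones(spec.n_clusters), size=spec.M)
        for reg in spec.unknown_regions
    }
    return [
        Theta(
            d=d[m],
            pm=pm[m],
            behavior=behavior,
            mu_unknown={reg: mus[reg][m] for reg in spec.unknown_regions},
        )
        for m in range(spec.M)
    ]


def importance_weights(loglik: np.ndarray) -> tuple[np.ndarray, float]:
    """Self-normalized importance weights under the flat prior, plus the ESS.

    Weights are proportional to exp(loglik) after a log-sum-exp shift;
    draws with -inf log-likelihood get exactly zero weight.  The effective
    sample size is 1 / Σ w².
    """
    ll = np.asarray(loglik, dtype=float)
    if np.any(np.isnan(ll)):
        raise ValueError("log-likelihoods contain NaN")
    if ll.size == 0 or not np.any(np.isfinite(ll)):
        raise DegeneratePosteriorError(
            "every draw has zero likelihood; the weighted posterior is undefined"
        )
    shift = ll.max()
    w = np.exp(ll - shift)
    w /= w.sum()
    ess = 1.0 / float((w**2).sum())
    return w, ess


@dataclass
class PosteriorSample:
    """Weighted importance-sampling draws for one dispersal behavior."""

    thetas: list[Theta]
    loglik: np.ndarray
    weights: np.ndarray
    ess: float
    behavior: Behavior
    seed: int | None = None

    @property
    def M(self) -> int:
        return len(self.thetas)

    @property
    def deviance(self) -> np.ndarray:
        """D(Θ_m) = -2 log L(Θ_m)."""
        return -2.0 * self.loglik

    def map_theta(self) -> Theta:
        """The draw with maximal log-likelihood."""
        return self.thetas[int(np.argmax(self.loglik))]

    def d_values(self) -> np.ndarray:
        return np.array([th.d for th in self.thetas])

    def pm_values(self) -> np.ndarray:
        return np.array([th.pm for th in self.thetas])


def weighted_percentile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> float | np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the smallest value whose cumulative weight reaches q (in [0,1]).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    idx = np.searchsorted(cw, np.asarray(q) - 1e-12, side="left")
    out = v[np.minimum(idx, v.size - 1)]
    return float(out) if out.ndim == 0 else out


def _wsummary(values: np.ndarray, w: np.ndarray) -> dict:
    mean = float(np.sum(w * values))
    lo, med, hi = weighted_percentile(values, w, np.array([0.025, 0.5, 0.975]))
    return {"mean": mean, "median": float(med), "ci95": (float(lo), float(hi))}


def posterior_emigration_draws(
    sample: PosteriorSample, cmap: ColonyMap, forcing: GrowthForcing
) -> np.ndarray:
    """Posterior draws of the realized emigration rates m_it.

    Shape (M, n_colonies, n_years): each parameter draw induces one full
    colony-by-year emigration-rate field through the departure rule.
    """
    T = forcing.years.size
    out = np.empty((sample.M, cmap.n_colonies, T))
    reg = cmap.region_index
    for m, th in enumerate(sample.thetas):
        out[m] = emigration_rate(
            forcing.r, th.pm[reg][:, None], forcing.rc_star, th.behavior
        )
    return out


def posterior_summary(
    sample: PosteriorSample,
    cmap: ColonyMap | None = None,
    forcing: GrowthForcing | None = None,
) -> dict:
    """Weighted posterior means, medians and 95% credible intervals.

    With a colony map and forcing, also summarizes the posterior of the
    colony-year emigration rates m_it and their grand mean.
    """
    w = sample.weights
    out: dict = {
        "behavior": sample.behavior.value,
        "ess": sample.ess,
        "d": _wsummary(sample.d_values(), w),
        "pm": [
            _wsummary(sample.pm_values()[:, j], w)
            for j in range(sample.pm_values().shape[1])
        ],
    }
    regs = sorted({reg for th in sample.thetas for reg in th.mu_unknown})
    mu_out = {}
    for reg in regs:
        rows = np.array([th.mu_unknown[reg] for th in sample.thetas])
        mu_out[reg] = [_wsummary(rows[:, r], w) for r in range(rows.shape[1])]
    out["mu_unknown"] = mu_out
    if cmap is not None and forcing is not None:
        m_draws = posterior_emigration_draws(sample, cmap, forcing)
        out["m_it"] = {
            "mean": np.tensordot(w, m_draws, axes=1),
            "median": np.stack(
                [
                    weighted_percentile(m_draws[:, i, t], w, 0.5)
                    for i in range(cmap.n_colonies)
                    for t in range(forcing.years.size)
                ]
            ).reshape(cmap.n_colonies, forcing.years.size),
        }
        out["mean_emigration_rate"] = _wsummary(m_draws.mean(axis=(1, 2)), w)
    return out


def dic(sample: PosteriorSample) -> float:
    """Deviance information criterion D̂ + V_D/2 from the weighted sample."""
    if sample.ess <= 1.0 + 1e-9:
        warnings.warn(
            "effective sample size <= 1: the deviance variance is not meaningful",
            stacklevel=2,
        )
    w = sample.weights
    finite = np.isfinite(sample.loglik)
    D = sample.deviance[finite]
    wf = w[finite]
    dbar = float(np.sum(wf * D))
    vd = float(np.sum(wf * (D - dbar) ** 2))
    return dbar + 0.5 * vd


def fit_behavior(
    data: GenotypeDataset,
    freqs: ClusterAlleleFreqs,
    cmap: ColonyMap,
    forcing: GrowthForcing,
    region_to_cluster: dict,
    spec: PriorSpec,
    behavior: Behavior | str,
    t0: int | None = None,
    t1: int | None = None,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> PosteriorSample:
    """Importance-sampling fit of one dispersal behavior."""
    behavior = Behavior(behavior)
    engine = LikelihoodEngine(
        data, freqs, cmap, forcing, region_to_cluster, t0=t0, t1=t1, trunc=trunc
    )
    thetas = sample_prior(spec, behavior)
    ll = np.array([engine.log_likelihood(th) for th in thetas])
    w, ess = importance_weights(ll)
    if ess < ESS_WARN_THRESHOLD:
        warnings.warn(
            f"effective sample size {ess:.1f} < {ESS_WARN_THRESHOLD:.0f} for "
            f"behavior {behavior.value}; consider more draws",
            stacklevel=2,
        )
    return PosteriorSample(
        thetas=thetas, loglik=ll, weights=w, ess=ess, behavior=behavior, seed=spec.seed
    )


@dataclass
class FitReport:
    """Per-behavior DIC comparison plus summaries for the selected behavior."""

    dic: dict
    selected: Behavior
    samples: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def select_behavior(
    data: GenotypeDataset,
    freqs: ClusterAlleleFreqs,
    cmap: ColonyMap,
    forcing: GrowthForcing,
    region_to_cluster: dict,
    spec: PriorSpec,
    behaviors: tuple = (Behavior.RANDOM, Behavior.SEMI_INFORMED, Behavior.INFORMED),
    t0: int | None = None,
    t1: int | None = None,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> FitReport:
    """Fit every candidate behavior and rank them by DIC.

    Each behavior reuses the same prior seed so DIC differences reflect
    model structure rather than sampling noise.  A behavior whose draws all
    have zero likelihood is reported with infinite DIC.
    """
    dics: dict = {}
    samples: dict = {}
    summaries: dict = {}
    notes: list = []
    for b in behaviors:
        b = Behavior(b)
        try:
            s = fit_behavior(
                data, freqs, cmap, forcing, region_to_cluster, spec, b, t0, t1, trunc
            )
        except DegeneratePosteriorError:
            dics[b] = np.inf
            notes.append(f"behavior {b.value}: degenerate posterior (all draws impossible)")
            logger.warning("behavior %s: degenerate posterior", b.value)
            continue
        samples[b] = s
        dics[b] = dic(s)
        summaries[b] = posterior_summary(s, cmap, forcing)
    if freqs.n_clusters == 1:
        notes.append(
            "single genetic cluster: the mixture degenerates and all behaviors "
            "share the same likelihood (non-identifiable)"
        )
    selected = min(dics, key=lambda b: dics[b])
    return FitReport(
        dic=dics, selected=selected, samples=samples, summaries=summaries, notes=notes
    )


def simulate_genotypes_from_mixture(
    rng: np.random.Generator,
    mu: np.ndarray,
    p: np.ndarray,
    n: int,
    locus_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n genotypes from a fitted cluster mixture.

    Returns ``(codes, clusters)`` where codes has shape (n, n_loci) with -1
    at masked-out loci.
    """
    R, L = p.shape
    clusters = rng.choice(R, size=n, p=mu)
    pm = np.nan_to_num(p[clusters], nan=0.5)
    codes = rng.binomial(2, pm).astype(np.int8)
    if locus_mask is not None:
        codes[:, ~locus_mask] = -1
    return codes, clusters


def _mixture_loglik_batch(
    codes: np.ndarray, tables: np.ndarray, mu: np.ndarray, locus_mask: np.ndarray
) -> np.ndarray:
    """Mixture log-probabilities of a batch of genotypes, shape (n,)."""
    n, L = codes.shape
    R = tables.shape[1]
    comp = np.empty((n, R))
    cols = np.arange(L)[None, :]
    cc = np.clip(codes, 0, 2)
    for r in range(R):
        vals = tables[cc, r, cols]
        use = (codes >= 0) & locus_mask[None, :]
        comp[:, r] = np.where(use, vals, 0.0).sum(axis=1)
    out = np.empty(n)
    keep = mu > 0
    with np.errstate(invalid="ignore"):
        shifted = comp[:, keep]
        mx = shifted.max(axis=1)
        safe_mx = np.where(np.isfinite(mx), mx, 0.0)
        s = np.sum(mu[keep][None, :] * np.exp(shifted - safe_mx[:, None]), axis=1)
        with np.errstate(divide="ignore"):
            out = np.where(np.isfinite(mx), np.log(s) + safe_mx, -np.inf)
    return out


def goodness_of_fit(
    theta_hat: Theta,
    data: GenotypeDataset,
    freqs: ClusterAlleleFreqs,
    cmap: ColonyMap,
    forcing: GrowthForcing,
    region_to_cluster: dict,
    S: int = 2000,
    seed: int = 0,
    t0: int | None = None,
    t1: int | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo 95% confidence-region check for every observed genotype.

    For each individual, S genotypes are simulated from the fitted mixture
    at its colony and sampling year (cluster from μ̂, genotype under HWE,
    restricted to the individual's observed loci).  The confidence region
    is the set of genotypes whose mixture log-probability reaches the
    empirical ``alpha`` quantile of the simulated log-probabilities; the
    function returns per-individual inside flags and the covered fraction.
    """
    if S < 100:
        raise ValueError("need at least 100 simulations per individual")
    rng = np.random.default_rng(seed)
    t0 = int(forcing.years[0]) if t0 is None else int(t0)
    t1 = int(data.years.max()) if t1 is None else int(t1)
    _, ctraj = project_clusters(
        cmap, forcing, theta_hat, t0, t1, region_to_cluster, freqs.clusters
    )
    nr = ctraj.nr
    tot = nr.sum(axis=1)
    tables = _hwe_log_tables(freqs)  # (3, R, n_loci)
    inside = np.zeros(data.n_individuals, dtype=bool)
    for i in range(data.n_individuals):
        ci = cmap.index(data.colony_ids[i])
        ti = data.years[i] - t0
        n_here = tot[ci, ti]
        if n_here <= 0:
            logger.warning(
                "individual %s: colony empty under fitted model; flagged outside",
                data.individual_ids[i],
            )
            continue
        mu = np.clip(nr[ci, :, ti] / n_here, 0.0, None)
        mu /= mu.sum()
        obs_mask = (data.codes[i] != -1) & ~np.isnan(freqs.p).all(axis=0)
        sim_codes, _ = simulate_genotypes_from_mixture(
            rng, mu, freqs.p, S, locus_mask=obs_mask
        )
        sim_lp = _mixture_loglik_batch(sim_codes, tables, mu, obs_mask)
        obs_lp = _mixture_loglik_batch(
            data.codes[i][None, :], tables, mu, obs_mask
        )[0]
        if np.isneginf(obs_lp):
            logger.warning(
                "individual %s: genotype impossible under every fitted cluster",
                data.individual_ids[i],
            )
            continue
        threshold = np.quantile(sim_lp, alpha)
        inside[i] = obs_lp >= threshold
    return inside, float(inside.mean())
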