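"""Annual metapopulation dynamics: Ricker reproduction then dispersal.

The female population vector n is updated each year as

    n(t+1) = D(t) F(t, n(t)) n(t)

where F is a diagonal Ricker reproduction matrix with colony-specific
growth rates r_it and carrying capacities K_i, and D is a column-stochastic
dispersal matrix built from the behavior-dependent emigration rates m_it
and a settlement distribution over colonies within dispersal range.
Dispersal conserves individuals exactly; abundances are continuous
(deterministic expected dynamics, no demographic stochasticity).
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ForcingGapError, InvalidForcingError
from .types import Behavior, ColonyMap, GrowthForcing, MetapopTrajectory, Theta

logger = logging.getLogger(__name__)

#: Settlement candidates are colonies within TRUNCATION_MULTIPLIER * d of the
#: source (an exponential kernel with mean d keeps ~95% of its mass below 3d).
TRUNCATION_MULTIPLIER = 3.0


def reproduction_step(n: np.ndarray, r_t: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Apply the diagonal Ricker reproduction matrix: f_i = exp(r_it (1 - n_i/K_i))."""
    n = np.asarray(n, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    K = np.asarray(K, dtype=float)
    if not (n.shape == r_t.shape == K.shape):
        raise ValueError(
            f"shape mismatch: n {n.shape}, r {r_t.shape}, K {K.shape}"
        )
    if np.any(K <= 0):
        raise ValueError("carrying capacities must be positive")
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    return n * np.exp(r_t * (1.0 - n / K))


def emigration_rate(
    r_it: np.ndarray | float,
    pm_i: np.ndarray | float,
    rc_star: float,
    behavior: Behavior | str,
) -> np.ndarray | float:
    """Annual emigration rate m_it in [0, 1].

    Random behavior: a fixed rate m = pm_i regardless of habitat quality.

    Informed (and semi-informed) emigration: individuals leave only when the
    local growth rate is negative, at

        m = min(1, r_it / ((1 - pm_i) rc_star))        for r_it < 0,

    so departure scales with the habitat-quality ratio r_it/rc_star and the
    per-region sensitivity pm_i: pm_i -> 1 makes even minor degradation
    trigger full emigration, pm_i = 0 gives the gradual response r_it/rc_star.
    """
    behavior = Behavior(behavior)
    r = np.asarray(r_it, dtype=float)
    pm = np.asarray(pm_i, dtype=float)
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("pm must lie in [0, 1]")
    if behavior is Behavior.RANDOM:
        out = np.broadcast_arrays(r, pm)[1].copy()
    else:
        rc_star = float(rc_star)
        if rc_star >= 0:
            raise InvalidForcingError(
                f"informed emigration requires a negative worst-case rate, got {rc_star:g}"
            )
        with np.errstate(divide="ignore"):
            ratio = r / ((1.0 - pm) * rc_star)  # pm = 1 -> +inf -> clipped to 1
        out = np.where(r < 0, np.minimum(ratio, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _candidate_mask(dist: np.ndarray, d: float, trunc: float) -> np.ndarray:
    """mask[i, j]: colony i is a settlement candidate for emigrants from j."""
    mask = dist <= trunc * d
    np.fill_diagonal(mask, False)
    return mask


def kernel_settlement_matrix(
    dist: np.ndarray, d: float, trunc: float = TRUNCATION_MULTIPLIER
) -> np.ndarray:
    """Random-settlement matrix S: S[i, j] = P(emigrant from j settles in i).

    Candidates are colonies within ``trunc * d`` of the source; weights decay
    as exp(-dist/d) (exponential kernel with mean d).  A source with no
    candidate in range keeps its emigrants (S[j, j] = 1).
    """
    if d <= 0:
        raise ValueError("dispersal distance must be positive")
    mask = _candidate_mask(dist, d, trunc)
    W = np.where(mask, np.exp(-dist / d), 0.0)
    colsum = W.sum(axis=0)
    empty = colsum == 0.0
    if np.any(empty):
        logger.warning(
            "%d colonies have no settlement candidate within %.0f km; "
            "their emigrants stay home",
            int(empty.sum()),
            trunc * d,
        )
    S = np.divide(W, np.where(empty, 1.0, colsum), out=W)
    S[np.diag_indices_from(S)] = np.where(empty, 1.0, 0.0)
    return S


def informed_settlement_matrix(
    dist: np.ndarray,
    d: float,
    r_t: np.ndarray,
    trunc: float = TRUNCATION_MULTIPLIER,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Informed-settlement matrix: unit mass on the best-growth candidate.

    Ties on growth rate are broken by smaller distance, then lower colony
    index.  A source with no candidate keeps its emigrants.
    """
    if mask is None:
        mask = _candidate_mask(dist, d, trunc)
    n = dist.shape[0]
    rcol = np.where(mask, r_t[:, None], -np.inf)
    rmax = rcol.max(axis=0)
    empty = np.isneginf(rmax)
    tied = rcol == rmax  # all-False column where empty
    dtie = np.where(tied, dist, np.inf)
    dmin = dtie.min(axis=0)
    winner = (tied & (dtie == dmin)).argmax(axis=0)  # argmax -> lowest index
    S = np.zeros((n, n))
    cols = np.arange(n)
    S[np.where(empty, cols, winner), cols] = 1.0
    return S


def settlement_distribution(
    cmap: ColonyMap,
    source: int,
    d: float,
    r_t: np.ndarray,
    behavior: Behavior | str,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> np.ndarray:
    """Probability distribution over destination colonies for one source colony."""
    behavior = Behavior(behavior)
    if behavior is Behavior.INFORMED:
        S = informed_settlement_matrix(cmap.dist, d, np.asarray(r_t, float), trunc)
    else:
        S = kernel_settlement_matrix(cmap.dist, d, trunc)
    return S[:, source]


def dispersal_matrix(
    cmap: ColonyMap,
    r_t: np.ndarray,
    theta: Theta,
    rc_star: float,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> np.ndarray:
    """Column-stochastic dispersal matrix for one year.

    Column j holds the destination distribution of colony j's residents:
    1 - m_j stays, m_j is spread over the settlement distribution.
    """
    r_t = np.asarray(r_t, dtype=float)
    m = emigration_rate(r_t, theta.pm[cmap.region_index], rc_star, theta.behavior)
    if theta.behavior is Behavior.INFORMED:
        S = informed_settlement_matrix(cmap.dist, theta.d, r_t, trunc)
    else:
        S = kernel_settlement_matrix(cmap.dist, theta.d, trunc)
    return _assemble_dispersal(S, m)


def _assemble_dispersal(S: np.ndarray, m: np.ndarray) -> np.ndarray:
    D = S * m[None, :]
    idx = np.diag_indices_from(D)
    # where S routes emigrants back to the source (no candidates) the
    # diagonal already carries m, so the column still sums to one
    D[idx] += 1.0 - m
    return D


def step(
    n: np.ndarray,
    t: int,
    cmap: ColonyMap,
    forcing: GrowthForcing,
    theta: Theta,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> np.ndarray:
    """One annual update: reproduction then dispersal."""
    r_t = forcing.r_at(t)
    grown = reproduction_step(np.asarray(n, float), r_t, cmap.K)
    D = dispersal_matrix(cmap, r_t, theta, forcing.rc_star, trunc)
    return D @ grown


def _iterate(
    cmap: ColonyMap,
    forcing: GrowthForcing,
    theta: Theta,
    t0: int,
    t1: int,
    nr0: np.ndarray | None = None,
    trunc: float = TRUNCATION_MULTIPLIER,
    store_matrices: bool = True,
):
    """Shared projection engine.

    Returns ``(trajectory, nr_history)`` where ``nr_history`` is the
    cluster-resolved abundance array (n_colonies, R, T+1) when ``nr0`` is
    given, else None.  Cluster vectors are advanced with the *same* F and D
    operators as the total population (neutral markers: dispersal and
    reproduction are independent of genetic background).
    """
    missing = forcing.covers(t0, t1)
    if missing:
        raise ForcingGapError(missing)
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    T = t1 - t0
    nc = cmap.n_colonies
    n_hist = np.empty((nc, T + 1))
    m_hist = np.empty((nc, T))
    D_hist = np.empty((T, nc, nc)) if store_matrices else None
    n = cmap.n0.astype(float).copy()
    n_hist[:, 0] = n
    nr = None
    nr_hist = None
    if nr0 is not None:
        nr = np.asarray(nr0, dtype=float).copy()
        nr_hist = np.empty((nc, nr.shape[1], T + 1))
        nr_hist[:, :, 0] = nr

    informed = theta.behavior is Behavior.INFORMED
    pm_col = theta.pm[cmap.region_index]
    # the random-settlement kernel depends only on distances and d
    S_static = None
    if not informed:
        S_static = kernel_settlement_matrix(cmap.dist, theta.d, trunc)

    # extreme parameter draws can make the Ricker update diverge (a colony
    # pushed far above K with negative growth); overflow is tolerated here
    # and such draws are rejected by the likelihood
    err = np.errstate(over="ignore", invalid="ignore")
    err.__enter__()
    for k, t in enumerate(range(t0, t1)):
        r_t = forcing.r_at(t)
        m = emigration_rate(r_t, pm_col, forcing.rc_star, theta.behavior)
        m = np.asarray(m, dtype=float)
        if informed:
            S = informed_settlement_matrix(cmap.dist, theta.d, r_t, trunc)
        else:
            S = S_static
        D = _assemble_dispersal(S, m)
        f = np.exp(r_t * (1.0 - n / cmap.K))
        n = D @ (f * n)
        n_hist[:, k + 1] = n
        m_hist[:, k] = m
        if D_hist is not None:
            D_hist[k] = D
        if nr is not None:
            nr = D @ (f[:, None] * nr)
            nr_hist[:, :, k + 1] = nr
    err.__exit__(None, None, None)

    traj = MetapopTrajectory(
        years=np.arange(t0, t1 + 1),
        n=n_hist,
        m=m_hist,
        D=D_hist if D_hist is not None else np.empty((0, nc, nc)),
        colony_ids=list(cmap.ids),
    )
    return traj, nr_hist


def project(
    cmap: ColonyMap,
    forcing: GrowthForcing,
    theta: Theta,
    t0: int,
    t1: int,
    trunc: float = TRUNCATION_MULTIPLIER,
    store_matrices: bool = True,
) -> MetapopTrajectory:
    """Deterministic projection of colony abundances from year t0 to t1."""
    traj, _ = _iterate(
        cmap, forcing, theta, t0, t1, trunc=trunc, store_matrices=store_matrices
    )
    return traj


def no_dispersal_theta(theta: Theta) -> Theta:
    """A copy of theta with dispersal switched off (random behavior, pm = 0)."""
    return Theta(
        d=theta.d,
        pm=np.zeros_like(theta.pm),
        behavior=Behavior.RANDOM,
        mu_unknown=dict(theta.mu_unknown),
    )


def forecast_scenarios(
    cmap: ColonyMap,
    scenario_forcings: dict[str, GrowthForcing],
    theta: Theta,
    t0: int,
    t1: int,
    reference: str | None = None,
    trunc: float = TRUNCATION_MULTIPLIER,
) -> dict:
    """Multi-decade projections under named forcing scenarios.

    For each scenario the total population is projected with dispersal
    (``theta``) and without dispersal, and the percentage difference series
    100 (N_disp - N_nodisp) / N_nodisp is reported.  If ``reference`` names a
    scenario, the dispersal totals of every other scenario are additionally
    compared against it on the same percentage scale.
    """
    if reference is not None and reference not in scenario_forcings:
        raise KeyError(f"unknown reference scenario {reference!r}")
    theta0 = no_dispersal_theta(theta)
    out: dict = {}
    for name, forcing in scenario_forcings.items():
        traj = project(cmap, forcing, theta, t0, t1, trunc, store_matrices=False)
        traj0 = project(cmap, forcing, theta0, t0, t1, trunc, store_matrices=False)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * (traj.total - traj0.total) / traj0.total
        out[name] = {
            "trajectory": traj,
            "trajectory_no_dispersal": traj0,
            "total": traj.total,
            "total_no_dispersal": traj0.total,
            "pct_diff_dispersal": pct,
        }
    if reference is not None:
        ref_total = out[reference]["total"]
        for name in out:
            with np.errstate(invalid="ignore", divide="ignore"):
                out[name]["pct_diff_vs_reference"] = (
                    100.0 * (out[name]["total"] - ref_total) / ref_total
                )
    return out
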