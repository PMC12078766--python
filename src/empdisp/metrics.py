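"""Emigration classifications and regional flow summaries.

Colonies are classified each year as "Emigration" (posterior median
emigration rate strictly positive) or "No emigration" (median exactly
zero); the average emigration probability of a colony is the proportion
of window years in which it is classified "Emigration".  Regional flows
average, over window years and source colonies of a region, the fraction
of residents that emigrate and settle in each destination region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import weighted_percentile
from .types import ColonyMap, MetapopTrajectory

DEFAULT_WINDOW = (2009, 2013)


@dataclass
class EmigrationClassification:
    """Posterior-median emigration rates and the binary per-year classes."""

    colony_ids: list[str]
    years: np.ndarray
    median_m: np.ndarray  # (n_colonies, n_years)
    emigrating: np.ndarray  # bool, median > 0

    def to_frame(self) -> pd.DataFrame:
        n_col, n_t = self.median_m.shape
        return pd.DataFrame(
            {
                "colony_id": np.repeat(self.colony_ids, n_t),
                "year": np.tile(self.years, n_col),
                "median_m": self.median_m.ravel(),
                "class": np.where(
                    self.emigrating.ravel(), "Emigration", "No emigration"
                ),
            }
        )


def classify_emigration(
    m_draws: np.ndarray,
    weights: np.ndarray,
    colony_ids: list[str],
    years: np.ndarray,
) -> EmigrationClassification:
    """Classify each colony-year by the sign of its weighted posterior median m_it.

    ``m_draws`` has shape (M, n_colonies, n_years): one emigration-rate
    field per posterior draw of the full parameter vector.
    """
    M, n_col, n_t = m_draws.shape
    if M < 1:
        raise ValueError("need at least one posterior draw")
    med = np.empty((n_col, n_t))
    for i in range(n_col):
        for t in range(n_t):
            med[i, t] = weighted_percentile(m_draws[:, i, t], weights, 0.5)
    return EmigrationClassification(
        colony_ids=list(colony_ids),
        years=np.asarray(years, dtype=int),
        median_m=med,
        emigrating=med > 0,
    )


def emigration_metrics(
    classification: EmigrationClassification,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-colony average emigration probability over a year window.

    The average is the proportion of window years in which the colony is
    classified "Emigration".
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty window")
    in_win = (classification.years >= lo) & (classification.years <= hi)
    if not in_win.any():
        raise ValueError(
            f"window {lo}-{hi} outside classified years "
            f"{classification.years[0]}-{classification.years[-1]}"
        )
    frac = classification.emigrating[:, in_win].mean(axis=1)
    return pd.DataFrame(
        {
            "colony_id": classification.colony_ids,
            "avg_emigration_prob": frac,
        }
    )


def regional_flows(
    trajectory: MetapopTrajectory,
    cmap: ColonyMap,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Region-to-region mean annual emigration-rate matrix.

    flow[A, B] is the mean, over window years and source colonies j in A,
    of the per-capita rate at which residents of j emigrate and settle in
    region B (within-region flow excludes the source colony itself).
    Requires a trajectory with stored dispersal matrices.
    """
    if trajectory.D.shape[0] == 0:
        raise ValueError("trajectory has no stored dispersal matrices")
    years = trajectory.years[:-1]  # D[k] acts on step years[k] -> years[k+1]
    if window is None:
        in_win = np.ones(years.size, dtype=bool)
    else:
        lo, hi = window
        in_win = (years >= lo) & (years <= hi)
        if not in_win.any():
            raise ValueError(f"window {lo}-{hi} outside trajectory years")
    regions = cmap.regions
    reg_idx = cmap.region_index
    n_reg = len(regions)
    flow = np.zeros((n_reg, n_reg))
    D_sel = trajectory.D[in_win]
    off = D_sel.copy()
    idx = np.arange(cmap.n_colonies)
    off[:, idx, idx] = 0.0  # off-diagonal column j = m_j * settlement shares
    # mean over years of, for each source colony, the mass landing in each region
    land = np.zeros((cmap.n_colonies, n_reg))
    for b in range(n_reg):
        rows = reg_idx == b
        land[:, b] = off[:, rows, :].sum(axis=1).mean(axis=0)
    for a in range(n_reg):
        cols = reg_idx == a
        flow[a] = land[cols].mean(axis=0)
    return pd.DataFrame(flow, index=regions, columns=regions)
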