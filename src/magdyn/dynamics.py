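"""Community-weighted functional capacity trajectories across treatments.

The community-weighted mean (CWM) capacity of a sample for one metabolic
function is the abundance-weighted average of the per-MAG metabolic
capacity indices, CWM_f = sum_i p_i * MCI(i, f).  Rare MAGs are removed
first with a prevalence filter (default: at least 0.1% relative abundance
in at least one sample).

Per (function, treatment) the trajectory point estimate is the mean CWM
across individuals, with a percentile bootstrap interval obtained by
resampling *individuals* with replacement — the individual, not the
sample, is the exchangeable unit in a repeated-measures design.
Consecutive treatments whose intervals do not overlap are flagged as
directional shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "filter_prevalent",
    "community_weighted_means",
    "CwmTrajectories",
    "TrajectoryResults",
    "treatment_intervals",
    "detect_shifts",
]


def filter_prevalent(abund: AbundanceTable, threshold: float = 0.001) -> AbundanceTable:
    """Keep MAGs reaching ``threshold`` relative abundance in >= 1 sample.

    Input must be (or is re-closed to) relative mode; surviving rows are
    re-closed to sum 1.
    """
    rel = abund.to_relative()
    colmax = rel.df.max(axis=0)
    keep = colmax >= threshold
    if not keep.any():
        raise ValueError(f"prevalence filter at {threshold} removed every MAG")
    out = rel.df.loc[:, keep]
    sums = out.sum(axis=1)
    out = out.div(sums.where(sums > 0, 1.0), axis=0)
    return AbundanceTable(out, "relative")


def community_weighted_means(
    abund: AbundanceTable | pd.DataFrame, mci: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample CWM of every function column in ``mci`` (samples x functions)."""
    df = abund.to_relative().df if isinstance(abund, AbundanceTable) else abund
    missing = [m for m in df.columns if m not in mci.index]
    if missing:
        raise KeyError(f"MAGs without MCI rows: {missing}")
    T = mci.loc[df.columns]
    return df @ T


@dataclass(frozen=True)
class CwmTrajectory:
    function_id: str
    treatment: str
    cwm_mean: float
    interval_low: float
    interval_high: float
    n_samples: int
    defined: bool = True


@dataclass
class TrajectoryResults:
    """Per (function, treatment) CWM means with bootstrap intervals."""

    table: pd.DataFrame
    level: float
    n_boot: int
    treatment_order: list

    def summary(self) -> pd.DataFrame:
        return self.table

    def shifts(self) -> pd.DataFrame:
        return detect_shifts(self)


class CwmTrajectories:
    """Model for treatment-level CWM trajectories with bootstrap intervals.

    Parameters
    ----------
    cwm : DataFrame
        Sample x function CWM table (e.g. from
        :func:`community_weighted_means`).
    metadata : DataFrame
        Sample metadata with sample_id, individual_id, treatment and
        time_index columns; defines the resampling unit and the
        chronological treatment order.
    resample_unit : str
        Metadata column naming the bootstrap resampling unit; default
        ``"individual_id"``.  Use ``"cage_id"`` for cage-clustered designs.
    """

    def __init__(self, cwm: pd.DataFrame, metadata: pd.DataFrame,
                 resample_unit: str = "individual_id"):
        meta = metadata.set_index("sample_id")
        if resample_unit not in meta.columns:
            raise ValueError(f"metadata has no {resample_unit!r} column")
        self.resample_unit = resample_unit
        missing = [s for s in cwm.index if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        self.cwm = cwm
        self.meta = meta.loc[cwm.index]
        order = (
            self.meta.groupby("treatment")["time_index"].min().sort_values().index
        )
        self.treatment_order = list(order)

    def fit(self, n_boot: int = 2000, level: float = 0.90, seed=None) -> TrajectoryResults:
        rng = np.random.default_rng(seed)
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        for treatment in self.treatment_order:
            samples = self.meta.index[self.meta["treatment"] == treatment]
            sub = self.cwm.loc[samples]
            units = self.meta.loc[samples, self.resample_unit]
            # mean CWM per resampling unit within the treatment, then across units
            ind_means = sub.groupby(units.to_numpy()).mean()
            point = ind_means.mean(axis=0)
            n_ind = len(ind_means)
            if n_ind < 2:
                warnings.warn(
                    f"treatment {treatment!r} has <2 individuals: interval undefined"
                )
                for fn in self.cwm.columns:
                    rows.append(
                        CwmTrajectory(fn, treatment, float(point[fn]), np.nan, np.nan,
                                      len(sub), defined=False)
                    )
                continue
            M = ind_means.to_numpy()
            idx = rng.integers(0, n_ind, size=(n_boot, n_ind))
            boot = M[idx].mean(axis=1)  # n_boot x n_functions
            lows = np.quantile(boot, lo_q, axis=0)
            highs = np.quantile(boot, hi_q, axis=0)
            for j, fn in enumerate(self.cwm.columns):
                rows.append(
                    CwmTrajectory(
                        fn, treatment, float(point[fn]),
                        float(min(lows[j], point[fn])),
                        float(max(highs[j], point[fn])),
                        len(sub),
                    )
                )
        table = pd.DataFrame([r.__dict__ for r in rows])
        return TrajectoryResults(
            table=table, level=level, n_boot=n_boot, treatment_order=self.treatment_order
        )


def treatment_intervals(
    cwm: pd.DataFrame,
    metadata: pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.90,
    seed=None,
) -> TrajectoryResults:
    """Convenience wrapper: build and fit :class:`CwmTrajectories`."""
    return CwmTrajectories(cwm, metadata).fit(n_boot=n_boot, level=level, seed=seed)


def detect_shifts(trajectories: TrajectoryResults) -> pd.DataFrame:
    """Flag consecutive treatment pairs whose intervals do not overlap.

    Returns one row per (function, consecutive treatment pair) with a
    boolean ``shift`` flag and the sign of the mean difference.  Pairs with
    undefined intervals are skipped with a warning.
    """
    t = trajectories.table
    order = trajectories.treatment_order
    rows = []
    for fn, sub in t.groupby("function_id", sort=False):
        sub = sub.set_index("treatment")
        for a, b in zip(order[:-1], order[1:]):
            ra, rb = sub.loc[a], sub.loc[b]
            if not (ra["defined"] and rb["defined"]):
                warnings.warn(f"undefined interval: pair ({a}, {b}) skipped for {fn}")
                continue
            no_overlap = (
                rb["interval_low"] > ra["interval_high"]
                or ra["interval_low"] > rb["interval_high"]
            )
            diff = rb["cwm_mean"] - ra["cwm_mean"]
            rows.append(
                {
                    "function_id": fn,
                    "from_treatment": a,
                    "to_treatment": b,
                    "shift": bool(no_overlap),
                    "direction": int(np.sign(diff)),
                    "difference": float(diff),
                }
            )
    return pd.DataFrame(rows)
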