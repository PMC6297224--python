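"""Survival classification and bulk-culture statistics.

Implements the ROC analysis used to ask whether a cell's state just before
a stress pulse predicts whether it survives: growth rate classifies
pass-if-below (slow cells pass), promoter activity pass-if-above.  The
true/false positive rates are computed per threshold as the fraction of
surviving / non-surviving cells past the threshold, the AUC by trapezoidal
integration, and the optimal threshold as the maximizer of TPR - FPR.

Also provides the CFU survival-fraction estimator with the 30-300
colonies-per-plate dynamic-range filter, exponential bulk growth-rate fits
to OD series, and the scaling fit that overlays simulated mean RpoS
concentration on experimental reporter medians as functions of population
growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RocCurve",
    "roc_curve",
    "cfu_survival_fraction",
    "bulk_growth_rate",
    "efficacy_scaling_fit",
    "CFU_MIN",
    "CFU_MAX",
]

#: dynamic range of the plate-count assay (colonies per plate, inclusive)
CFU_MIN, CFU_MAX = 30, 300


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    direction: str  # "below" | "above"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_curve(values, survived, direction: str = "below") -> RocCurve:
    """ROC curve of a scalar classifier of survival.

    ``direction="below"`` means a cell passes a threshold when its value is
    strictly below it (growth rate: slow cells pass); ``"above"`` the
    opposite (activity: high-activity cells pass).  Thresholds sweep all
    distinct values plus +/-inf sentinels so the curve runs from (0, 0) to
    (1, 1).  TPR(thr) = fraction of survivors past thr, FPR(thr) =
    fraction of non-survivors past thr.  AUC is the trapezoidal integral
    of TPR over FPR; the optimal threshold maximizes TPR - FPR, with ties
    broken toward the less permissive threshold (fewer cells passing).
    """
    values = np.asarray(values, dtype=float)
    survived = np.asarray(survived).astype(bool)
    if len(values) != len(survived):
        raise ValueError("values and labels must have equal length")
    n_pos = int(survived.sum())
    n_neg = int((~survived).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both survivors and non-survivors are required")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")

    uniq = np.unique(values)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    if direction == "below":
        passes = values[None, :] < thresholds[:, None]
        # permissiveness grows with the threshold: already sorted
    else:
        passes = values[None, :] > thresholds[:, None]
        thresholds = thresholds[::-1]
        passes = passes[::-1]
    tpr = passes[:, survived].mean(axis=1)
    fpr = passes[:, ~survived].mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax takes the first = least permissive
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    optimal_threshold=float(thresholds[best]),
                    direction=direction)


def cfu_survival_fraction(plates: pd.DataFrame,
                          count_range=(CFU_MIN, CFU_MAX),
                          include_mask: np.ndarray | None = None) -> float:
    """Survival fraction from colony counts: stressed / control cells per mL.

    ``plates`` needs columns (arm, dilution, count, plated_volume_ml) with
    arms "stressed" and "control".  Each arm's viable density is the mean
    of count * dilution / plated_volume over plates whose raw count lies
    in the assay's dynamic range (30-300 colonies inclusive by default).
    ``include_mask`` optionally restricts the rows considered (e.g. to
    re-run excluding ambiguous plates).
    """
    df = plates if include_mask is None else plates[np.asarray(include_mask)]
    lo, hi = count_range
    densities = {}
    for arm in ("stressed", "control"):
        sub = df[(df["arm"] == arm) & (df["count"] >= lo) & (df["count"] <= hi)]
        if len(sub) == 0:
            raise ValueError(f"no plate with {lo}-{hi} colonies in the "
                             f"'{arm}' arm")
        densities[arm] = float(np.mean(
            sub["count"] * sub["dilution"] / sub["plated_volume_ml"]))
    return densities["stressed"] / densities["control"]


def bulk_growth_rate(od: pd.DataFrame) -> float:
    """Exponential growth rate (1/h) from an OD series: slope of log OD vs t."""
    t = np.asarray(od["time_h"], dtype=float)
    y = np.asarray(od["od"], dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 OD points")
    if np.any(y <= 0):
        raise ValueError("OD values must be positive for a log-linear fit")
    slope, _ = np.polyfit(t, np.log(y), 1)
    return float(slope)


def _exp_fit(g: np.ndarray, y: np.ndarray):
    """Least-squares fit of y = a * exp(b * g) via log-linear regression."""
    if np.any(y <= 0):
        raise ValueError("values must be positive for an exponential fit")
    b, log_a = np.polyfit(g, np.log(y), 1)
    return float(np.exp(log_a)), float(b)


def efficacy_scaling_fit(exp_medians: pd.DataFrame,
                         sim_means: pd.DataFrame,
                         g_range=(0.29, 1.6),
                         n_grid: int = 1000):
    """Scale simulated RpoS concentration onto experimental reporter medians.

    Both inputs are tables of (g_pop, value) pairs: experimental reporter
    medians and simulated mean concentrations at matching population
    growth rates.  Each set is fit with y = a * exp(b * g); the scalar s
    minimizing the RMS difference between s * sim_fit(g) and exp_fit(g)
    over a dense uniform grid on ``g_range`` (default 0.29-1.6/h, the
    observed range +/- 20%) is returned together with the achieved RMSE.
    The minimizer is the closed-form least-squares scale
    s = <exp * sim> / <sim^2> over the grid.
    """
    for name, df in (("exp_medians", exp_medians), ("sim_means", sim_means)):
        if len(df) < 3:
            raise ValueError(f"{name}: need at least 3 (g_pop, value) pairs")
    ge, ye = (np.asarray(exp_medians.iloc[:, 0], dtype=float),
              np.asarray(exp_medians.iloc[:, 1], dtype=float))
    gs, ys = (np.asarray(sim_means.iloc[:, 0], dtype=float),
              np.asarray(sim_means.iloc[:, 1], dtype=float))
    ae, be = _exp_fit(ge, ye)
    as_, bs = _exp_fit(gs, ys)
    grid = np.linspace(g_range[0], g_range[1], n_grid)
    fe = ae * np.exp(be * grid)
    fs = as_ * np.exp(bs * grid)
    s = float(np.dot(fe, fs) / np.dot(fs, fs))
    rmse = float(np.sqrt(np.mean((s * fs - fe) ** 2)))
    return s, rmse
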