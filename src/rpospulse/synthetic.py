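"""Forward model: ground-truth histories -> noisy mother-machine observables.

Every estimator in :mod:`rpospulse.traces` and :mod:`rpospulse.survival`
can be validated against data whose answer is known.  This module turns a
simulated lineage (or any ground-truth activity/growth history) into the
observables a mother-machine experiment yields: per-frame length and mean
fluorescence with multiplicative measurement noise, survival cohorts whose
labels follow a known rule, bulk OD time series, and CFU plate counts.

The reporter obeys dF/dt = a*l - p*F for total fluorescence F, with ``a``
the *per-length* promoter activity (so the activity estimator's output has
``a`` as its ground truth), integrated with the same forward-Euler
discretization the analysis pipeline's forward differences assume; at
divisions F halves with the length, leaving mean fluorescence M = F/l
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cellsim import LineageTrace
from .traces import FrameSeries

__all__ = [
    "ObservationParams",
    "SurvivalRule",
    "logistic_rule",
    "step_rule",
    "constant_rule",
    "forward_fluorescence",
    "observe_frames",
    "make_survival_cohort",
    "make_od_series",
    "make_cfu_experiment",
]


@dataclass(frozen=True)
class ObservationParams:
    """Knobs of the measurement model."""

    frame_dt_min: float = 10.0  # frame interval (minutes)
    sigma_M: float = 0.0        # multiplicative (lognormal) fluorescence noise SD
    sigma_l: float = 0.0        # multiplicative (lognormal) length noise SD
    p: float = 0.1              # bleaching/degradation constant (1/h)
    F0: float = 0.0             # initial total fluorescence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_dt_min <= 0:
            raise ValueError("frame_dt_min must be positive")
        if self.sigma_M < 0 or self.sigma_l < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def frame_dt_h(self) -> float:
        return self.frame_dt_min / 60.0


@dataclass(frozen=True)
class SurvivalRule:
    """Maps pre-stress observables to a survival probability in [0, 1]."""

    prob: Callable[[float, float], float]  # (growth_pre, activity_pre) -> P
    name: str = "rule"

    def __call__(self, growth_pre: float, activity_pre: float) -> float:
        p = float(self.prob(growth_pre, activity_pre))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"survival probability {p} outside [0, 1]")
        return p


def logistic_rule(midpoint: float, slope: float,
                  on: str = "growth") -> SurvivalRule:
    """P(survive) = 1 / (1 + exp(slope * (value - midpoint))).

    With positive slope on growth, slower-growing cells survive more —
    the direction the stress-survival experiments show.
    """
    def prob(g, a):
        v = g if on == "growth" else a
        s = slope if on == "growth" else -slope
        return 1.0 / (1.0 + np.exp(s * (v - midpoint)))
    return SurvivalRule(prob, name=f"logistic_{on}")


def step_rule(threshold: float, on: str = "growth") -> SurvivalRule:
    """Survive iff growth < threshold (or activity > threshold)."""
    def prob(g, a):
        return 1.0 if ((g < threshold) if on == "growth"
                       else (a > threshold)) else 0.0
    return SurvivalRule(prob, name=f"step_{on}")


def constant_rule(p: float = 0.5) -> SurvivalRule:
    return SurvivalRule(lambda g, a: p, name="constant")


def forward_fluorescence(activity_per_length: np.ndarray,
                         lineage: LineageTrace,
                         params: ObservationParams):
    """Integrate the reporter along a lineage; returns (F, M) on its grid.

    Discrete forward-Euler counterpart of dF/dt = a*l - p*F on the
    lineage's step grid:

        F_{i+1} = F_i + dt * (a_i * l_i - p * F_i),

    applied with the pre-division length, then halved together with the
    length at division steps (mean fluorescence M = F/l is continuous
    across divisions).  This is the exact inverse of the discrete activity
    estimator: at steady state the analysis pipeline recovers ``a``
    exactly on the same grid.
    """
    a = np.asarray(activity_per_length, dtype=float)
    if len(a) != len(lineage):
        raise ValueError("activity series must align with the lineage grid")
    if np.any(a < 0):
        raise ValueError("activity must be non-negative")
    dt = lineage.dt
    n = len(lineage)
    F = np.empty(n)
    F[0] = params.F0
    # reconstruct the pre-division length at division steps: the recorded
    # length was halved after growing, so the undivided length is 2*l
    for i in range(n - 1):
        l_i = lineage.l[i]
        F_next = F[i] + dt * (a[i] * l_i - params.p * F[i])
        if lineage.divided[i + 1]:
            F_next /= 2.0
        F[i + 1] = F_next
    M = F / lineage.l
    return F, M


def observe_frames(lineage: LineageTrace, M: np.ndarray,
                   params: ObservationParams,
                   rng: np.random.Generator | None = None,
                   lineage_id=None) -> FrameSeries:
    """Downsample a lineage to the frame grid and add measurement noise.

    The frame interval must be an integer multiple of the simulation step.
    Length and mean fluorescence get independent multiplicative lognormal
    noise (exp of a zero-mean normal with SD sigma_l / sigma_M); a frame is
    marked ``division`` when any division fell in the interval since the
    previous frame.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    step_h = lineage.dt
    ratio = params.frame_dt_h / step_h
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("frame_dt must be an integer multiple of the "
                         "simulation step")
    idx = np.arange(0, len(lineage), k)
    t = lineage.t[idx]
    l_true = lineage.l[idx]
    M_true = np.asarray(M, dtype=float)[idx]
    l_obs = l_true * np.exp(rng.normal(0.0, params.sigma_l, len(idx))) \
        if params.sigma_l > 0 else l_true.copy()
    M_obs = M_true * np.exp(rng.normal(0.0, params.sigma_M, len(idx))) \
        if params.sigma_M > 0 else M_true.copy()
    # frame i is flagged when a division occurred in (idx[i-1], idx[i]]
    div = np.zeros(len(idx), dtype=np.int8)
    divided = lineage.divided.astype(bool)
    for i in range(1, len(idx)):
        if divided[idx[i - 1] + 1: idx[i] + 1].any():
            div[i] = 1
    return FrameSeries(t=t, l=l_obs, M=M_obs, division=div,
                       lineage_id=lineage_id)


def make_survival_cohort(records, rule: SurvivalRule,
                         rng: np.random.Generator | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Bernoulli survival labels from pre-stress observables.

    ``records`` is an iterable of (lineage_id, growth_pre, activity_pre)
    or a DataFrame with those columns; the rule gives each cell's survival
    probability evaluated at its designated pre-stress frame.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(records, pd.DataFrame):
        it = records[["lineage_id", "growth_pre", "activity_pre"]].itertuples(
            index=False)
    else:
        it = records
    rows = []
    for lid, g, a in it:
        p = rule(g, a)
        rows.append((lid, g, a, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["lineage_id", "growth_pre",
                                       "activity_pre", "survived"])


def make_od_series(g_pop: float, times, od0: float = 0.01,
                   noise: float = 0.0,
                   rng: np.random.Generator | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Bulk optical-density series OD(t) = od0 * exp(g_pop * t) * noise."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(seed)
    od = od0 * np.exp(g_pop * times)
    if noise > 0:
        od = od * np.exp(rng.normal(0.0, noise, len(times)))
    return pd.DataFrame({"time_h": times, "od": od})


def make_cfu_experiment(true_fraction: float, dilutions,
                        plating_density: float = 1e8,
                        plated_volume_ml: float = 0.1,
                        n_plates: int = 2,
                        rng: np.random.Generator | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Poisson colony counts for a stressed arm and a water-control arm.

    ``plating_density`` is the control culture's viable density (cells/mL
    before dilution); the stressed arm's density is ``true_fraction``
    times that.  Each plate at fold-dilution d receives on average
    density * plated_volume / d colonies.  Returns a long table with
    columns (arm, dilution, plate, count, plated_volume_ml).
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for arm, density in (("control", plating_density),
                         ("stressed", true_fraction * plating_density)):
        for d in dilutions:
            mean = density * plated_volume_ml / d
            for plate in range(n_plates):
                rows.append((arm, float(d), plate,
                             int(rng.poisson(mean)), plated_volume_ml))
    return pd.DataFrame(rows, columns=["arm", "dilution", "plate", "count",
                                       "plated_volume_ml"])
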