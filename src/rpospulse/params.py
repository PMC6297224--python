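"""Parameter containers for the coupled molecular/growth single-cell model.

The model follows two molecular species inside one growing, dividing cell:
RpoS (``r``), the general-stress sigma factor, and a growth factor (``gamma``)
standing in for sigma-70-driven growth capacity.  Both are produced by
zeroth-order reactions and degraded by first-order reactions, simulated
exactly with the Gillespie algorithm between deterministic growth steps.
Growth rate is a product of an activating Hill function of [gamma] and a
repressing Hill function of [r]; divisions follow the adder rule.

Default rate constants are calibrated so that, at the fast-growth condition,
the sampled single-cell growth-rate distribution is broad (mean near 1.2/h
with a pronounced low-growth tail that disappears when the RpoS arm of the
feedback is switched off) and RpoS concentration shows rare multi-generation
pulses, matching the qualitative single-cell phenomenology of E. coli in a
mother machine at 37 C.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["SimParams", "load_params", "save_params"]


@dataclass(frozen=True)
class SimParams:
    """All constants of the growth/reaction model plus run controls.

    Rates are per hour; lengths in units of the adder increment (the cell
    must add ``dL`` length units between divisions).  Concentrations are
    molecule counts per unit length.
    """

    # molecular reactions (zeroth-order production, first-order degradation)
    k_rp: float = 3.0    # RpoS production propensity (molecules/h)
    k_rd: float = 0.3    # RpoS degradation propensity (1/h)
    k_gp: float = 16.0   # growth-factor production propensity (molecules/h)
    k_gd: float = 1.0    # growth-factor degradation propensity (1/h)

    # growth-rate Hill readout
    g_max: float = 1.6   # maximum relative growth rate (1/h)
    f: float = 0.35      # residual growth fraction at saturating RpoS
    h_g: float = 3.0     # [gamma] at half-maximal activation (1/length)
    h_r: float = 2.0     # [r] at half-maximal repression (1/length)
    n_g: float = 2.0     # Hill coefficient for gamma (positive)
    n_r: float = -4.0    # Hill coefficient for RpoS (negative)

    # deterministic growth / division
    dt: float = 0.1      # deterministic growth step (h)
    dL: float = 1.0      # adder length increment required before division
    l0: float = 1.0      # initial length
    r0: int = 10         # initial RpoS count (no-dilution stationary mean)
    g0: int = 16         # initial gamma count (no-dilution stationary mean)

    # run controls
    t_total: float = 500.0   # total simulated time (h)
    t_burnin: float = 250.0  # initial span flagged as transient (h)
    feedback_on: bool = True
    efficacy_mode: Literal["constant", "reduced"] = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.n_g <= 0:
            raise ValueError("n_g must be positive (activating)")
        if self.n_r >= 0:
            raise ValueError("n_r must be negative (repressing)")
        if self.dt <= 0 or self.dL <= 0 or self.l0 <= 0:
            raise ValueError("dt, dL and l0 must be positive")
        for name in ("k_rp", "k_rd", "k_gp", "k_gd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r0 < 0 or self.g0 < 0:
            raise ValueError("initial molecule counts must be non-negative")
        if not self.t_burnin < self.t_total:
            raise ValueError("t_burnin must be smaller than t_total")
        if self.efficacy_mode not in ("constant", "reduced"):
            raise ValueError("efficacy_mode must be 'constant' or 'reduced'")

    @property
    def n_steps(self) -> int:
        """Number of deterministic growth steps (t_total rounded down to dt)."""
        return int(self.t_total / self.dt + 1e-9)

    @property
    def burnin_steps(self) -> int:
        return int(self.t_burnin / self.dt + 1e-9)

    def replace(self, **changes) -> "SimParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


def load_params(path: str | Path) -> SimParams:
    """Load a flat key/value YAML (or JSON, a YAML subset) parameter file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    known = {f.name for f in SimParams.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return SimParams(**raw)


def save_params(params: SimParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
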