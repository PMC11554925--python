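"""Process performance metrics and lag-phase correction.

Titer uses the unit-volume convention (the fed-batch state equations carry
no volume state), so titer = B(T) in g/L. Average productivity is titer
divided by the lag-free process length, and the product-to-substrate yield
divides by the cumulative glucose consumed. The biomass-specific yield
accepts a separate biomass timestamp because dry weight is typically not
measured at every sampling point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DomainError


@dataclass
class ProcessMetrics:
    titer: float            # g/L
    productivity: float     # g/L/h
    yield_: float           # g product / g glucose
    yield_biomass: float    # g product / g biomass
    T: float                # h, lag-free process length
    t_s1: float = float("nan")
    t_s2: float = float("nan")
    notes: dict = field(default_factory=dict)


@dataclass
class LagModel:
    """Inputs of the lag correction for one experimental run.

    t_ls1 is the uncorrected (lag-included) length of the aerobic stage,
    X_0 and X_s1 the biomass at its start and end, mu_s1 the fitted
    exponential growth rate, and T_L the uncorrected total process length.
    """

    t_ls1: float
    X_0: float
    X_s1: float
    mu_s1: float
    T_L: float


def compute_metrics(
    B: float, A: float, Gcon: float, X: float, T: float,
    t_s1: float = float("nan"), x_time: float = None,
) -> ProcessMetrics:
    """Metrics from final-state values at lag-free process length T."""
    if T <= 0:
        raise DomainError(f"process length T={T} must be positive")
    titer = B
    productivity = B / T
    yield_ = B / Gcon if Gcon > 0 else 0.0
    yield_biomass = B / X if X > 0 else 0.0
    notes = {}
    if x_time is not None:
        notes["biomass_measured_at_h"] = x_time
    return ProcessMetrics(
        titer=titer, productivity=productivity, yield_=yield_,
        yield_biomass=yield_biomass, T=T, t_s1=t_s1,
        t_s2=T - t_s1 if not math.isnan(t_s1) else float("nan"),
        notes=notes,
    )


def lag_correct(lag: LagModel) -> dict:
    """Lag length and lag-free process length from the stage-1 growth fit.

    The lag is the part of the uncorrected stage-1 length not explained by
    exponential growth between the observed start and end biomass:
    t_L = t_LS1 - ln(X_S1 / X_0) / mu_S1, and T = T_L - t_L.
    """
    if lag.X_0 <= 0 or lag.X_s1 <= 0:
        raise DomainError("biomass values must be positive")
    if lag.X_s1 < lag.X_0:
        raise DomainError(
            f"stage-1 end biomass {lag.X_s1} below start biomass {lag.X_0}"
        )
    if lag.mu_s1 <= 0:
        raise DomainError(f"mu_s1={lag.mu_s1} must be positive")
    t_growth = math.log(lag.X_s1 / lag.X_0) / lag.mu_s1
    t_l = lag.t_ls1 - t_growth
    if t_l < 0:
        warnings.warn(
            f"negative lag estimate {t_l:.3g} h clamped to 0", stacklevel=2
        )
        t_l = 0.0
    return {"t_l": t_l, "T": lag.T_L - t_l}
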