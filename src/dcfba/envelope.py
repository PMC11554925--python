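"""Production envelope: per-condition rate fitting and affine interpolation.

Specific rates are assumed constant within each aeration condition, so the
growth rate μ comes from the slope of ln X against time and every specific
exchange rate q from the slope of the species concentration against the
cumulative biomass integral ∫X dt: for dS/dt = q·X, S(t) is linear in
∫X dt with slope q. The envelope interpolates γ(μ), δ(μ) and min α(μ)
affinely between the microaerobic and aerobic anchors; feasibility of every
point on the line can be verified against the strain model by FBA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, InsufficientDataError
from .strainmodel import MetabolicNetwork, min_oxygen_uptake
from .errors import FeasibilityError

#: required columns of the time-series schema
TIMESERIES_COLUMNS = [
    "time_h", "biomass_gDW_L", "glucose_g_L", "acetoin_g_L", "btd_g_L", "condition",
]


@dataclass
class ConditionRates:
    """Fitted specific rates for one aeration condition.

    Units: mu in h⁻¹, all others in g·gDW⁻¹·h⁻¹. Signs follow the exchange
    convention: negative = uptake, positive = secretion. delta = alpha + beta
    is the net diol (acetoin + 2,3-butanediol) rate.
    """

    condition: str
    mu: float
    gamma: float
    alpha: float
    beta: float
    delta: float
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.delta - (self.alpha + self.beta)) > 1e-9:
            raise DataError(
                f"delta={self.delta} != alpha+beta={self.alpha + self.beta}"
            )
        if self.gamma > 0:
            raise DataError(f"gamma={self.gamma} must be <= 0 (uptake)")
        if self.mu < 0:
            raise DataError(f"mu={self.mu} must be >= 0")


@dataclass
class ProductionEnvelope:
    """Affine maps γ(μ), δ(μ), min α(μ) between two fitted anchors."""

    aerobic: ConditionRates
    microaerobic: ConditionRates

    def __post_init__(self):
        if self.aerobic.mu <= self.microaerobic.mu:
            raise DataError(
                f"aerobic mu {self.aerobic.mu} must exceed microaerobic mu "
                f"{self.microaerobic.mu}"
            )

    @property
    def mu_min(self) -> float:
        return self.microaerobic.mu

    @property
    def mu_max(self) -> float:
        return self.aerobic.mu

    def _affine(self, lo: float, hi: float):
        """Slope/intercept of the line through the two anchor mu values."""
        slope = (hi - lo) / (self.mu_max - self.mu_min)
        return lo - slope * self.mu_min, slope

    @property
    def gamma_coeffs(self):
        return self._affine(self.microaerobic.gamma, self.aerobic.gamma)

    @property
    def delta_coeffs(self):
        return self._affine(self.microaerobic.delta, self.aerobic.delta)

    @property
    def min_alpha_coeffs(self):
        # the microaerobic anchor contributes its acetoin *uptake* value;
        # the aerobic anchor secretes acetoin at its fitted rate
        return self._affine(self.microaerobic.alpha, self.aerobic.alpha)

    def rates_at(self, mu: float):
        """(γ, δ, min α) at growth rate mu; refuses extrapolation."""
        if not (self.mu_min - 1e-12 <= mu <= self.mu_max + 1e-12):
            raise DomainError(
                f"mu={mu} outside envelope domain [{self.mu_min}, {self.mu_max}]"
            )
        g0, g1 = self.gamma_coeffs
        d0, d1 = self.delta_coeffs
        a0, a1 = self.min_alpha_coeffs
        return g0 + g1 * mu, d0 + d1 * mu, a0 + a1 * mu

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def anchor(c):
            return {
                "condition": c.condition, "mu": c.mu, "gamma": c.gamma,
                "alpha": c.alpha, "beta": c.beta, "delta": c.delta,
                "stderr": c.stderr,
            }

        g0, g1 = self.gamma_coeffs
        d0, d1 = self.delta_coeffs
        a0, a1 = self.min_alpha_coeffs
        return {
            "aerobic": anchor(self.aerobic),
            "microaerobic": anchor(self.microaerobic),
            "coefficients": {
                "gamma": [g0, g1], "delta": [d0, d1], "min_alpha": [a0, a1],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProductionEnvelope":
        return cls(
            ConditionRates(**d["aerobic"]), ConditionRates(**d["microaerobic"])
        )

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "ProductionEnvelope":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def _slope(x, y):
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def fit_condition_rates(
    series: pd.DataFrame,
    condition: str,
    window=None,
    acetoin_floor: float = 1e-3,
    pulse_jump: float = 2.0,
) -> ConditionRates:
    """Fit μ and the specific rates for one condition of a time series.

    Parameters
    ----------
    series : DataFrame with the :data:`TIMESERIES_COLUMNS` schema.
    condition : 'aerobic' or 'microaerobic'; selects rows by label.
    window : optional (t_start, t_end) in h restricting the fit (e.g. to
        exclude a lag phase).
    acetoin_floor : g/L; in microaerobic windows the acetoin rate is fitted
        only while acetoin is above this floor and glucose is present —
        after depletion the exchange rate is zero by construction.
    pulse_jump : g/L; upward glucose jumps larger than this are treated as
        feed pulses. Pulse-crossing sampling intervals are excluded from the
        glucose regression entirely — the observed jump is the pulse amount
        minus the (unknown) consumption inside the interval, so merely
        subtracting it would drop that consumption and bias γ toward zero.
        Smaller upward wiggles are measurement noise and stay in the
        regression.
    """
    missing = [c for c in TIMESERIES_COLUMNS if c not in series.columns]
    if missing:
        raise DataError(f"time series missing columns: {missing}")
    df = series[series["condition"] == condition].copy()
    if window is not None:
        t0, t1 = window
        df = df[(df["time_h"] >= t0 - 1e-12) & (df["time_h"] <= t1 + 1e-12)]
    df = df.sort_values("time_h")
    if len(df) < 3:
        raise InsufficientDataError(
            f"need >=3 samples for condition {condition!r}, got {len(df)}"
        )
    t = df["time_h"].to_numpy(float)
    X = df["biomass_gDW_L"].to_numpy(float)
    if np.any(X <= 0):
        raise DataError("nonpositive biomass in fit window")

    mu, mu_se = _slope(t, np.log(X))
    mu = max(mu, 0.0)
    # cumulative biomass integral: trapezoid with an exponential-consistency
    # correction tanh(z/2)/(z/2), z = mu*dt, which is exact when X grows
    # exponentially at the fitted mu and reduces to the plain trapezoid as
    # mu*dt -> 0
    dt = np.diff(t)
    z = mu * dt
    w = np.ones_like(z)
    big = z > 1e-8
    w[big] = np.tanh(z[big] / 2.0) / (z[big] / 2.0)
    cumX = np.concatenate(([0.0], np.cumsum(dt * 0.5 * (X[1:] + X[:-1]) * w)))

    # glucose: accumulate consumption over non-pulse intervals only
    g = df["glucose_g_L"].to_numpy(float)
    jumps = np.diff(g)
    keep = jumps <= pulse_jump
    gcum = np.concatenate(([0.0], np.cumsum(np.where(keep, jumps, 0.0))))
    xcum = np.concatenate(([0.0], np.cumsum(np.where(keep, np.diff(cumX), 0.0))))
    gamma, gamma_se = _slope(xcum, gcum)
    gamma = min(gamma, 0.0)

    a = df["acetoin_g_L"].to_numpy(float)
    b = df["btd_g_L"].to_numpy(float)
    if condition == "microaerobic":
        # the net diol rate δ holds for the whole window (after acetoin
        # depletion α→0 and β→δ), while α and β = δ − α are the anchor
        # values only on the sub-window where acetoin is still present
        delta, delta_se = _slope(cumX, a + b)
        # fit only strictly-active samples: the interval in which acetoin
        # crosses zero is partially flattened and would bias the slope
        active = (a > acetoin_floor) & (g > 0)
        if active.sum() >= 3:
            alpha, alpha_se = _slope(cumX[active], a[active])
        else:
            alpha, alpha_se = 0.0, float("nan")
        beta = delta - alpha
        beta_se = float("nan")
    else:
        alpha, alpha_se = _slope(cumX, a)
        beta, beta_se = _slope(cumX, b)
        beta = max(beta, 0.0)
        delta = alpha + beta

    return ConditionRates(
        condition=condition, mu=mu, gamma=gamma, alpha=alpha, beta=beta,
        delta=delta,
        stderr={"mu": mu_se, "gamma": gamma_se, "alpha": alpha_se, "beta": beta_se},
    )


def rates_at(pe: ProductionEnvelope, mu: float):
    """Module-level convenience wrapper for :meth:`ProductionEnvelope.rates_at`."""
    return pe.rates_at(mu)


def build_envelope(aero: ConditionRates, micro: ConditionRates) -> ProductionEnvelope:
    """Assemble the affine envelope from the two fitted anchors."""
    if aero.mu <= micro.mu:
        raise DataError(
            f"anchor ordering violated: aerobic mu {aero.mu} <= "
            f"microaerobic mu {micro.mu}"
        )
    return ProductionEnvelope(aerobic=aero, microaerobic=micro)


def verify_envelope(
    pe: ProductionEnvelope, net: MetabolicNetwork, n_samples: int = 11,
    ids: dict = None,
) -> pd.DataFrame:
    """FBA feasibility of the envelope line at equidistant growth rates.

    For each μ the acetoin rate is set to min α(μ) and the butanediol rate
    to δ(μ) − min α(μ); infeasible points are reported, not raised. Returns
    a frame with columns mu, feasible, xi (oxygen exchange flux,
    mmol·gDW⁻¹·h⁻¹, NaN where infeasible).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mus = (
        np.array([pe.mu_min])
        if n_samples == 1
        else np.linspace(pe.mu_min, pe.mu_max, n_samples)
    )
    rows = []
    for mu in mus:
        gamma, delta, min_alpha = pe.rates_at(mu)
        try:
            xi = min_oxygen_uptake(net, mu, gamma, delta, min_alpha, ids=ids)
            rows.append({"mu": mu, "feasible": True, "xi": xi})
        except FeasibilityError:
            rows.append({"mu": mu, "feasible": False, "xi": np.nan})
    return pd.DataFrame(rows)
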