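"""Continuous two-reactor (two-stage chemostat) process design.

Two equal-volume stirred reactors in series share one feed flux φ (h⁻¹,
flow per reactor volume). The feed into reactor 1 carries glucose only
(concentration Gφ); reactor 2 receives the outflow of reactor 1. At steady
state each species balances inflow, outflow and the biomass-specific
envelope rates:

    reactor 1:  φ(c_in − c_1) + q_1 X_1 = 0,   c_in = (0, 0, 0, Gφ)
    reactor 2:  φ(c_1 − c_2) + q_2 X_2 = 0

with q = (α, β, μ, γ) coupled to the production envelope per reactor. The
design NLP maximises titer B₂ or volumetric productivity φ·B₂ over
(φ, Gφ, μ_i, α_i) subject to complete glucose consumption (G₂ = 0) and a
biomass ceiling, and the optimised steady state can be checked by dynamic
integration from the start-up initial condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .envelope import ProductionEnvelope
from .errors import ConfigError, FeasibilityError

STATE_COLS = ["A1", "B1", "X1", "G1", "A2", "B2", "X2", "G2"]


@dataclass
class ChemostatDesign:
    """Steady-state design of the two-reactor continuous process."""

    pe: ProductionEnvelope
    phi: float           # h^-1, feed flux per reactor volume
    G_feed: float        # g/L glucose in the feed
    mu: tuple            # (mu_1, mu_2), h^-1
    alpha: tuple         # (alpha_1, alpha_2), g/gDW/h
    state: dict          # steady-state concentrations, keys STATE_COLS

    def rates(self, reactor: int):
        """(alpha, beta, mu, gamma) of one reactor (1 or 2)."""
        i = reactor - 1
        gamma, delta, _ = self.pe.rates_at(self.mu[i])
        return self.alpha[i], delta - self.alpha[i], self.mu[i], gamma


def steady_state_residual(design: ChemostatDesign) -> np.ndarray:
    """8-vector of steady-state residuals (order: A1 B1 X1 G1 A2 B2 X2 G2)."""
    s = design.state
    phi, Gf = design.phi, design.G_feed
    a1, b1, m1, g1 = design.rates(1)
    a2, b2, m2, g2 = design.rates(2)
    r = np.empty(8)
    r[0] = phi * (0.0 - s["A1"]) + a1 * s["X1"]
    r[1] = phi * (0.0 - s["B1"]) + b1 * s["X1"]
    r[2] = phi * (0.0 - s["X1"]) + m1 * s["X1"]
    r[3] = phi * (Gf - s["G1"]) + g1 * s["X1"]
    r[4] = phi * (s["A1"] - s["A2"]) + a2 * s["X2"]
    r[5] = phi * (s["B1"] - s["B2"]) + b2 * s["X2"]
    r[6] = phi * (s["X1"] - s["X2"]) + m2 * s["X2"]
    r[7] = phi * (s["G1"] - s["G2"]) + g2 * s["X2"]
    return r


def chemostat_metrics(design: ChemostatDesign) -> dict:
    """Titer, productivity and yield of a steady design.

    Productivity is reported per reactor-2 volume (φ·B₂, the optimisation
    target) and, for comparison across volume conventions, per total
    volume of the two equal reactors (φ·B₂/2).
    """
    B2 = design.state["B2"]
    return {
        "titer": B2,
        "productivity": design.phi * B2,
        "productivity_total_volume": design.phi * B2 / 2.0,
        "yield": B2 / design.G_feed if design.G_feed > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# design optimisation
# ---------------------------------------------------------------------------

# variable order in the NLP
_VARS = ["phi", "G_feed", "mu1", "alpha1", "mu2", "alpha2"] + STATE_COLS


def _unpack(z):
    return dict(zip(_VARS, z))


def _residual_vec(z, pe):
    v = _unpack(z)
    design = ChemostatDesign(
        pe=pe, phi=v["phi"], G_feed=v["G_feed"],
        mu=(v["mu1"], v["mu2"]), alpha=(v["alpha1"], v["alpha2"]),
        state={k: v[k] for k in STATE_COLS},
    )
    return steady_state_residual(design)


def _residual_jac(z, pe):
    v = _unpack(z)
    g0, g1c = pe.gamma_coeffs
    d0, d1c = pe.delta_coeffs
    phi, Gf = v["phi"], v["G_feed"]
    idx = {name: i for i, name in enumerate(_VARS)}
    J = np.zeros((8, len(_VARS)))

    def gam(mu):
        return g0 + g1c * mu

    def beta(mu, alpha):
        return d0 + d1c * mu - alpha

    X1, X2 = v["X1"], v["X2"]
    # reactor 1
    J[0, idx["phi"]] = -v["A1"]
    J[0, idx["A1"]] = -phi
    J[0, idx["alpha1"]] = X1
    J[0, idx["X1"]] = v["alpha1"]
    J[1, idx["phi"]] = -v["B1"]
    J[1, idx["B1"]] = -phi
    J[1, idx["mu1"]] = d1c * X1
    J[1, idx["alpha1"]] = -X1
    J[1, idx["X1"]] = beta(v["mu1"], v["alpha1"])
    J[2, idx["phi"]] = -X1
    J[2, idx["X1"]] = -phi + v["mu1"]
    J[2, idx["mu1"]] = X1
    J[3, idx["phi"]] = Gf - v["G1"]
    J[3, idx["G_feed"]] = phi
    J[3, idx["G1"]] = -phi
    J[3, idx["mu1"]] = g1c * X1
    J[3, idx["X1"]] = gam(v["mu1"])
    # reactor 2
    J[4, idx["phi"]] = v["A1"] - v["A2"]
    J[4, idx["A1"]] = phi
    J[4, idx["A2"]] = -phi
    J[4, idx["alpha2"]] = X2
    J[4, idx["X2"]] = v["alpha2"]
    J[5, idx["phi"]] = v["B1"] - v["B2"]
    J[5, idx["B1"]] = phi
    J[5, idx["B2"]] = -phi
    J[5, idx["mu2"]] = d1c * X2
    J[5, idx["alpha2"]] = -X2
    J[5, idx["X2"]] = beta(v["mu2"], v["alpha2"])
    J[6, idx["phi"]] = X1 - X2
    J[6, idx["X1"]] = phi
    J[6, idx["X2"]] = -phi + v["mu2"]
    J[6, idx["mu2"]] = X2
    J[7, idx["phi"]] = v["G1"] - v["G2"]
    J[7, idx["G1"]] = phi
    J[7, idx["G2"]] = -phi
    J[7, idx["mu2"]] = g1c * X2
    J[7, idx["X2"]] = gam(v["mu2"])
    return J


def _analytic_design(pe, phi, mu2, X2, X_max, Gphi_max, alpha_cap):
    """Consistent steady state for given (phi, mu2, X2): reactor 1 runs at
    mu1 = phi with the envelope acetoin rate; reactor 2 re-consumes as much
    acetoin as the supply allows. Returns a variable vector or None."""
    if not (pe.mu_min <= mu2 < phi <= pe.mu_max):
        return None
    mu1 = phi
    g1v, d1v, a1v = pe.rates_at(mu1)
    g2v, d2v, a2min = pe.rates_at(mu2)
    alpha1 = min(max(a1v, 0.0), alpha_cap)
    X1 = X2 * (1.0 - mu2 / phi)
    A1 = alpha1 * X1 / phi
    alpha2 = max(a2min, -phi * A1 / X2 if X2 > 0 else 0.0)
    A2 = (alpha1 * X1 + alpha2 * X2) / phi
    B1 = (d1v - alpha1) * X1 / phi
    B2 = B1 + (d2v - alpha2) * X2 / phi
    G1 = -g2v * X2 / phi
    Gf = (-g1v * X1 - g2v * X2) / phi
    if Gf > Gphi_max or X1 > X_max or X2 > X_max:
        return None
    return np.array([
        phi, Gf, mu1, alpha1, mu2, alpha2,
        A1, B1, X1, G1, A2, B2, X2, 0.0,
    ])


def optimize_chemostat(
    pe: ProductionEnvelope,
    objective: str = "productivity",
    X_max: float = 25.0,
    titer_floor: float = None,
    Gphi_max: float = 600.0,
    psi1: float = 1.0,
    psi2: float = 1e-2,
    mu_lb: float = None,
    feas_tol: float = 1e-8,
) -> ChemostatDesign:
    """Optimise the steady-state two-reactor design with SLSQP.

    Maximises psi1·F1 with F1 = B₂ (titer) or φ·B₂ (productivity); the
    embedded-LP complementarity term carries weight psi2 but contributes 0
    with the envelope reduced to linear constraints. Constraints: steady
    state, complete glucose consumption (G₂ = 0), X_i ≤ X_max, envelope
    bounds on α_i, optional titer floor B₂ ≥ titer_floor, Gφ ≤ Gphi_max.
    """
    if objective not in ("titer", "productivity"):
        raise ConfigError(f"unknown objective {objective!r}")
    mu_lo = pe.mu_min if mu_lb is None else mu_lb
    alpha_cap = max(pe.aerobic.alpha, pe.microaerobic.alpha)
    a0, a1c = pe.min_alpha_coeffs
    idx = {name: i for i, name in enumerate(_VARS)}
    n = len(_VARS)

    def objective_fun(z):
        v = _unpack(z)
        f1 = v["B2"] if objective == "titer" else v["phi"] * v["B2"]
        return -psi1 * f1

    def objective_grad(z):
        v = _unpack(z)
        g = np.zeros(n)
        if objective == "titer":
            g[idx["B2"]] = -psi1
        else:
            g[idx["B2"]] = -psi1 * v["phi"]
            g[idx["phi"]] = -psi1 * v["B2"]
        return g

    def eq(z):
        out = np.empty(9)
        out[:8] = _residual_vec(z, pe)
        out[8] = z[idx["G2"]]  # complete consumption
        return out

    def eq_jac(z):
        J = np.zeros((9, n))
        J[:8] = _residual_jac(z, pe)
        J[8, idx["G2"]] = 1.0
        return J

    def ineq(z):
        v = _unpack(z)
        rows = [
            v["alpha1"] - (a0 + a1c * v["mu1"]),
            v["alpha2"] - (a0 + a1c * v["mu2"]),
        ]
        if titer_floor is not None:
            rows.append(v["B2"] - titer_floor)
        return np.array(rows)

    def ineq_jac(z):
        m = 2 + (1 if titer_floor is not None else 0)
        J = np.zeros((m, n))
        J[0, idx["alpha1"]] = 1.0
        J[0, idx["mu1"]] = -a1c
        J[1, idx["alpha2"]] = 1.0
        J[1, idx["mu2"]] = -a1c
        if titer_floor is not None:
            J[2, idx["B2"]] = 1.0
        return J

    big = 1e5
    bounds = []
    for name in _VARS:
        if name == "phi":
            bounds.append((1e-4, pe.mu_max))
        elif name == "G_feed":
            bounds.append((0.0, Gphi_max))
        elif name in ("mu1", "mu2"):
            bounds.append((mu_lo, pe.mu_max))
        elif name in ("alpha1", "alpha2"):
            bounds.append((min(a0 + a1c * mu_lo, 0.0), alpha_cap))
        elif name in ("X1", "X2"):
            bounds.append((0.0, X_max))
        elif name == "G2":
            bounds.append((0.0, 0.0))
        else:
            bounds.append((0.0, big))

    # deterministic multistart over a small set of analytic warm starts
    starts = []
    for phi in (pe.mu_max, 0.6 * pe.mu_max, 0.25 * pe.mu_max, 20 * mu_lo):
        for x2 in (X_max, 0.5 * X_max):
            z0 = _analytic_design(pe, phi, mu_lo, x2, X_max, Gphi_max, alpha_cap)
            if z0 is not None:
                starts.append(z0)
    if not starts:
        raise FeasibilityError("no feasible warm start for the chemostat NLP")

    constraints = [
        {"type": "eq", "fun": eq, "jac": eq_jac},
        {"type": "ineq", "fun": ineq, "jac": ineq_jac},
    ]
    best, best_val = None, -np.inf
    min_violation = np.inf
    for z0 in starts:
        res = minimize(
            objective_fun, z0, jac=objective_grad, bounds=bounds,
            constraints=constraints, method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        viol = max(
            np.abs(eq(res.x)).max(), max(-(ineq(res.x).min()), 0.0)
        )
        min_violation = min(min_violation, viol)
        if viol <= feas_tol and -res.fun > best_val:
            best, best_val = res, -res.fun
    if best is None:
        raise FeasibilityError(
            "chemostat design infeasible under the given constraints "
            f"(smallest violation {min_violation:.3e})"
        )
    v = _unpack(best.x)
    return ChemostatDesign(
        pe=pe, phi=v["phi"], G_feed=v["G_feed"],
        mu=(v["mu1"], v["mu2"]), alpha=(v["alpha1"], v["alpha2"]),
        state={k: v[k] for k in STATE_COLS},
    )


# ---------------------------------------------------------------------------
# dynamic start-up integration
# ---------------------------------------------------------------------------

def integrate_two_reactor(
    design: ChemostatDesign, t_end: float = None, initial: dict = None,
    n_out: int = 201,
) -> pd.DataFrame:
    """Integrate the two-reactor ODEs with rates frozen at design values.

    Default initial condition: X₁ at its steady-state value, all other
    concentrations zero (process start-up). Default horizon: 20/φ hours,
    several mean residence times past convergence.
    """
    phi, Gf = design.phi, design.G_feed
    if t_end is None:
        t_end = 20.0 / phi
    a1, b1, m1, g1 = design.rates(1)
    a2, b2, m2, g2 = design.rates(2)
    y0 = np.zeros(8)
    y0[STATE_COLS.index("X1")] = design.state["X1"]
    if initial:
        for k, val in initial.items():
            y0[STATE_COLS.index(k)] = val

    def rhs(t, y):
        A1, B1, X1, G1, A2, B2, X2, G2 = y
        return [
            phi * (0.0 - A1) + a1 * X1,
            phi * (0.0 - B1) + b1 * X1,
            phi * (0.0 - X1) + m1 * X1,
            phi * (Gf - G1) + g1 * X1,
            phi * (A1 - A2) + a2 * X2,
            phi * (B1 - B2) + b2 * X2,
            phi * (X1 - X2) + m2 * X2,
            phi * (G1 - G2) + g2 * X2,
        ]

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
        rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            f"two-reactor integration failed: {sol.message}; "
            f"last state {sol.y[:, -1] if sol.y.size else None}"
        )
    df = pd.DataFrame(sol.y.T, columns=STATE_COLS)
    df.insert(0, "time_h", sol.t)
    return df
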