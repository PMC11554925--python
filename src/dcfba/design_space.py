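"""Titer–productivity design-space mapping.

Sweeps process length and the minimal allowed growth rate over the
envelope, optimising each grid point for titer and/or productivity, then
classifies the solution space into a proportionality region (short
processes, where maximal titer and productivity rise together) and a
trade-off region (long processes, where titer gains cost productivity),
and extracts/fits the Pareto front between the two optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envelope import ProductionEnvelope
from .errors import ConfigError, InsufficientDataError
from .fedbatch import FedbatchProblem, solve_fedbatch, two_stage_oracle

#: default sweep (spans both regions for the fixture envelope)
DEFAULT_MU_LB = np.linspace(0.005, 0.055, 11)
DEFAULT_T = np.concatenate([np.linspace(10.0, 25.0, 10), np.linspace(25.0, 60.0, 8)])


@dataclass
class SweepGrid:
    T: np.ndarray = field(default_factory=lambda: DEFAULT_T.copy())
    mu_lb: np.ndarray = field(default_factory=lambda: DEFAULT_MU_LB.copy())
    Gmax: float = 200.0
    objectives: tuple = ("titer", "productivity")

    def __post_init__(self):
        self.T = np.unique(np.asarray(self.T, dtype=float))
        self.mu_lb = np.unique(np.asarray(self.mu_lb, dtype=float))
        for name, axis in (("T", self.T), ("mu_lb", self.mu_lb)):
            if len(axis) >= 2 and np.any(np.diff(axis) <= 0):
                raise ConfigError(f"{name} grid must be strictly increasing")
        bad = set(self.objectives) - {"titer", "productivity"}
        if bad:
            raise ConfigError(f"unknown objectives {bad}")


def sweep_solution_space(
    grid: SweepGrid,
    pe: ProductionEnvelope,
    X0: float = 0.25,
    mode: str = "oracle",
    nlp_kwargs: dict = None,
) -> pd.DataFrame:
    """One optimisation per (T, mu_lb, objective) grid point.

    ``mode='oracle'`` (default) uses the closed-form two-stage search;
    ``mode='nlp'`` additionally polishes with the collocation NLP. Failed
    points are recorded with their status, never dropped.
    """
    if mode not in ("oracle", "nlp"):
        raise ConfigError(f"unknown sweep mode {mode!r}")
    rows = []
    for T in grid.T:
        for mu_lb in grid.mu_lb:
            for objective in grid.objectives:
                rec = {"T": T, "mu_lb": mu_lb, "objective": objective}
                try:
                    prob = FedbatchProblem(
                        pe=pe, T=T, Gmax=grid.Gmax, mu_lb=mu_lb, X0=X0,
                        objective=objective,
                    )
                    sol = two_stage_oracle(prob)
                    if mode == "nlp":
                        nlp_sol = solve_fedbatch(prob, **(nlp_kwargs or {}))
                        if nlp_sol.objective_value > sol.objective_value:
                            sol = nlp_sol
                    gcon = float(sol.trajectory.Gcon[-1])
                    rec.update(
                        titer=sol.titer, productivity=sol.productivity,
                        gcon=gcon, t_s1_frac=sol.t_s1 / T,
                        all_glucose_consumed=bool(gcon >= 0.999 * grid.Gmax),
                        status=sol.status,
                    )
                except Exception as exc:  # record, don't drop
                    rec.update(
                        titer=np.nan, productivity=np.nan, gcon=np.nan,
                        t_s1_frac=np.nan, all_glucose_consumed=False,
                        status=f"failed: {type(exc).__name__}",
                    )
                rows.append(rec)
    return pd.DataFrame(rows)


def classify_regions(space: pd.DataFrame):
    """Split the map at the productivity-maximising process length T*.

    T* is taken at the smallest swept mu_lb (where performance is best).
    Records with T < T* belong to the proportionality region, T > T* to
    the trade-off region. A non-unimodal productivity profile triggers a
    warning listing all local maxima.
    """
    mu_min = space["mu_lb"].min()
    sub = space[
        (space["mu_lb"] == mu_min)
        & (space["objective"] == "productivity")
        & space["status"].isin(["oracle", "optimal"])
    ].sort_values("T")
    if sub["T"].nunique() < 4:
        raise InsufficientDataError(
            "need >=4 process lengths at the smallest mu_lb to classify"
        )
    T_vals = sub["T"].to_numpy()
    P_vals = sub["productivity"].to_numpy()
    k_star = int(np.argmax(P_vals))
    T_star = float(T_vals[k_star])
    # local maxima check
    local_max = [
        i for i in range(len(P_vals))
        if (i == 0 or P_vals[i] >= P_vals[i - 1])
        and (i == len(P_vals) - 1 or P_vals[i] >= P_vals[i + 1])
    ]
    if len(local_max) > 1:
        warnings.warn(
            "productivity-vs-T profile is not unimodal; local maxima at T = "
            + ", ".join(f"{T_vals[i]:g}" for i in local_max),
            stacklevel=2,
        )
    labels = np.where(
        space["T"] < T_star, "proportionality",
        np.where(space["T"] > T_star, "trade-off", "optimum"),
    )
    return T_star, pd.Series(labels, index=space.index, name="region")


def extract_pareto_front(space: pd.DataFrame) -> pd.DataFrame:
    """Non-dominated (titer, productivity) pairs of the trade-off region.

    Requires a 'region' column (see :func:`classify_regions`); the front is
    sorted by increasing titer with strictly decreasing productivity.
    """
    if "region" not in space.columns:
        raise ConfigError("space must carry a 'region' column; classify first")
    cand = space[
        space["region"].isin(["trade-off", "optimum"])
        & space["titer"].notna()
    ][["titer", "productivity"]].to_numpy()
    if len(cand) == 0:
        return pd.DataFrame(columns=["titer", "productivity"])
    keep = []
    for i, (ti, pi) in enumerate(cand):
        dominated = np.any(
            (cand[:, 0] >= ti) & (cand[:, 1] >= pi)
            & ((cand[:, 0] > ti) | (cand[:, 1] > pi))
        )
        if not dominated:
            keep.append(i)
    front = pd.DataFrame(cand[keep], columns=["titer", "productivity"])
    front = front.drop_duplicates().sort_values("titer").reset_index(drop=True)
    return front


def fit_pareto_quadratic(front: pd.DataFrame):
    """Least-squares quadratic productivity = a·titer² + b·titer + c.

    Returns ((a, b, c), R²) computed on the front points.
    """
    if len(front) < 4:
        raise InsufficientDataError(
            f"need >=4 front points for a quadratic fit, got {len(front)}"
        )
    x = front["titer"].to_numpy(float)
    y = front["productivity"].to_numpy(float)
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return tuple(coeffs), r2
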