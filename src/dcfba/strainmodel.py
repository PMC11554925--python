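"""Stoichiometric model of the engineered 2,3-butanediol producer.

The production strain derives from *E. coli*: the fermentative NADH sinks
(ethanol, D-lactate, succinate via fumarate reductase) and the
phosphotransacetylase acetate route are removed, and the three-step
2,3-butanediol pathway (acetolactate synthase ACLS, acetolactate
decarboxylase ACLDC, butanediol dehydrogenase BDH) is inserted. In the
edited network glycolytic NADH can only be re-oxidised by respiration or by
reducing acetoin to 2,3-butanediol, which couples product formation to the
oxygen supply.

Two dialects are supported: any SBML core-model file (read with cobrapy),
and a built-in minimal redox/energy network that captures exactly the
coupling needed for the production-envelope FBA checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import EditError, FeasibilityError, ModelError, UnboundedError
from .units import g_to_mmol

#: tag accepted by :func:`load_network` for the built-in minimal network
BUILTIN_TAG = "builtin"

#: maintenance ATP hydrolysis lower bound, mmol·gDW⁻¹·h⁻¹ (core-model dialect value)
ATPM_LB = 8.39

#: biomass ATP cost, mmol ATP per gDW; calibrated so the maximal aerobic
#: biomass yield of the built-in network is ≈0.49 g·g⁻¹ glucose
BIOMASS_ATP = 165.0

#: biomass pyruvate demand, mmol per gDW
BIOMASS_PYR = 11.0

LP_TOL = 1e-9


@dataclass
class MetabolicNetwork:
    """Stoichiometric matrix, flux bounds and objective weights.

    Flux units are mmol·gDW⁻¹·h⁻¹ except the biomass reaction (h⁻¹).
    """

    metabolite_ids: list
    reaction_ids: list
    stoich: sp.csc_matrix
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    objective_coeffs: np.ndarray
    biomass_id: str = "BIOMASS"

    def __post_init__(self):
        self.stoich = sp.csc_matrix(self.stoich)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self):
        n_met, n_rxn = self.stoich.shape
        if n_rxn != len(self.reaction_ids):
            raise ModelError(
                f"stoichiometric matrix has {n_rxn} columns for "
                f"{len(self.reaction_ids)} reactions"
            )
        if n_met != len(self.metabolite_ids):
            raise ModelError(
                f"stoichiometric matrix has {n_met} rows for "
                f"{len(self.metabolite_ids)} metabolites"
            )
        for arr, name in ((self.lower_bound, "lower"), (self.upper_bound, "upper")):
            if arr.shape != (n_rxn,):
                raise ModelError(f"{name} bounds length {arr.shape} != {n_rxn}")
        bad = np.where(self.lower_bound > self.upper_bound)[0]
        if bad.size:
            raise ModelError(
                "lower bound exceeds upper bound for reaction(s): "
                + ", ".join(self.reaction_ids[i] for i in bad)
            )
        if self.biomass_id not in self.reaction_ids:
            raise ModelError(f"biomass reaction {self.biomass_id!r} missing")
        for rid in self.reaction_ids:
            if rid.startswith(("EX_", "DM_", "SK_")):
                col = self.stoich[:, self.reaction_ids.index(rid)]
                if col.nnz != 1:
                    raise ModelError(
                        f"exchange reaction {rid} touches {col.nnz} metabolites"
                    )

    def index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ModelError(f"unknown reaction id {rid!r}") from None

    def reaction_stoichiometry(self, rid: str) -> dict:
        """Metabolite→coefficient map of one reaction column."""
        j = self.index(rid)
        col = self.stoich.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}

    def bounds(self, rid: str):
        j = self.index(rid)
        return self.lower_bound[j], self.upper_bound[j]

    def with_bounds(self, updates: dict) -> "MetabolicNetwork":
        """Copy of the network with per-reaction (lb, ub) overrides."""
        lb, ub = self.lower_bound.copy(), self.upper_bound.copy()
        for rid, (lo, hi) in updates.items():
            j = self.index(rid)
            lb[j], ub[j] = lo, hi
        return MetabolicNetwork(
            list(self.metabolite_ids), list(self.reaction_ids), self.stoich,
            lb, ub, self.objective_coeffs.copy(), self.biomass_id,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        coo = self.stoich.tocoo()
        return {
            "metabolites": list(self.metabolite_ids),
            "reactions": list(self.reaction_ids),
            "stoich": {
                "row": coo.row.tolist(),
                "col": coo.col.tolist(),
                "data": coo.data.tolist(),
            },
            "lower_bound": self.lower_bound.tolist(),
            "upper_bound": self.upper_bound.tolist(),
            "objective_coeffs": self.objective_coeffs.tolist(),
            "biomass_id": self.biomass_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicNetwork":
        s = d["stoich"]
        mat = sp.coo_matrix(
            (s["data"], (s["row"], s["col"])),
            shape=(len(d["metabolites"]), len(d["reactions"])),
        ).tocsc()
        return cls(
            d["metabolites"], d["reactions"], mat,
            np.array(d["lower_bound"]), np.array(d["upper_bound"]),
            np.array(d["objective_coeffs"]), d.get("biomass_id", "BIOMASS"),
        )

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "MetabolicNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GenotypeEdit:
    """Reaction deletions and additions describing a genotype."""

    deletions: list = field(default_factory=list)
    #: list of (reaction id, {metabolite: coefficient}, (lb, ub))
    additions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# built-in minimal network
# ---------------------------------------------------------------------------

_BUILTIN_REACTIONS = {
    # id: (stoichiometry, lb, ub)
    "GLYC": ({"glc": -1, "adp": -2, "nad": -2, "pyr": 2, "atp": 2, "nadh": 2}, 0.0, 1000.0),
    "PDH": ({"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1, "co2": 1}, 0.0, 1000.0),
    "TCA": ({"accoa": -1, "nad": -3, "adp": -1, "co2": 2, "nadh": 3, "atp": 1}, 0.0, 1000.0),
    "RESP": ({"nadh": -1, "o2": -0.5, "adp": -2, "nad": 1, "atp": 2}, 0.0, 1000.0),
    "ATPM": ({"atp": -1, "adp": 1}, ATPM_LB, 1000.0),
    "ACLS": ({"pyr": -2, "alac": 1, "co2": 1}, 0.0, 1000.0),
    "ACLDC": ({"alac": -1, "actn": 1, "co2": 1}, 0.0, 1000.0),
    "BDH": ({"actn": -1, "nadh": -1, "btd": 1, "nad": 1}, 0.0, 1000.0),
    "BIOMASS": (
        {"pyr": -BIOMASS_PYR, "atp": -BIOMASS_ATP, "adp": BIOMASS_ATP, "X": 1},
        0.0, 1000.0,
    ),
    "EX_glc": ({"glc": -1}, -10.0, 0.0),
    "EX_o2": ({"o2": -1}, -1000.0, 0.0),
    "EX_co2": ({"co2": -1}, 0.0, 1000.0),
    "EX_actn": ({"actn": -1}, -1000.0, 1000.0),
    "EX_btd": ({"btd": -1}, 0.0, 1000.0),
    "EX_X": ({"X": -1}, 0.0, 1000.0),
}

#: default mapping of the rates used by :func:`min_oxygen_uptake` to
#: reaction ids; override for SBML core-model files
BUILTIN_IDS = {
    "biomass": "BIOMASS",
    "glucose": "EX_glc",
    "acetoin": "EX_actn",
    "btd": "EX_btd",
    "oxygen": "EX_o2",
    "maintenance": "ATPM",
}


def builtin_network() -> MetabolicNetwork:
    """Construct the built-in minimal production network in code.

    The network already carries the engineered genotype: no ethanol,
    lactate, succinate or acetate routes exist, and the acetolactate →
    acetoin → 2,3-butanediol branch is present. NADH sinks are respiration
    and BDH only.
    """
    mets = ["glc", "pyr", "accoa", "alac", "actn", "btd",
            "nadh", "nad", "atp", "adp", "o2", "co2", "X"]
    midx = {m: i for i, m in enumerate(mets)}
    rxns = list(_BUILTIN_REACTIONS)
    rows, cols, data, lbs, ubs = [], [], [], [], []
    for j, rid in enumerate(rxns):
        stoich, lb, ub = _BUILTIN_REACTIONS[rid]
        for m, c in stoich.items():
            rows.append(midx[m])
            cols.append(j)
            data.append(float(c))
        lbs.append(lb)
        ubs.append(ub)
    mat = sp.coo_matrix((data, (rows, cols)), shape=(len(mets), len(rxns))).tocsc()
    obj = np.zeros(len(rxns))
    obj[rxns.index("BIOMASS")] = 1.0
    return MetabolicNetwork(mets, rxns, mat, np.array(lbs), np.array(ubs), obj)


def load_network(source) -> MetabolicNetwork:
    """Load a network from an SBML file or build the built-in one.

    Parameters
    ----------
    source : str or path
        ``"builtin"`` for the in-code minimal network, otherwise a path to
        an SBML (Level 3 FBC) core-model file, parsed with cobrapy.
    """
    if str(source) == BUILTIN_TAG:
        return builtin_network()
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(source))
    except Exception as exc:  # cobra raises various io errors
        raise ModelError(f"could not parse SBML {source!r}: {exc}") from exc
    return from_cobra(model)


def from_cobra(model) -> MetabolicNetwork:
    """Convert a cobra.Model to a :class:`MetabolicNetwork`."""
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, data = [], [], []
    for j, r in enumerate(model.reactions):
        for m, c in r.metabolites.items():
            rows.append(midx[m.id])
            cols.append(j)
            data.append(float(c))
    mat = sp.coo_matrix((data, (rows, cols)), shape=(len(mets), len(rxns))).tocsc()
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    obj = np.array(
        [r.objective_coefficient for r in model.reactions], dtype=float
    )
    biomass = None
    for r in model.reactions:
        if r.objective_coefficient != 0:
            biomass = r.id
            break
    if biomass is None:
        for r in model.reactions:
            if "biomass" in r.id.lower():
                biomass = r.id
                break
    if biomass is None:
        raise ModelError("no biomass reaction found (objective empty)")
    return MetabolicNetwork(mets, rxns, mat, lb, ub, obj, biomass_id=biomass)


def to_cobra(net: MetabolicNetwork):
    """Materialise the network as a cobra.Model (GLPK solver)."""
    import cobra

    model = cobra.Model("dcfba")
    mets = {m: cobra.Metabolite(m) for m in net.metabolite_ids}
    reactions = []
    for rid in net.reaction_ids:
        r = cobra.Reaction(rid)
        lo, hi = net.bounds(rid)
        r.lower_bound, r.upper_bound = lo, hi
        reactions.append(r)
    model.add_reactions(reactions)
    for rid in net.reaction_ids:
        stoich = net.reaction_stoichiometry(rid)
        model.reactions.get_by_id(rid).add_metabolites(
            {mets[m]: c for m, c in stoich.items()}
        )
    model.solver = "glpk"
    model.tolerance = LP_TOL
    return model


# ---------------------------------------------------------------------------
# genotype edits
# ---------------------------------------------------------------------------

def default_edit(dialect: str = BUILTIN_TAG) -> GenotypeEdit:
    """Genotype edit reproducing the production strain in a given dialect.

    The built-in network already encodes the genotype, so its edit is
    empty. For the *E. coli* core-model dialect the edit removes the
    adhE (ACALD + ALCD2x), ldhA (LDH_D), frdA (FRD7) and pta (PTAr)
    reactions and adds the butanediol pathway with transport/exchange.
    """
    if dialect == BUILTIN_TAG:
        return GenotypeEdit()
    if dialect != "core":
        raise EditError(f"unknown dialect {dialect!r}")
    inf = 1000.0
    return GenotypeEdit(
        deletions=["ACALD", "ALCD2x", "LDH_D", "FRD7", "PTAr"],
        additions=[
            ("ACLS", {"pyr_c": -2, "alac_c": 1, "co2_c": 1}, (0, inf)),
            ("ACLDC", {"alac_c": -1, "actn_c": 1, "co2_c": 1}, (0, inf)),
            ("BDH", {"actn_c": -1, "nadh_c": -1, "btd_c": 1, "nad_c": 1}, (0, inf)),
            ("ACTNt", {"actn_c": -1, "actn_e": 1}, (-inf, inf)),
            ("BTDt", {"btd_c": -1, "btd_e": 1}, (-inf, inf)),
            ("EX_actn", {"actn_e": -1}, (-inf, inf)),
            ("EX_btd", {"btd_e": -1}, (0, inf)),
        ],
    )


def apply_genotype(net: MetabolicNetwork, edit: GenotypeEdit) -> MetabolicNetwork:
    """Return a new network with the edit's deletions/additions applied."""
    for rid in edit.deletions:
        if rid not in net.reaction_ids:
            raise EditError(f"cannot delete unknown reaction {rid!r}")
    for rid, _, _ in edit.additions:
        if rid in net.reaction_ids and rid not in edit.deletions:
            raise EditError(f"addition {rid!r} collides with existing reaction")

    keep = [j for j, rid in enumerate(net.reaction_ids) if rid not in edit.deletions]
    rxns = [net.reaction_ids[j] for j in keep]
    mat = net.stoich[:, keep].tocoo()
    mets = list(net.metabolite_ids)
    midx = {m: i for i, m in enumerate(mets)}
    rows = list(mat.row)
    cols = list(mat.col)
    data = list(mat.data)
    lb = list(net.lower_bound[keep])
    ub = list(net.upper_bound[keep])
    for rid, stoich, (lo, hi) in edit.additions:
        j = len(rxns)
        rxns.append(rid)
        lb.append(float(lo))
        ub.append(float(hi))
        for m, c in stoich.items():
            if m not in midx:
                midx[m] = len(mets)
                mets.append(m)
            rows.append(midx[m])
            cols.append(j)
            data.append(float(c))
    newmat = sp.coo_matrix((data, (rows, cols)), shape=(len(mets), len(rxns))).tocsc()
    obj = np.zeros(len(rxns))
    if net.biomass_id in rxns:
        obj[rxns.index(net.biomass_id)] = 1.0
    return MetabolicNetwork(
        mets, rxns, newmat, np.array(lb), np.array(ub), obj, net.biomass_id
    )


def reverse_edit(original: MetabolicNetwork, edit: GenotypeEdit) -> GenotypeEdit:
    """Edit that undoes ``edit`` on a network derived from ``original``."""
    return GenotypeEdit(
        deletions=[rid for rid, _, _ in edit.additions],
        additions=[
            (rid, original.reaction_stoichiometry(rid), original.bounds(rid))
            for rid in edit.deletions
        ],
    )


# ---------------------------------------------------------------------------
# flux balance analysis
# ---------------------------------------------------------------------------

def fba_optimize(net: MetabolicNetwork, sense: str, objective: str):
    """Solve the FBA linear program for one objective reaction.

    Returns ``(fluxes, objective_value)`` where fluxes is a dict keyed by
    reaction id. Raises :class:`FeasibilityError` / :class:`UnboundedError`
    when the LP has no optimum in the requested sense.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    model = to_cobra(net)
    j = net.index(objective)  # validates the id
    model.objective = model.reactions.get_by_id(objective)
    model.objective_direction = "max" if sense == "max" else "min"
    with warnings.catch_warnings():
        # infeasibility is converted to a typed error below
        warnings.filterwarnings("ignore", message="Solver status")
        sol = model.optimize()
    if sol.status == "infeasible":
        fixed = {
            rid: net.bounds(rid)
            for rid in net.reaction_ids
            if net.bounds(rid)[0] == net.bounds(rid)[1]
            or net.bounds(rid)[0] > 0
            or net.bounds(rid)[1] < 0
        }
        raise FeasibilityError(
            f"FBA infeasible ({sense} {objective})", violated=fixed
        )
    if sol.status == "unbounded":
        raise UnboundedError(f"FBA unbounded ({sense} {objective})")
    if sol.status != "optimal":
        raise FeasibilityError(f"FBA solver status {sol.status!r}")
    fluxes = {rid: float(sol.fluxes[rid]) for rid in net.reaction_ids}
    return fluxes, float(sol.objective_value)


def min_oxygen_uptake(
    net: MetabolicNetwork,
    mu: float,
    gamma: float,
    delta: float,
    alpha: float,
    ids: dict = None,
    relax_maintenance: bool = False,
) -> float:
    """Minimal-magnitude oxygen exchange flux at fixed envelope rates.

    Parameters are production-envelope rates in g·gDW⁻¹·h⁻¹ (mu in h⁻¹):
    glucose uptake ``gamma`` (≤0), diol secretion ``delta``, acetoin
    exchange ``alpha``. The 2,3-butanediol rate is β = δ − α (must be ≥0).
    Growth and the three exchanges are fixed, then the oxygen exchange flux
    (≤0; negative = uptake) is maximised, i.e. its magnitude minimised.
    """
    ids = {**BUILTIN_IDS, **(ids or {})}
    beta = delta - alpha
    if beta < -1e-12:
        raise ValueError(f"beta = delta - alpha = {beta} must be >= 0")
    v_glc = g_to_mmol("glucose", gamma)
    v_actn = g_to_mmol("acetoin", alpha)
    v_btd = g_to_mmol("btd", max(beta, 0.0))
    updates = {
        ids["biomass"]: (mu, mu),
        ids["glucose"]: (v_glc, v_glc),
        ids["acetoin"]: (v_actn, v_actn),
        ids["btd"]: (v_btd, v_btd),
    }
    if relax_maintenance:
        lo, hi = net.bounds(ids["maintenance"])
        updates[ids["maintenance"]] = (0.0, hi)
    fixed = net.with_bounds(updates)
    try:
        _, xi = fba_optimize(fixed, "max", ids["oxygen"])
    except FeasibilityError as exc:
        raise FeasibilityError(
            f"no feasible flux state at mu={mu:.4g}, gamma={gamma:.4g}, "
            f"delta={delta:.4g}, alpha={alpha:.4g}",
            violated=exc.violated,
        ) from exc
    return xi
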