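"""Compartmentalized flux balance analysis with metabolite-rate constraints.

The model is a small C/N-annotated stoichiometric network spanning
extracellular space, cytosol, chloroplast, and mitochondrion.  Growth
(the biomass reaction) is maximized by linear programming subject to
S.v = 0, where measured metabolite pooling/consumption rates enter as
sink reactions with fixed flux (so the steady-state right-hand side
effectively becomes dx/dt).  A loopless solution is produced in the
CycleFreeFlux style: exchange, biomass, and sink fluxes are fixed,
internal reactions are restricted to the direction they carried, and
the internal L1 norm is minimized — the objective value is untouched
while thermodynamically infeasible cycles drop out.

Units are mmol per gram dry weight per hour throughout.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

ELEMENTS = ("C", "N")
BALANCED_TYPES = {"internal"}  # exchanges, biomass and sinks are exempt
FEAS_TOL = 1e-9


class ModelValidationError(ValueError):
    pass


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    type: str = "internal"  # internal | exchange | biomass | sink


@dataclass
class MetabolicModel:
    id: str
    compartments: dict[str, str]
    metabolites: dict[str, dict]          # id -> {compartment, C, N}
    reactions: list[Reaction]
    objective: str
    notes: str = ""

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id}")

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        mets = list(self.metabolites)
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[midx[met], j] = coef
        return S, mets

    def validate(self) -> None:
        """Check bounds, metabolite usage, and elemental balance."""
        violations = []
        used = set()
        for r in self.reactions:
            if r.lb > r.ub:
                raise ModelValidationError(f"{r.id}: lb > ub")
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    raise ModelValidationError(f"{r.id}: unknown metabolite {met}")
                used.add(met)
            if r.type in BALANCED_TYPES:
                for elem in ELEMENTS:
                    bal = sum(
                        coef * self.metabolites[met].get(elem, 0)
                        for met, coef in r.stoichiometry.items()
                    )
                    if abs(bal) > 1e-9:
                        violations.append(f"{r.id}: {elem} imbalance {bal:+g}")
        unused = set(self.metabolites) - used
        if unused:
            raise ModelValidationError(f"metabolites in no reaction: {sorted(unused)}")
        if violations:
            raise ModelValidationError(
                "unbalanced internal reactions:\n  " + "\n  ".join(violations)
            )
        self.reaction(self.objective)  # must exist


@dataclass
class FluxSolution:
    fluxes: pd.Series
    objective_value: float
    status: str
    model: MetabolicModel = field(repr=False, default=None)

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])


def load_model(source: str | Path | dict) -> MetabolicModel:
    """Load and validate a model from a JSON document (path or dict)."""
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lb=float(r["lb"]),
            ub=float(r["ub"]),
            type=r.get("type", "internal"),
        )
        for r in doc["reactions"]
    ]
    model = MetabolicModel(
        id=doc.get("id", "model"),
        compartments=doc.get("compartments", {}),
        metabolites={m["id"]: m for m in doc["metabolites"]},
        reactions=reactions,
        objective=doc["objective"],
        notes=doc.get("notes", ""),
    )
    model.validate()
    return model


def packaged_model() -> MetabolicModel:
    """The shipped toy compartmentalized nitrogen network."""
    with resources.files("nitrosense.data").joinpath("ptoy_nitrogen.json").open() as fh:
        return load_model(json.load(fh))


# ---------------------------------------------------------------------------
# constraints


def concentrations_to_rates(
    series: pd.DataFrame, protein_fraction: float = 0.70
) -> pd.Series:
    """Metabolite pooling/consumption rates from 0 h and 1 h concentrations.

    Concentrations are nmol per mg protein; with a protein fraction of
    total biomass f, the rate in mmol gDW^-1 h^-1 is
    dc * f * 1e3 (mg biomass/gDW) * 1e-6 (mmol/nmol) per hour.
    """
    for col in ("conc_0h", "conc_1h"):
        if col not in series.columns:
            raise ValueError(f"missing timepoint column {col}")
    delta = series["conc_1h"] - series["conc_0h"]
    rates = delta * protein_fraction * 1e-3
    return pd.Series(rates.to_numpy(), index=series["metabolite"].to_numpy(), name="rate")


def apply_constraints(
    model: MetabolicModel,
    rates: pd.Series | None = None,
    scenario: str = "nitrate",
    o2_max: float = 10.0,
    maintenance: float = 0.33,
    nh4_transport_cap: float = 0.1,
) -> MetabolicModel:
    """Apply the study's physiological constraints and metabolite sinks.

    Caps net O2 evolution, forces the maintenance flux through the
    mitochondrial alternative oxidase, restricts organelle-cytosol
    ammonium transport, opens exactly one nitrogen source exchange
    (nitrate or urea), and adds a fixed-flux sink for every measured
    metabolite rate.
    """
    if scenario not in ("nitrate", "urea"):
        raise ValueError("scenario must be 'nitrate' or 'urea'")
    m = model.copy()
    m.reaction("EX_o2_e").ub = o2_max
    m.reaction("AOX_m").lb = maintenance
    for rid in ("NH4t_hc", "NH4t_mc"):
        r = m.reaction(rid)
        r.lb, r.ub = -nh4_transport_cap, nh4_transport_cap
    no3, urea = m.reaction("EX_no3_e"), m.reaction("EX_urea_e")
    if scenario == "nitrate":
        no3.lb, no3.ub = -1000.0, 0.0
        urea.lb, urea.ub = 0.0, 0.0
    else:
        urea.lb, urea.ub = -1000.0, 0.0
        no3.lb, no3.ub = 0.0, 0.0
    if rates is not None:
        for met, rate in rates.items():
            if met not in m.metabolites:
                raise ValueError(f"sink metabolite {met!r} absent from model")
            m.reactions.append(
                Reaction(
                    id=f"SINK_{met}",
                    stoichiometry={met: -1.0},
                    lb=float(rate),
                    ub=float(rate),
                    type="sink",
                )
            )
    return m


# ---------------------------------------------------------------------------
# solving


def _solve(model: MetabolicModel, c: np.ndarray, extra_bounds=None):
    S, _ = model.stoichiometric_matrix()
    bounds = [(r.lb, r.ub) for r in model.reactions]
    if extra_bounds:
        for j, b in extra_bounds.items():
            bounds[j] = b
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL},
    )
    return res


def is_feasible(model: MetabolicModel) -> bool:
    res = _solve(model, np.zeros(len(model.reactions)))
    return res.status == 0


def fba_optimize(model: MetabolicModel) -> FluxSolution:
    """Maximize the objective reaction flux; raise on infeasibility."""
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective)] = -1.0
    res = _solve(model, c)
    if res.status == 2:
        raise RuntimeError(
            "model infeasible under current constraints; "
            "consider relax_to_feasible on the sink rates"
        )
    if res.status == 3:
        raise RuntimeError("objective unbounded; check exchange bounds")
    if res.status != 0:
        raise RuntimeError(f"solver failure: {res.message}")
    fluxes = pd.Series(res.x, index=model.reaction_ids)
    return FluxSolution(
        fluxes=fluxes,
        objective_value=float(-res.fun),
        status="optimal",
        model=model,
    )


def relax_to_feasible(model: MetabolicModel) -> tuple[MetabolicModel, list[dict]]:
    """Scale down infeasible sink rates until the model is feasible.

    Sinks are visited in order of decreasing rate magnitude; for each,
    the largest feasible scale of its rate is found by bisection (all
    later sinks untouched).  Returns the relaxed model and a report of
    every altered rate.  A feasible model is returned unchanged.
    """
    m = model.copy()
    report: list[dict] = []
    if is_feasible(m):
        return m, report
    sinks = sorted(
        (r for r in m.reactions if r.type == "sink"),
        key=lambda r: -abs(r.lb),
    )
    for sink in sinks:
        if is_feasible(m):
            break
        original = sink.lb
        sink.lb = sink.ub = 0.0
        if not is_feasible(m):
            continue  # zeroing this one is not enough on its own; keep at 0
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = (lo + hi) / 2
            sink.lb = sink.ub = original * mid
            if is_feasible(m):
                lo = mid
            else:
                hi = mid
        sink.lb = sink.ub = original * lo
        report.append(
            {"sink": sink.id, "original": original, "relaxed": original * lo}
        )
    if not is_feasible(m):
        raise RuntimeError("model infeasible even with all sinks at zero")
    return m, report


def loopless(model: MetabolicModel, solution: FluxSolution) -> FluxSolution:
    """CycleFreeFlux-style post-processing of an optimal solution.

    Exchange, biomass, and sink fluxes (and hence the objective) are
    fixed at their optimal values; every internal reaction is limited to
    the direction it carried; the internal L1 norm is minimized.  The
    result has the identical objective and exchange fluxes and an
    internal L1 norm no larger than the input's.
    """
    n = len(model.reactions)
    c = np.zeros(n)
    extra = {}
    v = solution.fluxes
    for j, r in enumerate(model.reactions):
        if r.type != "internal":
            extra[j] = (v[r.id], v[r.id])
        else:
            if v[r.id] >= 0:
                extra[j] = (0.0, v[r.id])
                c[j] = 1.0
            else:
                extra[j] = (v[r.id], 0.0)
                c[j] = -1.0
    res = _solve(model, c, extra_bounds=extra)
    if res.status != 0:
        raise RuntimeError(f"loopless LP failed: {res.message}")
    fluxes = pd.Series(res.x, index=model.reaction_ids)
    return FluxSolution(
        fluxes=fluxes,
        objective_value=float(fluxes[model.objective]),
        status="optimal",
        model=model,
    )


def internal_l1(model: MetabolicModel, solution: FluxSolution) -> float:
    return float(
        sum(abs(solution[r.id]) for r in model.reactions if r.type == "internal")
    )


# ---------------------------------------------------------------------------
# reporting


#: inter-organelle amino-nitrogen carriers: reaction id -> (carrier, N atoms)
SHUTTLE_ROUTES = {
    "ASPt_hm": ("aspartate", 1),
    "ALAt_mh": ("alanine", 1),
    "GLUt_hm": ("glutamate", 1),
    "GLNt_hm": ("glutamine", 2),
}


def shuttle_report(solution: FluxSolution) -> dict:
    """Net chloroplast-mitochondrion nitrogen shuttle usage.

    Route nitrogen flux is transporter flux times the N atoms of the
    carrier; dominance is each route's share of total inter-organelle
    amino nitrogen.  Also reports urea-cycle arginine synthesis flux,
    arginase flux, and the organelle of net ammonium assimilation.
    """
    model = solution.model
    missing = [rid for rid in SHUTTLE_ROUTES if rid not in solution.fluxes.index]
    if missing:
        raise ValueError(f"named transporters missing from model: {missing}")
    routes = {}
    for rid, (carrier, n_atoms) in SHUTTLE_ROUTES.items():
        routes[carrier] = abs(solution[rid]) * n_atoms
    total = sum(routes.values())
    dominance = {
        carrier: (flux / total if total > 0 else 0.0)
        for carrier, flux in routes.items()
    }
    gs_h = solution["GSII_h"] if "GSII_h" in solution.fluxes.index else 0.0
    gs_m = solution["GSIII_m"] if "GSIII_m" in solution.fluxes.index else 0.0
    report = {
        "routes_n_flux": routes,
        "dominance": dominance,
        "total_interorganelle_n": total,
        "arginine_synthesis_flux": solution["ASS_ASL_c"]
        if "ASS_ASL_c" in solution.fluxes.index
        else np.nan,
        "arginase_flux": solution["ARGASE_c"]
        if "ARGASE_c" in solution.fluxes.index
        else np.nan,
        "assimilation_organelle": "chloroplast" if gs_h >= gs_m else "mitochondrion",
    }
    return report


def nitrogen_balance(model: MetabolicModel, solution: FluxSolution) -> float:
    """Net nitrogen flux across non-internal reactions (should be ~0).

    Every boundary reaction's N throughput is summed; conservation means
    nitrogen entering via exchanges equals nitrogen leaving via biomass
    and sinks.
    """
    total = 0.0
    for r in model.reactions:
        if r.type in BALANCED_TYPES:
            continue
        n_flux = sum(
            coef * model.metabolites[met].get("N", 0)
            for met, coef in r.stoichiometry.items()
        )
        total += n_flux * solution[r.id]
    return total


def mass_balance_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    S, _ = model.stoichiometric_matrix()
    v = solution.fluxes.reindex(model.reaction_ids).to_numpy()
    return float(np.abs(S @ v).max())
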