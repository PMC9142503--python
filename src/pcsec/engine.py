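"""LP assembly, solving, and the bisection searches.

At a fixed specific growth rate mu the proteome-constrained model is a pure
LP: fluxes and abundances are nonnegative variables tied by mass balance,
per-protein dilution (v_syn - mu*a - v_deg = 0), enzyme/machinery capacity
(v <= kcat * a), Michaelis-Menten transporter saturation at the extracellular
substrate concentration, a total proteome mass budget and per-compartment
mass caps, and misfold coupling (v_misfold = r * v_translation).  Growth
itself is found by binary search on mu (feasibility is monotone), and the
minimal substrate concentration sustaining a given mu by binary search on S.

Abundance variables are scaled to umol/gDW internally to tame conditioning;
all reported quantities and tolerances are on the unscaled mmol/gDW scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .constants import ABUNDANCE_SCALE, TOTAL_PROTEIN_G_PER_GDW
from .core import PcModel, ValidationError

BIG = 1e6


def ppm_to_mmol(ppm: float, mw: float) -> float:
    """PaxDb-style ppm of proteome -> mmol/gDW at the package's reference
    total protein content."""
    return ppm * 1e-6 * TOTAL_PROTEIN_G_PER_GDW / mw


@dataclass
class SimulationContext:
    """Environment and experiment-specific constraints for one assembly."""

    #: extracellular glucose concentration, g/L (None = transporters saturated)
    glucose_conc: Optional[float] = None
    #: strip all capacity/budget rows (basic-GEM mode)
    basic_gem: bool = False
    #: uptake cap used for saturable uptake reactions in basic-GEM mode, mmol/gDW/h
    basic_uptake_cap: float = 10.0
    #: protein id -> fixed translation flux (mmol/gDW/h)
    translation_flux_fix: dict[str, float] = field(default_factory=dict)
    #: protein id -> extra lower bound on abundance (mmol/gDW)
    abundance_lb: dict[str, float] = field(default_factory=dict)
    #: protein id -> upper bound on abundance (mmol/gDW)
    abundance_ub: dict[str, float] = field(default_factory=dict)
    #: machinery id -> abundance cap (mmol/gDW)
    machinery_abundance_caps: dict[str, float] = field(default_factory=dict)
    #: total retro-translocation flux cap (mmol/gDW/h); enables accumulation
    retro_cap: Optional[float] = None
    #: apply native client demands (abundance/secretion lower bounds scaled
    #: from abundance_ref)
    native_demand: bool = True
    #: protein ids whose native demand is suspended (expression experiments)
    exclude_demand: set[str] = field(default_factory=set)
    #: extra overrides of compartment caps, g/gDW
    compartment_cap_overrides: dict[str, float] = field(default_factory=dict)
    #: cap on summed secretory machinery mass (g/gDW), the machinery_total knob
    machinery_total_cap: Optional[float] = None
    #: media overrides: exchange reaction id -> ub
    media_overrides: dict[str, float] = field(default_factory=dict)


@dataclass
class AssembledLP:
    var_names: list[str]
    lb: np.ndarray
    ub: np.ndarray
    #: equality rows (name, cols, coeffs, rhs)
    eq_rows: list[tuple[str, list[int], list[float], float]]
    #: inequality rows a.x <= rhs
    ub_rows: list[tuple[str, list[int], list[float], float]]
    index: dict[str, int]
    mu: float
    #: unscale factor per variable (multiply raw solution by this)
    unscale: np.ndarray

    def n(self) -> int:
        return len(self.var_names)

    def matrices(self):
        def build(rows):
            data, ri, ci = [], [], []
            rhs = np.zeros(len(rows))
            for r, (_, cols, coeffs, b) in enumerate(rows):
                rhs[r] = b
                for c, v in zip(cols, coeffs):
                    ri.append(r)
                    ci.append(c)
                    data.append(v)
            mat = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), self.n()))
            return mat, rhs

        return build(self.eq_rows), build(self.ub_rows)


@dataclass
class Solution:
    status: str  # optimal | infeasible | unbounded | numerical
    objective: Optional[float]
    values: Optional[np.ndarray]
    lp: Optional[AssembledLP]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, name: str) -> float:
        if self.values is None:
            raise KeyError("no solution values")
        return float(self.values[self.lp.index[name]])

    def get(self, name: str, default: float = 0.0) -> float:
        if self.values is None or name not in self.lp.index:
            return default
        return float(self.values[self.lp.index[name]])

    def abundance(self, protein_id: str) -> float:
        return self.get(f"a::{protein_id}")

    def flux(self, reaction_id: str) -> float:
        return self.get(reaction_id)


def _form_species(model: PcModel) -> dict[str, list[tuple[str, float]]]:
    """Map protein-form species -> [(reaction id, +1 produced / -1 consumed)]."""
    forms: dict[str, list[tuple[str, float]]] = {}
    for gid in sorted(model.generated):
        rxn = model.generated[gid]
        if rxn.form_in:
            forms.setdefault(rxn.form_in, []).append((rxn.id, -1.0))
        if rxn.form_out:
            forms.setdefault(rxn.form_out, []).append((rxn.id, +1.0))
    return forms


def assemble(model: PcModel, mu: float, context: Optional[SimulationContext] = None) -> AssembledLP:
    """Build the coupled LP at growth rate ``mu``."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not model.expanded and not context_is_metabolic_only(model):
        raise ValidationError("model must be expanded before assembly")
    ctx = context or SimulationContext()
    S = ctx.glucose_conc

    var_names: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    index: dict[str, int] = {}

    def add_var(name: str, lb: float = 0.0, ub: float = BIG) -> int:
        index[name] = len(var_names)
        var_names.append(name)
        lbs.append(lb)
        ubs.append(ub)
        return index[name]

    # --- variables (sorted ids: assembly order is canonical) ---------------
    for rid in sorted(model.network.reactions):
        rxn = model.network.reactions[rid]
        lb, ub = rxn.lb, rxn.ub
        if rxn.id in ctx.media_overrides:
            ub = ctx.media_overrides[rxn.id]
        if ctx.basic_gem and rxn.transporter is not None:
            ub = min(ub, ctx.basic_uptake_cap)
        if rxn.id == model.network.biomass_id:
            lb = ub = mu
        add_var(rxn.id, lb, ub)
    for gid in sorted(model.generated):
        add_var(gid)
    secreted: list[str] = []
    for pid in sorted(model.specs):
        spec = model.specs[pid]
        add_var(f"a::{pid}")
        if spec.localization == "extracellular" and model.expanded:
            add_var(f"SEC::{pid}")
            secreted.append(pid)
    for cid in sorted(model.complexes):
        add_var(f"ac::{cid}")
    accum_pids: list[str] = []
    if ctx.retro_cap is not None and model.expanded:
        for gid in sorted(model.generated):
            if gid.startswith("RETRO_"):
                accum_pids.append(model.generated[gid].protein_id)
        for pid in accum_pids:
            add_var(f"s::{pid}")

    # translation flux fixes
    for pid, v in ctx.translation_flux_fix.items():
        i = index[f"TRANSL_{pid}"]
        lbs[i] = ubs[i] = v

    scale = np.ones(len(var_names))
    for name, i in index.items():
        if name.startswith(("a::", "ac::")):
            scale[i] = 1.0 / ABUNDANCE_SCALE  # raw var is umol; value*scale = mmol

    eq_rows: list[tuple[str, list[int], list[float], float]] = []
    ub_rows: list[tuple[str, list[int], list[float], float]] = []

    def add_eq(name, cols, coeffs, rhs=0.0):
        eq_rows.append((name, cols, coeffs, rhs))

    def add_le(name, cols, coeffs, rhs=0.0):
        ub_rows.append((name, cols, coeffs, rhs))

    # --- metabolite mass balance ------------------------------------------
    met_rows: dict[str, tuple[list[int], list[float]]] = {
        m: ([], []) for m in sorted(model.network.metabolites)
    }
    for rid in sorted(model.network.reactions):
        rxn = model.network.reactions[rid]
        i = index[rxn.id]
        for m in sorted(rxn.stoich):
            met_rows[m][0].append(i)
            met_rows[m][1].append(rxn.stoich[m])
    for gid in sorted(model.generated):
        rxn = model.generated[gid]
        i = index[rxn.id]
        for m, c in sorted(rxn.met_stoich.items()):
            if m not in met_rows:
                raise ValidationError(f"generated reaction {rxn.id} uses unknown metabolite {m}")
            met_rows[m][0].append(i)
            met_rows[m][1].append(c)
    for m, (cols, coeffs) in met_rows.items():
        if cols:
            add_eq(f"mb::{m}", cols, coeffs)

    # --- protein-form balance and dilution --------------------------------
    ascale = 1.0 / ABUNDANCE_SCALE
    if model.expanded:
        forms = _form_species(model)
        for form in sorted(forms):
            parts = forms[form]
            pid = form.split(":", 1)[0]
            cols = [index[r] for r, _ in parts]
            coeffs = [s for _, s in parts]
            kind = form.split(":", 1)[1]
            if kind == "mature":
                spec = model.specs[pid]
                if spec.localization == "extracellular":
                    cols.append(index[f"SEC::{pid}"])
                    coeffs.append(-1.0)
                else:
                    cols.append(index[f"a::{pid}"])
                    coeffs.append(-mu * ascale)
                add_eq(f"pb::{pid}", cols, coeffs)
            elif kind == "erad_ready" and pid in accum_pids and model.specs[pid].retention_rounds > 0:
                cols.append(index[f"s::{pid}"])
                coeffs.append(-1.0)
                add_eq(f"fb::{form}", cols, coeffs)
            elif kind == "misfolded" and pid in accum_pids and model.specs[pid].retention_rounds == 0:
                cols.append(index[f"s::{pid}"])
                coeffs.append(-1.0)
                add_eq(f"fb::{form}", cols, coeffs)
            else:
                add_eq(f"fb::{form}", cols, coeffs)

        # misfold coupling v_misf = r * v_transl
        for gid in sorted(model.generated):
            rxn = model.generated[gid]
            if rxn.id.startswith("MISF_"):
                pid = rxn.protein_id
                r = model.specs[pid].misfold_ratio
                add_eq(
                    f"mc::{pid}",
                    [index[rxn.id], index[f"TRANSL_{pid}"]],
                    [1.0, -r],
                )

    if not ctx.basic_gem:
        # --- metabolic enzyme capacity ------------------------------------
        for rid_ in sorted(model.network.reactions):
            rxn = model.network.reactions[rid_]
            if rxn.transporter is not None:
                kin = model.transporters[rxn.transporter]
                sat = 1.0 if S is None else kin.saturation(S)
                cap = kin.kcat * sat * ascale
                add_le(
                    f"cap::{rxn.id}",
                    [index[rxn.id], index[f"a::{kin.protein_id}"]],
                    [1.0, -cap],
                )
            elif rxn.enzyme is not None:
                cx = model.complexes[rxn.enzyme]
                kcat = cx.kcats.get(rxn.id)
                if kcat is None:
                    raise ValidationError(f"no kcat for reaction {rxn.id} on complex {cx.id}")
                add_le(
                    f"cap::{rxn.id}",
                    [index[rxn.id], index[f"ac::{cx.id}"]],
                    [1.0, -kcat * ascale],
                )

        # --- complex allocation: sum_C n * a_C <= a_P ----------------------
        alloc: dict[str, tuple[list[int], list[float]]] = {}
        for cid_ in sorted(model.complexes):
            cx = model.complexes[cid_]
            for pid in sorted(cx.subunits):
                alloc.setdefault(pid, ([], []))
                alloc[pid][0].append(index[f"ac::{cx.id}"])
                alloc[pid][1].append(float(cx.subunits[pid]))
        for pid in sorted(alloc):
            cols, coeffs = alloc[pid]
            add_le(f"alloc::{pid}", cols + [index[f"a::{pid}"]], coeffs + [-1.0])

        if model.expanded:
            # --- machinery occupancy -------------------------------------
            mach_rows: dict[str, tuple[list[int], list[float]]] = {
                mid: ([], []) for mid in sorted(model.machineries)
            }
            for gid in sorted(model.generated):
                rxn = model.generated[gid]
                for mid, w in rxn.machinery:
                    if mid not in mach_rows:
                        raise ValidationError(f"unknown machinery {mid} in {rxn.id}")
                    if w > 0:
                        mach_rows[mid][0].append(index[rxn.id])
                        mach_rows[mid][1].append(float(w))
            for rid in sorted(model.network_machinery_load):
                for mid, w in model.network_machinery_load[rid]:
                    mach_rows[mid][0].append(index[rid])
                    mach_rows[mid][1].append(float(w))
            for mid in sorted(mach_rows):
                cols, coeffs = mach_rows[mid]
                mach = model.machineries[mid]
                cols = list(cols)
                coeffs = list(coeffs)
                cols.append(index[f"a::{mach.protein_id}"])
                coeffs.append(-mach.kcat * ascale)
                # retained/accumulated misfolded protein sequesters chaperones
                if mid in ("kar2", "pdi1") and accum_pids and mu > 0:
                    for pid in accum_pids:
                        cols.append(index[f"s::{pid}"])
                        coeffs.append(mach.kcat / mu)
                add_le(f"mcap::{mid}", cols, coeffs)

            # retro-translocation flux cap
            if ctx.retro_cap is not None:
                cols = [index[r.id] for r in model.generated.values() if r.id.startswith("RETRO_")]
                if cols:
                    add_le("retrocap", cols, [1.0] * len(cols), ctx.retro_cap)

            # machinery abundance caps (sensitivity knobs)
            for mid, cap in ctx.machinery_abundance_caps.items():
                pid = model.machineries[mid].protein_id
                i = index[f"a::{pid}"]
                ubs[i] = min(ubs[i], cap * ABUNDANCE_SCALE)

            # machinery_total knob: summed secretory machinery mass
            if ctx.machinery_total_cap is not None:
                pids = sorted({m.protein_id for m in model.machineries.values() if m.id != "ribosome"})
                cols = [index[f"a::{p}"] for p in pids]
                coeffs = [model.specs[p].composition.mw * ascale for p in pids]
                add_le("machtotal", cols, coeffs, ctx.machinery_total_cap)

        # --- proteome budget and compartment caps --------------------------
        budget = model.params.get("proteome_budget")
        if budget is not None and model.expanded:
            cols, coeffs = [], []
            for pid in sorted(model.specs):
                spec = model.specs[pid]
                if spec.localization == "extracellular":
                    continue
                cols.append(index[f"a::{pid}"])
                coeffs.append(spec.composition.mw * ascale)
            for pid in accum_pids:
                if mu > 0:
                    cols.append(index[f"s::{pid}"])
                    coeffs.append(model.specs[pid].composition.mw / mu)
            add_le("budget", cols, coeffs, budget)

        caps = dict(model.compartment_caps)
        caps.update(ctx.compartment_cap_overrides)
        if model.expanded:
            for comp in sorted(caps):
                cap = caps[comp]
                cols, coeffs = [], []
                for pid in sorted(model.specs):
                    spec = model.specs[pid]
                    if spec.localization == comp:
                        cols.append(index[f"a::{pid}"])
                        coeffs.append(spec.composition.mw * ascale)
                if comp in ("ER", "ER_membrane"):
                    for pid in accum_pids:
                        if mu > 0:
                            cols.append(index[f"s::{pid}"])
                            coeffs.append(model.specs[pid].composition.mw / mu)
                if cols:
                    add_le(f"ccap::{comp}", cols, coeffs, cap)

    # --- demands -----------------------------------------------------------
    if model.expanded:
        dummy_mass = model.params.get("dummy_mass")
        if dummy_mass and model.dummy_protein and not ctx.basic_gem:
            spec = model.specs[model.dummy_protein]
            i = index[f"a::{model.dummy_protein}"]
            lbs[i] = max(lbs[i], dummy_mass / spec.composition.mw * ABUNDANCE_SCALE)
        if ctx.native_demand:
            for pid in sorted(model.specs):
                spec = model.specs[pid]
                if model.roles.get(pid) != "client" or spec.abundance_ref <= 0:
                    continue
                if pid in ctx.exclude_demand:
                    continue
                ref = ppm_to_mmol(spec.abundance_ref, spec.composition.mw)
                if spec.localization == "extracellular":
                    i = index[f"SEC::{pid}"]
                    lbs[i] = max(lbs[i], mu * ref)
                else:
                    i = index[f"a::{pid}"]
                    lbs[i] = max(lbs[i], ref * ABUNDANCE_SCALE)
        for pid, v in ctx.abundance_lb.items():
            i = index[f"a::{pid}"]
            lbs[i] = max(lbs[i], v * ABUNDANCE_SCALE)
        for pid, v in ctx.abundance_ub.items():
            i = index[f"a::{pid}"]
            ubs[i] = min(ubs[i], v * ABUNDANCE_SCALE)

    return AssembledLP(
        var_names=var_names,
        lb=np.array(lbs),
        ub=np.array(ubs),
        eq_rows=eq_rows,
        ub_rows=ub_rows,
        index=index,
        mu=mu,
        unscale=scale,
    )


def context_is_metabolic_only(model: PcModel) -> bool:
    return len(model.specs) == 0


_STATUS = {0: "optimal", 1: "numerical", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve(
    lp: AssembledLP,
    objective: Optional[dict[str, float]] = None,
    sense: str = "min",
) -> Solution:
    """Solve the assembled LP with HiGHS (via scipy.optimize.linprog).

    ``objective`` maps variable names to coefficients on the *unscaled*
    (mmol) scale; ``None`` solves a pure feasibility problem.
    """
    n = lp.n()
    c = np.zeros(n)
    if objective:
        for name, coeff in objective.items():
            i = lp.index[name]
            c[i] = coeff * lp.unscale[i]
        if sense == "max":
            c = -c
    elif sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")

    (A_eq, b_eq), (A_ub, b_ub) = lp.matrices()
    res = linprog(
        c,
        A_ub=A_ub if A_ub.shape[0] else None,
        b_ub=b_ub if A_ub.shape[0] else None,
        A_eq=A_eq if A_eq.shape[0] else None,
        b_eq=b_eq if A_eq.shape[0] else None,
        bounds=np.column_stack([lp.lb, lp.ub]),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": 1e-9,
            "dual_feasibility_tolerance": 1e-9,
        },
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return Solution(status=status, objective=None, values=None, lp=lp)
    values = res.x * lp.unscale
    obj = float(res.fun) if objective else 0.0
    if objective and sense == "max":
        obj = -obj
    return Solution(status="optimal", objective=obj, values=values, lp=lp)


def solve_lexicographic(
    lp: AssembledLP,
    objectives: Sequence[tuple[dict[str, float], str]],
    slack: float = 1e-9,
) -> Solution:
    """Solve a sequence of objectives, fixing each optimum before the next."""
    sol: Optional[Solution] = None
    for k, (obj, sense) in enumerate(objectives):
        sol = solve(lp, obj, sense)
        if not sol.ok:
            return sol
        if k == len(objectives) - 1:
            break
        # pin this objective with a small relative slack (rows act on raw
        # internally-scaled variables, hence the unscale factor)
        cols = [lp.index[name] for name in obj]
        coeffs = [obj[name] * lp.unscale[i] for name, i in zip(obj, cols)]
        eps = slack * max(1.0, abs(sol.objective))
        if sense == "max":
            lp.ub_rows.append((f"lex{k}", cols, [-x for x in coeffs], -(sol.objective - eps)))
        else:
            lp.ub_rows.append((f"lex{k}", cols, coeffs, sol.objective + eps))
    return sol


def min_abundance_objective(model: PcModel) -> dict[str, float]:
    """Canonical tie-breaker: minimize total modeled proteome mass."""
    return {
        f"a::{pid}": spec.composition.mw
        for pid, spec in model.specs.items()
        if spec.localization != "extracellular"
    }


@dataclass
class GrowthResult:
    mu_star: float
    feasible: Solution
    infeasible_mu: float
    tol: float


def feasible_at(model: PcModel, mu: float, context: Optional[SimulationContext] = None) -> Solution:
    lp = assemble(model, mu, context)
    return solve(lp, None, "min")


def max_growth(
    model: PcModel,
    context: Optional[SimulationContext] = None,
    tol: float = 1e-4,
    mu_hi: float = 1.0,
    context_fn: Optional[Callable[[float], SimulationContext]] = None,
) -> GrowthResult:
    """Binary search for the maximum feasible specific growth rate.

    ``context_fn`` builds a mu-dependent context (e.g. expression levels
    pinned to a multiple of the native, mu-proportional translation flux);
    it overrides ``context`` when given.
    """
    def probe(mu: float) -> Solution:
        ctx = context_fn(mu) if context_fn is not None else context
        return solve(assemble(model, mu, ctx), None, "min")

    s0 = probe(0.0)
    if not s0.ok:
        raise ValidationError("model infeasible at mu = 0")
    lo, lo_sol = 0.0, s0
    hi = mu_hi
    while probe(hi).ok:
        lo = hi
        hi *= 2.0
        if hi > 16.0:
            raise ValidationError("growth appears unbounded (mu > 16/h)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        s = probe(mid)
        if s.ok:
            lo, lo_sol = mid, s
        else:
            hi = mid
    return GrowthResult(mu_star=lo, feasible=lo_sol, infeasible_mu=hi, tol=tol)


def min_glucose_for_growth(
    model: PcModel,
    mu: float,
    context: Optional[SimulationContext] = None,
    tol: float = 1e-4,
    s_hi: float = 400.0,
) -> float:
    """Binary search for the minimal glucose concentration sustaining ``mu``."""
    import copy

    ctx = copy.copy(context) if context is not None else SimulationContext()
    if mu == 0:
        return 0.0

    def ok(s: float) -> bool:
        ctx.glucose_conc = s
        return feasible_at(model, mu, ctx).ok

    if not ok(s_hi):
        raise ValidationError(f"mu={mu} infeasible even at S={s_hi} g/L")
    lo, hi = 0.0, s_hi
    while (hi - lo) > tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def residuals(sol: Solution) -> dict[str, float]:
    """Constraint residuals of an optimal solution, grouped by row class.

    Returns the maximum absolute equality residual and the maximum
    inequality violation for each row-name prefix (``pb`` protein balance,
    ``cap``/``mcap`` capacity, ``mb`` mass balance, ...), all on the raw
    row scale (fluxes mmol/gDW/h).
    """
    if not sol.ok:
        raise ValueError("residuals require an optimal solution")
    lp = sol.lp
    x = sol.values / lp.unscale
    out: dict[str, float] = {}
    for name, cols, coeffs, rhs in lp.eq_rows:
        r = abs(sum(c * x[i] for i, c in zip(cols, coeffs)) - rhs)
        key = name.split("::", 1)[0]
        out[key] = max(out.get(key, 0.0), r)
    for name, cols, coeffs, rhs in lp.ub_rows:
        r = sum(c * x[i] for i, c in zip(cols, coeffs)) - rhs
        key = name.split("::", 1)[0]
        out[key] = max(out.get(key, 0.0), r)
    return out


# ---------------------------------------------------------------------------
# LP-file emission (CPLEX LP text format)
# ---------------------------------------------------------------------------


def _lp_name(name: str) -> str:
    out = []
    for ch in name:
        out.append(ch if ch.isalnum() or ch in "_.#$%&()/," else "_")
    s = "".join(out)
    if s[0].isdigit() or s[0] == ".":
        s = "x" + s
    return s


def write_lp(lp: AssembledLP, path: str, objective: Optional[dict[str, float]] = None,
             sense: str = "min") -> None:
    """Emit the assembled LP in CPLEX LP text format (17 significant digits).

    Coefficients are written on the raw (internally scaled) variable basis so
    that re-parsing reproduces the constraint matrix exactly.
    """
    if objective is not None and len(objective) == 0:
        raise ValueError("empty objective")
    names = [_lp_name(v) for v in lp.var_names]
    if len(set(names)) != len(names):
        raise ValidationError("LP name mangling collided")
    lines = []
    lines.append("\\ pcsec assembled LP, mu=%.17g" % lp.mu)
    lines.append("Minimize" if sense == "min" else "Maximize")
    terms = []
    if objective:
        for vname, coeff in objective.items():
            i = lp.index[vname]
            terms.append("%+.17g %s" % (coeff * lp.unscale[i], names[i]))
    lines.append(" obj: " + (" ".join(terms) if terms else "0 " + names[0]))
    lines.append("Subject To")

    def emit(rows, op):
        for rname, cols, coeffs, rhs in rows:
            parts = " ".join("%+.17g %s" % (c, names[i]) for i, c in zip(cols, coeffs))
            lines.append(" %s: %s %s %.17g" % (_lp_name(rname), parts, op, rhs))

    emit(lp.eq_rows, "=")
    emit(lp.ub_rows, "<=")
    lines.append("Bounds")
    for i, name in enumerate(names):
        lo, hi = lp.lb[i], lp.ub[i]
        lines.append(" %.17g <= %s <= %.17g" % (lo, name, hi))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
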