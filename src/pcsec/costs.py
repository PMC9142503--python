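"""Secretory-cost calculus.

Three cost notions, all in glucose-equivalents (mmol glucose per mmol
protein):

* **direct cost** — minimal glucose to synthesize one protein's material
  content (amino acids, bound glycans, energetic molecules) on the
  capacity-free network: only mass balance and reaction bounds constrain
  the solution, no machinery share is charged.
* **unit secretory cost** — the slope of minimal glucose uptake versus a
  small forced production rate at fixed growth, on the full
  proteome-constrained model; this includes the proportional share of every
  catalytic machinery along the route.
* **transporter secretory cost** — unit cost times the transporter
  abundance required to carry a given total uptake at concentration S under
  Michaelis-Menten saturation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PcModel, ProteinSpec, TransporterKinetics, ValidationError
from .engine import SimulationContext, assemble, solve, solve_lexicographic
from .templates import add_cassette


def _production_model(model: PcModel, spec: ProteinSpec) -> tuple[PcModel, str]:
    """Model copy with a mature-form drain for ``spec`` and its var name."""
    m = copy.deepcopy(model)
    if spec.id in m.specs:
        # make a production copy so native demands are untouched
        spec = spec.model_copy(update={"id": spec.id + "_prod"})
    if spec.localization == "extracellular":
        add_cassette(m, spec)
        return m, f"SEC::{spec.id}"
    # cell-resident protein: drain the mature form explicitly
    add_cassette(m, spec)
    from .core import GenReaction

    drain = GenReaction(
        id=f"DRAIN_{spec.id}",
        protein_id=spec.id,
        process_id="vesicle_sorting",
        met_stoich={},
        form_in=f"{spec.id}:mature",
        form_out=None,
    )
    m.generated[drain.id] = drain
    return m, drain.id


def _glucose_objective(model: PcModel) -> dict[str, float]:
    obj = {
        r.id: 1.0
        for r in model.network.reactions.values()
        if r.transporter is not None
    }
    if not obj:
        # no saturable transporters: fall back to glucose source exchanges
        obj = {
            r.id: 1.0
            for r in model.network.reactions.values()
            if r.exchange and any(m.startswith("glc") and c > 0 for m, c in r.stoich.items())
        }
    if not obj:
        raise ValidationError("no glucose uptake reactions in model")
    return obj


def direct_cost(model: PcModel, spec: ProteinSpec) -> float:
    """Minimal glucose per mmol of finished protein, capacity-free.

    The protein's own route reactions supply the material recipe; with all
    enzyme/machinery coupling stripped the LP charges only precursor and
    energy stoichiometry.
    """
    if spec.composition.length == 0:
        return 0.0
    m, drain = _production_model(model, spec)
    ctx = SimulationContext(basic_gem=True, basic_uptake_cap=1e6, native_demand=False)
    lp = assemble(m, 0.0, ctx)
    i = lp.index[drain]
    lp.lb[i] = lp.ub[i] = 1.0
    # NGAM would contaminate the per-protein cost; remove the floor
    j = lp.index.get("NGAM")
    if j is not None:
        lp.lb[j] = 0.0
    sol = solve(lp, _glucose_objective(m), "min")
    if not sol.ok:
        raise ValidationError(f"direct cost infeasible for {spec.id}: {sol.status}")
    return sol.objective


def unit_secretory_cost(
    model: PcModel,
    spec: ProteinSpec,
    mu: float = 0.1,
    fractions: Optional[Sequence[float]] = None,
    glucose_conc: Optional[float] = None,
) -> tuple[float, dict]:
    """Slope of minimal glucose uptake against forced production at fixed mu.

    Returns ``(cost, diagnostics)`` where diagnostics carries the grid used
    and the R^2 of the least-squares slope fit (an LP response is locally
    linear, so R^2 should be ~1 within one basis).
    """
    m, drain = _production_model(model, spec)
    ctx = SimulationContext(glucose_conc=glucose_conc)
    obj = _glucose_objective(m)

    lp0 = assemble(m, mu, ctx)
    base = solve(lp0, obj, "min")
    if not base.ok:
        raise ValidationError(f"model infeasible at mu={mu}")

    if fractions is None:
        # default: 5 points spanning ~0.1-1% of proteome-budget throughput
        budget = m.params.get("proteome_budget", 0.1)
        scale = budget * mu / max(spec.composition.mw, 1e-9)
        fractions = list(np.linspace(0.001, 0.01, 5) * scale)

    rates, uptakes = [0.0], [base.objective]
    dropped = 0
    for p in fractions:
        lp = assemble(m, mu, ctx)
        i = lp.index[drain]
        lp.lb[i] = lp.ub[i] = float(p)
        sol = solve(lp, obj, "min")
        if not sol.ok:
            dropped += 1
            continue
        rates.append(float(p))
        uptakes.append(sol.objective)
    if len(rates) < 3:
        raise ValidationError(f"forced-production grid infeasible for {spec.id}")
    fit = stats.linregress(rates, uptakes)
    diags = {
        "points": len(rates),
        "dropped": dropped,
        "r2": float(fit.rvalue**2),
        "intercept": float(fit.intercept),
    }
    return float(fit.slope), diags


def transporter_cost(
    unit_cost: float,
    v_glc_total: float,
    kinetics: TransporterKinetics,
    s: float,
) -> float:
    """Secretory cost of carrying ``v_glc_total`` through one transporter.

    cost = unit_cost * required abundance
         = unit_cost * V / (kcat * S/(S+KM)).
    """
    if s <= 0:
        raise ValueError("S must be > 0")
    if unit_cost <= 0 or v_glc_total <= 0:
        raise ValueError("unit_cost and V must be > 0")
    return unit_cost * v_glc_total / (kinetics.kcat * kinetics.saturation(s))


def transporter_cost_crossing(
    unit_costs: tuple[float, float],
    kinetics: tuple[TransporterKinetics, TransporterKinetics],
    bracket: tuple[float, float],
    v_glc_total: float = 1.0,
) -> float:
    """Concentration at which two transporters' secretory costs are equal."""
    from scipy.optimize import brentq

    u1, u2 = unit_costs
    k1, k2 = kinetics

    def gap(s: float) -> float:
        return transporter_cost(u1, v_glc_total, k1, s) - transporter_cost(u2, v_glc_total, k2, s)

    return float(brentq(gap, *bracket))


@dataclass
class CostRecord:
    protein_id: str
    direct_cost: float
    unit_secretory_cost: float
    r2: float
    points: int

    @property
    def ratio(self) -> float:
        return self.unit_secretory_cost / self.direct_cost

    @property
    def flagged(self) -> bool:
        return self.r2 < 0.99


def cost_table(
    model: PcModel,
    specs: Optional[Sequence[ProteinSpec]] = None,
    mu: float = 0.1,
    glucose_conc: Optional[float] = None,
) -> pd.DataFrame:
    """Direct and unit secretory costs, one row per protein, sorted by id."""
    if specs is None:
        specs = [model.specs[k] for k in sorted(model.specs)]
    rows = []
    for spec in sorted(specs, key=lambda s: s.id):
        d = direct_cost(model, spec)
        u, diag = unit_secretory_cost(model, spec, mu=mu, glucose_conc=glucose_conc)
        rows.append(
            {
                "id": spec.id,
                "direct": d,
                "unit": u,
                "ratio": u / d if d > 0 else np.inf,
                "r2": diag["r2"],
                "flagged": diag["r2"] < 0.99,
            }
        )
    return pd.DataFrame(rows, columns=["id", "direct", "unit", "ratio", "r2", "flagged"])


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Convenience helper for users correlating costs with their own data."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
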