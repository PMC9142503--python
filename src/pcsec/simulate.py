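"""The three simulation campaigns: glucose-series physiology, recombinant
production curves, and misfolding/accumulation experiments.

All campaigns resolve solver degeneracy lexicographically: after the primary
objective is optimal it is pinned and total glucose uptake (where relevant)
and then total modeled proteome mass are minimized, which makes transporter
usage splits and reported abundances deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import PcModel, ProteinSpec, ValidationError
from .engine import (
    GrowthResult,
    SimulationContext,
    assemble,
    max_growth,
    min_abundance_objective,
    min_glucose_for_growth,
    ppm_to_mmol,
    solve,
    solve_lexicographic,
)
from .templates import add_cassette


def _uptake_reactions(model: PcModel) -> dict[str, str]:
    """transporter protein id -> uptake reaction id"""
    return {
        r.transporter: r.id
        for r in model.network.reactions.values()
        if r.transporter is not None
    }


def _glucose_objective(model: PcModel) -> dict[str, float]:
    return {rid: 1.0 for rid in _uptake_reactions(model).values()}


@dataclass
class GlucoseSeriesResult:
    table: pd.DataFrame  # one row per concentration
    solutions: list  # refined Solution per concentration (for audits)

    @property
    def critical_mu(self) -> Optional[float]:
        """Smallest mu* with positive overflow flux, if any."""
        above = self.table[self.table.overflow > 1e-6]
        return float(above.mu.min()) if len(above) else None


def glucose_series(model: PcModel, s_grid: Sequence[float], tol: float = 1e-4) -> GlucoseSeriesResult:
    """Max growth followed by lexicographic glucose/proteome minimization at
    each extracellular glucose concentration.

    Reports mu*, total and per-transporter uptake, overflow (ethanol) and
    respiration (oxygen) fluxes.
    """
    if len(s_grid) == 0:
        raise ValueError("empty concentration grid")
    upt = _uptake_reactions(model)
    if len(upt) < 1:
        raise ValidationError("model has no saturable transporter")
    rows = []
    sols = []
    for S in s_grid:
        ctx = SimulationContext(glucose_conc=float(S))
        growth = max_growth(model, ctx, tol=tol)
        lp = assemble(model, growth.mu_star, ctx)
        sol = solve_lexicographic(
            lp,
            [(_glucose_objective(model), "min"), (min_abundance_objective(model), "min")],
        )
        if not sol.ok:
            raise ValidationError(f"refinement infeasible at S={S}")
        per_t = {t: sol.get(rid) for t, rid in upt.items()}
        total = sum(per_t.values())
        row = {
            "S": float(S),
            "mu": growth.mu_star,
            "glucose_uptake": total,
            "overflow": sol.get("EX_etoh_out"),
            "respiration": sol.get("RESP"),
        }
        for t, v in per_t.items():
            row[f"uptake_{t}"] = v
            row[f"share_{t}"] = v / total if total > 1e-12 else 0.0
        rows.append(row)
        sols.append(sol)
    return GlucoseSeriesResult(table=pd.DataFrame(rows), solutions=sols)


# ---------------------------------------------------------------------------
# recombinant production
# ---------------------------------------------------------------------------


@dataclass
class RecombinantCurve:
    table: pd.DataFrame  # mu, S, production, production_basic
    mu_star: float
    solutions: list

    @property
    def argmax_mu(self) -> float:
        t = self.table.dropna(subset=["production"])
        return float(t.mu[t.production.idxmax()])


def chemostat_concentration(
    model: PcModel, mu_grid: Sequence[float], margin: float = 1.5, tol: float = 1e-3
) -> list[float]:
    """Residual glucose concentration per dilution rate: the minimal
    concentration sustaining mu (cassette-free), times a finite search
    margin, emulating a sampled minimal-concentration protocol."""
    return [margin * min_glucose_for_growth(model, mu, tol=tol) for mu in mu_grid]


def recombinant_curve(
    model: PcModel,
    cassette: ProteinSpec,
    mu_grid: Sequence[float],
    s_per_mu: Optional[Sequence[float]] = None,
    margin: float = 1.5,
) -> RecombinantCurve:
    """Maximum cassette secretion per growth rate, pc-model and basic-GEM.

    At each mu the extracellular glucose concentration is the chemostat
    residual concentration for that dilution rate; growth is fixed and
    cassette secretion maximized (then proteome mass minimized).  The
    basic-GEM variant strips every capacity/budget row and bounds uptake by
    the media cap only, which yields the contrasting linear profile.
    """
    base = model
    m = copy.deepcopy(model)
    add_cassette(m, cassette)
    sec = f"SEC::{cassette.id}"
    if s_per_mu is None:
        s_per_mu = chemostat_concentration(base, mu_grid, margin=margin)
    g = max_growth(m, SimulationContext(glucose_conc=None))
    rows, sols = [], []
    for mu, S in zip(mu_grid, s_per_mu):
        ctx = SimulationContext(glucose_conc=float(S))
        lp = assemble(m, float(mu), ctx)
        sol = solve_lexicographic(
            lp, [({sec: 1.0}, "max"), (min_abundance_objective(m), "min")]
        )
        prod = sol.get(sec) if sol.ok else np.nan
        bctx = SimulationContext(basic_gem=True)
        blp = assemble(m, float(mu), bctx)
        bsol = solve(blp, {sec: 1.0}, "max")
        rows.append(
            {
                "mu": float(mu),
                "S": float(S),
                "production": prod,
                "production_basic": bsol.objective if bsol.ok else np.nan,
                "feasible": sol.ok,
            }
        )
        sols.append(sol)
    return RecombinantCurve(table=pd.DataFrame(rows), mu_star=g.mu_star, solutions=sols)


def max_production(
    model: PcModel,
    cassette: ProteinSpec,
    n_mu: int = 6,
    mu_fractions: tuple[float, float] = (0.2, 0.9),
    s_per_mu: Optional[Sequence[float]] = None,
    mu_star: Optional[float] = None,
) -> float:
    """Maximum secretion over a mu grid (the label used by the
    feature-importance analysis)."""
    if mu_star is None:
        mu_star = max_growth(model, SimulationContext(glucose_conc=None)).mu_star
    grid = np.linspace(mu_fractions[0] * mu_star, mu_fractions[1] * mu_star, n_mu)
    curve = recombinant_curve(model, cassette, grid, s_per_mu=s_per_mu)
    return float(np.nanmax(curve.table.production.values))


# ---------------------------------------------------------------------------
# misfolding experiments
# ---------------------------------------------------------------------------


@dataclass
class MisfoldingResult:
    table: pd.DataFrame
    solutions: dict = field(default_factory=dict)


def _with_misfolding(model: PcModel, pid: str, r: float, rho: int) -> PcModel:
    m = copy.deepcopy(model)
    spec = m.specs[pid].model_copy(update={"misfold_ratio": r, "retention_rounds": rho})
    m.specs[pid] = spec
    from .templates import expand_all

    expand_all(m)  # routes depend only on specs; single pass
    return m


def misfolding_experiment(
    model: PcModel,
    pid: str,
    folds: Sequence[float],
    ratios: Sequence[float],
    rounds: int = 0,
    retro_cap: Optional[float] = None,
    tol: float = 1e-4,
) -> MisfoldingResult:
    """Expression-by-misfolding grid for one client protein.

    Expression at fold ``f`` fixes the translation flux to f times the
    native level (mu times the reference abundance), so the constraint
    scales with growth during the bisection.  With a retro-translocation
    cap the degradation flux plateaus at the cap and the accumulation slack
    activates, the accumulated species occupying ER space and sequestering
    the Kar2/Pdi1 analogs.
    """
    spec0 = model.specs[pid]
    ref = ppm_to_mmol(spec0.abundance_ref, spec0.composition.mw)
    rows = []
    sols = {}
    for r in ratios:
        m = _with_misfolding(model, pid, float(r), rounds if r > 0 else 0)

        for f in folds:
            def ctx_fn(mu: float, _f=f) -> SimulationContext:
                return SimulationContext(
                    glucose_conc=None,
                    translation_flux_fix={pid: _f * mu * ref},
                    exclude_demand={pid},
                    retro_cap=retro_cap,
                )

            try:
                growth = max_growth(m, context_fn=ctx_fn, tol=tol)
            except ValidationError:
                rows.append(
                    {"fold": f, "ratio": r, "rounds": rounds, "mu": np.nan,
                     "feasible": False, "v_transl": np.nan, "degradation": np.nan,
                     "accumulation": np.nan, "kar2": np.nan, "pdi1": np.nan}
                )
                continue
            mu = growth.mu_star
            lp = assemble(m, mu, ctx_fn(mu))
            objectives = [(min_abundance_objective(m), "min")]
            if retro_cap is not None:
                objectives.insert(0, ({f"s::{pid}": 1.0}, "min"))
            sol = solve_lexicographic(lp, objectives)
            deg = sol.get(f"ERAD_{pid}")
            acc = sol.get(f"s::{pid}")
            rows.append(
                {
                    "fold": f, "ratio": r, "rounds": rounds, "mu": mu,
                    "feasible": True,
                    "v_transl": sol.get(f"TRANSL_{pid}"),
                    "degradation": deg,
                    "accumulation": acc,
                    "kar2": sol.abundance("kar2"),
                    "pdi1": sol.abundance("pdi1"),
                }
            )
            sols[(f, r, rounds)] = sol
    return MisfoldingResult(table=pd.DataFrame(rows), solutions=sols)


SENSITIVITY_KNOBS = (
    "ERAD_capacity",
    "ER_volume",
    "ER_membrane",
    "machinery_total",
    "retro_translocation",
)


def parameter_sensitivity(
    model: PcModel,
    pid: str,
    knob: str,
    tighten: Sequence[float],
    fold: float = 25.0,
    ratio: float = 1.0,
    rounds: int = 1,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """mu* (and accumulation) as one constraint bound is tightened.

    ``tighten`` values multiply the knob's unconstrained reference bound;
    compartment-space knobs are proteome-abundance caps.  Only the
    retro-translocation knob admits ER accumulation of the misfolded
    protein — the others simply depress mu*.
    """
    if knob not in SENSITIVITY_KNOBS:
        raise ValueError(f"unknown sensitivity knob {knob!r}")
    spec0 = model.specs[pid]
    ref = ppm_to_mmol(spec0.abundance_ref, spec0.composition.mw)
    m = _with_misfolding(model, pid, ratio, rounds)

    # unconstrained reference levels for the knob
    base_ctx = SimulationContext(glucose_conc=None)
    base_growth = max_growth(m, context_fn=lambda mu: SimulationContext(
        glucose_conc=None, translation_flux_fix={pid: fold * mu * ref},
        exclude_demand={pid}), tol=tol)
    lp0 = assemble(m, base_growth.mu_star, SimulationContext(
        glucose_conc=None, translation_flux_fix={pid: fold * base_growth.mu_star * ref},
        exclude_demand={pid}))
    sol0 = solve_lexicographic(lp0, [(min_abundance_objective(m), "min")])

    rows = []
    for t in tighten:
        def ctx_fn(mu: float, _t=t) -> SimulationContext:
            ctx = SimulationContext(
                glucose_conc=None,
                translation_flux_fix={pid: fold * mu * ref},
                exclude_demand={pid},
            )
            if knob == "ERAD_capacity":
                ctx.machinery_abundance_caps = {
                    "proteasome": max(sol0.abundance("proteasome"), 1e-12) * _t
                }
            elif knob == "ER_volume":
                ctx.compartment_cap_overrides = {
                    "ER": model.compartment_caps.get("ER", 0.004) * _t
                }
            elif knob == "ER_membrane":
                ctx.compartment_cap_overrides = {
                    "ER_membrane": model.compartment_caps.get("ER_membrane", 0.02) * _t
                }
            elif knob == "machinery_total":
                mach_mass = sum(
                    sol0.abundance(mm.protein_id) * m.specs[mm.protein_id].composition.mw
                    for mm in m.machineries.values() if mm.id != "ribosome"
                )
                ctx.machinery_total_cap = max(mach_mass, 1e-12) * _t
            else:  # retro_translocation: flux cap, accumulation allowed
                kcat = m.machineries["retro"].kcat
                ctx.retro_cap = max(sol0.abundance("retro"), 1e-12) * kcat * _t
            return ctx

        try:
            growth = max_growth(m, context_fn=ctx_fn, tol=tol)
            mu = growth.mu_star
            lp = assemble(m, mu, ctx_fn(mu))
            objectives = [(min_abundance_objective(m), "min")]
            if knob == "retro_translocation":
                objectives.insert(0, ({f"s::{pid}": 1.0}, "min"))
            sol = solve_lexicographic(lp, objectives)
            rows.append({
                "knob": knob, "tighten": t, "mu": mu, "feasible": True,
                "accumulation": sol.get(f"s::{pid}", 0.0),
                "degradation": sol.get(f"ERAD_{pid}", 0.0),
            })
        except ValidationError:
            rows.append({"knob": knob, "tighten": t, "mu": np.nan,
                         "feasible": False, "accumulation": np.nan,
                         "degradation": np.nan})
    return pd.DataFrame(rows)
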