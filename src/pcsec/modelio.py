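"""Model serialization: native JSON schema, SBML (metabolic part) import,
and the PSIM TSV interface.

JSON is the native, versioned schema and round-trips the complete model
(including generated reactions).  SBML L3/FBC import covers the metabolic
network only — the secretory extensions have no SBML standard.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .constants import AMINO_ACIDS
from .core import (
    AminoAcidComposition,
    EnzymeComplex,
    GenReaction,
    Machinery,
    MetNetwork,
    Metabolite,
    PcModel,
    ProteinSpec,
    Reaction,
    TransporterKinetics,
    ValidationError,
)

SCHEMA_VERSION = 1


def _rxn_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoich": {k: r.stoich[k] for k in sorted(r.stoich)},
        "lb": r.lb,
        "ub": r.ub,
        "enzyme": r.enzyme,
        "isozymes": r.isozymes,
        "exchange": r.exchange,
        "transporter": r.transporter,
    }


def model_to_dict(model: PcModel) -> dict:
    net = model.network
    return {
        "schema_version": SCHEMA_VERSION,
        "network": {
            "metabolites": [
                {"id": m.id, "compartment": m.compartment}
                for m in sorted(net.metabolites.values(), key=lambda x: x.id)
            ],
            "reactions": [_rxn_to_dict(net.reactions[k]) for k in sorted(net.reactions)],
            "biomass_id": net.biomass_id,
            "protein_pool_met": net.protein_pool_met,
            "media": {k: net.media[k] for k in sorted(net.media)},
        },
        "specs": {k: model.specs[k].model_dump() for k in sorted(model.specs)},
        "complexes": {k: model.complexes[k].model_dump() for k in sorted(model.complexes)},
        "transporters": {k: model.transporters[k].model_dump() for k in sorted(model.transporters)},
        "machineries": {
            k: {"id": m.id, "protein_id": m.protein_id, "kcat": m.kcat, "basis": m.basis}
            for k, m in sorted(model.machineries.items())
        },
        "generated": {
            k: {
                "id": g.id,
                "protein_id": g.protein_id,
                "process_id": g.process_id,
                "met_stoich": {m: g.met_stoich[m] for m in sorted(g.met_stoich)},
                "form_in": g.form_in,
                "form_out": g.form_out,
                "machinery": sorted(g.machinery),
                "aa_release": {m: g.aa_release[m] for m in sorted(g.aa_release)},
            }
            for k, g in sorted(model.generated.items())
        },
        "dummy_protein": model.dummy_protein,
        "roles": {k: model.roles[k] for k in sorted(model.roles)},
        "network_machinery_load": {
            k: sorted(v) for k, v in sorted(model.network_machinery_load.items())
        },
        "params": {k: model.params[k] for k in sorted(model.params)},
        "compartment_caps": {k: model.compartment_caps[k] for k in sorted(model.compartment_caps)},
        "expanded": model.expanded,
    }


def model_from_dict(d: dict) -> PcModel:
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(f"/schema_version: expected {SCHEMA_VERSION}, got {d.get('schema_version')!r}")
    try:
        nd = d["network"]
        net = MetNetwork(
            metabolites={m["id"]: Metabolite(m["id"], m["compartment"]) for m in nd["metabolites"]},
            biomass_id=nd.get("biomass_id"),
            protein_pool_met=nd.get("protein_pool_met"),
            media=dict(nd.get("media", {})),
        )
        for rd in nd["reactions"]:
            net.reactions[rd["id"]] = Reaction(
                id=rd["id"],
                stoich=dict(rd["stoich"]),
                lb=rd["lb"],
                ub=rd["ub"],
                enzyme=rd.get("enzyme"),
                isozymes=rd.get("isozymes"),
                exchange=rd.get("exchange", False),
                transporter=rd.get("transporter"),
            )
        model = PcModel(
            network=net,
            specs={k: ProteinSpec(**v) for k, v in d.get("specs", {}).items()},
            complexes={k: EnzymeComplex(**v) for k, v in d.get("complexes", {}).items()},
            transporters={k: TransporterKinetics(**v) for k, v in d.get("transporters", {}).items()},
            machineries={
                k: Machinery(id=v["id"], protein_id=v["protein_id"], kcat=v["kcat"], basis=v.get("basis", "per_event"))
                for k, v in d.get("machineries", {}).items()
            },
            generated={
                k: GenReaction(
                    id=v["id"],
                    protein_id=v["protein_id"],
                    process_id=v["process_id"],
                    met_stoich=dict(v.get("met_stoich", {})),
                    form_in=v.get("form_in"),
                    form_out=v.get("form_out"),
                    machinery=[(a, float(b)) for a, b in v.get("machinery", [])],
                    aa_release=dict(v.get("aa_release", {})),
                )
                for k, v in d.get("generated", {}).items()
            },
            dummy_protein=d.get("dummy_protein"),
            roles=dict(d.get("roles", {})),
            network_machinery_load={
                k: [(a, float(b)) for a, b in v]
                for k, v in d.get("network_machinery_load", {}).items()
            },
            params=dict(d.get("params", {})),
            compartment_caps=dict(d.get("compartment_caps", {})),
            expanded=bool(d.get("expanded", False)),
        )
    except KeyError as e:
        raise ValidationError(f"/{e.args[0]}: missing required field") from e
    model.validate()
    return model


def save_model(model: PcModel, path: str) -> None:
    """Write the model as deterministic (sorted, fixed-format) JSON."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path: str) -> PcModel:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"cannot parse model JSON: {e}") from e
    return model_from_dict(d)


# ---------------------------------------------------------------------------
# SBML import (metabolic part only)
# ---------------------------------------------------------------------------


def read_sbml_network(path: str) -> MetNetwork:
    """Import the metabolic part of an SBML L3 (FBC) file as a MetNetwork."""
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValidationError(f"SBML parse error in {path}")
    sbml = doc.getModel()
    net = MetNetwork()

    # SBML identifiers are commonly namespaced with M_/R_ prefixes
    species_ids = [
        sbml.getSpecies(i).getId() for i in range(sbml.getNumSpecies())
    ]
    strip_m = bool(species_ids) and all(s.startswith("M_") for s in species_ids)
    rxn_ids = [sbml.getReaction(i).getId() for i in range(sbml.getNumReactions())]
    strip_r = bool(rxn_ids) and all(r.startswith("R_") for r in rxn_ids)

    def met_id(s: str) -> str:
        return s[2:] if strip_m else s

    def rxn_id(s: str) -> str:
        return s[2:] if strip_r else s

    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mid = met_id(sp.getId())
        net.metabolites[mid] = Metabolite(mid, sp.getCompartment() or "c")

    fbc = sbml.getPlugin("fbc")
    params = {
        sbml.getParameter(i).getId(): sbml.getParameter(i).getValue()
        for i in range(sbml.getNumParameters())
    }
    for i in range(sbml.getNumReactions()):
        rx = sbml.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            m = met_id(sr.getSpecies())
            if m in net.metabolites:
                stoich[m] = stoich.get(m, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            m = met_id(sr.getSpecies())
            if m in net.metabolites:
                stoich[m] = stoich.get(m, 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rfbc is not None:
            if rfbc.getLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.getUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
        elif rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        if not rx.getReversible() and lb < 0:
            lb = 0.0
        rid = rxn_id(rx.getId())
        net.reactions[rid] = Reaction(
            id=rid, stoich=stoich, lb=lb, ub=ub,
            exchange=len(stoich) <= 1,
        )
    return net


# ---------------------------------------------------------------------------
# PSIM TSV
# ---------------------------------------------------------------------------

PSIM_COLUMNS = (
    ["id"]
    + [f"count_{aa}" for aa in AMINO_ACIDS]
    + ["loc", "transloc", "NG", "OG", "DSB", "GPI", "TM", "r", "rho",
       "abundance_ppm", "complex", "paralog"]
)


def specs_to_psim(specs: Iterable[ProteinSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        row: dict = {"id": s.id}
        for aa in AMINO_ACIDS:
            row[f"count_{aa}"] = s.composition.counts.get(aa, 0)
        row.update(
            loc=s.localization, transloc=s.translocation_mode,
            NG=s.n_NG, OG=s.n_OG, DSB=s.n_DSB, GPI=int(s.gpi), TM=s.n_TM,
            r=s.misfold_ratio, rho=s.retention_rounds,
            abundance_ppm=s.abundance_ref,
            complex=int(s.is_complex_subunit), paralog=int(s.has_paralog),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=PSIM_COLUMNS)


def psim_to_specs(df: pd.DataFrame) -> list[ProteinSpec]:
    missing = [c for c in PSIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"PSIM table missing columns: {missing}")
    specs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        comp = AminoAcidComposition(
            counts={aa: int(d[f"count_{aa}"]) for aa in AMINO_ACIDS if int(d[f"count_{aa}"]) > 0}
        )
        specs.append(
            ProteinSpec(
                id=str(d["id"]), composition=comp, localization=str(d["loc"]),
                translocation_mode=str(d["transloc"]),
                n_NG=int(d["NG"]), n_OG=int(d["OG"]), n_DSB=int(d["DSB"]),
                gpi=bool(d["GPI"]), n_TM=int(d["TM"]),
                misfold_ratio=float(d["r"]), retention_rounds=int(d["rho"]),
                abundance_ref=float(d["abundance_ppm"]),
                is_complex_subunit=bool(d["complex"]), has_paralog=bool(d["paralog"]),
            )
        )
    return specs


def write_psim(specs: Iterable[ProteinSpec], path: str) -> None:
    specs_to_psim(specs).to_csv(path, sep="\t", index=False)


def read_psim(path: str) -> list[ProteinSpec]:
    return psim_to_specs(pd.read_csv(path, sep="\t"))
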