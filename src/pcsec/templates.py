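"""Template-reaction expansion of protein specifications.

Protein synthesis and secretion are divided into 12 processes (translation,
translocation, ER/Golgi N- and O-glycosylation, disulfide-bond formation,
GPI-anchor transfer, COPII/COPI transport, vesicle sorting, ERAD).  Each
process is a parameterized template: given a :class:`~pcsec.core.ProteinSpec`
it emits one reaction that consumes the protein's upstream form and small
metabolites (linear in residue/site counts) and produces the downstream form,
registering occupancy on the machinery that performs the process.

The misfolding branch is coupled to translation (v_misfold = r * v_transl)
at LP-assembly time; here the branch reactions themselves are generated:
misfolding, optional multi-round chaperone retention, retro-translocation,
and proteasomal degradation that recycles amino acids and glycan precursors
against an ATP toll.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .constants import DEFAULT_TEMPLATE_COEFFICIENTS, PROCESS_IDS
from .core import GenReaction, PcModel, ProteinSpec, ValidationError


@dataclass
class TemplateConfig:
    """Editable per-process coefficient table.

    Rows are ``(process, metabolite, coefficient, basis)`` with basis in
    {per_protein, per_residue, per_site}.  Defaults follow the package's
    documented assumptions (e.g. 4 ATP-equivalents per translated residue,
    1 glycan precursor per N-site, proteasome toll of 1 ATP per 4 residues).
    """

    rows: list[tuple[str, str, float, str]] = field(
        default_factory=lambda: list(DEFAULT_TEMPLATE_COEFFICIENTS)
    )
    #: fraction of amino acids recovered by proteasomal recycling
    erad_aa_recycle: float = 1.0
    #: extra translocation occupancy per transmembrane domain (residue-equivalents)
    tm_occupancy: float = 50.0

    def coefficients(self, process: str) -> list[tuple[str, float, str]]:
        return [(m, c, b) for p, m, c, b in self.rows if p == process]

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.rows, columns=["process", "metabolite", "coefficient", "basis"])
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "TemplateConfig":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        rows = [
            (str(r.process), str(r.metabolite), float(r.coefficient), str(r.basis))
            for r in df.itertuples()
        ]
        return cls(rows=rows)


@dataclass
class Route:
    """Ordered process list for one protein plus its branch choices."""

    protein_id: str
    processes: list[str]
    sorting_branch: str = "retained"   # LDSV | HDSV | ALPP | CPYP | retained
    misfolding_branch: str = "none"    # ERAD | retention | none


def derive_route(spec: ProteinSpec) -> Route:
    """Apply the per-process applicability predicates to one spec.

    ER PTM order is fixed (translocation -> NG -> DSB -> OG -> GPI); the
    sorting branch follows localization (vacuole via CPYP/ALPP, surface via
    LDSV/HDSV, ER/Golgi residents retrieved by COPI).
    """
    if not spec.is_secretory:
        return Route(spec.id, ["translation"])

    if spec.localization == "cytosol":
        raise ValidationError(f"{spec.id}: secretory route with cytosolic localization")

    procs = ["translation", "translocation"]
    if spec.ptm_count("n_NG") > 0:
        procs.append("ER_NG")
    if spec.ptm_count("n_DSB") > 0:
        procs.append("DSB")
    if spec.ptm_count("n_OG") > 0:
        procs.append("ER_OG")
    if spec.gpi or (spec.ptm_fractional or {}).get("gpi", 0) > 0:
        procs.append("GPI_transfer")

    misfold = "none"
    if spec.misfold_ratio > 0:
        misfold = "retention" if spec.retention_rounds > 0 else "ERAD"
        procs.append("ERAD")

    branch = "retained"
    loc = spec.localization
    if loc in ("ER", "ER_membrane"):
        procs.append("COPI")
    elif loc == "Golgi":
        procs.append("COPII")
        if spec.ptm_count("n_NG") > 0:
            procs.append("Golgi_NG")
        if spec.ptm_count("n_OG") > 0:
            procs.append("Golgi_OG")
        procs.append("COPI")
    else:
        procs.append("COPII")
        if spec.ptm_count("n_NG") > 0:
            procs.append("Golgi_NG")
        if spec.ptm_count("n_OG") > 0:
            procs.append("Golgi_OG")
        if loc == "vacuole":
            branch = "ALPP" if spec.gpi else "CPYP"
        elif loc == "plasma_membrane":
            branch = "LDSV"
        else:  # extracellular and other exported
            branch = "HDSV"
        procs.append("vesicle_sorting")

    return Route(spec.id, procs, sorting_branch=branch, misfolding_branch=misfold)


def _met_coeffs(config: TemplateConfig, process: str, spec: ProteinSpec, sites: float) -> dict[str, float]:
    L = spec.composition.length
    out: dict[str, float] = {}
    for met, coeff, basis in config.coefficients(process):
        if basis == "per_residue":
            amount = coeff * L
        elif basis == "per_site":
            amount = coeff * sites
        else:
            amount = coeff
        if amount != 0:
            out[met] = out.get(met, 0.0) - amount
    return out


MACHINERY_FOR_PROCESS = {
    "translocation": "sec61",
    "ER_NG": "ost",
    "DSB": "pdi1",
    "ER_OG": "pmt",
    "GPI_transfer": "gpit",
    "COPII": "copii",
    "COPI": "copi",
    "Golgi_NG": "gost",
    "Golgi_OG": "gpmt",
    "vesicle_sorting": "sorter",
}


def expand_protein(
    spec: ProteinSpec,
    config: TemplateConfig,
    known_metabolites: Optional[set[str]] = None,
) -> list[GenReaction]:
    """Generate the full reaction chain for one protein.

    Protein forms are chained ``P:nascent -> ... -> P:mature``; the
    misfolding branch (if ``misfold_ratio`` can be nonzero) splits at the
    end of ER processing into retention/retro-translocation/degradation.
    """
    route = derive_route(spec)
    L = spec.composition.length
    pid = spec.id
    rxns: list[GenReaction] = []

    def check_mets(stoich: dict[str, float], process: str) -> None:
        if known_metabolites is None:
            return
        for m in stoich:
            if m not in known_metabolites:
                raise ValidationError(
                    f"{pid}/{process}: precursor metabolite {m!r} missing from network"
                )

    # -- translation (always first, lumped) --------------------------------
    stoich = {aa_met(aa): -float(n) for aa, n in spec.composition.counts.items()}
    for met, coeff, basis in config.coefficients("translation"):
        amount = coeff * L if basis == "per_residue" else coeff
        stoich[met] = stoich.get(met, 0.0) - amount
    for met, coeff in spec.cofactor_demand.items():
        stoich[met] = stoich.get(met, 0.0) - coeff
    check_mets(stoich, "translation")
    form = f"{pid}:nascent" if spec.is_secretory else None
    rxns.append(
        GenReaction(
            id=f"TRANSL_{pid}",
            protein_id=pid,
            process_id="translation",
            met_stoich=stoich,
            form_in=None,
            form_out=form if form else f"{pid}:mature",
            machinery=[("ribosome", float(L))],
        )
    )
    if not spec.is_secretory:
        return rxns

    # -- ER entry and PTMs --------------------------------------------------
    prev = f"{pid}:nascent"

    def step(process: str, sites: float, suffix: str, machinery_weight: float,
             extra_mach: Optional[list[tuple[str, float]]] = None) -> None:
        nonlocal prev
        stoich = _met_coeffs(config, process, spec, sites)
        check_mets(stoich, process)
        nxt = f"{pid}:{suffix}"
        mach = []
        mname = MACHINERY_FOR_PROCESS.get(process)
        if mname is not None and machinery_weight > 0:
            mach.append((mname, machinery_weight))
        if extra_mach:
            mach.extend(extra_mach)
        rxns.append(
            GenReaction(
                id=f"{process.upper()}_{pid}",
                protein_id=pid,
                process_id=process,
                met_stoich=stoich,
                form_in=prev,
                form_out=nxt,
                machinery=mach,
            )
        )
        prev = nxt

    # translocation: co-translational uses GTP, post-translational ATP;
    # occupancy is per-residue plus a surcharge per TM domain.
    occ = float(L) + config.tm_occupancy * spec.ptm_count("n_TM")
    if spec.translocation_mode == "post_translational":
        stoich = _met_coeffs(config, "translocation_post", spec, 0.0)
    else:
        stoich = _met_coeffs(config, "translocation", spec, 0.0)
    check_mets(stoich, "translocation")
    rxns.append(
        GenReaction(
            id=f"TRANSLOC_{pid}",
            protein_id=pid,
            process_id="translocation",
            met_stoich=stoich,
            form_in=prev,
            form_out=f"{pid}:er",
            machinery=[("sec61", occ)],
        )
    )
    prev = f"{pid}:er"

    n_ng = spec.ptm_count("n_NG")
    n_og = spec.ptm_count("n_OG")
    n_dsb = spec.ptm_count("n_DSB")
    gpi_mult = (spec.ptm_fractional or {}).get("gpi", 1.0 if spec.gpi else 0.0)

    if "ER_NG" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("ER_NG"):
            amount = coeff * n_ng if basis == "per_site" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        check_mets(stoich, "ER_NG")
        rxns.append(GenReaction(
            id=f"ER_NG_{pid}", protein_id=pid, process_id="ER_NG",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:er_ng",
            machinery=[("ost", n_ng)],
        ))
        prev = f"{pid}:er_ng"
    if "DSB" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("DSB"):
            amount = coeff * n_dsb if basis == "per_site" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        check_mets(stoich, "DSB")
        rxns.append(GenReaction(
            id=f"DSB_{pid}", protein_id=pid, process_id="DSB",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:er_dsb",
            machinery=[("pdi1", n_dsb)],
        ))
        prev = f"{pid}:er_dsb"
    if "ER_OG" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("ER_OG"):
            amount = coeff * n_og if basis == "per_site" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        check_mets(stoich, "ER_OG")
        rxns.append(GenReaction(
            id=f"ER_OG_{pid}", protein_id=pid, process_id="ER_OG",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:er_og",
            machinery=[("pmt", n_og)],
        ))
        prev = f"{pid}:er_og"
    if "GPI_transfer" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("GPI_transfer"):
            stoich[met] = stoich.get(met, 0.0) - coeff * gpi_mult
        check_mets(stoich, "GPI_transfer")
        rxns.append(GenReaction(
            id=f"GPI_{pid}", protein_id=pid, process_id="GPI_transfer",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:er_gpi",
            machinery=[("gpit", max(gpi_mult, 1e-12))],
        ))
        prev = f"{pid}:er_gpi"

    er_done = prev

    # -- folding vs misfolding split ---------------------------------------
    # Folding occupies the Kar2-analog chaperone once per molecule.
    rxns.append(GenReaction(
        id=f"FOLD_{pid}", protein_id=pid, process_id="translocation",
        met_stoich={}, form_in=er_done, form_out=f"{pid}:folded",
        machinery=[("kar2", 1.0)],
    ))
    prev = f"{pid}:folded"

    if spec.misfold_ratio > 0 or route.misfolding_branch != "none":
        rho = spec.retention_rounds
        rxns.append(GenReaction(
            id=f"MISF_{pid}", protein_id=pid, process_id="ERAD",
            met_stoich={}, form_in=er_done, form_out=f"{pid}:misfolded",
            machinery=[],
        ))
        erad_in = f"{pid}:misfolded"
        if rho > 0:
            # each retention round occupies one Kar2 and one Pdi1 slot
            rxns.append(GenReaction(
                id=f"RETAIN_{pid}", protein_id=pid, process_id="ERAD",
                met_stoich={}, form_in=erad_in, form_out=f"{pid}:erad_ready",
                machinery=[("kar2", float(rho)), ("pdi1", float(rho))],
            ))
            erad_in = f"{pid}:erad_ready"
        rxns.append(GenReaction(
            id=f"RETRO_{pid}", protein_id=pid, process_id="ERAD",
            met_stoich={}, form_in=erad_in, form_out=f"{pid}:cyto_misfolded",
            machinery=[("retro", 1.0)],
        ))
        # proteasomal degradation: amino acids and ER glycans recycled,
        # ATP toll per residue basis from the template table.
        eta = config.erad_aa_recycle
        stoich = {aa_met(aa): eta * n for aa, n in spec.composition.counts.items()}
        for met, coeff, basis in config.coefficients("ERAD"):
            amount = coeff * L if basis == "per_residue" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        if n_ng > 0:
            stoich["glycan"] = stoich.get("glycan", 0.0) + n_ng
        check_mets(stoich, "ERAD")
        rxns.append(GenReaction(
            id=f"ERAD_{pid}", protein_id=pid, process_id="ERAD",
            met_stoich=stoich, form_in=f"{pid}:cyto_misfolded", form_out=None,
            machinery=[("proteasome", 1.0)],
            aa_release={aa: eta * n for aa, n in spec.composition.counts.items()},
        ))

    # -- anterograde transport / sorting / retention -----------------------
    loc = spec.localization
    if loc in ("ER", "ER_membrane"):
        stoich = _met_coeffs(config, "COPI", spec, 0.0)
        check_mets(stoich, "COPI")
        rxns.append(GenReaction(
            id=f"COPI_{pid}", protein_id=pid, process_id="COPI",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:mature",
            machinery=[("copi", 1.0)],
        ))
        return rxns

    stoich = _met_coeffs(config, "COPII", spec, 0.0)
    check_mets(stoich, "COPII")
    rxns.append(GenReaction(
        id=f"COPII_{pid}", protein_id=pid, process_id="COPII",
        met_stoich=stoich, form_in=prev, form_out=f"{pid}:golgi",
        machinery=[("copii", 1.0)],
    ))
    prev = f"{pid}:golgi"

    if "Golgi_NG" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("Golgi_NG"):
            amount = coeff * n_ng if basis == "per_site" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        check_mets(stoich, "Golgi_NG")
        rxns.append(GenReaction(
            id=f"GOLGI_NG_{pid}", protein_id=pid, process_id="Golgi_NG",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:golgi_ng",
            machinery=[("gost", n_ng)],
        ))
        prev = f"{pid}:golgi_ng"
    if "Golgi_OG" in route.processes:
        stoich = {}
        for met, coeff, basis in config.coefficients("Golgi_OG"):
            amount = coeff * n_og if basis == "per_site" else coeff
            stoich[met] = stoich.get(met, 0.0) - amount
        check_mets(stoich, "Golgi_OG")
        rxns.append(GenReaction(
            id=f"GOLGI_OG_{pid}", protein_id=pid, process_id="Golgi_OG",
            met_stoich=stoich, form_in=prev, form_out=f"{pid}:golgi_og",
            machinery=[("gpmt", n_og)],
        ))
        prev = f"{pid}:golgi_og"

    if loc == "Golgi":
        rxns.append(GenReaction(
            id=f"COPI_{pid}", protein_id=pid, process_id="COPI",
            met_stoich=_met_coeffs(config, "COPI", spec, 0.0),
            form_in=prev, form_out=f"{pid}:mature",
            machinery=[("copi", 1.0)],
        ))
        return rxns

    stoich = _met_coeffs(config, "vesicle_sorting", spec, 0.0)
    check_mets(stoich, "vesicle_sorting")
    rxns.append(GenReaction(
        id=f"SORT_{pid}", protein_id=pid, process_id="vesicle_sorting",
        met_stoich=stoich, form_in=prev, form_out=f"{pid}:mature",
        machinery=[("sorter", 1.0)],
    ))
    return rxns


def aa_met(aa: str) -> str:
    """Metabolite id of a free amino acid."""
    return f"aa_{aa}"


def expand_all(model: PcModel, config: Optional[TemplateConfig] = None) -> PcModel:
    """Expand every protein (clients, machinery, ribosomal) in place.

    Machinery proteins are expanded with the same templates, so an
    N-glycosylated machinery (a Pdi1-like protein) is itself an ER_NG
    client.  Expansion is a single pass and idempotent: routes depend only
    on the specs.
    """
    if config is None:
        config = TemplateConfig(rows=list(DEFAULT_TEMPLATE_COEFFICIENTS))
        if "template_erad_recycle" in model.params:
            config.erad_aa_recycle = model.params["template_erad_recycle"]
    for m in model.machineries.values():
        if m.protein_id not in model.specs:
            raise ValidationError(f"machinery {m.id} lacks a ProteinSpec")
    known = set(model.network.metabolites)
    model.generated = {}
    for pid in sorted(model.specs):
        for rxn in expand_protein(model.specs[pid], config, known_metabolites=known):
            model.generated[rxn.id] = rxn
    model.expanded = True
    model.params.setdefault("template_erad_recycle", config.erad_aa_recycle)
    model._template_config = config  # kept for incremental cassette insertion
    return model


def add_cassette(model: PcModel, spec: ProteinSpec, config: Optional[TemplateConfig] = None) -> PcModel:
    """Insert a recombinant cassette into an expanded model (in place)."""
    if not model.expanded:
        raise ValidationError("expand_all must run before adding a cassette")
    cfg = config or getattr(model, "_template_config", None) or TemplateConfig()
    model.specs[spec.id] = spec
    for rxn in expand_protein(spec, cfg, known_metabolites=set(model.network.metabolites)):
        model.generated[rxn.id] = rxn
    return model
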