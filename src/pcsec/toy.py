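"""Deterministic miniature cell for testing and demonstration.

The toy cell has the structural features the simulations assume, at a scale
of a few dozen proteins: two glucose transporters with opposing kinetics
(high-affinity/low-kcat/more N-glycans vs low-affinity/high-kcat/fewer
N-glycans), a fermentation/respiration branch whose yields and specific
activities produce overflow metabolism under a proteome budget, lumped
amino-acid and glycan/GPI/heme precursor synthesis, all 12 secretory-process
machineries plus the ER quality-control chain (Kar2/Pdi1 analogs,
retro-translocation complex, proteasome), a ribosome, an averaged dummy ER
protein, a CPY-like vacuolar client with configurable misfolding, and a
seeded panel of random secretory clients.

Identical configurations produce byte-identical JSON; the seed only affects
the random client panel, never the core metabolism or machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .canonical import canonicalize, make_dummy_er_protein, rescale_biomass_protein
from .constants import AMINO_ACIDS, BACKGROUND_AA_FREQ
from .core import (
    AminoAcidComposition,
    EnzymeComplex,
    Machinery,
    MetNetwork,
    Metabolite,
    PcModel,
    ProteinSpec,
    Reaction,
    TransporterKinetics,
    ValidationError,
)
from .templates import TemplateConfig, aa_met, expand_all


def composition_from_freq(length: int, freq: Optional[dict[str, float]] = None) -> AminoAcidComposition:
    """Deterministic composition: largest-remainder rounding of freq*length."""
    freq = freq or BACKGROUND_AA_FREQ
    total = sum(freq.values())
    raw = {aa: freq.get(aa, 0.0) / total * length for aa in AMINO_ACIDS}
    counts = {aa: int(np.floor(v)) for aa, v in raw.items()}
    short = length - sum(counts.values())
    remainders = sorted(raw, key=lambda aa: raw[aa] - np.floor(raw[aa]), reverse=True)
    for aa in remainders[:short]:
        counts[aa] += 1
    return AminoAcidComposition(counts={aa: n for aa, n in counts.items() if n > 0})


@dataclass
class TransporterConfig:
    protein_id: str
    kcat: float
    km: float
    n_NG: int


@dataclass
class ToyConfig:
    seed: int = 7
    n_clients: int = 15
    transporters: list[TransporterConfig] = field(
        default_factory=lambda: [
            TransporterConfig("hxt7", kcat=6000.0, km=0.5, n_NG=3),   # high affinity
            TransporterConfig("hxt1", kcat=20000.0, km=20.0, n_NG=1),  # low affinity
        ]
    )
    #: fermentation / respiration branch
    ferm_atp_per_glc: float = 2.0
    resp_atp_per_glc: float = 16.0
    ferm_kcat: float = 8000.0
    resp_kcat: float = 1000.0
    ferm_enzyme_length: int = 364
    resp_subunit_length: int = 900  # two subunits
    #: machinery kcats (capacity units per machinery molecule per hour)
    machinery_kcats: dict[str, float] = field(
        default_factory=lambda: {
            "ribosome": 36000.0,   # residues/h (10 aa/s elongation)
            "sec61": 144000.0,     # residues/h (40 aa/s translocation)
            "ost": 10000.0,        # N-sites/h
            "pdi1": 1000.0,        # disulfide events/h
            "kar2": 20.0,          # folding/retention rounds/h (slow QC cycling)
            "pmt": 4000.0,         # O-sites/h
            "gpit": 2000.0,        # anchors/h
            "copii": 5000.0,       # molecules/h
            "copi": 5000.0,
            "gost": 8000.0,        # N-sites/h
            "gpmt": 8000.0,
            "sorter": 5000.0,
            "retro": 6.0,          # molecules/h (slow dislocation)
            "proteasome": 12.0,    # molecules/h (whole-protein degradation)
        }
    )
    enzyme_kcat: float = 2000.0  # generic lumped biosynthetic enzymes, 1/h
    proteome_budget: float = 0.17  # g modeled protein / gDW
    compartment_caps: dict[str, float] = field(
        default_factory=lambda: {"ER": 0.008, "ER_membrane": 0.02}
    )
    dummy_mass: float = 0.01       # g/gDW of averaged dummy ER protein
    biomass_protein_ratio: float = 0.3
    gam_atp: float = 20.0          # growth-associated maintenance, mmol ATP/gDW
    ngam_atp: float = 1.0          # non-growth maintenance, mmol ATP/gDW/h
    other_biomass_glc: float = 3.9  # mmol glc per gDW of non-protein biomass
    cpy_abundance_ppm: float = 1000.0
    template_overrides: Optional[list[tuple[str, str, float, str]]] = None

    def validate(self) -> None:
        if not self.ferm_atp_per_glc < self.resp_atp_per_glc:
            raise ValidationError(
                "overflow regime requires fermentation ATP yield below respiration's"
            )
        mw_f = composition_from_freq(self.ferm_enzyme_length).mw
        mw_r = 2 * composition_from_freq(self.resp_subunit_length).mw
        ferm_rate = self.ferm_atp_per_glc * self.ferm_kcat / mw_f
        resp_rate = self.resp_atp_per_glc * self.resp_kcat / mw_r
        if not ferm_rate > resp_rate:
            raise ValidationError(
                "overflow regime requires fermentation ATP per enzyme mass above "
                f"respiration's (got {ferm_rate:.1f} vs {resp_rate:.1f})"
            )
        hi = min(self.transporters, key=lambda t: t.km)
        lo = max(self.transporters, key=lambda t: t.km)
        if not (hi.kcat < lo.kcat and hi.n_NG > lo.n_NG):
            raise ValidationError(
                "transporter panel must pair high-affinity/low-kcat/more-NG "
                "against low-affinity/high-kcat/fewer-NG"
            )


# machinery protein metadata: (length, localization, transloc, NG, TM, ref ppm)
_MACHINERY_PROTEINS: dict[str, tuple[int, str, str, int, int, float]] = {
    "ribosome": (22000, "cytosol", "none", 0, 0, 20000.0),
    "sec61": (1400, "ER_membrane", "co_translational", 0, 10, 150.0),
    "ost": (1500, "ER_membrane", "co_translational", 2, 8, 12.0),
    "pdi1": (500, "ER", "co_translational", 1, 0, 400.0),
    "kar2": (670, "ER", "co_translational", 0, 0, 900.0),
    "pmt": (750, "ER_membrane", "co_translational", 0, 7, 20.0),
    "gpit": (1200, "ER_membrane", "co_translational", 0, 6, 20.0),
    "copii": (3000, "cytosol", "none", 0, 0, 300.0),
    "copi": (3000, "cytosol", "none", 0, 0, 300.0),
    "gost": (800, "Golgi", "co_translational", 1, 2, 50.0),
    "gpmt": (800, "Golgi", "co_translational", 0, 5, 50.0),
    "sorter": (2500, "Golgi", "co_translational", 0, 3, 100.0),
    "retro": (9000, "ER_membrane", "co_translational", 0, 12, 30.0),
    "proteasome": (22000, "cytosol", "none", 0, 0, 4000.0),
}


def build_toy_cell(config: Optional[ToyConfig] = None) -> PcModel:
    """Construct, canonicalize, and expand the default miniature cell."""
    cfg = config or ToyConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    net = MetNetwork()
    small = [
        "glc_e", "glc", "atp", "gtp", "nh4", "o2", "co2", "etoh", "ox_equiv",
        "glycan", "man_donor", "gpi_anchor", "heme_a", "heme_b", "heme", "bioprot",
    ] + [aa_met(aa) for aa in AMINO_ACIDS]
    for m in small:
        net.add_metabolite(Metabolite(m, "c"))

    def rxn(id, stoich, enzyme=None, lb=0.0, ub=1e6, exchange=False, transporter=None, isozymes=None):
        net.add_reaction(Reaction(id=id, stoich=stoich, lb=lb, ub=ub, enzyme=enzyme,
                                  exchange=exchange, transporter=transporter, isozymes=isozymes))

    # exchanges (all irreversible in/out pairs)
    rxn("EX_glc_in", {"glc_e": 1.0}, exchange=True)
    rxn("EX_o2_in", {"o2": 1.0}, exchange=True)
    rxn("EX_nh4_in", {"nh4": 1.0}, exchange=True)
    rxn("EX_co2_out", {"co2": -1.0}, exchange=True)
    rxn("EX_etoh_out", {"etoh": -1.0}, exchange=True)

    # transport and central catabolism
    for t in cfg.transporters:
        rxn(f"UPT_{t.protein_id}", {"glc_e": -1.0, "glc": 1.0}, transporter=t.protein_id)
    rxn("FERM", {"glc": -1.0, "etoh": 2.0, "atp": cfg.ferm_atp_per_glc}, enzyme="cx_ferm_e")
    rxn("RESP", {"glc": -1.0, "o2": -6.0, "co2": 6.0, "atp": cfg.resp_atp_per_glc}, enzyme="cx_resp")
    rxn("NDK", {"atp": -1.0, "gtp": 1.0})
    rxn("ERO_OX", {"o2": -1.0, "ox_equiv": 2.0})
    rxn("NGAM", {"atp": -1.0}, lb=cfg.ngam_atp)

    # lumped anabolism, one enzyme each (cysteine costs more carbon/energy)
    for aa in AMINO_ACIDS:
        if aa == "C":
            stoich = {"glc": -1.0, "atp": -2.0, "nh4": -1.0, aa_met(aa): 1.0}
        else:
            stoich = {"glc": -0.5, "atp": -1.5, "nh4": -1.0, aa_met(aa): 1.0}
        rxn(f"AAS_{aa}", stoich, enzyme=f"cx_aas_{aa}")
    rxn("GLYS", {"glc": -1.5, "atp": -2.0, "glycan": 1.0}, enzyme="cx_glys")
    rxn("MANS", {"glc": -0.25, "atp": -0.5, "man_donor": 1.0}, enzyme="cx_mans")
    rxn("GPIS", {"glc": -2.0, "atp": -3.0, "gpi_anchor": 1.0}, enzyme="cx_gpis")
    rxn("HEM1", {"glc": -1.0, "atp": -2.0, "heme_a": 1.0}, enzyme="cx_hem1")
    rxn("HEM2", {"heme_a": -1.0, "atp": -1.0, "heme_b": 1.0}, enzyme="cx_hem2")
    rxn("HEM3", {"heme_b": -1.0, "heme": 1.0}, enzyme="cx_hem3")

    # biomass protein (non-modeled proteome) synthesized as one pseudo-protein
    bp_len = 400
    bp_comp = composition_from_freq(bp_len)
    bp_stoich = {aa_met(aa): -float(n) for aa, n in bp_comp.counts.items()}
    bp_stoich["atp"] = -4.0 * bp_len
    bp_stoich["bioprot"] = 1.0
    rxn("BIOPROT_SYNTH", bp_stoich)

    rxn(
        "BIOMASS",
        {
            "bioprot": -1.0 / bp_comp.mw,  # 1 g protein/gDW before rescaling
            "atp": -cfg.gam_atp,
            "glc": -cfg.other_biomass_glc,
        },
    )
    net.biomass_id = "BIOMASS"
    net.protein_pool_met = "bioprot"
    net = rescale_biomass_protein(net, cfg.biomass_protein_ratio)

    # --- proteins ----------------------------------------------------------
    specs: dict[str, ProteinSpec] = {}
    complexes: dict[str, EnzymeComplex] = {}
    roles: dict[str, str] = {}

    def protein(pid, length, loc="cytosol", transloc="none", role="enzyme",
                n_NG=0, n_OG=0, n_DSB=0, n_TM=0, gpi=False, ref=1500.0,
                r=0.0, rho=0, comp=None, subunit=False, paralog=False, cofactor=None):
        specs[pid] = ProteinSpec(
            id=pid,
            composition=comp or composition_from_freq(length),
            localization=loc, translocation_mode=transloc,
            n_NG=n_NG, n_OG=n_OG, n_DSB=n_DSB, n_TM=n_TM, gpi=gpi,
            misfold_ratio=r, retention_rounds=rho,
            abundance_ref=ref, is_complex_subunit=subunit, has_paralog=paralog,
            cofactor_demand=cofactor or {},
        )
        roles[pid] = role

    # machinery proteins
    for mid, (length, loc, transloc, n_ng, n_tm, ref) in _MACHINERY_PROTEINS.items():
        protein(mid, length, loc=loc, transloc=transloc, role="machinery",
                n_NG=n_ng, n_TM=n_tm, ref=ref)
    machineries = {
        mid: Machinery(id=mid, protein_id=mid, kcat=cfg.machinery_kcats[mid])
        for mid in _MACHINERY_PROTEINS
    }

    # transporters (identical compositions: the kinetic/NG contrast is the point)
    t_comp = composition_from_freq(570)
    for t in cfg.transporters:
        protein(t.protein_id, 570, loc="plasma_membrane", transloc="co_translational",
                role="enzyme", n_NG=t.n_NG, n_TM=12, ref=2000.0, comp=t_comp)

    # metabolic enzymes
    protein("ferm_e", cfg.ferm_enzyme_length, ref=3000.0)
    complexes["cx_ferm_e"] = EnzymeComplex(
        id="cx_ferm_e", subunits={"ferm_e": 1}, kcats={"FERM": cfg.ferm_kcat}
    )
    protein("resp_a", cfg.resp_subunit_length, loc="mitochondrion", ref=1000.0, subunit=True)
    protein("resp_b", cfg.resp_subunit_length, loc="mitochondrion", ref=1000.0, subunit=True)
    complexes["cx_resp"] = EnzymeComplex(
        id="cx_resp", subunits={"resp_a": 1, "resp_b": 1}, kcats={"RESP": cfg.resp_kcat}
    )
    for aa in AMINO_ACIDS:
        pid = f"aas_{aa}"
        protein(pid, 364, ref=1500.0)
        complexes[f"cx_{pid}"] = EnzymeComplex(
            id=f"cx_{pid}", subunits={pid: 1}, kcats={f"AAS_{aa}": cfg.enzyme_kcat}
        )
    for pid, rid, ref in [
        ("glys", "GLYS", 500.0), ("mans", "MANS", 500.0), ("gpis", "GPIS", 200.0),
        ("hem1", "HEM1", 50.0), ("hem2", "HEM2", 50.0), ("hem3", "HEM3", 50.0),
    ]:
        protein(pid, 364, ref=ref)
        kc = cfg.enzyme_kcat if not pid.startswith("hem") else 1000.0
        if pid == "mans":
            kc = 4000.0
        complexes[f"cx_{pid}"] = EnzymeComplex(id=f"cx_{pid}", subunits={pid: 1}, kcats={rid: kc})

    # CPY-like vacuolar quality-control substrate
    protein("cpy", 532, loc="vacuole", transloc="co_translational", role="client",
            n_NG=4, ref=cfg.cpy_abundance_ppm)

    # random secretory client panel (the only seed-dependent part)
    for k in range(cfg.n_clients):
        pid = f"client{k:02d}"
        length = int(rng.integers(250, 700))
        loc = str(rng.choice(["plasma_membrane", "extracellular", "vacuole"], p=[0.4, 0.3, 0.3]))
        n_ng = min(int(rng.geometric(0.45) - 1), 8)
        n_dsb = min(int(rng.poisson(0.8)), 6)
        n_og = min(int(rng.integers(0, 2) * rng.geometric(0.5)), 6)
        n_tm = int(rng.integers(1, 13)) if loc == "plasma_membrane" else 0
        gpi = bool(loc == "plasma_membrane" and rng.random() < 0.2)
        ref = float(np.round(np.exp(rng.normal(np.log(250.0), 0.6)), 3))
        counts = rng.multinomial(length, [BACKGROUND_AA_FREQ[aa] for aa in AMINO_ACIDS])
        comp = AminoAcidComposition(
            counts={aa: int(n) for aa, n in zip(AMINO_ACIDS, counts) if n > 0}
        )
        mode = "post_translational" if rng.random() < 0.25 else "co_translational"
        protein(pid, length, loc=loc, transloc=mode, role="client",
                n_NG=n_ng, n_OG=n_og, n_DSB=n_dsb, n_TM=n_tm, gpi=gpi, ref=ref, comp=comp)

    model = PcModel(
        network=canonicalize(net, complexes),
        specs=specs,
        complexes=complexes,
        transporters={
            t.protein_id: TransporterKinetics(protein_id=t.protein_id, kcat=t.kcat, km=t.km)
            for t in cfg.transporters
        },
        machineries=machineries,
        roles=roles,
        network_machinery_load={"BIOPROT_SYNTH": [("ribosome", float(bp_len))]},
        params={
            "proteome_budget": cfg.proteome_budget,
            "dummy_mass": cfg.dummy_mass,
            "biomass_protein_ratio": cfg.biomass_protein_ratio,
        },
        compartment_caps=dict(cfg.compartment_caps),
    )

    # averaged dummy ER protein over the secretory client panel
    client_specs = [s for pid, s in specs.items() if roles[pid] == "client"]
    abundances = {s.id: s.abundance_ref for s in client_specs}
    dummy = make_dummy_er_protein(client_specs, abundances, bp_comp)
    model.specs[dummy.id] = dummy
    model.roles[dummy.id] = "dummy"
    model.dummy_protein = dummy.id

    tpl = TemplateConfig()
    if cfg.template_overrides:
        tpl.rows = list(cfg.template_overrides)
    expand_all(model, tpl)
    model.validate()
    return model


def generate_recombinant_spec(
    name: str,
    length: int,
    n_NG: int = 0,
    n_OG: int = 0,
    n_DSB: int = 0,
    gpi: bool = False,
    cofactor: Optional[dict[str, float]] = None,
    aa_freq: Optional[dict[str, float]] = None,
    n_TM: int = 0,
) -> ProteinSpec:
    """An extracellular recombinant cassette with the stated features.

    Composition is drawn from the background frequency unless ``aa_freq``
    overrides it (e.g. a cysteine-enriched amylase-like profile).
    """
    return ProteinSpec(
        id=name,
        composition=composition_from_freq(length, aa_freq),
        localization="extracellular",
        translocation_mode="co_translational",
        n_NG=n_NG, n_OG=n_OG, n_DSB=n_DSB, gpi=gpi, n_TM=n_TM,
        cofactor_demand=cofactor or {},
    )


def amylase_like(name: str = "amylase") -> ProteinSpec:
    """Cysteine-enriched, glycosylated, disulfide-bonded secreted cassette."""
    freq = dict(BACKGROUND_AA_FREQ)
    freq["C"] = 0.18
    return generate_recombinant_spec(name, 480, n_NG=3, n_DSB=4, aa_freq=freq)


def insulin_like(name: str = "insulin") -> ProteinSpec:
    """Small cassette with disulfides and no N-glycosylation."""
    return generate_recombinant_spec(name, 110, n_NG=0, n_DSB=3)


def hemoglobin_like(name: str = "hemoglobin") -> ProteinSpec:
    """Cassette whose translation draws a heme prosthetic group."""
    return generate_recombinant_spec(name, 290, cofactor={"heme": 1.0})
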