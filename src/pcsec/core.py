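"""Domain types for proteome-constrained secretory models.

The central objects are :class:`ProteinSpec` (one row of a protein-specific
information matrix: composition, PTM site counts, localization, misfolding
parameters), :class:`MetNetwork` (the metabolic part), and :class:`PcModel`
(the assembled proteome-constrained model, including the per-protein
synthesis/processing/degradation reactions generated from templates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .constants import (
    AMINO_ACIDS,
    FREE_AA_MASS_G_PER_MOL,
    LOCALIZATIONS,
    PROCESS_IDS,
    TRANSLOCATION_MODES,
    WATER_MASS_G_PER_MOL,
)


class ValidationError(ValueError):
    """Raised when a model object violates its invariants."""


class AminoAcidComposition(BaseModel):
    """Counts per canonical amino acid.

    Length ``L`` is the residue total and ``MW`` is the average molecular
    mass of the chain in g/mmol-scale units (g/mol): the sum of free
    amino-acid masses minus ``L - 1`` waters lost in peptide bonds.
    """

    counts: dict[str, int]

    @field_validator("counts")
    @classmethod
    def _check_counts(cls, v: dict[str, int]) -> dict[str, int]:
        for aa, n in v.items():
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {aa!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {aa} must be a nonnegative integer")
        if sum(v.values()) < 1:
            raise ValueError("composition must contain at least one residue")
        return {aa: int(n) for aa, n in v.items() if n > 0}

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    @property
    def mw_g_per_mol(self) -> float:
        """Average chain mass, g/mol."""
        residue_sum = sum(FREE_AA_MASS_G_PER_MOL[aa] * n for aa, n in self.counts.items())
        return residue_sum - (self.length - 1) * WATER_MASS_G_PER_MOL

    @property
    def mw(self) -> float:
        """Chain mass in g/mmol (numerically kDa); pairs with mmol/gDW abundances."""
        return self.mw_g_per_mol / 1000.0

    def __add__(self, other: "AminoAcidComposition") -> "AminoAcidComposition":
        merged = dict(self.counts)
        for aa, n in other.counts.items():
            merged[aa] = merged.get(aa, 0) + n
        return AminoAcidComposition(counts=merged)

    def scaled(self, k: int) -> "AminoAcidComposition":
        return AminoAcidComposition(counts={aa: n * k for aa, n in self.counts.items()})


class ProteinSpec(BaseModel):
    """One PSIM row: everything route generation needs to know about a protein."""

    id: str
    composition: AminoAcidComposition
    localization: str = "cytosol"
    translocation_mode: str = "none"
    n_NG: int = Field(default=0, ge=0)
    n_OG: int = Field(default=0, ge=0)
    n_DSB: int = Field(default=0, ge=0)
    gpi: bool = False
    n_TM: int = Field(default=0, ge=0)
    misfold_ratio: float = Field(default=0.0, ge=0.0, le=1.0)
    retention_rounds: int = Field(default=0, ge=0)
    cofactor_demand: dict[str, float] = Field(default_factory=dict)
    abundance_ref: float = Field(default=0.0, ge=0.0)  # ppm, PaxDb-style
    is_complex_subunit: bool = False
    has_paralog: bool = False

    #: Fractional PTM multiplicities are permitted for the averaged dummy
    #: ER protein only; they are carried on these override fields.
    ptm_fractional: Optional[dict[str, float]] = None

    @field_validator("localization")
    @classmethod
    def _check_loc(cls, v: str) -> str:
        if v not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {v!r}")
        return v

    @field_validator("translocation_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in TRANSLOCATION_MODES:
            raise ValueError(f"unknown translocation mode {v!r}")
        return v

    @model_validator(mode="after")
    def _check_secretory(self) -> "ProteinSpec":
        if self.translocation_mode != "none" and self.localization == "cytosol":
            raise ValueError(
                f"{self.id}: secretory protein cannot be localized to the cytosol"
            )
        if self.misfold_ratio > 0 and self.translocation_mode == "none":
            raise ValueError(
                f"{self.id}: misfold_ratio > 0 requires a secretory route"
            )
        return self

    @property
    def is_secretory(self) -> bool:
        return self.translocation_mode != "none"

    def ptm_count(self, key: str) -> float:
        """PTM multiplicity, honouring fractional overrides (dummy protein)."""
        if self.ptm_fractional and key in self.ptm_fractional:
            return self.ptm_fractional[key]
        return float(getattr(self, key))


class EnzymeComplex(BaseModel):
    """A catalytic unit: subunit stoichiometry plus per-reaction kcat values."""

    id: str
    subunits: dict[str, int]  # protein id -> copies
    kcats: dict[str, float] = Field(default_factory=dict)  # reaction id -> kcat (1/h)

    @field_validator("subunits")
    @classmethod
    def _check_subunits(cls, v: dict[str, int]) -> dict[str, int]:
        if not v:
            raise ValueError("complex needs at least one subunit")
        for p, n in v.items():
            if n < 1:
                raise ValueError(f"subunit {p} copies must be >= 1")
        return v

    @field_validator("kcats")
    @classmethod
    def _check_kcats(cls, v: dict[str, float]) -> dict[str, float]:
        for r, k in v.items():
            if not (k > 0):
                raise ValueError(f"kcat for {r} must be > 0")
        return v


class TransporterKinetics(BaseModel):
    """Michaelis-Menten kinetics of a substrate transporter."""

    protein_id: str
    kcat: float = Field(gt=0)  # 1/h, per transporter molecule at saturation
    km: float = Field(gt=0)    # same unit as the extracellular concentration (g/L)

    def saturation(self, s: float) -> float:
        if s < 0:
            raise ValueError("concentration must be >= 0")
        return s / (s + self.km)


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"


@dataclass
class Reaction:
    """A metabolic reaction with sparse stoichiometry.

    ``enzyme`` names the catalyzing :class:`EnzymeComplex` (``None`` for
    spontaneous/exchange reactions).  ``transporter`` names a
    :class:`TransporterKinetics` entry for saturable uptake reactions.
    ``isozymes`` may list several complexes before canonicalization.
    """

    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = 1e6
    enzyme: Optional[str] = None
    isozymes: Optional[list[str]] = None
    exchange: bool = False
    transporter: Optional[str] = None

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoich=dict(self.stoich),
            lb=self.lb,
            ub=self.ub,
            enzyme=self.enzyme,
            isozymes=list(self.isozymes) if self.isozymes else None,
            exchange=self.exchange,
            transporter=self.transporter,
        )


@dataclass
class MetNetwork:
    """The metabolic part: metabolites, reactions, biomass, media."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_id: Optional[str] = None
    protein_pool_met: Optional[str] = None  # metabolite drained as biomass protein
    media: dict[str, float] = field(default_factory=dict)  # exchange id -> uptake cap

    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        for m in rxn.stoich:
            if m not in self.metabolites:
                raise ValidationError(f"reaction {rxn.id} references unknown metabolite {m}")
        self.reactions[rxn.id] = rxn

    def validate(self, complexes: Optional[dict[str, EnzymeComplex]] = None) -> None:
        for rxn in self.reactions.values():
            if not math.isfinite(rxn.lb) or not math.isfinite(rxn.ub):
                raise ValidationError(f"reaction {rxn.id} has non-finite bounds")
            if rxn.lb > rxn.ub:
                raise ValidationError(f"reaction {rxn.id} has lb > ub")
            for m in rxn.stoich:
                if m not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id} references unknown metabolite {m}"
                    )
            if complexes is not None:
                names = []
                if rxn.enzyme:
                    names.append(rxn.enzyme)
                if rxn.isozymes:
                    names.extend(rxn.isozymes)
                for e in names:
                    if e not in complexes:
                        raise ValidationError(
                            f"reaction {rxn.id} cites unknown enzyme {e!r}"
                        )
        if self.biomass_id is not None and self.biomass_id not in self.reactions:
            raise ValidationError(f"biomass reaction {self.biomass_id} not present")

    def copy(self) -> "MetNetwork":
        net = MetNetwork(
            metabolites={k: Metabolite(v.id, v.compartment) for k, v in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            biomass_id=self.biomass_id,
            protein_pool_met=self.protein_pool_met,
            media=dict(self.media),
        )
        return net


@dataclass
class GenReaction:
    """A generated per-protein synthesis/processing/degradation reaction.

    ``met_stoich`` covers small metabolites (negative = consumed);
    ``form_in``/``form_out`` are protein-form species ids; ``machinery``
    lists ``(machinery_id, occupancy weight)`` pairs for capacity coupling.
    """

    id: str
    protein_id: str
    process_id: str
    met_stoich: dict[str, float] = field(default_factory=dict)
    form_in: Optional[str] = None
    form_out: Optional[str] = None
    machinery: list[tuple[str, float]] = field(default_factory=list)
    #: amino acids released on degradation (positive counts), if any
    aa_release: dict[str, float] = field(default_factory=dict)


@dataclass
class Machinery:
    """A capacity-coupled machinery: the protein that does a process."""

    id: str
    protein_id: str
    kcat: float  # capacity units per machinery molecule per hour
    basis: str = "per_event"  # descriptive: what one capacity unit is


@dataclass
class PcModel:
    """The assembled proteome-constrained model."""

    network: MetNetwork
    specs: dict[str, ProteinSpec] = field(default_factory=dict)
    complexes: dict[str, EnzymeComplex] = field(default_factory=dict)
    transporters: dict[str, TransporterKinetics] = field(default_factory=dict)
    machineries: dict[str, Machinery] = field(default_factory=dict)
    generated: dict[str, GenReaction] = field(default_factory=dict)
    #: protein id of the averaged dummy ER protein, if present
    dummy_protein: Optional[str] = None
    #: protein id -> role (client | machinery | enzyme | ribosome | dummy | cassette)
    roles: dict[str, str] = field(default_factory=dict)
    #: network reaction id -> [(machinery id, occupancy per unit flux)] for
    #: pseudo-translation reactions living in the metabolic part (biomass protein)
    network_machinery_load: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)
    #: per-compartment proteome mass caps, g/gDW (missing = uncapped)
    compartment_caps: dict[str, float] = field(default_factory=dict)
    expanded: bool = False

    def validate(self) -> None:
        self.network.validate(self.complexes)
        for cx in self.complexes.values():
            for pid in cx.subunits:
                if pid not in self.specs:
                    raise ValidationError(f"complex {cx.id} subunit {pid} has no ProteinSpec")
        for m in self.machineries.values():
            if m.protein_id not in self.specs:
                raise ValidationError(f"machinery {m.id} protein {m.protein_id} has no ProteinSpec")
            if not m.kcat > 0:
                raise ValidationError(f"machinery {m.id} kcat must be > 0")
        for pid in PROCESS_IDS:
            pass  # vocabulary is fixed in constants; machineries may add helpers

    def copy(self) -> "PcModel":
        import copy as _copy

        return _copy.deepcopy(self)
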