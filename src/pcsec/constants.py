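"""Physical constants and default template coefficients.

All units are fixed package-wide: fluxes in mmol/gDW/h, protein abundances in
mmol/gDW, kcat in 1/h, molecular masses in g/mmol (numerically equal to kDa).
"""

from __future__ import annotations

#: Average (not monoisotopic) masses of the free amino acids, g/mmol * 1e-3
#: i.e. g/mol / 1000 so that a mmol-based abundance times MW gives grams.
#: Values are the standard average masses of the free amino acids in g/mol.
FREE_AA_MASS_G_PER_MOL: dict[str, float] = {
    "A": 89.094,   # Ala
    "R": 174.203,  # Arg
    "N": 132.119,  # Asn
    "D": 133.104,  # Asp
    "C": 121.154,  # Cys
    "E": 147.131,  # Glu
    "Q": 146.146,  # Gln
    "G": 75.067,   # Gly
    "H": 155.156,  # His
    "I": 131.175,  # Ile
    "L": 131.175,  # Leu
    "K": 146.189,  # Lys
    "M": 149.208,  # Met
    "F": 165.192,  # Phe
    "P": 115.132,  # Pro
    "S": 105.093,  # Ser
    "T": 119.120,  # Thr
    "W": 204.228,  # Trp
    "Y": 181.191,  # Tyr
    "V": 117.148,  # Val
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(FREE_AA_MASS_G_PER_MOL))

WATER_MASS_G_PER_MOL: float = 18.01528

#: Background amino-acid frequencies used for generated compositions
#: (rounded S. cerevisiae proteome-like frequencies; they only need to be a
#: plausible, fixed background).
BACKGROUND_AA_FREQ: dict[str, float] = {
    "A": 0.055, "R": 0.044, "N": 0.061, "D": 0.058, "C": 0.013,
    "E": 0.065, "Q": 0.039, "G": 0.050, "H": 0.022, "I": 0.066,
    "L": 0.096, "K": 0.073, "M": 0.021, "F": 0.045, "P": 0.044,
    "S": 0.090, "T": 0.059, "W": 0.010, "Y": 0.034, "V": 0.055,
}

#: The 12-process vocabulary of the secretory reconstruction.
PROCESS_IDS: tuple[str, ...] = (
    "translation",
    "translocation",
    "ER_NG",
    "DSB",
    "ER_OG",
    "GPI_transfer",
    "COPII",
    "COPI",
    "Golgi_NG",
    "Golgi_OG",
    "vesicle_sorting",
    "ERAD",
)

#: Default per-process template coefficients.  One parameterized template per
#: process; the exact per-process ATP/GTP coefficients are assumptions and can
#: be overridden through TemplateConfig / the TSV interface.
#: basis: per_protein | per_residue | per_site
DEFAULT_TEMPLATE_COEFFICIENTS: list[tuple[str, str, float, str]] = [
    # (process, metabolite, coefficient (consumed > 0), basis)
    ("translation", "atp", 4.0, "per_residue"),       # lumped init+elong+term
    ("translocation", "gtp", 1.0, "per_residue"),     # co-translational SRP/Sec61
    ("translocation_post", "atp", 1.0, "per_residue"),  # post-translational (Kar2 ATPase)
    ("ER_NG", "glycan", 1.0, "per_site"),
    ("DSB", "ox_equiv", 1.0, "per_site"),             # Ero1/FAD-mediated oxidation
    ("ER_OG", "man_donor", 1.0, "per_site"),
    ("GPI_transfer", "gpi_anchor", 1.0, "per_protein"),
    ("COPII", "gtp", 1.0, "per_protein"),             # Sar1 GTPase cycle
    ("COPI", "gtp", 1.0, "per_protein"),              # Arf1 GTPase cycle
    ("Golgi_NG", "man_donor", 1.0, "per_site"),       # mannan elaboration
    ("Golgi_OG", "man_donor", 1.0, "per_site"),
    ("vesicle_sorting", "gtp", 1.0, "per_protein"),
    ("ERAD", "atp", 0.25, "per_residue"),             # proteasome toll: 1 ATP / 4 residues
]

#: Sorting branches.
SORTING_BRANCHES: tuple[str, ...] = ("LDSV", "HDSV", "ALPP", "CPYP", "retained")

LOCALIZATIONS: tuple[str, ...] = (
    "cytosol", "ER", "ER_membrane", "Golgi", "vacuole",
    "plasma_membrane", "extracellular", "mitochondrion", "other",
)

TRANSLOCATION_MODES: tuple[str, ...] = ("co_translational", "post_translational", "none")

#: Internal variable scaling: abundances are carried in umol/gDW inside the LP
#: to tame conditioning; all tolerances are applied after unscaling.
ABUNDANCE_SCALE: float = 1000.0

#: ppm-of-proteome -> mass fraction conversion uses this total protein content
#: (g protein / gDW), the reference for PaxDb-style abundances.
TOTAL_PROTEIN_G_PER_GDW: float = 0.45
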