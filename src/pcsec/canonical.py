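"""Network canonicalization and derived pseudo-proteins.

Canonical form: every reaction is irreversible (0 <= lb <= ub) and every
enzymatic reaction carries exactly one enzyme complex.  Reversible reactions
are split into forward/reverse halves; reactions with k isozymes are
duplicated k times.  Net-flux solutions of the canonical network map onto
those of the original.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .core import (
    AminoAcidComposition,
    EnzymeComplex,
    MetNetwork,
    ProteinSpec,
    Reaction,
    ValidationError,
)


def canonicalize(network: MetNetwork, complexes: Mapping[str, EnzymeComplex] | None = None) -> MetNetwork:
    """Split reversible reactions and isozyme-catalyzed reactions.

    Returns a new network; the input is unmodified.  A reaction that is
    already irreversible with at most one enzyme passes through unchanged.
    """
    network.validate(dict(complexes) if complexes is not None else None)
    out = MetNetwork(
        metabolites={k: v for k, v in network.copy().metabolites.items()},
        biomass_id=network.biomass_id,
        protein_pool_met=network.protein_pool_met,
        media=dict(network.media),
    )

    for rxn in network.reactions.values():
        enzymes: list[str | None]
        if rxn.isozymes:
            enzymes = list(rxn.isozymes)
        elif rxn.enzyme:
            enzymes = [rxn.enzyme]
        else:
            enzymes = [None]

        halves: list[Reaction] = []
        if rxn.lb < 0:
            fwd = rxn.copy()
            fwd.lb, fwd.ub = 0.0, max(rxn.ub, 0.0)
            rev = rxn.copy()
            rev.id = rxn.id + "_REV"
            rev.stoich = {m: -c for m, c in rxn.stoich.items()}
            rev.lb, rev.ub = 0.0, -rxn.lb
            halves = [fwd, rev] if fwd.ub > 0 else [rev]
        else:
            halves = [rxn.copy()]

        for half in halves:
            if len(enzymes) == 1:
                half.enzyme = enzymes[0]
                half.isozymes = None
                out.reactions[half.id] = half
            else:
                for i, enz in enumerate(enzymes, start=1):
                    dup = half.copy()
                    dup.id = f"{half.id}_iso{i}"
                    dup.enzyme = enz
                    dup.isozymes = None
                    out.reactions[dup.id] = dup

    return out


def is_canonical(network: MetNetwork) -> bool:
    return all(
        r.lb >= 0 and not r.isozymes for r in network.reactions.values()
    )


def rescale_biomass_protein(network: MetNetwork, ratio: float) -> MetNetwork:
    """Multiply the biomass protein-pool coefficient by ``ratio``.

    Mirrors rescaling the biomass protein content from 1 to a lower value
    (0.3 in the reference reconstruction) when most of the proteome becomes
    explicitly modeled.
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must be in (0, 1]")
    if network.biomass_id is None or network.biomass_id not in network.reactions:
        raise ValidationError("network has no biomass reaction")
    if network.protein_pool_met is None:
        raise ValidationError("network has no protein-pool metabolite")
    out = network.copy()
    bio = out.reactions[out.biomass_id]
    if network.protein_pool_met not in bio.stoich:
        raise ValidationError("biomass reaction does not drain the protein pool")
    bio.stoich[network.protein_pool_met] *= ratio
    return out


def make_dummy_er_protein(
    specs: Iterable[ProteinSpec],
    abundances: Mapping[str, float],
    biomass_composition: AminoAcidComposition,
    protein_id: str = "dummy_er",
) -> ProteinSpec:
    """Averaged stand-in for unmodeled proteins passing through the ER.

    Composition equals the biomass protein composition; PTM multiplicities
    are the abundance-weighted means over secretory proteins and are kept
    fractional (template coefficients accept non-integer multiplicities).
    """
    sec = [s for s in specs if s.is_secretory and abundances.get(s.id, 0.0) > 0]
    if not sec:
        raise ValidationError("no secretory protein with positive abundance")
    wsum = sum(abundances[s.id] for s in sec)
    means = {}
    for key in ("n_NG", "n_OG", "n_DSB", "n_TM"):
        means[key] = sum(abundances[s.id] * getattr(s, key) for s in sec) / wsum
    gpi_mean = sum(abundances[s.id] * (1.0 if s.gpi else 0.0) for s in sec) / wsum

    return ProteinSpec(
        id=protein_id,
        composition=biomass_composition,
        localization="plasma_membrane",
        translocation_mode="co_translational",
        n_NG=int(means["n_NG"]),
        n_OG=int(means["n_OG"]),
        n_DSB=int(means["n_DSB"]),
        n_TM=int(means["n_TM"]),
        gpi=False,
        ptm_fractional={
            "n_NG": means["n_NG"],
            "n_OG": means["n_OG"],
            "n_DSB": means["n_DSB"],
            "n_TM": means["n_TM"],
            "gpi": gpi_mean,
        },
    )
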