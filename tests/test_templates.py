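"""Template expansion: routes, per-site stoichiometry, recycling, and the
elemental bookkeeping of generated reactions."""

from __future__ import annotations

import pytest

from pcsec.core import AminoAcidComposition, ProteinSpec, ValidationError
from pcsec.templates import (
    TemplateConfig,
    aa_met,
    derive_route,
    expand_all,
    expand_protein,
)


def spec(pid="p", length=100, loc="cytosol", transloc="none", **kw):
    counts = {"A": length - 10, "C": 5, "G": 5} if length > 10 else {"A": length}
    return ProteinSpec(
        id=pid, composition=AminoAcidComposition(counts=counts),
        localization=loc, translocation_mode=transloc, **kw,
    )


class TestRoutes:
    def test_cytosolic_is_translation_only(self):
        r = derive_route(spec())
        assert r.processes == ["translation"]
        assert r.misfolding_branch == "none"

    def test_extracellular_glycoprotein(self):
        r = derive_route(spec(loc="extracellular", transloc="co_translational", n_NG=3))
        assert r.processes == [
            "translation", "translocation", "ER_NG", "COPII", "Golgi_NG", "vesicle_sorting"
        ]
        assert r.sorting_branch == "HDSV"

    def test_cpy_like_route(self):
        r = derive_route(
            spec(loc="vacuole", transloc="co_translational", n_NG=4,
                 misfold_ratio=0.45)
        )
        assert "ERAD" in r.processes
        assert r.sorting_branch == "CPYP"
        assert r.misfolding_branch == "ERAD"

    def test_retention_branch(self):
        r = derive_route(
            spec(loc="vacuole", transloc="co_translational",
                 misfold_ratio=1.0, retention_rounds=2)
        )
        assert r.misfolding_branch == "retention"

    def test_er_resident_retained_by_copi(self):
        r = derive_route(spec(loc="ER", transloc="co_translational"))
        assert r.processes[-1] == "COPI"
        assert "COPII" not in r.processes

    def test_ptm_order_fixed(self):
        r = derive_route(
            spec(loc="plasma_membrane", transloc="co_translational",
                 n_NG=1, n_OG=1, n_DSB=1, gpi=True)
        )
        er = [p for p in r.processes if p in ("translocation", "ER_NG", "DSB", "ER_OG", "GPI_transfer")]
        assert er == ["translocation", "ER_NG", "DSB", "ER_OG", "GPI_transfer"]


class TestExpansion:
    def test_translation_energy_is_per_residue(self):
        rxns = expand_protein(spec(length=100), TemplateConfig())
        transl = rxns[0]
        assert transl.process_id == "translation"
        assert transl.met_stoich["atp"] == pytest.approx(-400.0)  # 4 per residue
        assert transl.machinery == [("ribosome", 100.0)]

    def test_ng_sites_linear(self):
        rxns = expand_protein(
            spec(loc="extracellular", transloc="co_translational", n_NG=2),
            TemplateConfig(),
        )
        er_ng = next(r for r in rxns if r.process_id == "ER_NG")
        assert er_ng.met_stoich["glycan"] == pytest.approx(-2.0)
        assert ("ost", 2.0) in er_ng.machinery

    def test_erad_recycles_and_tolls(self):
        s = spec(pid="m", length=100, loc="vacuole", transloc="co_translational",
                 n_NG=1, misfold_ratio=1.0)
        rxns = expand_protein(s, TemplateConfig())
        erad = next(r for r in rxns if r.id == "ERAD_m")
        # amino acids come back, one glycan is recycled, ATP toll 1 per 4 residues
        for aa, n in s.composition.counts.items():
            assert erad.met_stoich[aa_met(aa)] == pytest.approx(n)
        assert erad.met_stoich["glycan"] == pytest.approx(1.0)
        assert erad.met_stoich["atp"] == pytest.approx(-25.0)

    def test_cofactor_consumed_at_translation(self):
        s = spec(cofactor_demand={"heme": 1.0})
        rxns = expand_protein(s, TemplateConfig())
        assert rxns[0].met_stoich["heme"] == pytest.approx(-1.0)

    def test_missing_precursor_named(self):
        s = spec(loc="extracellular", transloc="co_translational", n_NG=1)
        with pytest.raises(ValidationError, match="glycan"):
            expand_protein(s, TemplateConfig(), known_metabolites={"atp", "gtp"} |
                           {aa_met(a) for a in s.composition.counts})


class TestElementalBookkeeping:
    def test_amino_acid_conservation_symbolic(self, toy_model):
        """Residues entering a protein's route equal residues leaving.

        Translation charges the composition; only ERAD releases residues
        (scaled by the recycle fraction); every other step carries the
        chain through unchanged.
        """
        eta = toy_model.params.get("template_erad_recycle", 1.0)
        for pid, s in toy_model.specs.items():
            consumed = {}
            released = {}
            for rxn in toy_model.generated.values():
                if rxn.protein_id != pid:
                    continue
                for met, c in rxn.met_stoich.items():
                    if met.startswith("aa_"):
                        if c < 0:
                            consumed[met] = consumed.get(met, 0.0) - c
                        else:
                            released[met] = released.get(met, 0.0) + c
            for aa, n in s.composition.counts.items():
                assert consumed.get(aa_met(aa), 0) == pytest.approx(float(n))
                if released:
                    assert released.get(aa_met(aa), 0) == pytest.approx(eta * n)

    def test_monotone_precursor_demand(self):
        """Total precursor demand never decreases in NG/OG/DSB site counts."""
        def total_demand(**kw):
            s = spec(loc="extracellular", transloc="co_translational", **kw)
            rxns = expand_protein(s, TemplateConfig())
            return -sum(
                c for r in rxns for met, c in r.met_stoich.items() if c < 0
            )

        base = total_demand()
        assert total_demand(n_NG=2) > total_demand(n_NG=1) > base
        assert total_demand(n_OG=2) > total_demand(n_OG=1) > base
        assert total_demand(n_DSB=2) > total_demand(n_DSB=1) > base


class TestExpandAll:
    def test_every_protein_has_one_translation(self, toy_model):
        transl = [r for r in toy_model.generated.values() if r.process_id == "translation"]
        per_protein = {r.protein_id for r in transl}
        assert per_protein == set(toy_model.specs)
        assert len(transl) == len(toy_model.specs)

    def test_machinery_expanded_as_client(self, toy_model):
        """An N-glycosylated machinery protein is itself an ER_NG client."""
        assert toy_model.specs["pdi1"].n_NG > 0
        assert "ER_NG_pdi1" in toy_model.generated
        assert "ER_NG_sec61" not in toy_model.generated  # no NG sites

    def test_idempotent(self, toy_model):
        import copy

        m = copy.deepcopy(toy_model)
        before = {k: (v.met_stoich, v.machinery) for k, v in m.generated.items()}
        expand_all(m)
        after = {k: (v.met_stoich, v.machinery) for k, v in m.generated.items()}
        assert before == after

    def test_machinery_only_model_grows(self):
        """With no clients the machinery/ribosome core still sustains growth."""
        from pcsec import build_toy_cell
        from pcsec.engine import SimulationContext, max_growth
        from pcsec.toy import ToyConfig

        m = build_toy_cell(ToyConfig(n_clients=0))
        g = max_growth(m, SimulationContext(glucose_conc=20.0))
        assert g.mu_star > 0.05
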