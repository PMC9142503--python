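"""Canonicalization: reversible/isozyme splitting, biomass rescaling,
and the averaged dummy ER protein."""

from __future__ import annotations

import numpy as np
import pytest

from pcsec.canonical import canonicalize, is_canonical, make_dummy_er_protein, rescale_biomass_protein
from pcsec.core import (
    AminoAcidComposition,
    EnzymeComplex,
    MetNetwork,
    Metabolite,
    ProteinSpec,
    Reaction,
    ValidationError,
)


def tiny_network():
    net = MetNetwork()
    for m in ("A", "B"):
        net.add_metabolite(Metabolite(m))
    return net


def test_reversible_split_bounds():
    net = tiny_network()
    net.add_reaction(Reaction(id="R", stoich={"A": -1, "B": 1}, lb=-5, ub=10, enzyme="E"))
    out = canonicalize(net, {"E": EnzymeComplex(id="E", subunits={"p": 1}, kcats={"R": 1.0})})
    assert out.reactions["R"].ub == 10 and out.reactions["R"].lb == 0
    assert out.reactions["R_REV"].ub == 5 and out.reactions["R_REV"].lb == 0
    assert out.reactions["R_REV"].stoich == {"A": 1, "B": -1}
    assert is_canonical(out)


def test_isozymes_duplicated():
    net = tiny_network()
    net.add_reaction(Reaction(id="R", stoich={"A": -1, "B": 1}, ub=3, isozymes=["E1", "E2"]))
    cx = {e: EnzymeComplex(id=e, subunits={"p": 1}, kcats={"R": 1.0}) for e in ("E1", "E2")}
    out = canonicalize(net, cx)
    assert set(out.reactions) == {"R_iso1", "R_iso2"}
    assert out.reactions["R_iso1"].enzyme == "E1"
    assert out.reactions["R_iso2"].enzyme == "E2"
    assert out.reactions["R_iso1"].stoich == out.reactions["R_iso2"].stoich


def test_irreversible_single_enzyme_unchanged():
    net = tiny_network()
    net.add_reaction(Reaction(id="R", stoich={"A": -1, "B": 1}, lb=0, ub=4, enzyme="E"))
    out = canonicalize(net, {"E": EnzymeComplex(id="E", subunits={"p": 1}, kcats={"R": 1.0})})
    assert out.reactions["R"].stoich == net.reactions["R"].stoich
    assert (out.reactions["R"].lb, out.reactions["R"].ub) == (0, 4)


def test_unknown_enzyme_rejected():
    net = tiny_network()
    net.add_reaction(Reaction(id="R", stoich={"A": -1, "B": 1}, enzyme="ghost"))
    with pytest.raises(ValidationError, match="R"):
        canonicalize(net, {})


def test_split_preserves_lp_optimum():
    """100 random small LPs: optimal objective unchanged by splitting."""
    from scipy.optimize import linprog

    rng = np.random.default_rng(0)
    for trial in range(100):
        n_m, n_r = 4, 7
        net = MetNetwork()
        for i in range(n_m):
            net.add_metabolite(Metabolite(f"m{i}"))
        for j in range(n_r):
            picks = rng.choice(n_m, size=2, replace=False)
            stoich = {f"m{picks[0]}": -1.0, f"m{picks[1]}": float(rng.integers(1, 3))}
            lb = float(rng.choice([0.0, -rng.uniform(0, 5)]))
            net.add_reaction(Reaction(id=f"r{j}", stoich=stoich, lb=lb, ub=float(rng.uniform(1, 10))))
        # sources and a sink so something can flow
        net.add_reaction(Reaction(id="src", stoich={"m0": 1.0}, ub=float(rng.uniform(1, 5))))
        net.add_reaction(Reaction(id="snk", stoich={f"m{n_m-1}": -1.0}, ub=100.0))

        def solve_net(network):
            rids = sorted(network.reactions)
            mets = sorted(network.metabolites)
            A = np.zeros((len(mets), len(rids)))
            for k, rid in enumerate(rids):
                for m, c in network.reactions[rid].stoich.items():
                    A[mets.index(m), k] = c
            c_vec = np.zeros(len(rids))
            c_vec[rids.index("snk")] = -1.0
            bounds = [(network.reactions[r].lb, network.reactions[r].ub) for r in rids]
            res = linprog(c_vec, A_eq=A, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
            return -res.fun if res.status == 0 else None

        before = solve_net(net)
        after = solve_net(canonicalize(net))
        if before is None:
            assert after is None
        else:
            assert after == pytest.approx(before, rel=1e-9, abs=1e-9)


class TestRescaleBiomass:
    def make(self):
        net = MetNetwork()
        net.add_metabolite(Metabolite("prot"))
        net.add_metabolite(Metabolite("atp"))
        net.add_reaction(Reaction(id="BIO", stoich={"prot": -1.0, "atp": -20.0}))
        net.biomass_id = "BIO"
        net.protein_pool_met = "prot"
        return net

    def test_rescale(self):
        out = rescale_biomass_protein(self.make(), 0.3)
        assert out.reactions["BIO"].stoich["prot"] == pytest.approx(-0.3)
        assert out.reactions["BIO"].stoich["atp"] == -20.0

    def test_identity(self):
        out = rescale_biomass_protein(self.make(), 1.0)
        assert out.reactions["BIO"].stoich["prot"] == -1.0

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            rescale_biomass_protein(self.make(), 0.0)

    def test_missing_biomass(self):
        net = self.make()
        net.biomass_id = None
        with pytest.raises(ValidationError):
            rescale_biomass_protein(net, 0.3)


class TestDummyProtein:
    def spec(self, pid, n_NG=0, n_DSB=0):
        return ProteinSpec(
            id=pid, composition=AminoAcidComposition(counts={"A": 10}),
            localization="extracellular", translocation_mode="co_translational",
            n_NG=n_NG, n_DSB=n_DSB,
        )

    def test_equal_abundance_mean(self):
        bio = AminoAcidComposition(counts={"G": 5})
        d = make_dummy_er_protein(
            [self.spec("a", n_NG=2), self.spec("b", n_NG=4)], {"a": 1.0, "b": 1.0}, bio
        )
        assert d.ptm_count("n_NG") == pytest.approx(3.0)
        assert d.composition.counts == {"G": 5}

    def test_single_protein(self):
        bio = AminoAcidComposition(counts={"G": 5})
        d = make_dummy_er_protein([self.spec("a", n_NG=7)], {"a": 3.0}, bio)
        assert d.ptm_count("n_NG") == pytest.approx(7.0)

    def test_weighted_mean(self):
        # abundances 10 and 30 ppm, n_DSB 0 and 4 -> 0*0.25 + 4*0.75 = 3
        bio = AminoAcidComposition(counts={"G": 5})
        d = make_dummy_er_protein(
            [self.spec("a", n_DSB=0), self.spec("b", n_DSB=4)], {"a": 10.0, "b": 30.0}, bio
        )
        assert d.ptm_count("n_DSB") == pytest.approx(3.0)

    def test_no_secretory_proteins_rejected(self):
        bio = AminoAcidComposition(counts={"G": 5})
        cyto = ProteinSpec(id="c", composition=bio, localization="cytosol")
        with pytest.raises(ValidationError):
            make_dummy_er_protein([cyto], {"c": 5.0}, bio)
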