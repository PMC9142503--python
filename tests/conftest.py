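from __future__ import annotations

import numpy as np
import pytest

from pcsec import build_toy_cell
from pcsec.toy import ToyConfig


def make_hand_model(glc_cap: float = 0.2):
    """Six-reaction hand-built pc model with an analytically known optimum.

    Glucose (capped uptake) feeds ATP and a single amino acid; biomass
    drains both; one catalytic enzyme and a ribosome are the only proteins.
    """
    from pcsec.core import (
        AminoAcidComposition,
        EnzymeComplex,
        Machinery,
        MetNetwork,
        Metabolite,
        PcModel,
        ProteinSpec,
        Reaction,
    )
    from pcsec.templates import expand_all

    net = MetNetwork()
    for m in ("glc", "atp", "aa_A", "prot"):
        net.add_metabolite(Metabolite(m))
    net.add_reaction(Reaction(id="EX_glc", stoich={"glc": 1.0}, ub=glc_cap, exchange=True))
    net.add_reaction(Reaction(id="CAT", stoich={"glc": -1.0, "atp": 12.0}, enzyme="cx_cat"))
    net.add_reaction(Reaction(id="AAS", stoich={"glc": -0.5, "atp": -1.0, "aa_A": 1.0}))
    net.add_reaction(Reaction(id="PSYN", stoich={"aa_A": -100.0, "atp": -400.0, "prot": 1.0}))
    net.add_reaction(Reaction(id="BIOMASS", stoich={"prot": -0.02, "atp": -10.0, "glc": -1.0}))
    net.add_reaction(Reaction(id="NGAM", stoich={"atp": -1.0}, lb=0.1))
    net.biomass_id = "BIOMASS"
    net.protein_pool_met = "prot"
    net.network_machinery_load = {}

    cat = ProteinSpec(id="cat", composition=AminoAcidComposition(counts={"A": 300}))
    ribo = ProteinSpec(id="ribo", composition=AminoAcidComposition(counts={"A": 2000}))
    model = PcModel(
        network=net,
        specs={"cat": cat, "ribo": ribo},
        complexes={"cx_cat": EnzymeComplex(id="cx_cat", subunits={"cat": 1}, kcats={"CAT": 500.0})},
        machineries={"ribosome": Machinery(id="ribosome", protein_id="ribo", kcat=36000.0)},
        network_machinery_load={"PSYN": [("ribosome", 100.0)]},
        params={"proteome_budget": 0.02},
    )
    expand_all(model)
    return model


@pytest.fixture(scope="session")
def hand_model():
    return make_hand_model()


@pytest.fixture(scope="session")
def toy_model():
    """The default miniature cell, built once per session."""
    return build_toy_cell(ToyConfig())


@pytest.fixture(scope="session")
def glucose_grid():
    return np.geomspace(0.01, 100.0, 20)


@pytest.fixture(scope="session")
def series(toy_model, glucose_grid):
    """Shared glucose-series run (transporter switch + overflow + audits)."""
    from pcsec.simulate import glucose_series

    return glucose_series(toy_model, glucose_grid)


@pytest.fixture(scope="session")
def misfold_cap_grid(toy_model):
    """Shared retro-capped misfolding grid."""
    from pcsec.simulate import misfolding_experiment

    return misfolding_experiment(
        toy_model, "cpy",
        folds=[1.0, 7.0, 13.0, 19.0, 25.0],
        ratios=[0.2, 0.4, 0.6, 0.8, 1.0],
        rounds=1,
        retro_cap=1.5e-5,
        tol=2e-5,
    )


@pytest.fixture(scope="session")
def amylase_curve(toy_model):
    from pcsec import amylase_like
    from pcsec.engine import SimulationContext, max_growth
    from pcsec.simulate import recombinant_curve

    mu_star = max_growth(toy_model, SimulationContext(glucose_conc=None)).mu_star
    grid = np.linspace(0.05 * mu_star, 0.95 * mu_star, 15)
    return recombinant_curve(toy_model, amylase_like(), grid)
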