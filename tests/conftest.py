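"""Shared fixtures: small LP fixtures and one session-scoped synthetic study."""

import pytest

from ecflux.model import (
    EcModel,
    Enzyme,
    EnzymeLink,
    Metabolite,
    Reaction,
    to_enzyme_constrained,
)
from ecflux.sampling import SamplingConfig, sample_flux_distributions
from ecflux.synthetic import (
    SyntheticScenario,
    enzyme_gene_map,
    make_core_ecmodel,
    simulate_enzyme_de,
)
from ecflux.transcriptome import (
    build_perturbation_set,
    perturbed_growth_screen,
    select_de_enzymes,
)

SEED = 1
N_SAMPLES = 200


@pytest.fixture
def chain_model():
    """EX_A -> (A->B, ub 7) -> EX_B: the bottleneck sets the optimum."""
    return EcModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, "exchange"),
            Reaction("AtoB", {"A": -1.0, "B": 1.0}, 0.0, 7.0),
            Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, "exchange"),
        ],
    )


@pytest.fixture
def tradeoff_model():
    """One substrate feeding two competing products (B capped at 8, C at 8)."""
    return EcModel(
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("EX_in", {"A": 1.0}, 0.0, 10.0, "exchange"),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
            Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, 100.0),
            Reaction("EX_B", {"B": -1.0}, 0.0, 8.0, "exchange"),
            Reaction("EX_C", {"C": -1.0}, 0.0, 8.0, "exchange"),
        ],
    )


@pytest.fixture
def single_enzyme_ec():
    """One catalysed step (kcat 360000 h^-1, mw 50): max flux = kcat*P/mw = 720."""
    plain = EcModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_in", {"A": 1.0}, 0.0, 1000.0, "exchange"),
            Reaction("CAT", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, "metabolic",
                     [EnzymeLink("E1", 360000.0)]),
            Reaction("EX_out", {"B": -1.0}, 0.0, 1000.0, "exchange"),
        ],
    )
    return to_enzyme_constrained(plain, [Enzyme("E1", 50.0, ["E1"])], pool_bound=0.1)


@pytest.fixture
def atp_toy_model():
    """Glucose -> 2 ATP, consumed by NGAM or biomass (hand stoichiometry)."""
    return EcModel(
        metabolites=[Metabolite("GLC"), Metabolite("ATP")],
        reactions=[
            Reaction("EX_glc", {"GLC": 1.0}, 0.0, 100.0, "exchange"),
            Reaction("GG", {"GLC": -1.0, "ATP": 2.0}, 0.0, 1000.0),
            Reaction("NGAM", {"ATP": -1.0}, 0.0, 1000.0, "ngam"),
            Reaction("BIO", {"ATP": -1.0}, 0.0, 1000.0, "biomass"),
        ],
        biomass_id="BIO",
        ngam_id="NGAM",
        carbon_exchange_ids={"glucose": "EX_glc"},
    )


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=SEED)


@pytest.fixture(scope="session")
def core_model(scenario):
    return make_core_ecmodel(scenario)


@pytest.fixture(scope="session")
def reference_samples(core_model):
    config = SamplingConfig(n_samples=N_SAMPLES, seed=SEED)
    return sample_flux_distributions(core_model, config)


@pytest.fixture(scope="session")
def perturbation_set(scenario, core_model):
    de, _ = simulate_enzyme_de(scenario, core_model)
    gmap = select_de_enzymes(de, enzyme_gene_map(core_model), scenario.deleted_genes)
    return build_perturbation_set(de, gmap, scenario.deleted_genes,
                                  delta=scenario.enzyme_delta)


@pytest.fixture(scope="session")
def screen_records(core_model, reference_samples, perturbation_set):
    return perturbed_growth_screen(core_model, reference_samples, perturbation_set)


@pytest.fixture(scope="session")
def rescue_results(scenario, core_model, reference_samples, perturbation_set,
                   screen_records):
    from ecflux.rescue import single_enzyme_rescue

    return single_enzyme_rescue(
        core_model, reference_samples, perturbation_set,
        mu_target=scenario.target_mu_ethanol, delta=scenario.growth_delta,
        screen=screen_records,
    )
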