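import pytest

from gemtx import (
    MetabolicModel,
    Reaction,
    ThresholdConfig,
    ThresholdSpec,
    ToySpec,
    TranscriptomeDataset,
    generate_toy_model,
)

# Worked example: seven yeast genes with read counts, classified against a
# global cutoff of 130 reads (and 50/130 for the two-threshold approach).
TABLE1_VALUES = {
    "YDL227C": 871.0,
    "YDL226C": 126.0,
    "YDL225W": 319.0,
    "YDL224C": 56.0,
    "YDL223C": 13.0,
    "YDL222C": 3.0,
    "YDL221W": 135.0,
}
LT1_LOCALS = {"YDL227C": 600.0, "YDL225W": 350.0}
LT2_LOCALS = {"YDL226C": 70.0, "YDL224C": 60.0}


@pytest.fixture
def table1_dataset() -> TranscriptomeDataset:
    return TranscriptomeDataset(phenotype="WT", sample="S1", expression=dict(TABLE1_VALUES))


@pytest.fixture
def gt1_config() -> ThresholdConfig:
    return ThresholdConfig("GT1", ThresholdSpec("exact", 130.0))


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_S(-10,0) -> R1 -> R2 -> BIOMASS; unique route, optimum 10."""
    return generate_toy_model(ToySpec(n_linear=3))


@pytest.fixture
def isozyme_model() -> MetabolicModel:
    """Chain with R1 gated by 'gA or gB' and R2 by 'gC and gD'."""
    return generate_toy_model(ToySpec(n_linear=4, with_isozymes=True, with_complex=True))


@pytest.fixture
def parallel_model() -> MetabolicModel:
    """Two redundant branches (R1, P2) each with capacity 10 between M1 and M2."""
    return generate_toy_model(ToySpec(n_linear=3, n_parallel=2))


@pytest.fixture
def reversible_model() -> MetabolicModel:
    """Chain containing one reversible and one backward-irreversible reaction."""
    reactions = [
        Reaction("EX_A", -10.0, 0.0),
        Reaction("R_REV", -1000.0, 1000.0, "gX"),
        Reaction("R_BACK", -1000.0, 0.0, "gY"),
        Reaction("BIOMASS", 0.0, 1000.0),
    ]
    stoich = {
        ("A", "EX_A"): -1.0,
        ("A", "R_REV"): -1.0,
        ("B", "R_REV"): 1.0,
        # R_BACK runs backward: its negative flux converts B to C
        ("C", "R_BACK"): -1.0,
        ("B", "R_BACK"): 1.0,
        ("C", "BIOMASS"): -1.0,
    }
    return MetabolicModel(
        metabolites=["A", "B", "C"],
        reactions=reactions,
        genes=["gX", "gY"],
        stoichiometry=stoich,
        objective_reaction="BIOMASS",
    )
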