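from pathlib import Path

import pytest
from hypothesis import settings

import softcorona as sc

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def corona_exp() -> sc.CoronaExperiment:
    """One synthetic five-sample corona experiment with planted SC structure."""
    return sc.generate_corona_experiment(sc.CoronaSimConfig(seed=7))


@pytest.fixture(scope="session")
def corona_matrix(corona_exp) -> sc.CoronaMatrix:
    """Copy-number matrix recovered by the quantification stage."""
    return sc.build_corona_matrix(corona_exp.records, corona_exp.samples)


@pytest.fixture()
def two_protein_records() -> list:
    """Hand-checkable pair: equal emPAI*Mw products -> equal mass fractions."""
    return [
        sc.ProteinRecord("P1", mw=5e4, empai={"HC+SC": 2.0}),
        sc.ProteinRecord("P2", mw=1e5, empai={"HC+SC": 1.0}),
    ]
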