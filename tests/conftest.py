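from pathlib import Path

import numpy as np
import pytest

from dadl import (LibraryDesign, OracleParams, RuleOracle, parse_design_spec,
                  run_campaign)


@pytest.fixture(scope="session")
def oracle() -> RuleOracle:
    """Default planted-boundary fitness oracle."""
    return RuleOracle()


@pytest.fixture(scope="session")
def nnk8() -> LibraryDesign:
    return parse_design_spec("(nnk)8")


@pytest.fixture(scope="session")
def nnk11() -> LibraryDesign:
    return parse_design_spec("(nnk)11")


@pytest.fixture(scope="session")
def small_campaign(tmp_path_factory, oracle, nnk8):
    """A short seeded selection/antiselection campaign shared across tests."""
    outdir = tmp_path_factory.mktemp("campaign")
    return run_campaign(nnk8, oracle, outdir, n_rounds=3, n_variants=4000,
                        seed=0)


class ConstantPredictor:
    """Stub predictor returning a fixed probability for every insert."""

    def __init__(self, value: float, max_len: int = 12):
        self.value = value
        self.max_len = max_len

    def predict_fitness(self, inserts):
        return np.full(len(list(inserts)), self.value)

    def predict(self, inserts):
        return (self.predict_fitness(inserts) > 0.5).astype(int)


@pytest.fixture
def constant_predictor():
    return ConstantPredictor
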