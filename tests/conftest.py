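import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from abcquant import ChipSpec, GateResult, gdna_concentration, simulate_chip
from abcquant import fixtures

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def crlf2_panel():
    return fixtures.crlf2_panel()


@pytest.fixture(scope="session")
def crlf2_amplicon():
    return fixtures.crlf2_amplicon()


@pytest.fixture(scope="session")
def bcl2_panel():
    return fixtures.bcl2_panel()


@pytest.fixture(scope="session")
def default_chip():
    return ChipSpec()


@pytest.fixture(scope="session")
def total_conc():
    """Default template load: 10 ng human gDNA in a 9 uL reaction."""
    return gdna_concentration(10.0, 9.0)


def gate_from_truth(truth, dyes) -> GateResult:
    """Noise-free gating oracle: calls taken directly from simulator truth.

    Lets quantification be tested against the Poisson layer alone, without
    fluorescence noise or threshold placement in the loop.
    """
    calls = pd.DataFrame({d: np.asarray(truth.true_state[d]) for d in dyes})
    n_pos = {d: int(calls[d].sum()) for d in dyes}
    n_neg = {d: int(len(calls) - n_pos[d]) for d in dyes}
    return GateResult(
        chip_id=truth.chip_id, thresholds={d: float("nan") for d in dyes},
        calls=calls, n_pos=n_pos, n_neg=n_neg,
    )


def simulate_truth_gate(panel, chip, species, seed):
    """Simulate a chip and return its truth-derived (noise-free) GateResult."""
    _, truth = simulate_chip(panel, chip, species, seed=seed)
    return gate_from_truth(truth, panel.dyes), truth
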