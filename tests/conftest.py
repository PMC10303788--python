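import numpy as np
import pytest
from hypothesis import settings

from mrpipe import HarmonizedInstrument, InstrumentSet, harmonize, load_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reverse_fixture():
    """ADHD-exposure / cortisol-outcome instrument tables (7 SNPs)."""
    return load_fixture("adhd_to_cortisol")


@pytest.fixture(scope="session")
def forward_fixture():
    """Cortisol-exposure / ADHD-outcome tables (5 SNPs, outcome betas absent)."""
    return load_fixture("cortisol_to_adhd")


@pytest.fixture(scope="session")
def reverse_set(reverse_fixture):
    exp, out = reverse_fixture
    return harmonize(exp, out, exposure_name="ADHD",
                     outcome_name="cortisol", direction="reverse")


@pytest.fixture(scope="session")
def forward_set(forward_fixture):
    exp, out = forward_fixture
    return harmonize(exp, out, exposure_name="cortisol",
                     outcome_name="ADHD", direction="forward")


def random_instruments(rng: np.random.Generator, k: int) -> InstrumentSet:
    """Random complete instrument set for oracle cross-checks."""
    instruments = []
    for i in range(k):
        be = rng.uniform(0.03, 0.3) * rng.choice([-1, 1])
        instruments.append(
            HarmonizedInstrument(
                snp_id=f"rs{i:05d}",
                effect_allele="A",
                other_allele="G",
                beta_exp=be,
                se_exp=rng.uniform(0.005, 0.05),
                beta_out=rng.normal(0.0, 0.1),
                se_out=rng.uniform(0.005, 0.05),
            )
        )
    return InstrumentSet("x", "y", instruments)
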