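import numpy as np
import pytest
from hypothesis import settings

from rop.simulate import hap_freqs_from_ld, sample_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# The full coding table for the ten diplotypes, frozen as the reference
# truth for the encoder.  Column order:
# GA, GB, DA, DB, Cis_AB, Cis_aB, Cis_Ab, Cis_ab, Trans_AB, Trans_aB,
# Trans_Ab, Trans_ab.
CODING_TABLE = {
    "ab/ab": (0, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0, 2),
    "Ab/ab": (1, 0, 1, 0, 0, 0, 1, 1, 0, 0, 1, 1),
    "aB/ab": (0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1),
    "AB/ab": (1, 1, 1, 1, 1, 0, 0, 1, 0, 1, 1, 0),
    "Ab/aB": (1, 1, 1, 1, 0, 1, 1, 0, 1, 0, 0, 1),
    "Ab/Ab": (2, 0, 0, 0, 0, 0, 2, 0, 0, 0, 2, 0),
    "aB/aB": (0, 2, 0, 0, 0, 2, 0, 0, 0, 2, 0, 0),
    "AB/aB": (1, 2, 1, 0, 1, 1, 0, 0, 1, 1, 0, 0),
    "AB/Ab": (2, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0),
    "AB/AB": (2, 2, 0, 0, 2, 0, 0, 0, 2, 0, 0, 0),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def balanced_cohort(rng):
    """~400-sample cohort containing all ten diplotypes (full-rank designs)."""
    freqs = hap_freqs_from_ld(0.4, 0.45, 0.1)
    H = sample_cohort(freqs, 400, rng)
    return H


@pytest.fixture
def gaussian_null(rng, balanced_cohort):
    """Continuous phenotype with marginal effects but no phase effect."""
    from rop.coding import phasetype_table

    pt = phasetype_table(balanced_cohort)
    y = (
        0.3 * pt["GA"].to_numpy()
        - 0.2 * pt["DB"].to_numpy()
        + rng.normal(size=len(pt))
    )
    return y


@pytest.fixture
def binary_null(rng, balanced_cohort):
    from rop.coding import phasetype_table
    from scipy.special import expit

    pt = phasetype_table(balanced_cohort)
    eta = -0.5 + 0.4 * pt["GA"].to_numpy()
    return (rng.random(len(pt)) < expit(eta)).astype(float)
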