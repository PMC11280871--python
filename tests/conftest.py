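import numpy as np
import pytest

from beatline.beat_model import N_SAMPLES, FiducialSet


def random_fiducials(rng: np.random.Generator) -> FiducialSet:
    """A uniformly random valid fiducial set (P absent ~15% of the time)."""
    cuts = np.sort(rng.choice(N_SAMPLES, size=5, replace=False))
    if rng.random() < 0.15:
        return FiducialSet(qrs_onset=int(cuts[2]), qrs_offset=int(cuts[3]),
                           t_offset=int(cuts[4]), p_present=False)
    return FiducialSet(p_onset=int(cuts[0]), p_offset=int(cuts[1]),
                       qrs_onset=int(cuts[2]), qrs_offset=int(cuts[3]),
                       t_offset=int(cuts[4]), p_present=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture(scope="session")
def small_dataset():
    """Sixty annotated synthetic beats shared across tests."""
    from beatline.synth import SynthParams, generate_dataset
    return generate_dataset(SynthParams(n_beats=60, seed=42))
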