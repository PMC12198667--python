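import numpy as np
import pytest
from hypothesis import settings

from bmdkit import DoseResponseDataset, StudyDesign, generate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

ORAL_DOSES = (0.0, 0.02, 0.2, 20.0, 200.0)


@pytest.fixture
def hill_dataset() -> DoseResponseDataset:
    """Hill-generated study, 5 dose groups x 8 animals, increasing."""
    design = StudyDesign(
        study_id="sim",
        endpoint_id="hormone",
        doses=ORAL_DOSES,
        n_per_group=8,
        true_model="hill",
        true_params=(8.0, 8.0, 60.0, 1.2),
        log_sd=0.3,
        seed=42,
        direction=+1,
        units="ng/ml",
    )
    return generate_study(design)


@pytest.fixture
def toy_dataset() -> DoseResponseDataset:
    """Tiny fixed dataset for exact-arithmetic checks."""
    rng = np.random.default_rng(7)
    doses = np.repeat([0.0, 1.0, 10.0], 4)
    responses = np.exp(rng.normal(np.log(10.0), 0.2, doses.size))
    return DoseResponseDataset("toy", "endpoint", doses, responses)
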