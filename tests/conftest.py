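import pytest

from lncnet.lncrna_discovery import train_and_calibrate
from lncnet.synthetic_data import (
    SyntheticConfig,
    generate_study,
    generate_training_sequences,
)

SMALL = dict(n_mrna=60, n_known_lnc=8, n_novel_lnc=20)


@pytest.fixture(scope="session")
def small_study():
    """One small but complete synthetic study shared across tests."""
    return generate_study(SyntheticConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def coding_model():
    """Coding-potential model trained once on generated labelled sets."""
    coding, noncoding = generate_training_sequences(11, n_each=200)
    return train_and_calibrate(coding, noncoding)
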