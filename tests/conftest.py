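import pytest

from rrnhet import MultiAlignment, SequenceRecord
from rrnhet.synthetic import SyntheticConfig, generate_dataset


def make_alignment(rows: dict[str, str], **meta) -> MultiAlignment:
    return MultiAlignment(
        [SequenceRecord(id=k, residues=v, **meta) for k, v in rows.items()]
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Default-sized dataset at zero within-type noise: every planted
    feature is exactly recoverable."""
    return generate_dataset(SyntheticConfig(within_type_site_noise=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default configuration (small within-type noise)."""
    return generate_dataset(SyntheticConfig(seed=12))
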