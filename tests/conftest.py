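import numpy as np
import pytest

from metabscreen.feature_table import (
    FeatureID,
    FeatureTable,
    Label,
    Role,
    SampleRecord,
)


def make_table(x, roles=None, labels=None, allow_negative=False):
    """Build a small FeatureTable from a matrix; defaults to all-study/case-less."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    roles = roles if roles is not None else [Role.STUDY] * n
    labels = labels if labels is not None else [
        (Label.CONTROL if r is Role.STUDY else None) for r in roles
    ]
    samples = [
        SampleRecord(sample_id=f"s{i}", role=roles[i], label=labels[i]) for i in range(n)
    ]
    features = [FeatureID(rt=0.5 + 0.01 * j, mass=100.0 + j) for j in range(p)]
    return FeatureTable(samples=samples, features=features, intensities=x,
                        allow_negative=allow_negative)


@pytest.fixture
def small_planted():
    """A quick planted dataset shared by several integration-ish tests."""
    from metabscreen.synthetic import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_cases=20, n_controls=60, n_qc=8, n_blank=5,
        n_features=120, n_discriminative=10, effect_size=1.5, seed=11,
    )
    return generate_dataset(cfg)
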