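import numpy as np
import pandas as pd
import pytest

from mwlindex import GeneratorConfig, Recording, generate_recording
from mwlindex.features import FEATURE_NAMES


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Short, artifact-free cohort settings for fast unit tests."""
    return GeneratorConfig(n_subjects=4, duration_s=20.0, seed=7, blink_rate_hz=0.0)


@pytest.fixture(scope="session")
def rest_recording(small_cfg) -> Recording:
    return generate_recording(small_cfg, 1, "Rest")


@pytest.fixture(scope="session")
def simkap_recording(small_cfg) -> Recording:
    return generate_recording(small_cfg, 1, "Simkap")


def make_labeled_table(
    n_per_class: int = 20,
    n_features: int = 6,
    seed: int = 0,
    informative: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Random binary-labeled feature table with unique subject ids.

    The first ``informative`` features are shifted by +1.5 for the
    superoptimal class; the rest are pure noise.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array(["suboptimal"] * n_per_class + ["superoptimal"] * n_per_class)
    x = rng.standard_normal((n, n_features))
    x[labels == "superoptimal", :informative] += 1.5
    if feature_names is None:
        feature_names = list(FEATURE_NAMES[:n_features])
    df = pd.DataFrame(x, columns=feature_names)
    df.insert(0, "subject_id", np.arange(1, n + 1))
    df.insert(1, "condition", np.where(labels == "suboptimal", "Rest", "Simkap"))
    df.insert(2, "label", labels)
    return df
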