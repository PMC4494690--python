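import numpy as np
import pytest

from basalmir.simulate import ExpressionSimConfig, gen_expression
from basalmir.types import ExpressionMatrix, SampleAnnotation, Stage


@pytest.fixture
def rng():
    return np.random.default_rng(20150708)


@pytest.fixture
def small_raw_matrix():
    """3 features x 2 samples, positive raw intensities."""
    return ExpressionMatrix(
        [[200.0, 300.0], [151.0, 149.0], [10.0, 20.0]],
        Stage.RAW,
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture
def two_group_annotations():
    """Six samples, two groups, one run / one chip."""
    return [
        SampleAnnotation(f"a{i}", "basal_brca1", "run1", "chip1") for i in range(3)
    ] + [SampleAnnotation(f"b{i}", "basal_sporadic", "run1", "chip1") for i in range(3)]


@pytest.fixture(scope="session")
def study_like_simulation():
    """One seeded draw from the default study-design simulation."""
    return gen_expression(ExpressionSimConfig(seed=11))


def clustering_fixture_config(seed: int) -> ExpressionSimConfig:
    """The standard two-group clustering fixture: planted effect 2.0,
    residual noise 0.5, 15 + 15 samples."""
    return ExpressionSimConfig(
        seed=seed,
        n_features=300,
        n_low_features=0,
        n_per_group={"basal_brca1": 15, "basal_sporadic": 15},
        de_features=50,
        log2_effect=2.0,
        noise_sd=0.5,
        run1_size=6,
    )
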