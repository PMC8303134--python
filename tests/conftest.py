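import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_truth():
    """A noise-free default phantom's ground truth."""
    from grafscreen.phantom import PhantomSpec, build_truth

    return build_truth(PhantomSpec(speckle_sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def clean_image(clean_truth):
    from grafscreen.phantom import rasterize_phantom

    return rasterize_phantom(clean_truth)


@pytest.fixture(scope="session")
def reference_cohort():
    from grafscreen.datasets import synthetic_reference_cohort

    return synthetic_reference_cohort(seed=0)


@pytest.fixture(scope="session")
def reference_check_table(reference_cohort):
    from grafscreen.gating import tabulate_check

    common = [p for p in reference_cohort if p.ai.detectable and p.human.detectable]
    return tabulate_check(common)
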