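import numpy as np
import pytest

from morphoface.synthetic import SyntheticSpec, build_template, generate_cohort


@pytest.fixture(scope="session")
def template_and_scheme():
    return build_template()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small landmark+image cohort shared by io/pipeline tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticSpec(n=8, seed=11, image_size=(48, 48))
    configs, scheme, truth = generate_cohort(spec, out)
    return {"dir": out, "spec": spec, "configs": configs, "scheme": scheme,
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_config(rng, k, spread=1.0):
    """A non-degenerate random landmark configuration."""
    return rng.uniform(-spread, spread, size=(k, 2)) + np.array([0.0, 0.0])
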