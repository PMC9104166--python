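import numpy as np
import pandas as pd
import pytest

from iaqscreen.core import POLLUTANTS, SCHEME_1
from iaqscreen.synthetic import GeneratorConfig, generate_offices


@pytest.fixture(scope="session")
def small_survey():
    """A 400-office synthetic survey under default Scheme-1 conditions."""
    config = GeneratorConfig.for_scheme(SCHEME_1, n_offices=400, seed=7)
    return generate_offices(config, SCHEME_1)


@pytest.fixture(scope="session")
def random_records():
    """Unstructured random records spanning 0–2× the Scheme-1 limits."""
    rng = np.random.default_rng(123)
    data = {
        p: rng.uniform(0.0, 2.0 * SCHEME_1.limit(p), size=5000) for p in POLLUTANTS
    }
    return pd.DataFrame(data)


def passing_record(**overrides):
    """A record comfortably below every limit of both schemes."""
    base = {p: 0.5 * SCHEME_1.limit(p) for p in POLLUTANTS}
    base.update(co=2.0, rsp=40.0, radon=80.0)
    base.update(overrides)
    return base
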