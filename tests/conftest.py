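import numpy as np
import pytest

from batkinetics.steady_state import Analyte, EnrichmentSeries, Pool
from batkinetics.synthetic import (
    PhantomConfig,
    generate_kinetic_subject,
    generate_phantom,
    make_sampling_schedule,
)


@pytest.fixture(scope="session")
def schedule():
    return make_sampling_schedule()


@pytest.fixture(scope="session")
def noiseless_subject():
    """Noise-free tracer study generated from known parameters."""
    return generate_kinetic_subject(
        true_fcr=0.5, true_k_delay=1.2, noise_cv=0.0, seed=7
    )


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomConfig(seed=3))


def make_series(times, ttr, analyte=Analyte.PALMITATE, pool=Pool.PLASMA_FREE, conc=None):
    return EnrichmentSeries(
        subject_id="T000",
        analyte=analyte,
        pool=pool,
        times=np.asarray(times, float),
        ttr=np.asarray(ttr, float),
        concentration=conc,
    )
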