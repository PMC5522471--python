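import numpy as np
import pytest

import mibiquant as mq


@pytest.fixture(scope="session")
def records():
    """The packaged 20-patient reference cohort."""
    return mq.load_cohort_table()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default benign-kinetics phantom without counting noise."""
    return mq.build_phantom(noise="none")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_valid_kinetics(rng, apply_physical_decay=False):
    """Draw kinetic parameters for which both indices are well defined."""
    while True:
        a0_bg = rng.uniform(0.005, 0.05)
        a0_par = a0_bg + rng.uniform(0.05, 0.3)
        a0_n = a0_par + rng.uniform(0.02, 0.4)
        f_par = rng.uniform(0.2, 0.9)
        f_n = rng.uniform(f_par + 0.02, 1.0)
        f_bg = rng.uniform(0.3, 1.0)
        if a0_par * f_par <= a0_bg * f_bg:
            continue
        return mq.KineticParams(
            a0_nodule=a0_n,
            a0_parenchyma=a0_par,
            a0_body_background=a0_bg,
            f_nodule=f_n,
            f_parenchyma=f_par,
            f_background=f_bg,
            apply_physical_decay=apply_physical_decay,
        )
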