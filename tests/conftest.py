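import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pscea import config
from pscea.costing import Patient
from pscea.curves import ArmCurves, SurvivalCurve, make_arm_curves

#: User-supplied PFS median (months) for the sorafenib arm, which has no
#: published value; used wherever a full two-arm run is needed.
SORAFENIB_PFS_MEDIAN = 2.8


@pytest.fixture(scope="session")
def patient():
    return Patient(161.5, 61.8)


@pytest.fixture(scope="session")
def params():
    return config.load_params()


@pytest.fixture(scope="session")
def model(params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # residual survivors at the 60-month horizon
        return config.build_model(
            params, pfs_median_overrides={"sorafenib": SORAFENIB_PFS_MEDIAN}
        )


@pytest.fixture(scope="session")
def folfox_curves():
    """Exponential FOLFOX4 curves from the published medians."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_arm_curves(6.40, 2.93, horizon=60, arm_name="folfox4")


@pytest.fixture(scope="session")
def toy_curves():
    """Hand-sized 5-month curve pair with non-trivial PD occupancy."""
    os_v = np.array([1.0, 0.9, 0.7, 0.45, 0.2, 0.0])
    pfs_v = np.array([1.0, 0.6, 0.35, 0.15, 0.05, 0.0])
    return ArmCurves("toy", SurvivalCurve("OS", os_v), SurvivalCurve("PFS", pfs_v))
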