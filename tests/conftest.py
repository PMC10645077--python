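import numpy as np
import pytest

from paleodyn.calibration import CalibrationCurve, RadiocarbonDate
from paleodyn.models import MODEL_SPECS, ParameterSet
from paleodyn.proxies import GenerationTable


@pytest.fixture
def identity_curve():
    """Toy curve with mu(cal BP) = cal BP and zero curve error."""
    calbp = np.arange(0.0, 3001.0, 10.0)
    return CalibrationCurve(cal_bp=calbp, mu=calbp.copy(),
                            sigma_curve=np.zeros_like(calbp), name="identity")


@pytest.fixture
def wiggly_curve():
    # wiggle steep enough that mu is locally non-monotone: a single 14C age
    # then crosses the curve several times (genuinely multimodal calibration)
    calbp = np.arange(0.0, 3001.0, 5.0)
    mu = calbp + 80.0 * np.sin(2 * np.pi * calbp / 300.0)
    return CalibrationCurve(cal_bp=calbp, mu=mu,
                            sigma_curve=np.full_like(calbp, 8.0), name="wiggly")


def make_date(age, site="S1", sigma=20.0, lab=None):
    return RadiocarbonDate(lab_id=lab or f"L{age:.0f}-{site}", age_c14=age,
                           sigma=sigma, site_id=site)


def random_table(seed, n=55, step=25):
    """Well-conditioned random generation table (not from the dynamic model)."""
    rng = np.random.default_rng(seed)
    years = 100.0 + step * np.arange(n)
    x = np.exp(rng.uniform(np.log(2.0), np.log(30.0), size=n))
    z = rng.uniform(0, 1, size=n)
    zw = rng.uniform(0, 1, size=n)
    zs = rng.uniform(0, 1, size=n)
    return GenerationTable.from_arrays(years, x, z, zw, zs, step=step)


@pytest.fixture
def table_from_model_a():
    """Noise-free table generated exactly by the endogenous model A."""
    params = ParameterSet(R_m=0.5, c=0.01, w=0.001)
    n = 30
    X = np.empty(n)
    X[0] = np.log(5.0)
    for t in range(n - 1):
        X[t + 1] = X[t] + params.R_m - params.c * np.exp(X[t]) - params.w * np.exp(-X[t])
    years = 100.0 + 25.0 * np.arange(n)
    rng = np.random.default_rng(1)
    return params, GenerationTable.from_arrays(
        years, np.exp(X), rng.uniform(0, 1, n), rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    )
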