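import numpy as np
import pytest

import psmcea
from psmcea.model import calibrate_case


@pytest.fixture(scope="session")
def case():
    """The packaged advanced-HCC case study (uncalibrated)."""
    return psmcea.load_case_study()


@pytest.fixture(scope="session")
def calibrated_and_report(case):
    return calibrate_case(case)


@pytest.fixture(scope="session")
def calibrated(calibrated_and_report):
    """Case study after linear cost calibration to the published totals."""
    return calibrated_and_report[0]


@pytest.fixture(scope="session")
def calibration_report(calibrated_and_report):
    return calibrated_and_report[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def lognormal_ipd(n, meanlog, sdlog, seed, censored_fraction=0.0):
    """Lognormal event times with a fraction lost to follow-up uniformly
    before their event (random-dropout censoring)."""
    r = np.random.default_rng(seed)
    t = np.exp(r.normal(meanlog, sdlog, n))
    event = np.ones(n, dtype=int)
    n_cens = int(round(censored_fraction * n))
    if n_cens:
        idx = r.choice(n, n_cens, replace=False)
        event[idx] = 0
        t = t.copy()
        t[idx] = r.uniform(0.0, t[idx])
    return [psmcea.IPDRecord(float(a), int(b)) for a, b in zip(t, event)]
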