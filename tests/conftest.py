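import numpy as np
import pytest

import breathflow as bf


@pytest.fixture(scope="session")
def narrow_grid():
    """Fine grid covering the attributed marker range (keeps tests fast)."""
    return bf.FeatureGrid(50.0, 210.0, 0.001)


@pytest.fixture(scope="session")
def small_cohort_cfg():
    """Tiny scan-level cohort: 3 untreated vs 3 treated, nine markers."""
    return bf.CohortConfig(
        n_untreated=3,
        n_treated=3,
        n_control=0,
        panel=bf.table2_panel(),
        n_baseline_peaks=8,
        mass_range=(50.0, 210.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg):
    sessions, records, gt = bf.simulate_cohort_sessions(small_cohort_cfg)
    return sessions, records, gt


@pytest.fixture()
def gaussian_spectrum():
    """One analytic Gaussian peak: apex 10 cps at m/z 100, TOF-like width."""
    sigma = 100.0 / 30000.0 / 2.3548
    mz = np.arange(99.9, 100.1, 0.0005)
    intensity = 10.0 * np.exp(-0.5 * ((mz - 100.0) / sigma) ** 2)
    return bf.MassSpectrum(mz=mz, intensity=intensity, scan_time=0.0)
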