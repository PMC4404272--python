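import numpy as np
import pytest

from ntcp_lab.dvh_io import Cohort, CumulativeDVH, PatientRecord
from ntcp_lab.synthetic_data import generate_cohort


def random_cumulative_dvh(rng: np.random.Generator, n_bins: int = 40) -> CumulativeDVH:
    """A valid random cumulative DVH: sorted doses, non-increasing fractions."""
    doses = np.sort(rng.uniform(0.0, 80.0, size=n_bins))
    doses[0] = 0.0
    doses += np.arange(n_bins) * 1e-6  # enforce strict increase under duplicates
    drops = rng.dirichlet(np.ones(n_bins))
    fractions = 1.0 - np.concatenate([[0.0], np.cumsum(drops[:-1])])
    return CumulativeDVH(doses, fractions)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_lkb_cohort() -> Cohort:
    """120 patients with outcomes drawn from the LKB truth model."""
    return generate_cohort(n_patients=120, truth_model="lkb", seed=424242)


@pytest.fixture(scope="session")
def small_logistic_cohort() -> Cohort:
    """120 patients with outcomes drawn from the logistic truth model."""
    return generate_cohort(n_patients=120, truth_model="logistic", seed=515151)


@pytest.fixture(scope="session")
def fitted_lkb(small_lkb_cohort):
    from ntcp_lab.lkb import fit_lkb

    return fit_lkb(small_lkb_cohort)


def toy_patient(pid: str, late: int, doses=(0.0, 40.0, 76.0), fracs=(1.0, 0.5, 0.1),
                ah_ac: int = 0, acute: int = 0) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        dvh=CumulativeDVH(np.array(doses), np.array(fracs)),
        ah_ac=ah_ac,
        acute_gi=acute,
        late_gi=late,
    )
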