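import numpy as np
import pytest

from canidnm.records import TrioRecord
from canidnm.simulate import SimulationConfig, default_region_map, simulate_cohort


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture(scope="session")
def small_cohort(region_map):
    """60-trio cohort under default study conditions."""
    return simulate_cohort(SimulationConfig(seed=101, n_trios=60), region_map)


@pytest.fixture(scope="session")
def full_cohort(region_map):
    """Cohort at the study scale (390 trios)."""
    return simulate_cohort(SimulationConfig(seed=202), region_map)


@pytest.fixture
def trio():
    return TrioRecord(
        trio_id="T1",
        offspring_id="O1",
        sire_id="S1",
        dam_id="D1",
        offspring_sex="M",
        paternal_age_years=5.0,
        maternal_age_years=4.0,
        mean_depth={"offspring": 43.3, "sire": 43.3, "dam": 43.3},
    )


def phased_arrays(cohort, sex="paternal", phase_col="true_phase"):
    """Per-trio phased counts, ages, haploid exposures from a cohort."""
    phased = cohort.dnms[cohort.dnms[phase_col] == sex].groupby("trio_id").size()
    counts = np.array([phased.get(t.trio_id, 0) for t in cohort.trios], float)
    col = "paternal_age_years" if sex == "paternal" else "maternal_age_years"
    ages = np.array([getattr(t, col) for t in cohort.trios])
    expo = np.array(
        [cohort.callable_sites[t.trio_id]["AUTOSOME"] for t in cohort.trios], float
    )
    return counts, ages, expo
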