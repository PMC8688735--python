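import hypothesis
import numpy as np
import pandas as pd
import pytest

from dqtaper.cohort import Cohort, validate_cohort
from dqtaper.constants import CANONICAL_MONTHS
from dqtaper.intervals import build_interval_table
from dqtaper.simulate import generate_paper_shaped

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_cohort(n_patients=2, asdas=None, dq=None, mri=None) -> Cohort:
    """Hand-constructable small cohort; per-patient overrides by index.

    ``asdas``/``dq`` map patient index -> per-month values; ``mri`` maps
    patient index -> {month: (sparcc, fat, erosion, backfill)} (months
    omitted from the dict are unmeasured).
    """
    groups = ["tapering", "withdrawal"]
    diags = ["AS", "nr-axSpA"]
    sexes = ["male", "female"]
    patients, visits, mri_rows, doses = [], [], [], []
    for i in range(n_patients):
        pid = f"P{i + 1}"
        patients.append(
            {
                "patient_id": pid,
                "group": groups[i % 2],
                "diagnosis": diags[i % 2],
                "sex": sexes[i % 2],
                "age": 28 + i,
                "duration": 12,
                "hla_b27": 1 - i % 2,
                "smoking": i % 2,
            }
        )
        a = (asdas or {}).get(i, {m: 1.0 for m in CANONICAL_MONTHS})
        d = (dq or {}).get(i, {m: 100.0 for m in CANONICAL_MONTHS})
        scans = (mri or {}).get(
            i, {m: (10.0, 5.0, 5.0, 1.0) for m in CANONICAL_MONTHS}
        )
        for m in CANONICAL_MONTHS:
            visits.append(
                {
                    "patient_id": pid,
                    "month": m,
                    "asdas_crp": a[m],
                    "asdas_esr": np.nan,
                    "basdai": np.nan,
                    "basfi": np.nan,
                    "crp": np.nan,
                    "esr": np.nan,
                }
            )
            # standard etanercept scaled to the requested DQ level
            if d[m] > 0:
                doses.append(
                    {
                        "patient_id": pid,
                        "month": m,
                        "drug": "etanercept",
                        "actual_dose": 25.0,
                        "actual_interval": 3.5 * 100.0 / d[m],
                    }
                )
            else:
                doses.append(
                    {
                        "patient_id": pid,
                        "month": m,
                        "drug": "etanercept",
                        "actual_dose": 0.0,
                        "actual_interval": 3.5,
                    }
                )
        for m, scores in scans.items():
            mri_rows.append(
                {
                    "patient_id": pid,
                    "month": m,
                    "sparcc": float(scores[0]),
                    "fat": float(scores[1]),
                    "erosion": float(scores[2]),
                    "backfill": float(scores[3]),
                    "measured": 1,
                }
            )
    cohort = Cohort(
        patients=pd.DataFrame(patients),
        visits=pd.DataFrame(visits),
        mri=pd.DataFrame(mri_rows),
        doses=pd.DataFrame(doses),
    )
    return validate_cohort(cohort)


@pytest.fixture
def two_patient_cohort() -> Cohort:
    return make_cohort(2)


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-shaped cohort (108 patients, 63/45 arms), shared."""
    cohort, truth = generate_paper_shaped(seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def paper_intervals(paper_cohort):
    cohort, _ = paper_cohort
    return build_interval_table(cohort)
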