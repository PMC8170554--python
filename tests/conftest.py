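import numpy as np
import pandas as pd
import pytest

from rnflcomp import Cohort, EffectSizes, generate_cohort
from rnflcomp.profiles import COVARIATE_COLUMNS, profile_columns


def zero_effects(**overrides) -> EffectSizes:
    """All systematic and random effects off unless overridden."""
    base = dict(
        age_rate=0.0,
        al_thinning=0.0,
        al_peak_convergence=0.0,
        al_thinning_hinge=0.0,
        al_convergence_hinge=0.0,
        dfa_rotation=0.0,
        dfd_scale=0.0,
        gender_offset=0.0,
        noise_sd=0.0,
        subject_sd=0.0,
        peak_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
    )
    base.update(overrides)
    return EffectSizes(**base)


def toy_cohort(values: np.ndarray, ages=None, **cov) -> Cohort:
    """Build a cohort directly from a (n, P) matrix for solver tests."""
    values = np.asarray(values, dtype=float)
    n, P = values.shape
    rows = []
    for k in range(n):
        row = {"eye_id": f"T{k:03d}"}
        row.update(zip(profile_columns(P), values[k]))
        row.update(
            age=float(ages[k]) if ages is not None else 60.0,
            gender=cov.get("gender", "F"),
            axial_length=cov.get("axial_length", 23.18),
            disc_fovea_distance=cov.get("disc_fovea_distance", 4.88),
            disc_fovea_angle=cov.get("disc_fovea_angle", 7.59),
            quality_score=30.0,
            label="normal",
        )
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["eye_id", *profile_columns(P), *COVARIATE_COLUMNS])
    return Cohort(frame, P=P)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Mixed-label cohort at small P for I/O and detection tests."""
    return generate_cohort(40, 15, seed=11, P=32)
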