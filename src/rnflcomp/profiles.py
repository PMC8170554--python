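"""Domain containers for circumpapillary RNFL thickness profiles.

A profile is a circular vector of P thickness samples (µm) taken on the
3.4-mm peripapillary scan circle; by convention index 0 sits at the
temporal horizontal position and indices increase superiorly (TSNIT
unrolling), so the two arcuate-bundle humps appear near ±70° from the
origin.  A cohort joins one wide table of profiles with one table of
per-eye covariates (age, gender, axial length, disc-fovea distance and
angle), a scan-quality score and a diagnostic label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError

DEFAULT_P = 768

#: CSV column order for the covariates table.
COVARIATE_COLUMNS = [
    "age",
    "gender",
    "axial_length",
    "disc_fovea_distance",
    "disc_fovea_angle",
    "quality_score",
    "label",
]

#: Continuous covariates consumed by the compensation networks.
NETWORK_COVARIATES = ["axial_length", "disc_fovea_distance", "disc_fovea_angle"]

GENDER_CODES = {"F": 0.0, "M": 1.0}
LABELS = ("normal", "glaucoma")


def profile_columns(P: int) -> list[str]:
    """Column names ``p0 .. p{P-1}`` of the wide profiles table."""
    return [f"p{i}" for i in range(P)]


def angles_deg(P: int, start_angle: float = 0.0) -> np.ndarray:
    """Angular position (degrees) of each of the P samples."""
    return (start_angle + 360.0 * np.arange(P) / P) % 360.0


def circular_distance_deg(a, b) -> np.ndarray:
    """Shortest angular distance |a-b| on the circle, in degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass
class AngularProfile:
    """Circular thickness profile.

    Parameters
    ----------
    values : array of shape (P,)
        Thickness in µm; finite and non-negative.
    start_angle : float
        Angle (degrees) assigned to index 0.
    orientation : str
        Unrolling convention; ``"TSNIT"`` means indices run
        temporal → superior → nasal → inferior → temporal.
    """

    values: np.ndarray
    start_angle: float = 0.0
    orientation: str = "TSNIT"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ContractError("profile must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("profile contains non-finite values")
        if np.any(self.values < 0):
            raise ContractError("thickness must be >= 0 µm")

    @property
    def P(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.P

    def __getitem__(self, i: int) -> float:
        # circular indexing: index P is index 0 again
        return float(self.values[int(i) % self.P])

    def angles(self) -> np.ndarray:
        return angles_deg(self.P, self.start_angle)


@dataclass
class Covariates:
    """Per-eye covariates used by the compensation."""

    age: float
    gender: str
    axial_length: float
    disc_fovea_distance: float
    disc_fovea_angle: float

    def __post_init__(self):
        if self.age < 0:
            raise ContractError(f"age must be >= 0, got {self.age}")
        if not 15.0 < self.axial_length < 35.0:
            raise ContractError(
                f"axial_length must lie in (15, 35) mm, got {self.axial_length}"
            )
        if self.disc_fovea_distance <= 0:
            raise ContractError("disc_fovea_distance must be > 0 mm")
        if self.gender not in GENDER_CODES:
            raise ContractError(f"gender must be one of {set(GENDER_CODES)}")

    @property
    def gender_code(self) -> float:
        return GENDER_CODES[self.gender]


@dataclass
class EyeRecord:
    """One eye: profile + covariates + diagnostic label + scan quality."""

    eye_id: str
    profile: AngularProfile
    covariates: Covariates
    label: str
    quality_score: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise ContractError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class Cohort:
    """Ordered collection of eyes sharing a profile length P.

    Internally a single wide DataFrame (``frame``) with columns
    ``eye_id, p0..p{P-1}`` plus the covariate columns; this is also the
    feature matrix consumed by the estimators.
    """

    frame: pd.DataFrame
    P: int = field(default=0)

    def __post_init__(self):
        if self.P == 0:
            self.P = sum(1 for c in self.frame.columns if _is_profile_col(c))
        missing = [
            c
            for c in ["eye_id", *profile_columns(self.P), *COVARIATE_COLUMNS]
            if c not in self.frame.columns
        ]
        if missing:
            raise ContractError(f"cohort frame missing columns: {missing[:5]}")
        if self.frame["eye_id"].duplicated().any():
            dup = self.frame.loc[self.frame["eye_id"].duplicated(), "eye_id"].iloc[0]
            raise ContractError(f"duplicate eye_id in cohort: {dup!r}")
        bad = set(self.frame["label"]) - set(LABELS)
        if bad:
            raise ContractError(f"unknown labels in cohort: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def profiles(self) -> np.ndarray:
        """(n, P) thickness matrix, µm."""
        return self.frame[profile_columns(self.P)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def eye_ids(self) -> np.ndarray:
        return self.frame["eye_id"].to_numpy()

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[COVARIATE_COLUMNS]

    def to_frame(self) -> pd.DataFrame:
        """Feature matrix for the estimators (profiles + covariates)."""
        return self.frame[profile_columns(self.P) + COVARIATE_COLUMNS].copy()

    def records(self) -> Iterator[EyeRecord]:
        for _, row in self.frame.iterrows():
            yield EyeRecord(
                eye_id=row["eye_id"],
                profile=AngularProfile(
                    row[profile_columns(self.P)].to_numpy(dtype=float)
                ),
                covariates=Covariates(
                    age=row["age"],
                    gender=row["gender"],
                    axial_length=row["axial_length"],
                    disc_fovea_distance=row["disc_fovea_distance"],
                    disc_fovea_angle=row["disc_fovea_angle"],
                ),
                label=row["label"],
                quality_score=row["quality_score"],
            )

    def subset(self, mask_or_index) -> "Cohort":
        return Cohort(self.frame.loc[mask_or_index].reset_index(drop=True), P=self.P)

    def with_profiles(self, values: np.ndarray) -> "Cohort":
        """Copy of the cohort with the thickness matrix replaced."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self), self.P):
            raise ContractError(
                f"profile matrix shape {values.shape} != {(len(self), self.P)}"
            )
        frame = self.frame.copy()
        frame[profile_columns(self.P)] = values
        return Cohort(frame, P=self.P)

    @classmethod
    def from_records(cls, records: Sequence[EyeRecord]) -> "Cohort":
        if not records:
            raise ContractError("cannot build a cohort from zero records")
        P = records[0].profile.P
        rows = []
        for r in records:
            if r.profile.P != P:
                raise ContractError(
                    f"record {r.eye_id!r} has P={r.profile.P}, expected {P}"
                )
            row = {"eye_id": r.eye_id}
            row.update(zip(profile_columns(P), r.profile.values))
            row.update(
                age=r.covariates.age,
                gender=r.covariates.gender,
                axial_length=r.covariates.axial_length,
                disc_fovea_distance=r.covariates.disc_fovea_distance,
                disc_fovea_angle=r.covariates.disc_fovea_angle,
                quality_score=r.quality_score,
                label=r.label,
            )
            rows.append(row)
        return cls(pd.DataFrame(rows), P=P)


def _is_profile_col(name: str) -> bool:
    return name.startswith("p") and name[1:].isdigit()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cohort(profiles_path, covariates_path) -> Cohort:
    """Read a cohort from the two CSV tables and join them on ``eye_id``.

    The profiles table has columns ``eye_id, p0..p{P-1}``; the covariates
    table has ``eye_id`` plus the covariate columns.  Row order follows
    the profiles table.
    """
    prof = pd.read_csv(
        profiles_path, dtype={"eye_id": str}, float_precision="round_trip"
    )
    cov = pd.read_csv(
        covariates_path, dtype={"eye_id": str}, float_precision="round_trip"
    )
    if "eye_id" not in prof.columns or "eye_id" not in cov.columns:
        raise ContractError("both tables must contain an eye_id column")
    P = sum(1 for c in prof.columns if _is_profile_col(c))
    if P == 0:
        raise ContractError(f"no profile columns (p0..) found in {profiles_path}")
    pcols = profile_columns(P)
    missing_cols = [c for c in pcols if c not in prof.columns]
    if missing_cols:
        raise ContractError(f"profiles table missing columns {missing_cols[:5]}")
    for c in pcols:
        coerced = pd.to_numeric(prof[c], errors="coerce")
        bad = coerced.isna() & prof[c].notna()
        if bad.any() or prof[c].isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ContractError(
                f"non-numeric thickness at row {row}, column {c!r} "
                f"in {profiles_path}"
            )
        prof[c] = coerced
    only_prof = set(prof["eye_id"]) - set(cov["eye_id"])
    only_cov = set(cov["eye_id"]) - set(prof["eye_id"])
    if only_prof or only_cov:
        raise ContractError(
            "eye_id mismatch between tables; "
            f"missing from covariates: {sorted(only_prof)[:5]}, "
            f"missing from profiles: {sorted(only_cov)[:5]}"
        )
    merged = prof.merge(cov, on="eye_id", how="left", validate="one_to_one")
    return Cohort(merged, P=P)


def write_cohort(cohort: Cohort, profiles_path, covariates_path) -> None:
    """Write the two CSV tables; ``read_cohort`` inverts this exactly."""
    pcols = profile_columns(cohort.P)
    prof = cohort.frame[["eye_id", *pcols]]
    cov = cohort.frame[["eye_id", *COVARIATE_COLUMNS]]
    _write_exact(prof, profiles_path)
    _write_exact(cov, covariates_path)


def _write_exact(df: pd.DataFrame, path) -> None:
    buf = io.StringIO()
    # 17 significant digits keep the float round-trip bit-exact
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# quality filtering and magnification correction
# ---------------------------------------------------------------------------

def filter_quality(cohort: Cohort, min_quality: float = 15.0) -> tuple[Cohort, int]:
    """Drop scans whose quality score is below ``min_quality``.

    Returns the filtered cohort (order preserved) and the number of
    records removed.  The default threshold of 15 is the conventional
    Spectralis acquisition cut-off.
    """
    if min_quality < 0:
        raise ContractError("min_quality must be >= 0")
    keep = cohort.frame["quality_score"] >= min_quality
    removed = int((~keep).sum())
    return Cohort(cohort.frame.loc[keep].reset_index(drop=True), P=cohort.P), removed


def littmann_bennett_factor(axial_length: float) -> float:
    """Ocular magnification factor q = 0.01306·(AL − 1.82).

    Bennett's simplification of the Littmann method: the true fundus
    distance is t = p·q·s where p is the instrument factor and s the
    on-image distance.  Used when converting fundus-photograph
    measurements (disc-fovea distance) to millimetres.
    """
    if not 15.0 < axial_length < 35.0:
        raise ContractError(
            f"axial_length must lie in (15, 35) mm, got {axial_length}"
        )
    return 0.01306 * (axial_length - 1.82)
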