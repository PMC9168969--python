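"""Virtual patient cohorts observed at two screening rounds.

Each virtual patient carries an age (which fixes the screening interval:
18 months up to age 54, 24 months from 55), a TVDT drawn from the clinical
fit, a first-round tumor diameter uniform on 3.5-13 mm, and breast
metadata (volume 450-950 mL, percent dense compartments 5-60%, a random
lesion location).  The second-round diameter follows deterministically
from the growth law.  Tumors exceeding palpable size (> 20 mm) at the
second round are flagged, not removed: interval cancers are deliberately
not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tvdtsim.distribution import ClinicalFit, clinical_fit
from tvdtsim.growth import DAYS_PER_MONTH, estimate_tvdt, months_to_days, project_diameter

AGE_MIN, AGE_MAX = 40.0, 74.0
PALPABLE_MM = 20.0

_COHORT_COLUMNS = [
    "id",
    "age_years",
    "interval_months",
    "tvdt_days",
    "d1_mm",
    "d2_mm",
    "breast_volume_ml",
    "density_pct",
    "loc_x",
    "loc_y",
    "loc_z",
    "palpable_flag",
]


@dataclass(frozen=True)
class VirtualPatient:
    id: int
    age: float  # years, 40-74
    interval: int  # months, 18 or 24
    tvdt: float  # days
    d_round1: float  # mm, true diameter at first screening
    d_round2: float  # mm, true diameter at second screening
    breast_volume: float  # mL
    density: float  # percent dense compartments
    lesion_location: tuple[float, float, float]  # normalized breast coords

    @property
    def palpable(self) -> bool:
        """True when the second-round tumor exceeds palpable size."""
        return self.d_round2 > PALPABLE_MM


@dataclass
class CohortConfig:
    """Configuration for cohort generation.

    ``age_table`` optionally supplies an empirical age-at-detection sample
    to resample from; by default ages are uniform over the screening range.
    """

    n: int = 30
    seed: int | None = None
    tvdt_source: ClinicalFit = field(default_factory=clinical_fit)
    diameter_range: tuple[float, float] = (3.5, 13.0)
    age_range: tuple[float, float] = (AGE_MIN, AGE_MAX)
    age_table: np.ndarray | None = None
    interval_age_threshold: float = 54.0
    month_length: float = DAYS_PER_MONTH
    volume_range_ml: tuple[float, float] = (450.0, 950.0)
    density_range_pct: tuple[float, float] = (5.0, 60.0)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        lo, hi = self.diameter_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid diameter_range {self.diameter_range}")


def assign_interval(age: float, threshold: float = 54.0) -> int:
    """Screening interval in months from age: 18 up to ``threshold``, else 24."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside screening range [{AGE_MIN}, {AGE_MAX}]")
    return 18 if age <= threshold else 24


def generate_cohort(config: CohortConfig) -> list[VirtualPatient]:
    """Draw ``config.n`` virtual patients and grow their tumors to round 2."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tvdts = config.tvdt_source.frozen.rvs(size=config.n, random_state=rng)
    if config.age_table is not None:
        ages = rng.choice(np.asarray(config.age_table, dtype=float), size=config.n)
    else:
        ages = rng.uniform(*config.age_range, size=config.n)
    d1 = rng.uniform(*config.diameter_range, size=config.n)
    volumes = rng.uniform(*config.volume_range_ml, size=config.n)
    densities = rng.uniform(*config.density_range_pct, size=config.n)
    locations = rng.uniform(0.0, 1.0, size=(config.n, 3))

    patients = []
    for i in range(config.n):
        interval = assign_interval(ages[i], config.interval_age_threshold)
        dt = months_to_days(interval, config.month_length)
        d2 = project_diameter(d1[i], tvdts[i], dt)
        patients.append(
            VirtualPatient(
                id=i + 1,
                age=float(ages[i]),
                interval=interval,
                tvdt=float(tvdts[i]),
                d_round1=float(d1[i]),
                d_round2=float(d2),
                breast_volume=float(volumes[i]),
                density=float(densities[i]),
                lesion_location=tuple(locations[i]),
            )
        )
    return patients


def cohort_tvdt_roundtrip(patient: VirtualPatient, month_length: float = DAYS_PER_MONTH) -> float:
    """Re-estimate the patient's TVDT from its noise-free true sizes."""
    dt = months_to_days(patient.interval, month_length)
    est = estimate_tvdt(patient.d_round1, patient.d_round2, dt)
    return est.days


def cohort_to_frame(cohort: list[VirtualPatient]) -> pd.DataFrame:
    rows = [
        {
            "id": p.id,
            "age_years": p.age,
            "interval_months": p.interval,
            "tvdt_days": p.tvdt,
            "d1_mm": p.d_round1,
            "d2_mm": p.d_round2,
            "breast_volume_ml": p.breast_volume,
            "density_pct": p.density,
            "loc_x": p.lesion_location[0],
            "loc_y": p.lesion_location[1],
            "loc_z": p.lesion_location[2],
            "palpable_flag": p.palpable,
        }
        for p in cohort
    ]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort(cohort: list[VirtualPatient], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path) -> list[VirtualPatient]:
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - {"palpable_flag"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    patients = []
    for idx, row in df.iterrows():
        try:
            patients.append(
                VirtualPatient(
                    id=int(row["id"]),
                    age=float(row["age_years"]),
                    interval=int(row["interval_months"]),
                    tvdt=float(row["tvdt_days"]),
                    d_round1=float(row["d1_mm"]),
                    d_round2=float(row["d2_mm"]),
                    breast_volume=float(row["breast_volume_ml"]),
                    density=float(row["density_pct"]),
                    lesion_location=(
                        float(row["loc_x"]),
                        float(row["loc_y"]),
                        float(row["loc_z"]),
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row {idx}: {exc}") from exc
    return patients
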