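"""Simulated radiologist: repeated two-orthogonal-diameter measurements.

The clinical protocol this emulates: a reader records the largest tumor
size and the size orthogonal to it, at 0.1-mm precision, in three repeated
sessions; the mean of the two sizes enters the growth law to estimate the
TVDT.  Because the simulated tumors are spheres, both directions see the
same true diameter, so the two sizes are modelled as i.i.d. noisy reads:

    size = round_to_0.1(true_d + bias + N(0, sd))

truncated below at 0.1 mm.  Each session draws from its own seeded
substream so that session independence holds by construction.  The noise
SD is a tunable stand-in for intrareader variability, not a clinically
measured quantity; the default 0.5 mm per direction yields scatter of the
same order as published reader measurements of spherical masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tvdtsim.cohort import VirtualPatient
from tvdtsim.growth import (
    DAYS_PER_MONTH,
    GrowthStatus,
    estimate_tvdt,
    mean_diameter,
    months_to_days,
)

_MEASUREMENT_COLUMNS = ["patient_id", "session", "round", "size_a_mm", "size_b_mm"]


@dataclass(frozen=True)
class ObserverNoise:
    """Additive Gaussian error per single-direction measurement."""

    sd: float = 0.5  # mm
    bias: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One session's two orthogonal sizes for one patient and round."""

    patient_id: int
    session: int  # 1-based
    round: int  # 1 or 2
    size_a: float  # mm, multiple of 0.1
    size_b: float  # mm, multiple of 0.1

    @property
    def mean_size(self) -> float:
        return mean_diameter(self.size_a, self.size_b)


def _quantize(x: float) -> float:
    """Round to 0.1 mm, truncating below at the 0.1-mm floor."""
    return max(round(x, 1), 0.1)


def simulate_measurement(
    true_d: float, noise: ObserverNoise, rng=None
) -> tuple[float, float]:
    """Two independent noisy reads of ``true_d``, recorded at 0.1 mm."""
    if true_d <= 0:
        raise ValueError(f"true diameter must be positive, got {true_d}")
    gen = np.random.default_rng(rng)
    raw = true_d + noise.bias + gen.normal(0.0, noise.sd, size=2)
    return _quantize(raw[0]), _quantize(raw[1])


def measure_cohort(
    cohort: list[VirtualPatient],
    noise: ObserverNoise,
    n_sessions: int = 3,
    seed=None,
) -> list[MeasurementRecord]:
    """Measure every patient at both rounds in ``n_sessions`` sessions.

    Returns ``n_sessions * 2 * len(cohort)`` records.  Sessions use
    independent substreams spawned from ``seed``.
    """
    streams = np.random.SeedSequence(seed).spawn(n_sessions)
    records = []
    for s, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        for p in cohort:
            for rnd, true_d in ((1, p.d_round1), (2, p.d_round2)):
                a, b = simulate_measurement(true_d, noise, rng)
                records.append(
                    MeasurementRecord(
                        patient_id=p.id, session=s, round=rnd, size_a=a, size_b=b
                    )
                )
    return records


def estimate_cohort_tvdt(
    records: list[MeasurementRecord],
    cohort: list[VirtualPatient],
    month_length: float = DAYS_PER_MONTH,
) -> pd.DataFrame:
    """Per-patient, per-session estimated TVDT from measured mean sizes.

    Returns a frame with columns ``patient_id, session, tvdt_est_days,
    status``; non-growth cases carry NaN with their sentinel status.
    Raises if any patient/session lacks one of the two rounds.
    """
    intervals = {p.id: p.interval for p in cohort}
    by_key: dict[tuple[int, int], dict[int, float]] = {}
    for r in records:
        by_key.setdefault((r.patient_id, r.session), {})[r.round] = r.mean_size

    missing = [
        f"patient {pid} session {s} round {rnd}"
        for (pid, s), rounds in sorted(by_key.items())
        for rnd in (1, 2)
        if rnd not in rounds
    ]
    if missing:
        raise ValueError("missing measurements: " + "; ".join(missing))

    rows = []
    for (pid, s), rounds in sorted(by_key.items()):
        if pid not in intervals:
            raise ValueError(f"measurement for unknown patient {pid}")
        dt = months_to_days(intervals[pid], month_length)
        est = estimate_tvdt(rounds[1], rounds[2], dt)
        rows.append(
            {
                "patient_id": pid,
                "session": s,
                "tvdt_est_days": est.days,
                "status": est.status.value,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "session", "tvdt_est_days", "status"])


def write_measurements(records: list[MeasurementRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "session": r.session,
                "round": r.round,
                "size_a_mm": r.size_a,
                "size_b_mm": r.size_b,
            }
            for r in records
        ],
        columns=_MEASUREMENT_COLUMNS,
    ).to_csv(path, index=False)


def read_measurements(path) -> list[MeasurementRecord]:
    """Read and validate a measurement CSV.

    Sizes must be positive; granularity coarser than 0.1 mm is accepted
    (real readers may report whole millimetres).
    """
    df = pd.read_csv(path)
    missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        a, b = row["size_a_mm"], row["size_b_mm"]
        if not (a > 0 and b > 0) or math.isnan(a) or math.isnan(b):
            raise ValueError(f"{path}: row {idx}: sizes must be positive, got {a}, {b}")
        records.append(
            MeasurementRecord(
                patient_id=int(row["patient_id"]),
                session=int(row["session"]),
                round=int(row["round"]),
                size_a=float(a),
                size_b=float(b),
            )
        )
    return records
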