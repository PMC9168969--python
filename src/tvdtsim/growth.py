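"""Exponential, sphere-approximated tumor growth law and its inversion.

Under exponential volume growth a tumor's volume doubles every TVDT days.
Because volume scales with the cube of the diameter, the diameter of a
spherical tumor evolves as

    d(t) = d(0) * 2 ** (t / (3 * TVDT))

and, inversely, the doubling time recovered from two diameters ``d1 < d2``
measured ``dt`` days apart is

    TVDT = ln(2) * dt / (3 * ln(d2 / d1)).

Measured sizes may be unchanged or smaller at the later round (measurement
noise); those cases map to explicit non-numeric sentinels rather than being
dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

#: Days per month used to convert screening intervals; mean Gregorian month.
DAYS_PER_MONTH = 365.25 / 12


class GrowthStatus(str, Enum):
    """Outcome category of a doubling-time estimate."""

    GROWING = "growing"
    NO_GROWTH = "no_growth"
    SHRINKING = "shrinking"


@dataclass(frozen=True)
class DoublingTime:
    """A tumor volume doubling time in days, or a sentinel.

    ``days`` is a finite positive number only when ``status`` is GROWING
    (or a negative number when shrinkage was requested as a signed value);
    otherwise it is NaN.
    """

    days: float
    status: GrowthStatus = GrowthStatus.GROWING

    @property
    def is_defined(self) -> bool:
        return self.status is GrowthStatus.GROWING and math.isfinite(self.days)


def months_to_days(months: float, month_length: float = DAYS_PER_MONTH) -> float:
    """Convert a screening interval in months to days.

    The default month length is 365.25/12 days (18 mo = 547.9 d, 24 mo =
    730.5 d); passing ``month_length=730/24`` gives the simpler 730/548-day
    convention.
    """
    if months <= 0:
        raise ValueError(f"interval must be positive, got {months} months")
    return months * month_length


def project_diameter(d_start: float, tvdt: float, dt: float) -> float:
    """Diameter (mm) after ``dt`` days of exponential growth.

    Parameters
    ----------
    d_start : float
        Diameter at time zero, mm (> 0).
    tvdt : float
        Tumor volume doubling time, days (> 0).
    dt : float
        Elapsed time, days (>= 0).
    """
    if not (d_start > 0 and math.isfinite(d_start)):
        raise ValueError(f"d_start must be positive and finite, got {d_start}")
    if not (tvdt > 0 and math.isfinite(tvdt)):
        raise ValueError(f"tvdt must be positive and finite, got {tvdt}")
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    return d_start * 2.0 ** (dt / (3.0 * tvdt))


def estimate_tvdt(
    d_early: float,
    d_late: float,
    dt: float,
    *,
    shrinkage: str = "sentinel",
) -> DoublingTime:
    """Doubling time from two diameters ``dt`` days apart.

    Equal sizes yield the undefined-growth sentinel (infinite doubling
    time).  A smaller late size yields the shrinkage sentinel by default;
    with ``shrinkage="signed"`` the (negative) halving time is returned
    instead, still flagged as SHRINKING.
    """
    if d_early <= 0 or d_late <= 0:
        raise ValueError("diameters must be positive")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if shrinkage not in ("sentinel", "signed"):
        raise ValueError(f"unknown shrinkage policy {shrinkage!r}")
    if d_late == d_early:
        return DoublingTime(math.nan, GrowthStatus.NO_GROWTH)
    value = math.log(2.0) * dt / (3.0 * math.log(d_late / d_early))
    if d_late < d_early:
        days = value if shrinkage == "signed" else math.nan
        return DoublingTime(days, GrowthStatus.SHRINKING)
    return DoublingTime(value, GrowthStatus.GROWING)


def sphere_volume(d: float) -> float:
    """Volume (mm^3) of a sphere with diameter ``d`` mm: (pi/6) d^3."""
    if d < 0:
        raise ValueError(f"diameter must be non-negative, got {d}")
    return math.pi / 6.0 * d**3


def mean_diameter(a: float, b: float) -> float:
    """Mean of two orthogonal size measurements (mm)."""
    if a <= 0 or b <= 0:
        raise ValueError("sizes must be positive")
    return (a + b) / 2.0
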