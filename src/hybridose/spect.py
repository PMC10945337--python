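"""Quantitative SPECT: calibration and partial-volume recovery correction.

Post-reconstruction voxel values are converted to activity with the
camera calibration factor and divided by a volume-dependent recovery
coefficient RC(v) ∈ (0, 1] that compensates partial-volume count losses
in small structures.  The packaged default curve is the parametric form
RC(v) = v / (v + v50) — a synthetic stand-in with v50 = 2 mL, since
scanner-specific recovery tables are site measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .warn import RC_EXTRAPOLATED, warn_code

__all__ = ["RecoveryCurve", "SpectMeasurement", "spect_activity", "recovery_correct"]


@dataclass
class RecoveryCurve:
    """Volume-dependent recovery coefficient.

    Either parametric, ``RC(v) = v / (v + v50_mL)``, or tabulated as
    ``points`` of (volume_mL, recovery_fraction) interpolated linearly on
    a log-volume axis.  ``v50_mL = 0`` gives the identity curve RC ≡ 1.
    """

    v50_mL: float | None = None
    points: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.v50_mL is None) == (self.points is None):
            raise ValueError("give exactly one of v50_mL or points")
        if self.points is not None:
            pts = sorted(self.points)
            vols = [v for v, _ in pts]
            rcs = [rc for _, rc in pts]
            if any(v <= 0 for v in vols):
                raise ValueError("tabulated volumes must be > 0")
            if any(not 0 < rc <= 1 for rc in rcs):
                raise ValueError("recovery fractions must be in (0, 1]")
            if any(b < a for a, b in zip(rcs, rcs[1:])):
                raise ValueError("recovery must be non-decreasing in volume")
            self.points = tuple(pts)
        elif self.v50_mL < 0:
            raise ValueError("v50_mL must be >= 0")

    @classmethod
    def parametric(cls, v50_mL: float = 2.0) -> "RecoveryCurve":
        return cls(v50_mL=v50_mL)

    @classmethod
    def from_table(cls, points) -> "RecoveryCurve":
        return cls(points=tuple(tuple(p) for p in points))

    def __call__(self, volume_mL: float) -> float:
        if volume_mL <= 0:
            raise ValueError("volume must be > 0")
        if self.v50_mL is not None:
            if self.v50_mL == 0:
                return 1.0
            return volume_mL / (volume_mL + self.v50_mL)
        vols = np.array([v for v, _ in self.points])
        rcs = np.array([rc for _, rc in self.points])
        if volume_mL < vols[0]:
            warn_code(RC_EXTRAPOLATED,
                      f"volume {volume_mL:.3g} mL below smallest tabulated "
                      f"({vols[0]:.3g} mL); using RC={rcs[0]:.3g}")
            return float(rcs[0])
        if volume_mL > vols[-1]:
            return float(rcs[-1])
        return float(np.interp(np.log(volume_mL), np.log(vols), rcs))


@dataclass
class SpectMeasurement:
    """Total counts in a segmented VOI at one SPECT time point."""

    region_id: str
    time_h: float
    counts: float
    volume_mL: float
    calibration_counts_per_MBq: float

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValueError("counts must be >= 0")
        if self.volume_mL <= 0:
            raise ValueError("volume_mL must be > 0")
        if self.calibration_counts_per_MBq <= 0:
            raise ValueError("calibration must be > 0")


def spect_activity(m: SpectMeasurement) -> float:
    """Convert VOI counts to activity (MBq) with the camera calibration."""
    return m.counts / m.calibration_counts_per_MBq


def recovery_correct(activity_MBq: float, volume_mL: float,
                     rc: RecoveryCurve) -> float:
    """Divide measured activity by RC(volume); corrected >= measured."""
    r = rc(volume_mL)
    if r <= 0:
        raise ValueError(f"recovery coefficient must be > 0, got {r}")
    return activity_MBq / r
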