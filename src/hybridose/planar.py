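"""Conjugate-view quantification of planar whole-body scintigraphy.

Activity in a region is estimated from paired anterior/posterior count
rates via their geometric mean,

    A = sqrt(I_A * I_P / T) * f / C,

where ``T`` is the photon transmission through the body measured with a
blank/transmission scan pair, ``f`` an optional source self-attenuation
factor and ``C`` the planar calibration factor (counts per MBq).  Before
entering the geometric mean each view is scatter-corrected with the
dual-energy-window (DEW) estimate and background-corrected with a
per-pixel background scaled to the ROI pixel count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .warn import CLAMPED_COUNTS, warn_code

__all__ = [
    "PlanarMeasurement",
    "SegmentationConfig",
    "dew_scatter_correct",
    "background_correct",
    "conjugate_view_activity",
    "threshold_segment",
    "thin_slab_self_attenuation",
    "quantify_planar_table",
    "tb161_width_ratio",
    "lu177_width_ratio",
]


def _window_width_ratio(peak_keV: float, peak_frac: float,
                        scatter_keV: float, scatter_frac: float) -> float:
    return (peak_frac * peak_keV) / (scatter_frac * scatter_keV)


def tb161_width_ratio() -> float:
    """Photopeak/scatter window width ratio for the Tb-161 protocol
    (20% window at 74.6 keV over 15% window at 69.4 keV)."""
    return _window_width_ratio(74.6, 0.20, 69.4, 0.15)


def lu177_width_ratio() -> float:
    """Width ratio for the Lu-177 protocol (20% at 208 keV / 15% at 187 keV)."""
    return _window_width_ratio(208.0, 0.20, 187.0, 0.15)


@dataclass
class PlanarMeasurement:
    """One region at one time point on a conjugate planar acquisition."""

    region_id: str
    time_h: float
    ant_counts: float
    post_counts: float
    ant_scatter: float = 0.0
    post_scatter: float = 0.0
    transmission_T: float = 1.0
    bg_per_pixel: float = 0.0
    n_pixels: int = 1
    window_width_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ant_counts", "post_counts", "ant_scatter", "post_scatter",
                     "bg_per_pixel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.transmission_T <= 1:
            raise ValueError("transmission_T must be in (0, 1]")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass
class SegmentationConfig:
    """Threshold segmentation parameters.

    ``threshold_fraction`` applies to organ ROIs on planar images;
    ``lesion_isocontour_fraction`` is the SUVmax isocontour fraction used
    for lesion volumes (clinically 20-40%).
    """

    threshold_fraction: float = 0.4
    lesion_isocontour_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if not 0.20 <= self.lesion_isocontour_fraction <= 0.40:
            raise ValueError("lesion_isocontour_fraction must be in [0.20, 0.40]")


def dew_scatter_correct(peak: float, scatter: float, width_ratio: float,
                        k: float = 1.0) -> float:
    """Subtract the dual-energy-window scatter estimate from the photopeak.

    The scatter contribution in the photopeak is estimated as
    ``k * scatter * width_ratio`` where ``width_ratio`` converts counts
    between windows of different keV width.  Negative results clamp to 0
    with a ``CLAMPED_COUNTS`` warning.
    """
    if peak < 0 or scatter < 0:
        raise ValueError("count rates must be >= 0")
    if width_ratio <= 0:
        raise ValueError("width_ratio must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    corrected = peak - k * scatter * width_ratio
    if corrected < 0:
        warn_code(CLAMPED_COUNTS,
                  f"DEW scatter correction drove counts negative "
                  f"({corrected:.3g}); clamped to 0")
        return 0.0
    return corrected


def background_correct(counts: float, bg_per_pixel: float, n_pixels: int) -> float:
    """Subtract background scaled from per-pixel rate to the ROI pixel count."""
    if counts < 0 or bg_per_pixel < 0 or n_pixels < 0:
        raise ValueError("inputs must be >= 0")
    corrected = counts - bg_per_pixel * n_pixels
    if corrected < 0:
        warn_code(CLAMPED_COUNTS,
                  f"background correction drove counts negative "
                  f"({corrected:.3g}); clamped to 0")
        return 0.0
    return corrected


def conjugate_view_activity(m: PlanarMeasurement, calibration_cps_per_MBq: float,
                            self_att_f: float = 1.0) -> float:
    """Geometric-mean activity (MBq) from corrected conjugate views.

    ``m.ant_counts``/``m.post_counts`` must already be scatter- and
    background-corrected.  ``self_att_f`` is the source self-attenuation
    factor (1 = thin source).
    """
    if m.transmission_T <= 0:
        raise ValueError("transmission_T must be > 0")
    if calibration_cps_per_MBq <= 0:
        raise ValueError("calibration must be > 0")
    if not 0 < self_att_f <= 1:
        raise ValueError("self_att_f must be in (0, 1]")
    geo = math.sqrt(m.ant_counts * m.post_counts / m.transmission_T)
    return geo * self_att_f / calibration_cps_per_MBq


def thin_slab_self_attenuation(mu_per_cm: float, thickness_cm: float) -> float:
    """Source self-attenuation factor f = (μt/2)/sinh(μt/2) for a uniform slab.

    A distributed slab source attenuates its own photons less than the
    midline point the whole-body transmission assumes, so the geometric
    mean overestimates activity; f ∈ (0, 1] corrects this.  Tends to 1 as
    the source gets thin; opt-in (the default pipeline uses f = 1).
    """
    x = 0.5 * mu_per_cm * thickness_cm
    if x == 0:
        return 1.0
    return x / math.sinh(x)


def threshold_segment(image: np.ndarray, boundary_mask: np.ndarray,
                      cfg: SegmentationConfig, *, lesion: bool = False) -> np.ndarray:
    """Threshold-based segmentation inside a manually drawn boundary.

    Selects pixels/voxels whose intensity is >= fraction x (max intensity
    inside ``boundary_mask``).  ``lesion=True`` uses the isocontour
    fraction, else the organ threshold fraction.
    """
    image = np.asarray(image, dtype=float)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if image.shape != boundary_mask.shape:
        raise ValueError("image and boundary_mask shapes differ")
    if not boundary_mask.any():
        raise ValueError("boundary mask is empty")
    if not np.isfinite(image[boundary_mask]).all():
        raise ValueError("image has non-finite values inside the boundary")
    vmax = image[boundary_mask].max()
    if vmax <= 0:
        raise ValueError("no positive maximum inside the boundary")
    frac = cfg.lesion_isocontour_fraction if lesion else cfg.threshold_fraction
    return boundary_mask & (image >= frac * vmax)


def quantify_planar_table(planar: pd.DataFrame, calibration_cps_per_MBq: float,
                          *, dew_k: float = 1.0, self_att_f: float = 1.0,
                          injected_activity_MBq: float | None = None) -> pd.DataFrame:
    """Quantify a planar measurement table (schema of ``planar.csv``).

    Expected columns: region, time_h, ant_counts, post_counts, ant_scatter,
    post_scatter, transmission, bg_per_pixel, n_pixels, window_width_ratio.
    Returns columns region, time_h, activity_MBq and, when the injected
    activity is given, percent_IA.
    """
    out = []
    for row in planar.itertuples(index=False):
        ant = dew_scatter_correct(row.ant_counts, row.ant_scatter,
                                  row.window_width_ratio, dew_k)
        post = dew_scatter_correct(row.post_counts, row.post_scatter,
                                   row.window_width_ratio, dew_k)
        ant = background_correct(ant, row.bg_per_pixel, int(row.n_pixels))
        post = background_correct(post, row.bg_per_pixel, int(row.n_pixels))
        m = PlanarMeasurement(
            region_id=row.region, time_h=row.time_h, ant_counts=ant,
            post_counts=post, transmission_T=row.transmission,
            n_pixels=int(row.n_pixels),
            window_width_ratio=row.window_width_ratio,
        )
        out.append((row.region, row.time_h,
                    conjugate_view_activity(m, calibration_cps_per_MBq, self_att_f)))
    df = pd.DataFrame(out, columns=["region", "time_h", "activity_MBq"])
    if injected_activity_MBq is not None:
        df["percent_IA"] = 100.0 * df["activity_MBq"] / injected_activity_MBq
    return df
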