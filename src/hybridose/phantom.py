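"""Synthetic planar + SPECT phantom with known ground-truth kinetics.

Emulates the acquisition design of a post-therapy dosimetry protocol:
three conjugate-view planar time points (days 1, 2 and 4 after
injection), one quantitative SPECT estimate per region, monoexponential
washout A(t) = A0·exp(−(λ_bio + λ_phys)·t) per region, and detector
effects — planar calibration factor, body attenuation (transmission),
dual-energy-window scatter, diffuse background, Poisson counting noise,
and a volume-dependent SPECT recovery coefficient with additive noise.

The simulation is region-level: the dosimetry chain consumes ROI count
rates, so pixel-level realism is optional (``paint_planar_image`` gives
threshold segmentation a 2D surface to run on).  SPECT reconstruction is
not simulated; the generator emits post-reconstruction region activities
degraded only by the recovery curve and noise.

``true_dose`` is the closed-form oracle: TIAC = (A0/100)/λ_eff applied
to the same self-dose model as the dose engine, so end-to-end recovery
can be asserted against an analytic truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import DoseResult, RegionSpec, self_dose
from .nuclides import Nuclide, decay_constant, load_nuclide
from .planar import tb161_width_ratio
from .spect import RecoveryCurve

__all__ = [
    "PhantomRegion",
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "true_dose",
    "default_phantom_spec",
    "paint_planar_image",
    "write_dataset",
    "read_dataset",
]

#: nominal whole-body matrix (256 x 1024 pixels of 4.66 mm) over which the
#: diffuse background is spread
_BODY_PIXELS = 10_000


@dataclass
class PhantomRegion:
    """Ground-truth kinetics and geometry of one source region."""

    region_id: str
    A0_percentIA: float
    lambda_bio_per_h: float
    mass_g: float
    thickness_cm: float = 4.0
    depth_cm: float = 6.0
    density_g_per_mL: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.A0_percentIA <= 100:
            raise ValueError("A0_percentIA must be in (0, 100]")
        if self.lambda_bio_per_h < 0:
            raise ValueError("lambda_bio_per_h must be >= 0")
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.depth_cm <= 0 or self.thickness_cm < 0:
            raise ValueError("geometry must be positive")

    @property
    def volume_mL(self) -> float:
        return self.mass_g / self.density_g_per_mL


@dataclass
class PhantomSpec:
    """Full study-condition specification of a synthetic acquisition."""

    nuclide: Nuclide
    regions: tuple[PhantomRegion, ...]
    acquisition_times_h: tuple[float, ...] = (24.0, 48.0, 96.0)
    spect_time_h: float = 48.0
    calibration_cps_per_MBq: float = 100.0
    mu_per_cm: float = 0.15
    scatter_fraction: float = 0.2
    background_percentIA: float = 5.0
    injected_activity_GBq: float = 6.4
    seed: int | None = None
    poisson_noise: bool = True
    spect_noise_sd: float = 0.02
    dew_k: float = 1.0
    window_width_ratio: float = field(default_factory=tb161_width_ratio)
    recovery: RecoveryCurve = field(
        default_factory=lambda: RecoveryCurve.parametric(2.0))

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        self.acquisition_times_h = tuple(float(t) for t in self.acquisition_times_h)
        times = self.acquisition_times_h
        if any(t < 0 for t in times) or any(
                b <= a for a, b in zip(times, times[1:])):
            raise ValueError("acquisition times must be >= 0, strictly increasing")
        if self.calibration_cps_per_MBq <= 0:
            raise ValueError("calibration must be > 0")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must be in [0, 1)")
        if self.mu_per_cm <= 0:
            raise ValueError("mu_per_cm must be > 0")
        if self.spect_noise_sd < 0:
            raise ValueError("spect_noise_sd must be >= 0")
        total = sum(r.A0_percentIA for r in self.regions)
        if total + self.background_percentIA > 100.0 + 1e-9:
            raise ValueError(
                f"regions + background = {total + self.background_percentIA:.1f} "
                "%IA exceed 100% of the injected activity")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")

    def region(self, region_id: str) -> PhantomRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"unknown region {region_id!r}")

    def lambda_eff(self, region_id: str) -> float:
        return self.region(region_id).lambda_bio_per_h + decay_constant(self.nuclide)

    def true_percent_ia(self, region_id: str, time_h: float) -> float:
        r = self.region(region_id)
        return r.A0_percentIA * math.exp(-self.lambda_eff(region_id) * time_h)


@dataclass
class PhantomDataset:
    """Generated measurements plus the truth that generated them."""

    planar: pd.DataFrame
    spect: pd.DataFrame
    truth: PhantomSpec


def _region_pixels(region: PhantomRegion) -> int:
    # ROI pixel count grows with projected region size; deterministic
    return max(10, int(round(20.0 * region.mass_g ** (2.0 / 3.0) / 4.0)))


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate one noisy (or noiseless) planar + SPECT dataset.

    The conjugate-view forward model per region and time point:
    primary geometric counts P = C·A_MBq·√T with T = exp(−2μ·depth);
    the photopeak additionally contains k·SF·width_ratio·P of scatter and
    the pixel-scaled background, the scatter window records SF·P, so the
    standard DEW + background + geometric-mean chain inverts the model
    exactly in the noiseless case.  Identical seed ⇒ identical dataset.
    """
    if spec.seed is None:
        raise ValueError("PhantomSpec.seed is required (determinism is mandatory)")
    times = spec.acquisition_times_h
    if not (times[0] - 12.0 <= spec.spect_time_h <= times[-1] + 12.0):
        raise ValueError(
            f"spect_time_h={spec.spect_time_h} not covered by acquisition "
            f"times {times} (± 12 h)")
    rng = np.random.default_rng(spec.seed)
    inj_MBq = spec.injected_activity_GBq * 1000.0
    lam_phys = decay_constant(spec.nuclide)
    C = spec.calibration_cps_per_MBq

    planar_rows = []
    for r in spec.regions:
        T = math.exp(-2.0 * spec.mu_per_cm * r.depth_cm)
        n_px = _region_pixels(r)
        for t in times:
            a_MBq = spec.true_percent_ia(r.region_id, t) / 100.0 * inj_MBq
            primary = C * a_MBq * math.sqrt(T)
            scatter_window = spec.scatter_fraction * primary
            bg_px = (C * (spec.background_percentIA / 100.0) * inj_MBq
                     * math.exp(-lam_phys * t) / _BODY_PIXELS)
            peak = (primary
                    + spec.dew_k * spec.window_width_ratio * scatter_window
                    + bg_px * n_px)
            if spec.poisson_noise:
                ant = float(rng.poisson(peak))
                post = float(rng.poisson(peak))
                ant_sc = float(rng.poisson(scatter_window))
                post_sc = float(rng.poisson(scatter_window))
            else:
                ant = post = peak
                ant_sc = post_sc = scatter_window
            planar_rows.append((r.region_id, t, ant, post, ant_sc, post_sc,
                                T, bg_px, n_px, spec.window_width_ratio))
    planar = pd.DataFrame(planar_rows, columns=[
        "region", "time_h", "ant_counts", "post_counts", "ant_scatter",
        "post_scatter", "transmission", "bg_per_pixel", "n_pixels",
        "window_width_ratio"])

    spect_rows = []
    for r in spec.regions:
        a_true = spec.true_percent_ia(r.region_id, spec.spect_time_h) / 100.0 * inj_MBq
        measured = a_true * spec.recovery(r.volume_mL)
        if spec.spect_noise_sd > 0:
            measured += rng.normal(0.0, spec.spect_noise_sd * a_true)
        spect_rows.append((r.region_id, spec.spect_time_h,
                           max(0.0, measured), r.volume_mL))
    spect = pd.DataFrame(spect_rows, columns=[
        "region", "time_h", "activity_MBq", "volume_mL"])

    return PhantomDataset(planar=planar, spect=spect, truth=spec)


def true_dose(spec: PhantomSpec, region_id: str) -> DoseResult:
    """Closed-form ground-truth dose (Gy/GBq) for a phantom region.

    TIAC = (A0/100)/(λ_bio + λ_phys) hours, pushed through the same
    self-dose model as the dose engine.
    """
    r = spec.region(region_id)
    lam = spec.lambda_eff(region_id)
    if lam <= 0:
        raise ValueError("lambda_bio + lambda_phys must be > 0")
    tiac_h = (r.A0_percentIA / 100.0) / lam
    region = RegionSpec(region_id=region_id, mass_g=r.mass_g,
                        model="sphere", density_g_per_mL=r.density_g_per_mL)
    return self_dose(tiac_h, region, spec.nuclide)


def default_phantom_spec(nuclide: str | Nuclide = "Tb161", *, seed: int,
                         **overrides) -> PhantomSpec:
    """A realistic six-region phantom on the scale of a PSMA-617 patient.

    Uptake fractions and effective washout rates sit at typical cohort
    values (kidneys ~2.6 %IA, λ_eff ~0.021 h⁻¹; liver ~3.7 %IA; salivary
    glands ~0.5 %IA; one 10-mL lesion with ~46 h effective half-life).
    """
    nuc = load_nuclide(nuclide) if isinstance(nuclide, str) else nuclide
    lam_phys = decay_constant(nuc)

    def bio(lambda_eff: float) -> float:
        return max(0.0, lambda_eff - lam_phys)

    regions = (
        PhantomRegion("kidneys", 2.64, bio(0.021), 310.0, 4.0, 8.0),
        PhantomRegion("liver", 3.72, bio(0.022), 1800.0, 12.0, 10.0),
        PhantomRegion("parotid", 0.53, bio(0.026), 25.0, 2.5, 4.0),
        PhantomRegion("submandibular", 0.41, bio(0.027), 12.5, 2.0, 4.0),
        PhantomRegion("lesion_1", 1.00, bio(math.log(2.0) / 46.1), 10.0, 2.0, 6.0),
    )
    return PhantomSpec(nuclide=nuc, regions=regions, seed=seed, **overrides)


def paint_planar_image(spec: PhantomSpec, time_h: float,
                       shape: tuple[int, int] = (256, 1024)
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Optional 2D mode: paint regions as rectangles on a planar matrix.

    Returns the anterior expected-count image (no noise) and a boundary
    mask per region, giving the threshold-segmentation operator a surface
    to run on.  Pixel size is nominally 4.66 mm.
    """
    img = np.zeros(shape)
    masks: dict[str, np.ndarray] = {}
    inj_MBq = spec.injected_activity_GBq * 1000.0
    n = len(spec.regions)
    for i, r in enumerate(spec.regions):
        n_px = _region_pixels(r)
        h = max(3, int(math.sqrt(n_px / 2)))
        w = max(3, n_px // h)
        r0 = (i + 1) * shape[0] // (n + 2)
        c0 = (i + 1) * shape[1] // (n + 2)
        a_MBq = spec.true_percent_ia(r.region_id, time_h) / 100.0 * inj_MBq
        T = math.exp(-2.0 * spec.mu_per_cm * r.depth_cm)
        density = spec.calibration_cps_per_MBq * a_MBq * math.sqrt(T) / (h * w)
        img[r0:r0 + h, c0:c0 + w] += density
        mask = np.zeros(shape, dtype=bool)
        mask[max(0, r0 - 2):r0 + h + 2, max(0, c0 - 2):c0 + w + 2] = True
        masks[r.region_id] = mask
    img += (spec.calibration_cps_per_MBq * spec.background_percentIA / 100.0
            * inj_MBq * math.exp(-decay_constant(spec.nuclide) * time_h)
            / _BODY_PIXELS)
    return img, masks


def write_dataset(dataset: PhantomDataset, outdir: str | Path) -> None:
    """Write planar.csv / spect.csv / truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.planar.to_csv(outdir / "planar.csv", index=False)
    dataset.spect.to_csv(outdir / "spect.csv", index=False)
    truth = asdict(dataset.truth)
    truth["nuclide"] = dataset.truth.nuclide.name
    truth["recovery"] = {"v50_mL": dataset.truth.recovery.v50_mL,
                         "points": dataset.truth.recovery.points}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_dataset(indir: str | Path) -> PhantomDataset:
    """Read a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    planar = pd.read_csv(indir / "planar.csv", comment="#")
    spect = pd.read_csv(indir / "spect.csv", comment="#")
    truth = json.loads((indir / "truth.json").read_text())
    rc = truth.pop("recovery")
    recovery = (RecoveryCurve.parametric(rc["v50_mL"]) if rc["v50_mL"] is not None
                else RecoveryCurve.from_table(rc["points"]))
    regions = tuple(PhantomRegion(**r) for r in truth.pop("regions"))
    nuclide = load_nuclide(truth.pop("nuclide"))
    spec = PhantomSpec(nuclide=nuclide, regions=regions, recovery=recovery,
                       **{k: tuple(v) if isinstance(v, list) else v
                          for k, v in truth.items()})
    return PhantomDataset(planar=planar, spect=spect, truth=spec)
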