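"""Time-activity curves, hybrid rescaling, monoexponential fits and TIACs.

Serial planar activities form a region's time-activity curve (TAC) in
percent injected activity.  A single quantitative SPECT point rescales
the planar curve (hybrid method): the planar monoexponential fit is
evaluated at the SPECT time and all samples are multiplied by
SPECT / planar-prediction.  The (rescaled) TAC is then fitted by
weighted least squares to A(t) = A0·exp(−λ_eff·t) and integrated
analytically to the time-integrated activity coefficient

    TIAC (h) = (A0 / 100) / λ_eff,

the total number of decays in the region per unit administered activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .nuclides import Nuclide, decay_constant
from .warn import LAMBDA_BELOW_PHYSICAL, NON_DECAYING, warn_code

__all__ = [
    "TimeActivityCurve",
    "FitResult",
    "TIACRecord",
    "rescale_tac",
    "fit_monoexp",
    "effective_half_life",
    "tiac",
]

WEIGHTINGS = ("uniform", "inverse_activity", "sigma")


@dataclass
class TimeActivityCurve:
    """Sampled activity (percent injected) of one region over time."""

    region_id: str
    times_h: tuple[float, ...]
    percent_ia: tuple[float, ...]
    provenance: str = "planar"  # planar | rescaled

    def __post_init__(self) -> None:
        self.times_h = tuple(float(t) for t in self.times_h)
        self.percent_ia = tuple(float(a) for a in self.percent_ia)
        if len(self.times_h) != len(self.percent_ia):
            raise ValueError("times and activities differ in length")
        if len(self.times_h) < 2:
            raise ValueError("need at least 2 samples")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("times must be strictly increasing")
        if any(a < 0 for a in self.percent_ia):
            raise ValueError("percent_ia must be >= 0")


@dataclass
class FitResult:
    """Monoexponential fit A(t) = A0·exp(−λ t) of a region TAC."""

    region_id: str
    A0_percentIA: float
    lambda_eff_per_h: float
    weights_used: str
    sse: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def predict(self, time_h: float) -> float:
        return self.A0_percentIA * math.exp(-self.lambda_eff_per_h * time_h)


@dataclass
class TIACRecord:
    """Time-integrated activity coefficient of a region, in hours."""

    region_id: str
    tiac_h: float


def _loglinear_init(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Unweighted log-linear regression; returns (A0, lambda)."""
    slope, intercept = np.polyfit(t, np.log(a), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_monoexp(tac: TimeActivityCurve, weighting: str = "inverse_activity",
                sigma=None, nuclide: Nuclide | None = None) -> FitResult:
    """Weighted least-squares monoexponential fit of a TAC.

    Minimises Σ wᵢ (Aᵢ − A0·e^{−λtᵢ})² over A0 > 0, λ > 0 with weights

    * ``uniform``: wᵢ = 1
    * ``inverse_activity`` (default): wᵢ = 1/Aᵢ, the Poisson-like choice
      for count-derived activities
    * ``sigma``: wᵢ = 1/σᵢ² from caller-supplied ``sigma``

    Initialisation is the unweighted log-linear regression.  Data whose
    log-linear slope is non-negative are flagged ``NON_DECAYING`` (the fit
    is still returned, λ clamped to a tiny positive value).  If a
    ``nuclide`` is given, a fitted λ below its physical decay constant
    raises a ``LAMBDA_BELOW_PHYSICAL`` data-quality warning (implies
    biological accumulation), not an error.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    t = np.asarray(tac.times_h, dtype=float)
    a = np.asarray(tac.percent_ia, dtype=float)
    pos = a > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 samples with positive activity")
    t, a = t[pos], a[pos]

    if weighting == "uniform":
        w = np.ones_like(a)
    elif weighting == "inverse_activity":
        w = 1.0 / a
    else:
        if sigma is None:
            raise ValueError("weighting='sigma' requires sigma values")
        sig = np.asarray(sigma, dtype=float)[pos]
        if np.any(sig <= 0):
            raise ValueError("sigma values must be > 0")
        w = 1.0 / sig**2
    sqw = np.sqrt(w)

    flags: list[str] = []
    A0_init, lam_init = _loglinear_init(t, a)
    if lam_init <= 0:
        flags.append(NON_DECAYING)
        warn_code(NON_DECAYING,
                  f"region {tac.region_id}: log-linear slope >= 0; "
                  "activity does not decay over the sampled times")
        lam_init = 1e-6

    def residuals(p):
        A0, lam = p
        return sqw * (a - A0 * np.exp(-lam * t))

    sol = least_squares(residuals, x0=[A0_init, lam_init],
                        bounds=([1e-300, 1e-12], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    A0, lam = float(sol.x[0]), float(sol.x[1])
    sse = float(np.sum(sol.fun**2))

    if nuclide is not None and lam < decay_constant(nuclide):
        flags.append(LAMBDA_BELOW_PHYSICAL)
        warn_code(LAMBDA_BELOW_PHYSICAL,
                  f"region {tac.region_id}: fitted λ={lam:.4g} h⁻¹ below "
                  f"physical λ={decay_constant(nuclide):.4g} h⁻¹ "
                  "(implies biological accumulation)")
    return FitResult(region_id=tac.region_id, A0_percentIA=A0,
                     lambda_eff_per_h=lam, weights_used=weighting, sse=sse,
                     warnings=tuple(flags))


def rescale_tac(planar: TimeActivityCurve, spect_point: tuple[float, float],
                weighting: str = "inverse_activity") -> TimeActivityCurve:
    """Rescale a planar TAC so it passes through the SPECT estimate.

    ``spect_point`` is (time_h, percent_IA).  The planar monoexponential
    fit is evaluated at the SPECT time; every planar sample is multiplied
    by SPECT / prediction.  The SPECT time must lie within the planar
    sampling window ± 12 h.
    """
    t_s, a_s = spect_point
    if not (planar.times_h[0] - 12.0 <= t_s <= planar.times_h[-1] + 12.0):
        raise ValueError(
            f"SPECT time {t_s} h outside planar window "
            f"[{planar.times_h[0]}, {planar.times_h[-1]}] ± 12 h")
    fit = fit_monoexp(planar, weighting=weighting)
    predicted = fit.predict(t_s)
    if predicted <= 0:
        raise ValueError("planar fit predicts non-positive activity at SPECT time")
    s = a_s / predicted
    return TimeActivityCurve(
        region_id=planar.region_id,
        times_h=planar.times_h,
        percent_ia=tuple(a * s for a in planar.percent_ia),
        provenance="rescaled",
    )


def effective_half_life(fit: FitResult) -> float:
    """Effective half-life ln2/λ_eff in hours."""
    if fit.lambda_eff_per_h <= 0:
        raise ValueError("lambda must be > 0")
    return math.log(2.0) / fit.lambda_eff_per_h


def tiac(fit: FitResult, t_start: float = 0.0) -> TIACRecord:
    """Analytic time-integrated activity coefficient from ``t_start`` to ∞.

    TIAC (h) = (A0/100)·e^{−λ·t_start}/λ — the closed-form integral of the
    fitted monoexponential per unit administered activity.
    """
    if fit.lambda_eff_per_h <= 0:
        raise ValueError("lambda must be > 0: curve is not integrable")
    value = (fit.A0_percentIA / 100.0) * math.exp(
        -fit.lambda_eff_per_h * t_start) / fit.lambda_eff_per_h
    return TIACRecord(region_id=fit.region_id, tiac_h=value)
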