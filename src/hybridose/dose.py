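"""Sphere-model absorbed dose per administered activity.

Self-dose of a unit-density region from its time-integrated activity
coefficient (TIAC, hours).  Electrons (mean beta plus any configured
conversion/Auger energy) are assumed locally absorbed (φ_e = 1); photons
are absorbed with the mean-chord fraction

    φ_p(m, E) = 1 − exp(−μ_en(E) · l̄),   l̄ = (4/3)·r,

where r is the radius of a sphere of mass m and μ_en the linear
energy-absorption coefficient of water at the line energy.  Cross-organ
photon dose is neglected.  This is a deliberately transparent self-dose
model, not a reimplementation of reference S-value libraries: absolute
organ doses carry the approximation, while ratios and indices downstream
are largely insensitive to it.

The result unit Gy/GBq is numerically identical to mGy/MBq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .kinetics import TIACRecord
from .nuclides import Nuclide

__all__ = [
    "RegionSpec",
    "DoseResult",
    "photon_absorbed_fraction",
    "self_dose",
    "sphere_region",
    "reference_organ_masses",
    "KEV_TO_J",
]

#: exact SI: 1 keV in joules (1e3 × elementary charge)
KEV_TO_J = 1.602176634e-16
_S_PER_H = 3600.0
_BQ_PER_GBQ = 1e9


@dataclass
class RegionSpec:
    """Target region for self-dose: a unit-density sphere or a reference organ."""

    region_id: str
    mass_g: float
    model: str = "sphere"  # sphere | reference_organ
    density_g_per_mL: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.density_g_per_mL <= 0:
            raise ValueError("density must be > 0")
        if self.model not in ("sphere", "reference_organ"):
            raise ValueError("model must be 'sphere' or 'reference_organ'")


@dataclass
class DoseResult:
    """Absorbed dose per administered activity, Gy/GBq (= mGy/MBq)."""

    region_id: str
    nuclide: str
    dose_Gy_per_GBq: float
    electron_component: float
    photon_component: float


def sphere_region(region_id: str, volume_mL: float,
                  density_g_per_mL: float = 1.0) -> RegionSpec:
    """Sphere region from a segmented volume (mass = volume × density)."""
    return RegionSpec(region_id=region_id, mass_g=volume_mL * density_g_per_mL,
                      model="sphere", density_g_per_mL=density_g_per_mL)


def reference_organ_masses() -> dict[str, float]:
    """Default reference-adult organ masses (g) from the packaged table."""
    text = resources.files("hybridose.data").joinpath("organ_masses.csv").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    out = {}
    for ln in rows[1:]:
        region, mass, _model = ln.split(",")
        out[region] = float(mass)
    return out


def _mu_en_table() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("hybridose.data").joinpath("mu_en_water.csv").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    data = np.array([[float(x) for x in ln.split(",")] for ln in rows[1:]])
    return data[:, 0], data[:, 1]


_MU_EN_E, _MU_EN_V = _mu_en_table()


def mu_en_per_cm(energy_keV: float, density_g_per_mL: float = 1.0) -> float:
    """Linear energy-absorption coefficient (cm⁻¹) of water-equivalent tissue.

    Log-log interpolation of the packaged μ_en/ρ table; energies outside
    20-2000 keV raise.
    """
    if not _MU_EN_E[0] <= energy_keV <= _MU_EN_E[-1]:
        raise ValueError(
            f"energy {energy_keV} keV outside table range "
            f"[{_MU_EN_E[0]:.0f}, {_MU_EN_E[-1]:.0f}] keV")
    val = np.exp(np.interp(np.log(energy_keV), np.log(_MU_EN_E), np.log(_MU_EN_V)))
    return float(val) * density_g_per_mL


def photon_absorbed_fraction(mass_g: float, energy_keV: float,
                             density_g_per_mL: float = 1.0) -> float:
    """Mean-chord photon absorbed fraction for a sphere of given mass."""
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    mu = mu_en_per_cm(energy_keV, density_g_per_mL)
    radius_cm = (3.0 * mass_g / (4.0 * math.pi * density_g_per_mL)) ** (1.0 / 3.0)
    mean_chord_cm = (4.0 / 3.0) * radius_cm
    return 1.0 - math.exp(-mu * mean_chord_cm)


def self_dose(tiac: TIACRecord | float, region: RegionSpec,
              nuclide: Nuclide) -> DoseResult:
    """Self-dose (Gy/GBq) of a region from its TIAC.

    electron component: TIAC·3600·E_e·q/m with φ_e = 1;
    photon component: TIAC·3600·Σ_lines E_γ·yield·q·φ_p(m, E_γ)/m;
    q converts keV to joules, m is the region mass in kg, and the per-Bq
    dose is scaled by 1e9 to Gy per administered GBq.
    """
    tiac_h = tiac.tiac_h if isinstance(tiac, TIACRecord) else float(tiac)
    if tiac_h < 0:
        raise ValueError("tiac must be >= 0")
    mass_kg = region.mass_g / 1000.0
    decays_per_GBq = tiac_h * _S_PER_H * _BQ_PER_GBQ

    electron = decays_per_GBq * nuclide.electron_keV * KEV_TO_J / mass_kg
    photon = 0.0
    for energy, yield_ in nuclide.photon_lines:
        phi = photon_absorbed_fraction(region.mass_g, energy,
                                       region.density_g_per_mL)
        photon += decays_per_GBq * energy * yield_ * KEV_TO_J * phi / mass_kg

    return DoseResult(
        region_id=region.region_id,
        nuclide=nuclide.name,
        dose_Gy_per_GBq=electron + photon,
        electron_component=electron,
        photon_component=photon,
    )
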