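"""Physical decay data for therapy radionuclides.

The packaged table ships the two beta-emitters relevant to PSMA-617
radioligand therapy, ``Tb161`` and ``Lu177``.  Besides a similar mean
beta energy (154 vs 133 keV) and half-life (6.906 vs 6.647 d), Tb-161
additionally emits short-range conversion/Auger electrons; their summed
per-decay energy is carried in ``extra_electron_keV`` and defaults to 0
in the packaged table so that only the tabulated beta and gamma data
drive the dose model.  Users may override it from ICRP-107-style decay
tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Nuclide", "load_nuclide", "available_nuclides", "decay_constant"]

#: photon lines below this energy are dropped by default: at organ scale
#: they are absorbed locally and indistinguishable from the electron dose.
DEFAULT_PHOTON_CUTOFF_KEV = 20.0


@dataclass(frozen=True)
class Nuclide:
    """Decay data needed by the self-dose model.

    Parameters
    ----------
    name
        Identifier, e.g. ``"Tb161"``.
    half_life_h
        Physical half-life in hours (> 0).
    mean_beta_keV
        Mean beta-minus energy emitted per decay, keV.
    extra_electron_keV
        Conversion + Auger electron energy per decay, keV.
    photon_lines
        Principal gamma lines as ``(energy_keV, yield_per_decay)`` pairs,
        yields in (0, 1].
    """

    name: str
    half_life_h: float
    mean_beta_keV: float = 0.0
    extra_electron_keV: float = 0.0
    photon_lines: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be > 0, got {self.half_life_h}")
        if self.mean_beta_keV < 0 or self.extra_electron_keV < 0:
            raise ValueError("electron energies must be >= 0")
        for energy, yield_ in self.photon_lines:
            if energy < 0:
                raise ValueError(f"photon energy must be >= 0, got {energy}")
            if not 0 < yield_ <= 1:
                raise ValueError(f"photon yield must be in (0, 1], got {yield_}")

    @property
    def electron_keV(self) -> float:
        """Total locally deposited electron energy per decay (keV)."""
        return self.mean_beta_keV + self.extra_electron_keV


def _read_table() -> dict[str, dict[str, str]]:
    text = resources.files("hybridose.data").joinpath("nuclides.csv").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    table = {}
    for row in csv.DictReader(rows):
        table[row["name"]] = row
    return table


def available_nuclides() -> list[str]:
    """Names present in the packaged decay-data table."""
    return sorted(_read_table())


def load_nuclide(
    name: str, *, photon_cutoff_keV: float = DEFAULT_PHOTON_CUTOFF_KEV
) -> Nuclide:
    """Load a nuclide from the packaged table.

    Photon lines below ``photon_cutoff_keV`` are dropped (negligible
    escape from organ-sized volumes); pass 0 to keep all lines.

    Raises
    ------
    KeyError
        If ``name`` is not in the table; the message lists the
        available nuclides.
    """
    table = _read_table()
    if name not in table:
        raise KeyError(
            f"unknown nuclide {name!r}; available: {', '.join(sorted(table))}"
        )
    row = table[name]
    lines = []
    for part in row["photon_lines"].split(";"):
        if not part.strip():
            continue
        energy, yield_ = part.split(":")
        if float(energy) >= photon_cutoff_keV:
            lines.append((float(energy), float(yield_)))
    return Nuclide(
        name=row["name"],
        half_life_h=float(row["half_life_h"]),
        mean_beta_keV=float(row["mean_beta_keV"]),
        extra_electron_keV=float(row["extra_electron_keV"]),
        photon_lines=tuple(lines),
    )


def decay_constant(nuclide: Nuclide) -> float:
    """Physical decay constant λ_phys = ln2 / T½, in h⁻¹."""
    return math.log(2.0) / nuclide.half_life_h
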