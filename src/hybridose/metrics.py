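"""Cohort statistics, therapeutic indices and biochemical response.

Summarises per-patient absorbed doses (Gy/GBq) across a cohort,
compares two radionuclides via the ratio of cohort means, computes the
therapeutic index

    TI = mean tumor dose / organ-at-risk dose

per patient and organ, the relative therapeutic index rTI = TI(Tb-161) /
TI(Lu-177) (rTI > 1 favours the Tb-161 energy deposition pattern), and
classifies PSA changes by the PCWG3 rule: progressive disease (PD) for
an increase > 25%, partial remission (PR) for a decrease > 50%, stable
disease (SD) otherwise — strict inequalities.

Cohort "mean ± SD" uses the population (denominator-n) standard
deviation: that is the convention the packaged six-patient dose table
was summarised with, and the sample (n−1) convention does not reproduce
its printed SD cells.

A six-patient reference dose table and the matching PSA changes ship as
packaged fixtures (``load_cohort_doses`` / ``load_psa_changes``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "TIResult",
    "cohort_summary",
    "dose_ratio",
    "therapeutic_index",
    "relative_ti",
    "pcwg3_classify",
    "classify_cohort",
    "load_cohort_doses",
    "load_psa_changes",
    "summarize_cohort_table",
    "internuclide_ratios",
    "ti_table",
    "round_half_away",
]


@dataclass
class TIResult:
    """Therapeutic index of one patient/organ, and the Tb/Lu ratio of TIs."""

    patient_id: str
    organ_id: str
    mean_tumor_dose_Gy_per_GBq: float
    organ_dose_Gy_per_GBq: float
    ti: float
    rti: float | None = None


def cohort_summary(values) -> tuple[float, float]:
    """Arithmetic mean and population SD (denominator n) of doses."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=0))


def dose_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two cohort mean doses."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be > 0")
    return mean_a / mean_b


def therapeutic_index(mean_tumor_dose: float, organ_dose: float) -> float:
    """TI = mean tumor dose over organ-at-risk dose (same units)."""
    if organ_dose <= 0:
        raise ValueError("organ dose must be > 0")
    return mean_tumor_dose / organ_dose


def relative_ti(ti_tb: float, ti_lu: float) -> float:
    """rTI = TI(Tb-161) / TI(Lu-177)."""
    if ti_lu <= 0:
        raise ValueError("denominator TI must be > 0")
    return ti_tb / ti_lu


def pcwg3_classify(psa_change_percent: float) -> str:
    """PCWG3 biochemical response class from a relative PSA change (%).

    PD if change > +25, PR if change < −50, SD otherwise (strict
    inequalities; a decrease is a negative change).
    """
    if not math.isfinite(psa_change_percent):
        raise ValueError("PSA change must be finite")
    if psa_change_percent > 25.0:
        return "PD"
    if psa_change_percent < -50.0:
        return "PR"
    return "SD"


def classify_cohort(psa_changes: pd.DataFrame) -> pd.DataFrame:
    """Attach a PCWG3 category column to a psa_change_percent table."""
    out = psa_changes.copy()
    out["category"] = out["psa_change_percent"].map(pcwg3_classify)
    return out


def _read_fixture(name: str) -> pd.DataFrame:
    text = resources.files("hybridose.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), comment="#")


def load_cohort_doses() -> pd.DataFrame:
    """Packaged six-patient organ dose table (Gy/GBq, both nuclides)."""
    return _read_fixture("cohort_doses.csv")


def load_psa_changes() -> pd.DataFrame:
    """Packaged per-patient relative PSA changes (%) after one Tb-161 cycle."""
    return _read_fixture("psa_changes.csv")


def summarize_cohort_table(doses: pd.DataFrame) -> pd.DataFrame:
    """Mean and population SD per region and nuclide.

    ``doses`` needs columns patient_id, region_id, nuclide,
    dose_Gy_per_GBq; both-nuclide completeness per patient/region is
    required so comparisons stay paired.
    """
    _check_paired(doses)
    rows = []
    for (region, nuclide), grp in doses.groupby(["region_id", "nuclide"],
                                                sort=True):
        mean, sd = cohort_summary(grp["dose_Gy_per_GBq"])
        rows.append((region, nuclide, len(grp), mean, sd))
    return pd.DataFrame(rows, columns=["region_id", "nuclide", "n",
                                       "mean_Gy_per_GBq", "sd_Gy_per_GBq"])


def internuclide_ratios(doses: pd.DataFrame, nuclide_a: str = "Tb161",
                        nuclide_b: str = "Lu177") -> pd.DataFrame:
    """Per-region ratio of cohort mean doses, nuclide_a over nuclide_b."""
    summary = summarize_cohort_table(doses)
    rows = []
    for region, grp in summary.groupby("region_id", sort=True):
        by_nuc = grp.set_index("nuclide")["mean_Gy_per_GBq"]
        rows.append((region, dose_ratio(by_nuc[nuclide_a], by_nuc[nuclide_b])))
    return pd.DataFrame(rows, columns=["region_id", "mean_dose_ratio"])


def _check_paired(doses: pd.DataFrame) -> None:
    required = {"patient_id", "region_id", "nuclide", "dose_Gy_per_GBq"}
    missing = required - set(doses.columns)
    if missing:
        raise ValueError(f"dose table lacks columns: {sorted(missing)}")
    if (doses["dose_Gy_per_GBq"] <= 0).any():
        raise ValueError("doses must be > 0")
    counts = doses.groupby(["patient_id", "region_id"])["nuclide"].nunique()
    nuclides = doses["nuclide"].nunique()
    if nuclides > 1 and (counts < nuclides).any():
        bad = counts[counts < nuclides].index.tolist()
        raise ValueError(f"unpaired patient/region keys: {bad}")


def ti_table(organ_doses: pd.DataFrame, tumor_doses: pd.DataFrame,
             nuclide_a: str = "Tb161", nuclide_b: str = "Lu177") -> pd.DataFrame:
    """Per-patient TI for each organ and nuclide, with rTI (a over b).

    ``tumor_doses`` has columns patient_id, nuclide, dose_Gy_per_GBq (one
    row per analyzed lesion); the per-patient mean tumor dose is the
    unweighted mean over that patient's lesions.
    """
    _check_paired(organ_doses)
    mean_tumor = (tumor_doses.groupby(["patient_id", "nuclide"])
                  ["dose_Gy_per_GBq"].mean())
    rows = []
    for (patient, region), grp in organ_doses.groupby(
            ["patient_id", "region_id"], sort=True):
        by_nuc = grp.set_index("nuclide")["dose_Gy_per_GBq"]
        tis = {}
        for nuc in (nuclide_a, nuclide_b):
            if nuc not in by_nuc.index or (patient, nuc) not in mean_tumor.index:
                raise ValueError(
                    f"missing {nuc} dose for patient/region ({patient}, {region})")
            tis[nuc] = therapeutic_index(mean_tumor[(patient, nuc)], by_nuc[nuc])
        rti = relative_ti(tis[nuclide_a], tis[nuclide_b])
        rows.append((patient, region,
                     mean_tumor[(patient, nuclide_a)], by_nuc[nuclide_a],
                     tis[nuclide_a], tis[nuclide_b], rti))
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", f"mean_tumor_dose_{nuclide_a}",
        f"organ_dose_{nuclide_a}", f"ti_{nuclide_a}", f"ti_{nuclide_b}", "rti"])


def round_half_away(x: float, decimals: int) -> float:
    """Presentation rounding, half away from zero (3 d.p. doses, 2 d.p. ratios)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
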