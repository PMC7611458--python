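"""Water-referenced absolute quantification with T2 and CSF corrections.

The fitted metabolite amplitude is converted to mmol/L against the
unsuppressed-water reference from the same voxel:

    conc = A_met * (C_water * f_tissue_water) / (A_tissue * exp(-TE / T2_tissue))

where C_water = 55510 mmol/L is pure water, f_tissue_water the tissue water
content (0.70 for white matter), A_tissue the tissue-water amplitude
extrapolated to TE = 0 from the biexponential fit, and the exponential
undoes the tissue-water T2 decay at the metabolite echo time.  Referencing
to A_tissue rather than the total water amplitude is what excludes the CSF
compartment (the CSF partial-volume correction).  Metabolite T2 attenuation
is deliberately not corrected (metabolite T2s are not measured at short
TE), and T1 saturation is neglected at TR = 5 s; both are uniform scale
factors across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .waterfit import WaterT2Results

#: Composite measures and their components.
DERIVED_SUMS = {
    "tNAA": ("NAA", "NAAG"),
    "tCr": ("Cr", "PCr"),
    "tCho": ("GPC", "PCho"),
    "Glx": ("Gln", "Glu"),
}


class QuantificationError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants and assumptions of the water-reference scaling."""

    pure_water_conc_mmol_L: float = 55510.0
    water_protons: int = 2
    tissue_water_content: float = 0.70  # white-matter literature value
    te_ms: float = 11.0
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tissue_water_content <= 1.0:
            raise ValueError("tissue_water_content must be in (0, 1]")


def absolute_concentration(
    amplitude: float, water: WaterT2Results, k: QuantConstants | None = None
) -> float:
    """Absolute concentration (mmol/L) of one fitted metabolite amplitude."""
    k = k or QuantConstants()
    if amplitude < 0:
        raise QuantificationError("amplitude must be non-negative")
    if not water.converged:
        raise QuantificationError("water fit did not converge")
    if water.t2_tissue_ms <= 0:
        raise QuantificationError("non-positive tissue-water T2")
    if water.a_tissue <= 0:
        raise QuantificationError("zero tissue-water amplitude")
    t2_decay = np.exp(-k.te_ms / water.t2_tissue_ms)
    return float(
        amplitude
        * k.pure_water_conc_mmol_L
        * k.tissue_water_content
        / (water.a_tissue * t2_decay)
        * k.calibration
    )


def signal_scale(water: WaterT2Results, k: QuantConstants | None = None) -> float:
    """Factor mapping true mmol/L to fitted-amplitude units for a voxel.

    This is the inverse of the ``absolute_concentration`` scaling; the
    synthetic cohort generator uses it so that simulated spectra and water
    series share a consistent unit system.
    """
    k = k or QuantConstants()
    return (
        water.a_tissue
        * np.exp(-k.te_ms / water.t2_tissue_ms)
        / (k.pure_water_conc_mmol_L * k.tissue_water_content * k.calibration)
    )


def derived_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Append composite rows (tNAA, tCr, tCho, Glx) per subject and site.

    ``table`` must have columns subject_id, group, site, metabolite,
    conc_mmol_L (crlb_pct and retained are carried if present).  A composite
    is added only where both components are present; missing components
    leave the sum out rather than imputing.  Additivity is exact.
    """
    required = {"subject_id", "group", "site", "metabolite", "conc_mmol_L"}
    if table.empty:
        return table.copy()
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    dup = table.duplicated(subset=["subject_id", "site", "metabolite"])
    if dup.any():
        raise ValueError("(subject, site, metabolite) rows must be unique")
    new_rows = []
    for (subj, grp, site), sub in table.groupby(["subject_id", "group", "site"]):
        present = dict(zip(sub["metabolite"], sub["conc_mmol_L"]))
        retained = (
            dict(zip(sub["metabolite"], sub["retained"]))
            if "retained" in sub.columns
            else {}
        )
        for name, (a, b) in DERIVED_SUMS.items():
            if a in present and b in present and name not in present:
                row = {
                    "subject_id": subj,
                    "group": grp,
                    "site": site,
                    "metabolite": name,
                    "conc_mmol_L": present[a] + present[b],
                }
                if "crlb_pct" in sub.columns:
                    row["crlb_pct"] = np.nan  # CRLB of a sum not defined here
                if retained:
                    row["retained"] = bool(retained.get(a)) and bool(retained.get(b))
                new_rows.append(row)
    if not new_rows:
        return table.copy()
    return (
        pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
        .sort_values(["subject_id", "site", "metabolite"])
        .reset_index(drop=True)
    )


def ratio(numerator: float, denominator: float) -> float:
    """Plain concentration quotient.

    Ratios are computed per subject before any averaging (mean of ratios,
    not ratio of means).
    """
    if denominator <= 0:
        raise UndefinedRatioError("ratio denominator must be positive")
    return numerator / denominator
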