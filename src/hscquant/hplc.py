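"""Liver retinoid quantification from HPLC peak areas.

Retinoids are extracted from 40-50 mg of liver, spiked with 2.5 µg of
retinyl acetate as internal standard (IS), and quantified by UV absorbance
at 325 nm against external calibration curves.  The pipeline starts at
integrated peak areas (trace integration is out of scope):

1. fit ordinary least-squares calibration lines (area vs µg) for retinol,
   retinyl acetate and retinyl palmitate standards;
2. estimate each sample's extraction yield from the recovered IS amount;
3. invert sample peak areas through the curves, divide by the yield, and
   normalize by tissue mass to µg per g of liver.  Retinyl esters are
   quantified collectively against the retinyl palmitate curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "PeakTable",
    "RetinoidResult",
    "fit_calibration",
    "extraction_yield",
    "quantify_sample",
    "quantify_table",
    "DEFAULT_IS_SPIKE_UG",
]

#: Internal-standard spike per sample (µg retinyl acetate).
DEFAULT_IS_SPIKE_UG = 2.5
#: Analyte name of the internal standard.
IS_ANALYTE = "retinyl_acetate"
#: Yields above 1 are retained with a warning; above this they are capped.
YIELD_CAP = 1.5

ANALYTES = ("retinol", "retinyl_acetate", "retinyl_palmitate")


@dataclass
class CalibrationCurve:
    """Linear response curve, area = slope * amount_ug + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    valid_range_ug: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")

    def predict_area(self, amount_ug) -> np.ndarray:
        return self.slope * np.asarray(amount_ug, dtype=float) + self.intercept

    def invert(self, area) -> np.ndarray:
        """Amount (µg) corresponding to a peak area."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope


@dataclass
class PeakTable:
    """Integrated peak areas, long format.

    ``data`` columns: ``sample_id``, ``tissue_mass_mg``, ``analyte``
    (retinol / retinyl_acetate / retinyl_palmitate), ``area_at_325nm``,
    ``retention_time_min``.  Each sample carries exactly one internal
    standard (retinyl acetate) peak.
    """

    data: pd.DataFrame
    is_spike_ug: float = DEFAULT_IS_SPIKE_UG

    REQUIRED = ("sample_id", "tissue_mass_mg", "analyte", "area_at_325nm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if (self.data["area_at_325nm"] < 0).any():
            raise ValueError("peak areas must be non-negative")
        if (self.data["tissue_mass_mg"] <= 0).any():
            raise ValueError("tissue mass must be positive")
        if self.is_spike_ug <= 0:
            raise ValueError("is_spike_ug must be positive")
        counts = (
            self.data[self.data["analyte"] == IS_ANALYTE]
            .groupby("sample_id")
            .size()
        )
        for sid in self.data["sample_id"].unique():
            if counts.get(sid, 0) != 1:
                raise ValueError(
                    f"sample {sid!r} must have exactly one internal-standard peak"
                )

    def to_csv(self, path) -> None:
        self.data.assign(is_spike_ug=self.is_spike_ug).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        df = pd.read_csv(path)
        spike = DEFAULT_IS_SPIKE_UG
        if "is_spike_ug" in df.columns:
            spike = float(df["is_spike_ug"].iloc[0])
            df = df.drop(columns=["is_spike_ug"])
        return cls(df, is_spike_ug=spike)


@dataclass
class RetinoidResult:
    """Yield-corrected per-gram retinoid content.

    ``data`` columns: ``sample_id``, ``retinol_ug_per_g``,
    ``retinyl_esters_ug_per_g``, ``extraction_yield``, ``warnings``.
    """

    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def fit_calibration(
    standards, analyte: str = "", through_origin: bool = False
) -> CalibrationCurve:
    """Fit a calibration line to (amount_ug, area) standard pairs.

    Ordinary least squares with a free intercept by default; pass
    ``through_origin=True`` to force a zero intercept.  Requires at least 3
    standards at distinct amounts.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (amount_ug, area) standards")
    amounts, areas = arr[:, 0], arr[:, 1]
    if np.unique(amounts).size < 2:
        raise ValueError("degenerate design: all standard amounts equal")
    if through_origin:
        slope = float(amounts @ areas / (amounts @ amounts))
        intercept = 0.0
        ss_res = float(np.sum((areas - slope * amounts) ** 2))
        ss_tot = float(np.sum((areas - areas.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    else:
        fit = stats.linregress(amounts, areas)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        valid_range_ug=(float(amounts.min()), float(amounts.max())),
    )


def extraction_yield(
    is_area: float,
    is_curve: CalibrationCurve,
    is_spike_ug: float = DEFAULT_IS_SPIKE_UG,
) -> float:
    """Per-sample extraction yield from the recovered internal standard.

    yield = (IS amount inverted through the retinyl acetate curve) / spike.
    Yields above 1 are physically impossible but tolerated with a warning
    (calibration noise); above ``YIELD_CAP`` they are capped.
    """
    if is_spike_ug <= 0:
        raise ValueError("is_spike_ug must be positive")
    recovered = float(is_curve.invert(is_area))
    if recovered <= 0:
        raise ValueError(
            "internal-standard peak inverts to a non-positive amount"
        )
    y = recovered / is_spike_ug
    if y > 1:
        warnings.warn(
            f"extraction yield {y:.3f} exceeds 1; check calibration",
            stacklevel=2,
        )
    return min(y, YIELD_CAP)


def quantify_sample(
    sample_peaks: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    is_spike_ug: float = DEFAULT_IS_SPIKE_UG,
) -> dict:
    """Quantify one sample's retinol and retinyl esters (µg per g liver).

    ``sample_peaks``: this sample's rows of a :class:`PeakTable`.  Retinol
    inverts through the retinol curve, retinyl esters through the retinyl
    palmitate curve; both are divided by the IS-derived extraction yield and
    by the tissue mass in grams.
    """
    for name in ANALYTES:
        if name not in curves:
            raise ValueError(f"missing calibration curve for {name}")
    is_rows = sample_peaks[sample_peaks["analyte"] == IS_ANALYTE]
    if len(is_rows) != 1:
        raise ValueError("sample must have exactly one internal-standard peak")
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        y = extraction_yield(
            float(is_rows["area_at_325nm"].iloc[0]),
            curves[IS_ANALYTE],
            is_spike_ug,
        )
        notes.extend(str(w.message) for w in caught)

    mass_g = float(sample_peaks["tissue_mass_mg"].iloc[0]) / 1000.0

    def per_g(analyte: str, curve_name: str) -> float:
        rows = sample_peaks[sample_peaks["analyte"] == analyte]
        if rows.empty:
            return 0.0
        amount = float(curves[curve_name].invert(rows["area_at_325nm"].iloc[0]))
        if amount < 0:
            notes.append(f"{analyte} inverted below zero; clipped to 0")
            amount = 0.0
        return amount / y / mass_g

    return {
        "sample_id": sample_peaks["sample_id"].iloc[0],
        "retinol_ug_per_g": per_g("retinol", "retinol"),
        "retinyl_esters_ug_per_g": per_g(
            "retinyl_palmitate", "retinyl_palmitate"
        ),
        "extraction_yield": y,
        "warnings": "; ".join(notes),
    }


def quantify_table(
    peaks: PeakTable, curves: dict[str, CalibrationCurve]
) -> RetinoidResult:
    """Quantify every sample of a peak table."""
    rows = [
        quantify_sample(group, curves, peaks.is_spike_ug)
        for _, group in peaks.data.groupby("sample_id", sort=False)
    ]
    return RetinoidResult(pd.DataFrame(rows))
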