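"""Calibration-curve quantitation, LOD/LOQ evaluation and QC precision.

Tracer concentrations are read off a calibration line fitted to
analyte/internal-standard peak-area ratios against nominal spiked
concentrations (pg/ml).  The internal standard (F22 glucagon, added at
50 pg/ml to every sample) normalizes recovery and ionization, so the
area ratio is what tracks concentration.

Validation follows standard bioanalytical practice:

* LOD — the lowest level whose peaks reach S/N >= 3 and whose mean signal
  exceeds the blank mean by 3 blank SDs;
* LOQ — the lowest level meeting precision (replicate CV <= 25%) and
  accuracy (relative error of the mean <= 25%);
* QC precision — intra-day CV (pooled within-day) and inter-day CV (total
  CV across days) at the nominal QC levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IS_SPIKE_PG_ML",
    "CalibrationStandard",
    "CalibrationCurve",
    "ConcentrationEstimate",
    "LODResult",
    "LOQResult",
    "QCResult",
    "area_ratio",
    "fit_calibration",
    "inverse_predict",
    "evaluate_lod",
    "evaluate_loq",
    "qc_precision",
    "expected_infusate_conc",
    "read_area_table",
    "standards_from_table",
]

# Internal-standard spike concentration, pg/ml.
IS_SPIKE_PG_ML = 50.0

WEIGHTING_SCHEMES = ("none", "1/x", "1/x2")


@dataclass(frozen=True)
class CalibrationStandard:
    """Replicate peak areas for one calibration level of one species."""

    species: str
    nominal_pg_ml: float
    analyte_areas: tuple[float, ...]
    is_areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.nominal_pg_ml <= 0:
            raise ValueError("nominal concentration must be > 0")
        if len(self.analyte_areas) == 0:
            raise ValueError("at least one replicate is required")
        if len(self.analyte_areas) != len(self.is_areas):
            raise ValueError("analyte and IS replicate counts differ")
        if any(a <= 0 for a in self.is_areas):
            raise ValueError("internal-standard area must be > 0")

    @property
    def ratios(self) -> np.ndarray:
        return np.asarray(self.analyte_areas) / np.asarray(self.is_areas)

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted area-ratio-vs-concentration line for one species."""

    species: str
    slope: float
    intercept: float
    r: float
    weighting: str
    lod_pg_ml: float | None = None
    loq_pg_ml: float | None = None

    def predict_ratio(self, conc_pg_ml: float) -> float:
        return self.slope * conc_pg_ml + self.intercept


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Back-calculated concentration; negative values flagged, not clipped."""

    pg_ml: float
    below_zero: bool


def area_ratio(analyte_area: float, is_area: float) -> float:
    """Analyte/internal-standard peak-area ratio.

    A non-positive IS area signals failed enrichment or spiking and is an
    error rather than a zero division.
    """
    if is_area <= 0:
        raise ValueError(
            f"internal-standard area must be > 0 (got {is_area}); "
            "non-positive IS signals failed enrichment"
        )
    return analyte_area / is_area


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    weighting: str = "none",
) -> CalibrationCurve:
    """Least-squares line of mean area ratio on nominal concentration.

    ``weighting`` is one of ``none`` (OLS), ``1/x`` or ``1/x2`` (weights
    inversely proportional to concentration or its square — the usual
    choices when assay noise grows with concentration).  The correlation
    coefficient ``r`` is the unweighted Pearson correlation of the same
    (concentration, mean ratio) points.
    """
    if weighting not in WEIGHTING_SCHEMES:
        raise ValueError(f"weighting must be one of {WEIGHTING_SCHEMES}")
    if not standards:
        raise ValueError("no calibration standards supplied")
    species = standards[0].species
    conc = np.array([s.nominal_pg_ml for s in standards], dtype=float)
    ratio = np.array([s.mean_ratio for s in standards], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError(
            f"need >= 3 distinct concentration levels, got {len(np.unique(conc))}"
        )
    if np.ptp(conc) == 0:
        raise ValueError("zero variance in concentration levels")
    if weighting == "none":
        w = np.ones_like(conc)
    elif weighting == "1/x":
        w = 1.0 / conc
    else:
        w = 1.0 / conc**2
    slope, intercept = np.polyfit(conc, ratio, 1, w=np.sqrt(w))
    r = float(np.corrcoef(conc, ratio)[0, 1])
    return CalibrationCurve(
        species=species,
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        weighting=weighting,
    )


def inverse_predict(curve: CalibrationCurve, ratio: float) -> ConcentrationEstimate:
    """Back-calculate a concentration from an area ratio.

    Negative results (ratio below the fitted intercept) are returned as-is
    with ``below_zero=True`` so downstream summary statistics stay
    unbiased.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    conc = (ratio - curve.intercept) / curve.slope
    return ConcentrationEstimate(pg_ml=conc, below_zero=conc < 0)


@dataclass(frozen=True)
class LODResult:
    lod_pg_ml: float | None
    per_level: pd.DataFrame  # nominal_pg_ml, mean, min_snr, passes


def evaluate_lod(
    levels: Mapping[float, Sequence[float]],
    blank_replicates: Sequence[float],
    snr_values: Mapping[float, Sequence[float]],
) -> LODResult:
    """Detection-limit decision per calibration level.

    A level is detected when every replicate reaches S/N >= 3 *and* its mean
    response exceeds the blank mean by 3 blank standard deviations.  The LOD
    is the lowest passing concentration.
    """
    if len(blank_replicates) < 2:
        raise ValueError("need >= 2 blank replicates to estimate the blank SD")
    blank = np.asarray(blank_replicates, dtype=float)
    threshold = blank.mean() + 3.0 * blank.std(ddof=1)
    rows = []
    for conc in sorted(levels):
        values = np.asarray(levels[conc], dtype=float)
        snr = np.asarray(snr_values.get(conc, []), dtype=float)
        min_snr = float(snr.min()) if snr.size else float("nan")
        passes = bool(snr.size and min_snr >= 3.0 and values.mean() >= threshold)
        rows.append(
            {
                "nominal_pg_ml": conc,
                "mean": float(values.mean()),
                "min_snr": min_snr,
                "passes": passes,
            }
        )
    table = pd.DataFrame(rows)
    passing = table.loc[table["passes"], "nominal_pg_ml"]
    return LODResult(
        lod_pg_ml=float(passing.min()) if len(passing) else None,
        per_level=table,
    )


@dataclass(frozen=True)
class LOQResult:
    loq_pg_ml: float | None
    per_level: pd.DataFrame  # nominal_pg_ml, cv_pct, re_pct, passes
    diagnostic: str = ""


def evaluate_loq(
    measurements: Mapping[float, Sequence[float]],
    cv_limit_pct: float = 25.0,
    re_limit_pct: float = 25.0,
) -> LOQResult:
    """Quantitation limit from replicate back-calculated concentrations.

    LOQ is the lowest nominal concentration whose replicates satisfy both
    CV <= ``cv_limit_pct`` and |mean - nominal|/nominal <= ``re_limit_pct``.
    """
    rows = []
    for conc in sorted(measurements):
        values = np.asarray(measurements[conc], dtype=float)
        if values.size < 3:
            raise ValueError(
                f"need >= 3 replicates per level, got {values.size} at {conc}"
            )
        mean = values.mean()
        cv = float(values.std(ddof=1) / mean * 100.0) if mean != 0 else math.inf
        re = float(abs(mean - conc) / conc * 100.0)
        rows.append(
            {
                "nominal_pg_ml": conc,
                "cv_pct": cv,
                "re_pct": re,
                "passes": cv <= cv_limit_pct and re <= re_limit_pct,
            }
        )
    table = pd.DataFrame(rows)
    passing = table.loc[table["passes"], "nominal_pg_ml"]
    if len(passing):
        return LOQResult(loq_pg_ml=float(passing.min()), per_level=table)
    return LOQResult(
        loq_pg_ml=None,
        per_level=table,
        diagnostic=(
            f"no level met CV <= {cv_limit_pct}% and RE <= {re_limit_pct}%"
        ),
    )


@dataclass(frozen=True)
class QCResult:
    """Precision/accuracy summary for one QC level of one species."""

    species: str
    nominal_pg_ml: float
    intra_day_cv_pct: float
    inter_day_cv_pct: float
    relative_error_pct: float


def qc_precision(
    batches: Mapping[object, Sequence[float]],
    species: str,
    nominal_pg_ml: float,
    inter_day_estimator: str = "total",
) -> QCResult:
    """Intra- and inter-day precision of replicate QC measurements.

    ``batches`` maps a day identifier to that day's replicate
    concentrations.  Intra-day CV pools the per-day CVs as a root mean
    square; inter-day CV is, by default, the total CV of all measurements
    across days (``inter_day_estimator="total"``).  The variance-components
    alternative (``"anova"``) estimates the between-day SD from a one-way
    ANOVA decomposition and reports it relative to the grand mean.
    """
    if len(batches) < 1:
        raise ValueError("no QC batches supplied")
    per_day_cv = []
    all_values: list[float] = []
    day_means = []
    day_sizes = []
    for day, values in batches.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"need >= 2 replicates per day (day {day!r})")
        per_day_cv.append(arr.std(ddof=1) / arr.mean() * 100.0)
        day_means.append(arr.mean())
        day_sizes.append(arr.size)
        all_values.extend(arr.tolist())
    intra = float(np.sqrt(np.mean(np.square(per_day_cv))))
    if len(batches) < 2:
        raise ValueError("inter-day precision needs >= 2 days")
    pooled = np.asarray(all_values)
    grand_mean = pooled.mean()
    if inter_day_estimator == "total":
        inter = float(pooled.std(ddof=1) / grand_mean * 100.0)
    elif inter_day_estimator == "anova":
        # One-way random-effects decomposition: between-day variance
        # component sigma_b^2 = (MSB - MSW)/n0, floored at zero.
        k = len(day_means)
        n0 = float(np.mean(day_sizes))
        msb = n0 * np.var(day_means, ddof=1)
        msw = np.mean(
            [np.var(np.asarray(v, dtype=float), ddof=1) for v in batches.values()]
        )
        sigma_b2 = max((msb - msw) / n0, 0.0)
        inter = float(np.sqrt(sigma_b2) / grand_mean * 100.0)
    else:
        raise ValueError("inter_day_estimator must be 'total' or 'anova'")
    re = float((grand_mean - nominal_pg_ml) / nominal_pg_ml * 100.0)
    return QCResult(
        species=species,
        nominal_pg_ml=nominal_pg_ml,
        intra_day_cv_pct=intra,
        inter_day_cv_pct=inter,
        relative_error_pct=re,
    )


def expected_infusate_conc(stock_ug_ml: float, dilution_factor: float) -> float:
    """Expected infusate tracer concentration in pg/ml after dilution.

    ``stock_ug_ml`` is the measured stock concentration in µg/ml;
    ``dilution_factor`` is the fold-dilution (100 for a 1/100 dilution).
    """
    if stock_ug_ml <= 0:
        raise ValueError("stock concentration must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return stock_ug_ml * 1.0e6 / dilution_factor


AREA_TABLE_COLUMNS = [
    "species",
    "level_id",
    "nominal_pg_ml",
    "day",
    "replicate",
    "analyte_area",
    "is_area",
]


def read_area_table(path) -> pd.DataFrame:
    """Read a calibration/QC peak-area CSV; ``snr`` column is optional."""
    df = pd.read_csv(path)
    missing = [c for c in AREA_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area table missing columns: {missing}")
    return df


def standards_from_table(df: pd.DataFrame, species: str) -> list[CalibrationStandard]:
    """Group a peak-area table into per-level calibration standards.

    Rows with missing or non-positive IS area (the plasma-only blank
    control carries no internal standard) are excluded.
    """
    sub = df[(df["species"] == species) & (df["is_area"] > 0)].dropna(
        subset=["is_area", "analyte_area"]
    )
    out = []
    for conc, grp in sub.groupby("nominal_pg_ml"):
        if conc <= 0:
            continue
        out.append(
            CalibrationStandard(
                species=species,
                nominal_pg_ml=float(conc),
                analyte_areas=tuple(grp["analyte_area"]),
                is_areas=tuple(grp["is_area"]),
            )
        )
    out.sort(key=lambda s: s.nominal_pg_ml)
    return out
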