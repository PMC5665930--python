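"""Calibration fitting, concentration back-calculation, percent formation
and metabotype classification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidAssayError,
    MissingValueError,
    UndefinedStatisticError,
    ValidationError,
)

METABOLITES = ("sn38", "sn38g")


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary-least-squares calibration of peak-area ratio on concentration.

    LLOD/LLOQ follow the ICH convention: 3.3·σ/slope and 10·σ/slope, with σ
    the residual standard deviation of the fit (df = n − 2).
    """

    metabolite: str
    slope: float
    intercept: float
    residual_sd: float
    llod: float
    lloq: float
    n_points: int

    def to_concentration(self, area_ratio: float) -> float:
        """Invert the line; negative back-calculations floor at 0."""
        return max(0.0, (area_ratio - self.intercept) / self.slope)


def fit_calibration(table: pd.DataFrame, metabolite: str | None = None) -> CalibrationCurve:
    """Fit a calibration line by ordinary least squares.

    ``table`` must have ``concentration_uM`` and ``area_ratio`` columns
    (and optionally ``metabolite`` to select one analyte). Raises
    :class:`InvalidAssayError` if all concentrations are equal or the
    fitted slope is not positive.
    """
    if metabolite is not None and "metabolite" in table.columns:
        table = table[table["metabolite"] == metabolite]
    name = metabolite or (
        str(table["metabolite"].iloc[0]) if "metabolite" in table.columns and len(table) else ""
    )
    x = np.asarray(table["concentration_uM"], dtype=float)
    y = np.asarray(table["area_ratio"], dtype=float)
    if len(np.unique(x)) < 2:
        raise InvalidAssayError("calibration requires >= 2 distinct concentration levels")
    n = len(x)
    # normal equations: slope = Sxy/Sxx so an exactly flat line gives 0.0
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    if slope <= 0:
        raise InvalidAssayError(f"non-positive calibration slope ({slope:.4g}): invalid assay")
    resid = y - (slope * x + intercept)
    ssr = float(resid @ resid)
    residual_sd = float(np.sqrt(ssr / (n - 2))) if n > 2 else 0.0
    llod = 3.3 * residual_sd / slope
    lloq = 10.0 * residual_sd / slope
    return CalibrationCurve(
        metabolite=name,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
        llod=llod,
        lloq=lloq,
        n_points=n,
    )


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def quantify(
    timecourse: pd.DataFrame, curves: Mapping[str, CalibrationCurve]
) -> pd.DataFrame:
    """Back-calculate concentrations from a peak-area time course.

    Per measurement the analyte/ISTD area ratio is inverted through that
    metabolite's calibration curve (floored at 0); replicates are then
    summarized as mean ± sem per (individual, timepoint). Replicates with
    non-positive ISTD area are excluded with a warning; a cell whose
    replicates are all excluded raises :class:`MissingValueError`.

    Output columns: ``individual, timepoint_min, n_replicates`` plus, per
    metabolite m, ``conc_<m>_uM, sem_<m>_uM, below_llod_<m>``.
    """
    required = {"individual", "timepoint_min", "area_istd"} | {
        f"area_{m}" for m in curves
    }
    missing = required - set(timecourse.columns)
    if missing:
        raise ValidationError(f"time-course table missing columns: {sorted(missing)}")

    rows = []
    for (ind, tp), cell in timecourse.groupby(["individual", "timepoint_min"], sort=True):
        istd = np.asarray(cell["area_istd"], dtype=float)
        ok = istd > 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} replicate(s) with non-positive ISTD area "
                f"for individual {ind} at t={tp}",
                stacklevel=2,
            )
        if not ok.any():
            raise MissingValueError(
                f"all replicates excluded for individual {ind} at t={tp}"
            )
        row: dict = {"individual": ind, "timepoint_min": float(tp), "n_replicates": int(ok.sum())}
        for m, curve in curves.items():
            area = np.asarray(cell[f"area_{m}"], dtype=float)[ok]
            raw = (area / istd[ok] - curve.intercept) / curve.slope
            conc = np.maximum(raw, 0.0)
            row[f"conc_{m}_uM"] = float(conc.mean())
            row[f"sem_{m}_uM"] = _sem(conc)
            # negative back-calculations are flagged, not propagated
            row[f"below_llod_{m}"] = bool(raw.mean() < curve.llod or raw.mean() < 0)
        rows.append(row)
    return pd.DataFrame(rows)


def percent_formation(
    quant: pd.DataFrame,
    substrate_initial: float = 100.0,
    final_timepoint: float | None = None,
    metabolite: str = "sn38",
) -> pd.Series:
    """Percent of initial substrate converted to analyte at the final timepoint.

    ``percent = 100 * conc_<metabolite>(final) / substrate_initial``,
    clipped to [0, 100]. Raises if an individual lacks the final timepoint.
    """
    if substrate_initial <= 0:
        raise ValidationError("substrate_initial must be > 0")
    col = f"conc_{metabolite}_uM"
    if col not in quant.columns:
        raise ValidationError(f"quant table missing column {col}")
    if final_timepoint is None:
        final_timepoint = float(quant["timepoint_min"].max())
    out: dict[str, float] = {}
    for ind, sub in quant.groupby("individual", sort=True):
        at_final = sub[sub["timepoint_min"] == final_timepoint]
        if at_final.empty:
            raise MissingValueError(
                f"individual {ind} has no measurement at final timepoint {final_timepoint}"
            )
        pct = 100.0 * float(at_final[col].iloc[0]) / substrate_initial
        out[str(ind)] = float(np.clip(pct, 0.0, 100.0))
    return pd.Series(out, name="percent_formation")


@dataclass(frozen=True)
class MetabotypeAssignment:
    """Low/high metabotype labels from a largest-gap split of percent formation."""

    assignments: pd.DataFrame  # columns: individual, percent_formation, metabotype
    split_gap: float
    threshold: float | None  # midpoint of the split gap; None when no high group
    method: str = "largest_gap"

    @property
    def labels(self) -> pd.Series:
        return self.assignments.set_index("individual")["metabotype"]

    @property
    def n_low(self) -> int:
        return int((self.assignments["metabotype"] == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.assignments["metabotype"] == "high").sum())


def classify_metabotype(
    percents: pd.Series | Mapping[str, float], min_gap: float = 10.0
) -> MetabotypeAssignment:
    """Split individuals into low/high metabotypes at the largest gap.

    Sorts percent-formation values and splits at the largest consecutive
    gap; if that gap is below ``min_gap`` percentage points the cohort is
    considered unimodal and everyone is labeled low.
    """
    s = pd.Series(percents, dtype=float)
    if len(s) < 2:
        raise ValidationError("metabotype classification requires >= 2 individuals")
    order = s.sort_values(kind="stable")
    gaps = np.diff(order.to_numpy())
    i = int(np.argmax(gaps))  # first largest gap
    split_gap = float(gaps[i])
    if split_gap < min_gap:
        labels = pd.Series("low", index=s.index)
        threshold = None
    else:
        threshold = float((order.iloc[i] + order.iloc[i + 1]) / 2.0)
        labels = pd.Series(np.where(s > threshold, "high", "low"), index=s.index)
    table = pd.DataFrame(
        {
            "individual": s.index,
            "percent_formation": s.to_numpy(),
            "metabotype": labels.to_numpy(),
        }
    )
    return MetabotypeAssignment(assignments=table, split_gap=split_gap, threshold=threshold)


def correlate_assays(x, y) -> tuple[float, float, int]:
    """Pearson correlation between two paired per-individual assays.

    Returns ``(r, two_sided_p, n)``; p comes from the t-transform with
    n − 2 degrees of freedom. Zero variance in either vector raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("assay vectors must be paired (same length)")
    if len(x) < 3:
        raise ValidationError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("assay values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)
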