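"""Differential feature abundance between metabotypes.

Welch's two-sided t-test per feature, Storey q-values across features
within a category, and a ratio-of-proportions effect-size filter
(features with ratio < 2 are filtered out), plus a Shapiro–Wilk
normality QC gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

Q_THRESHOLD = 0.05
EFFECT_THRESHOLD = 2.0
STOREY_LAMBDA = 0.5


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample column to proportions (columns sum to 1).

    Idempotent; a sample with zero total raises.
    """
    if (table.to_numpy() < 0).any():
        raise ValidationError("abundance table contains negative entries")
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {list(zero.index)}")
    return table / totals


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_a − mean_b)/sqrt(s²_a/n_a + s²_b/n_b), df by
    Welch–Satterthwaite. Degenerate zero-variance cases: equal means give
    (0, pooled df, 1); unequal means give (±inf, pooled df, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("welch_t requires >= 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("welch_t requires finite values")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    # zero variance up to floating noise relative to the data scale
    scale = max(abs(a).max(), abs(b).max(), np.finfo(float).tiny)
    if np.sqrt(va) <= 1e-12 * scale and np.sqrt(vb) <= 1e-12 * scale:
        df = float(na + nb - 2)
        if abs(diff) <= 1e-12 * scale:
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, diff)), df, 0.0
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class QValueEstimate:
    """Storey q-values with a single-λ π0 estimate."""

    pi0: float
    lam: float
    q_values: np.ndarray


def storey_qvalues(pvalues, lam: float = STOREY_LAMBDA) -> QValueEstimate:
    """Storey FDR q-values.

    π0 = min(1, #{p > λ} / ((1 − λ)·m)), floored at 1/m when the estimate
    is zero; q(i) = min_{j ≥ i} π0·m·p(j)/j over p sorted ascending,
    capped at 1, returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValidationError("pvalues must be a non-empty 1-d array")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("pvalues must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValidationError("lambda must lie in (0, 1)")
    m = len(p)
    pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    pi0 = min(1.0, pi0)
    if pi0 == 0.0:
        pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, pi0 * m * p[order] / ranks)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return QValueEstimate(pi0=float(pi0), lam=float(lam), q_values=q)


def effect_ratio(mean_low: float, mean_high: float, pseudo: float | None = None) -> float:
    """Symmetric ratio-of-proportions effect size, max(m)/min(m).

    Zero means are replaced by ``pseudo`` (half the smallest nonzero
    proportion in the table, supplied by the caller); both-zero gives 1.
    """
    if mean_low < 0 or mean_high < 0:
        raise ValidationError("means must be >= 0")
    if mean_low == 0 and mean_high == 0:
        return 1.0
    if mean_low == 0 or mean_high == 0:
        if pseudo is None or pseudo <= 0:
            raise ValidationError("a positive pseudo-proportion is required for zero means")
        mean_low = mean_low or pseudo
        mean_high = mean_high or pseudo
    return float(max(mean_low, mean_high) / min(mean_low, mean_high))


def differential_features(
    table: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    q_threshold: float = Q_THRESHOLD,
    effect_threshold: float = EFFECT_THRESHOLD,
    lam: float = STOREY_LAMBDA,
) -> pd.DataFrame:
    """Per-feature differential abundance between low and high groups.

    Raw abundances are converted to proportions, each feature is tested
    with Welch's t (high vs low), q-values are computed across the
    features of the table (one category per call), and the effect filter
    retains features whose symmetric proportion ratio is >= the threshold.
    ``significant ⟺ q < q_threshold and effect_ratio >= effect_threshold``.

    Returns a DataFrame indexed by feature with columns ``mean_low,
    mean_high, t, df, p, q, effect_ratio, direction, significant``.
    """
    labels = pd.Series(labels)
    missing = [c for c in table.columns if c not in labels.index]
    if missing:
        raise ValidationError(f"samples missing a metabotype label: {missing}")
    labels = labels.loc[list(table.columns)]
    bad = sorted(set(labels) - {"low", "high"})
    if bad:
        raise ValidationError(f"unknown metabotype labels: {bad}")
    low_cols = labels.index[labels == "low"]
    high_cols = labels.index[labels == "high"]
    if len(low_cols) < 2 or len(high_cols) < 2:
        raise ValidationError("each metabotype group needs >= 2 samples")

    rel = to_relative(table)
    low = rel[low_cols].to_numpy()
    high = rel[high_cols].to_numpy()
    stats_rows = [welch_t(h, l) for h, l in zip(high, low)]
    t_arr, df_arr, p_arr = map(np.array, zip(*stats_rows))
    qest = storey_qvalues(p_arr, lam=lam)

    nonzero = rel.to_numpy()
    nonzero = nonzero[nonzero > 0]
    pseudo = float(nonzero.min() / 2.0) if len(nonzero) else None
    mean_low = low.mean(axis=1)
    mean_high = high.mean(axis=1)
    ratios = np.array(
        [effect_ratio(ml, mh, pseudo) for ml, mh in zip(mean_low, mean_high)]
    )
    direction = np.where(
        mean_high > mean_low, "high", np.where(mean_high < mean_low, "low", "none")
    )
    out = pd.DataFrame(
        {
            "mean_low": mean_low,
            "mean_high": mean_high,
            "t": t_arr,
            "df": df_arr,
            "p": p_arr,
            "q": qest.q_values,
            "effect_ratio": ratios,
            "direction": direction,
            "significant": (qest.q_values < q_threshold) & (ratios >= effect_threshold),
        },
        index=table.index,
    )
    out.attrs["pi0"] = qest.pi0
    out.attrs["lambda"] = qest.lam
    return out


def normality_check(values) -> tuple[float, float]:
    """Shapiro–Wilk normality QC for a hit distribution.

    Returns (W, p); warns (does not raise) when p < 0.05. Zero-variance
    or out-of-range n raises.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("normality check requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("normality undefined for identical values")
    w, p = stats.shapiro(x)
    if p < 0.05:
        warnings.warn(
            f"hit distribution departs from normality (Shapiro-Wilk p={p:.3g})",
            stacklevel=2,
        )
    return float(w), float(p)
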