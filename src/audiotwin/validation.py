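"""Screening-test validation: ROC analysis, repeatability, correlations.

The speech-in-noise score is validated against binary references derived
from audiogram phenotypes (e.g. PTA > 40 dB).  Higher (less negative) SNR
means worse speech-in-noise hearing, so a subject is test-positive when the
score strictly exceeds the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # ordered cutoffs, -inf first (everyone positive)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    reference_rule: str = ""


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    ci95_mean_diff: tuple[float, float]
    loa95: tuple[float, float]
    pitman_stat: float
    pitman_p: float
    degenerate: bool = False


def binary_reference(table: pd.DataFrame, rule: dict[str, float]) -> np.ndarray:
    """0/1 impairment labels from a strict-threshold rule.

    ``{"pta_gt": 40}`` labels subjects with PTA strictly above 40 dB;
    ``{"pc_diff_gt": 3.4}`` uses the PC1-PC2 composite instead.
    """
    if len(rule) != 1:
        raise ValidationError("rule must have exactly one entry")
    (key, threshold), = rule.items()
    column = {"pta_gt": "pta", "pc_diff_gt": "pc1_minus_pc2"}.get(key)
    if column is None:
        raise ValidationError(f"unknown rule {key!r}")
    if column not in table.columns:
        raise ValidationError(f"column {column!r} missing from table")
    labels = (table[column].to_numpy(dtype=float) > threshold).astype(int)
    if labels.sum() == 0:
        logger.warning("binary_reference: no positive labels under %s > %s", column, threshold)
    if labels.sum() == len(labels):
        logger.warning("binary_reference: all labels positive under %s > %s", column, threshold)
    return labels


def roc(scores, labels, reference_rule: str = "") -> ROCCurve:
    """ROC by direct counting: positive when ``score > cutoff``.

    Cutoffs sweep every distinct score, plus -inf (all positive).  AUC is
    the trapezoid over (1 - specificity, sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    cutoffs = np.concatenate([[-np.inf], np.unique(scores)])
    sens = np.empty(len(cutoffs))
    spec = np.empty(len(cutoffs))
    for i, c in enumerate(cutoffs):
        pred = scores > c
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # vertical steps carry zero area
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCCurve(
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        reference_rule=reference_rule,
    )


def best_operating_point(curve: ROCCurve) -> OperatingPoint:
    """Cutoff maximizing Youden's J; ties broken toward higher sensitivity."""
    j = curve.sensitivity + curve.specificity - 1.0
    if len(j) == 0:
        raise ValidationError("degenerate curve")
    best = max(
        range(len(j)), key=lambda i: (round(j[i], 12), curve.sensitivity[i])
    )
    return OperatingPoint(
        cutoff=float(curve.thresholds[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        youden_j=float(j[best]),
    )


def operating_point_at(curve: ROCCurve, cutoff: float) -> OperatingPoint:
    """Sensitivity/specificity at the largest stored cutoff <= ``cutoff``."""
    idx = np.searchsorted(curve.thresholds, cutoff, side="right") - 1
    idx = int(np.clip(idx, 0, len(curve.thresholds) - 1))
    return OperatingPoint(
        cutoff=float(cutoff),
        sensitivity=float(curve.sensitivity[idx]),
        specificity=float(curve.specificity[idx]),
        youden_j=float(curve.sensitivity[idx] + curve.specificity[idx] - 1.0),
    )


def bland_altman(first, second) -> BlandAltmanResult:
    """Agreement of paired measurements plus Pitman's variance test.

    Differences ``d = first - second`` give the mean with a t-based 95% CI
    and limits of agreement ``mean ± 1.96 SD``.  Pitman's test is the t-test
    on the correlation between sums and differences (n - 2 df); degenerate
    inputs (zero variance of sums or differences) report p = 1 with a flag.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    mask = np.isfinite(first) & np.isfinite(second)
    first, second = first[mask], second[mask]
    n = len(first)
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    d = first - second
    s = first + second
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    ci = (mean_diff - tcrit * sd / np.sqrt(n), mean_diff + tcrit * sd / np.sqrt(n))
    loa = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    if sd == 0 or np.std(s, ddof=1) == 0:
        return BlandAltmanResult(
            n=n,
            mean_diff=mean_diff,
            ci95_mean_diff=ci,
            loa95=loa,
            pitman_stat=0.0,
            pitman_p=1.0,
            degenerate=True,
        )
    r = float(np.corrcoef(s, d)[0, 1])
    if abs(r) >= 1.0:
        tstat, p = np.inf, 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        ci95_mean_diff=ci,
        loa95=loa,
        pitman_stat=float(tstat),
        pitman_p=p,
    )


def correlate_tests(
    table: pd.DataFrame,
    score_column: str = "snr",
    phenotype_columns: tuple[str, ...] = ("pta", "behl", "pc1", "pc2", "pc1_minus_pc2"),
) -> pd.DataFrame:
    """Pairwise Pearson correlation of the score with each phenotype.

    Listwise deletion per pair; the complete-case count is reported per row.
    """
    score = table[score_column].to_numpy(dtype=float)
    rows = []
    for col in phenotype_columns:
        if col not in table.columns:
            continue
        vals = table[col].to_numpy(dtype=float)
        mask = np.isfinite(score) & np.isfinite(vals)
        if mask.sum() < 3:
            logger.warning("correlate_tests: skipping %r (fewer than 3 complete rows)", col)
            continue
        rows.append(
            {
                "phenotype": col,
                "r": float(np.corrcoef(score[mask], vals[mask])[0, 1]),
                "n": int(mask.sum()),
            }
        )
    if not rows:
        raise ValidationError("no phenotype with at least 3 complete rows")
    return pd.DataFrame(rows)
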