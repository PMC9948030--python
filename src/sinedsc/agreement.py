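"""ROI summarisation and method-agreement statistics.

Regional perfusion values are compared between methods with Pearson
correlation over ROI means, Bland–Altman 95% limits of agreement
(normalised by the grand mean of the two methods and reported as
percentages), and inter-subject / test–retest coefficients of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "roi_summary",
    "pearson_roi",
    "limits_of_agreement",
    "coefficient_of_variation",
]


@dataclass
class AgreementReport:
    """Bland–Altman agreement between two paired methods, in percent."""

    pearson_r: float
    bias_percent: float
    loa_low_percent: float
    loa_high_percent: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low_percent <= self.bias_percent <= self.loa_high_percent):
            raise ValueError("limits of agreement must bracket the bias")


def roi_summary(
    volume: np.ndarray,
    labels: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI mean and sample standard deviation of a parameter map.

    Suppressed (``exclusion_mask``) and undefined (NaN) voxels are excluded;
    an ROI left empty after exclusion is dropped with a warning.  Label 0 is
    background and is never reported.
    """
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ValueError("map and labels must share the grid")
    keep = np.isfinite(volume)
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != volume.shape:
            raise ValueError("exclusion mask must share the grid")
        keep &= ~excl
    rows = []
    for roi in np.unique(labels):
        if roi == 0:
            continue
        sel = (labels == roi) & keep
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"ROI {roi} empty after exclusion; dropped", stacklevel=2)
            continue
        vals = volume[sel]
        rows.append({
            "roi": roi,
            "n_voxels": n,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["roi", "n_voxels", "mean", "sd"])


def pearson_roi(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Pearson correlation of ROI means shared by two summaries."""
    merged = table_a.merge(table_b, on="roi", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least 3 shared ROIs")
    a = merged["mean_a"].to_numpy()
    b = merged["mean_b"].to_numpy()
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in ROI means; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def limits_of_agreement(vals_a: np.ndarray, vals_b: np.ndarray) -> AgreementReport:
    """Bland–Altman bias and 95% limits of agreement, as percentages.

    d = A − B; bias = mean(d); limits = bias ± 1.96·sd(d) with the sample
    (n−1) standard deviation; all three are divided by the grand mean of
    the pairwise averages (A+B)/2 and multiplied by 100.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired 1D arrays of equal length >= 2")
    d = a - b
    bias = d.mean()
    sd = d.std(ddof=1)
    norm = ((a + b) / 2.0).mean()
    if norm == 0:
        raise ValueError("zero normaliser (grand mean of pairwise averages)")
    scale = 100.0 / norm
    return AgreementReport(
        pearson_r=float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else float("nan"),
        bias_percent=float(bias * scale),
        loa_low_percent=float((bias - 1.96 * sd) * scale),
        loa_high_percent=float((bias + 1.96 * sd) * scale),
        n=a.size,
    )


def coefficient_of_variation(
    values: np.ndarray, mode: str = "intersubject"
) -> float:
    """Coefficient of variation, percent.

    ``intersubject``: sd/mean × 100 over a 1D array of per-subject values.
    ``test_retest``: values is (n_subjects, n_replicates); the root mean
    square of within-subject standard deviations divided by the grand mean.
    """
    values = np.asarray(values, dtype=float)
    if mode == "intersubject":
        if values.ndim != 1 or values.size < 2:
            raise ValueError("intersubject CoV needs >= 2 values")
        mean = values.mean()
        if mean == 0:
            raise ValueError("zero mean")
        return float(values.std(ddof=1) / mean * 100.0)
    if mode == "test_retest":
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError("test-retest CoV needs >= 2 replicates per subject")
        grand = values.mean()
        if grand == 0:
            raise ValueError("zero grand mean")
        within_sd = values.std(axis=1, ddof=1)
        return float(np.sqrt(np.mean(within_sd**2)) / grand * 100.0)
    raise ValueError(f"unknown mode {mode!r}")
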