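"""Per-gene two-group differential expression on log-scale matrices.

For each gene the contrast ``group_a - group_b`` is summarized by the mean
log2 fold change, a two-sided Welch t-test, Benjamini-Hochberg adjusted
p-values across all genes, and a variance-floored signal-to-noise ratio
(SNR) in the GSEA tradition — the statistic used downstream to rank genes
for signature derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleAnnotation, ValidationError

#: relative and absolute floor applied to each group's sd inside the SNR
SNR_SD_FLOOR_REL = 0.2
SNR_SD_FLOOR_ABS = 0.2


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fc: float
    t_stat: float
    p_value: float
    fdr_bh: float
    snr: float


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1].

    adjusted[i] = min over j with p_(j) >= p_(i) of p_(j) * m / j, which the
    implementation computes by a reverse cumulative minimum over the sorted
    p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return adjusted


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(SNR_SD_FLOOR_REL * np.abs(mean), SNR_SD_FLOOR_ABS))


def signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise SNR (meanA - meanB) / (sdA + sdB) with floored sds.

    The floor (each sd at least max(0.2*|mean|, 0.2)) keeps the ratio finite
    and stable at the tiny group sizes typical of sorted-population RNA-seq.
    """
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = _floored_sd(a.std(axis=1, ddof=1), mean_a)
    sd_b = _floored_sd(b.std(axis=1, ddof=1), mean_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def differential_expression(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Welch-t differential expression of ``group_a`` vs ``group_b``.

    Returns a DataFrame with one row per gene (input order preserved) and
    columns gene_id, log2_fc, t_stat, p_value, fdr_bh, snr.  Genes with
    identical values in both groups get t = 0, p = 1.
    """
    annotation.validate_against(matrix)
    groups = annotation.groups
    for label in (group_a, group_b):
        if label not in set(groups):
            raise KeyError(f"group {label!r} not present in annotation")
    samples_a = annotation.samples_in(group_a)
    samples_b = annotation.samples_in(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs >= 2 samples")

    a = matrix.data[samples_a].to_numpy()
    b = matrix.data[samples_b].to_numpy()

    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    t_stat, p_value = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero-variance, zero-difference rows come back NaN; they carry no signal
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "fdr_bh": benjamini_hochberg(p_value),
            "snr": signal_to_noise(a, b),
        }
    )
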