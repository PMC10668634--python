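"""Single-sample gene-set enrichment (ssGSEA).

Each sample is treated independently: its expression profile is rank
normalized (average ranks mapped to (0, 1]), genes are ordered by
decreasing normalized rank, and the enrichment score of a gene set is the
running-sum total of the difference between the weighted in-set ECDF and
the out-of-set ECDF,

    ES = sum_i [ P_in^w(i) - P_out(i) ],

where P_in^w accumulates the in-set genes' normalized ranks raised to the
weight exponent ``w`` (normalized to end at 1) and P_out is the plain
count ECDF of the remaining genes.  A positive score means the set's genes
concentrate at the top of the sample's ranking; a negative score, at the
bottom.  With ``w = 0`` the score reduces to the unweighted running-sum
total.  Scores are a function of within-sample ranks only, hence invariant
under any strictly increasing per-sample transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 0.75
DEFAULT_MIN_OVERLAP = 5


class OverlapError(ValidationError):
    """Gene set has no usable overlap with the profile's gene space."""

    def __init__(self, message: str, overlap: int = 0):
        super().__init__(message)
        self.overlap = overlap


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample ssGSEA scores."""

    scores: pd.DataFrame  # sets x samples
    weight_exponent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("enrichment matrix contains non-finite scores")
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValidationError("duplicate set or sample names")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def minmax_normalized(self) -> "EnrichmentMatrix":
        """Scores rescaled to [0, 1] across the whole matrix."""
        v = self.scores.to_numpy()
        span = v.max() - v.min()
        if span == 0:
            raise ValidationError("cannot min-max normalize a constant score matrix")
        return EnrichmentMatrix((self.scores - v.min()) / span, self.weight_exponent)


def rank_normalize(profile: np.ndarray) -> np.ndarray:
    """Map a profile to normalized ranks in (0, 1]: rank/n, average ties."""
    values = np.asarray(profile, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("profile must be a 1-D vector with >= 2 genes")
    if not np.isfinite(values).all():
        raise ValidationError("profile contains non-finite values")
    return stats.rankdata(values, method="average") / values.size


def enrichment_score(
    normalized_ranks: np.ndarray,
    gene_ids: list[str],
    gene_set: GeneSet,
    weight: float = DEFAULT_WEIGHT,
) -> float:
    """Enrichment score of one gene set in one rank-normalized profile."""
    if weight < 0:
        raise ValidationError("weight exponent must be nonnegative")
    r = np.asarray(normalized_ranks, dtype=float)
    n = r.size
    if len(gene_ids) != n:
        raise ValidationError("gene_ids and rank vector lengths differ")
    members = set(gene_set.genes)
    in_set = np.fromiter((g in members for g in gene_ids), dtype=bool, count=n)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise OverlapError(f"gene set {gene_set.name!r} has zero overlap with profile", 0)
    if n_in == n:
        raise OverlapError(
            f"gene set {gene_set.name!r} covers every profiled gene", n_in
        )

    order = np.argsort(-r, kind="stable")  # descending rank
    in_sorted = in_set[order]
    r_sorted = r[order]

    weighted = np.where(in_sorted, r_sorted**weight, 0.0)
    p_in = np.cumsum(weighted) / weighted.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def score_sample(
    matrix: ExpressionMatrix,
    sample_id: str,
    sets: GeneSetCollection,
    weight: float = DEFAULT_WEIGHT,
) -> dict[str, float]:
    """ssGSEA scores of every set for one sample (sets with no overlap raise)."""
    profile = matrix.data[sample_id].to_numpy()
    ranks = rank_normalize(profile)
    return {
        s.name: enrichment_score(ranks, matrix.gene_ids, s, weight) for s in sets
    }


def score_collection(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    weight: float = DEFAULT_WEIGHT,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EnrichmentMatrix:
    """Score every (set, sample) pair; sets below ``min_overlap`` are dropped."""
    genes = set(matrix.gene_ids)
    usable = []
    for s in sets:
        overlap = len(genes.intersection(s.genes))
        if overlap < min_overlap or overlap == len(genes):
            logger.warning(
                "dropping gene set %r (overlap %d, min %d)", s.name, overlap, min_overlap
            )
        else:
            usable.append(s)
    if not usable:
        raise ValidationError("every gene set fell below the overlap threshold")

    gene_ids = matrix.gene_ids
    values = matrix.values
    rows = {s.name: [] for s in usable}
    for j in range(values.shape[1]):
        ranks = rank_normalize(values[:, j])
        for s in usable:
            rows[s.name].append(enrichment_score(ranks, gene_ids, s, weight))
    scores = pd.DataFrame(rows, index=matrix.sample_ids).T
    scores.columns = matrix.sample_ids
    return EnrichmentMatrix(scores, weight)
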