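import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungplast.io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError
from lungplast.ssgsea import (
    OverlapError,
    enrichment_score,
    rank_normalize,
    score_collection,
    score_sample,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: ranks by pairwise counting, score by an
# explicit per-position double loop over the definition
# ---------------------------------------------------------------------------


def brute_force_ranks(values):
    n = len(values)
    ranks = []
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        ties = sum(1 for j in range(n) if values[j] == values[i])
        ranks.append((less + (less + ties + 1)) / 2.0 / n)
    return np.array(ranks)


def brute_force_es(values, gene_ids, set_genes, w):
    ranks = brute_force_ranks(values)
    order = sorted(range(len(values)), key=lambda i: -ranks[i])
    in_set = [gene_ids[i] in set_genes for i in order]
    r_sorted = [ranks[i] for i in order]
    denom_in = sum(r_sorted[j] ** w for j in range(len(order)) if in_set[j])
    n_out = sum(1 for f in in_set if not f)
    total = 0.0
    for i in range(len(order)):
        p_in = sum(r_sorted[j] ** w for j in range(i + 1) if in_set[j]) / denom_in
        p_out = sum(1 for j in range(i + 1) if not in_set[j]) / n_out
        total += p_in - p_out
    return total


def make_matrix(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestRankNormalize:
    def test_simple_example(self):
        assert rank_normalize([3, 1, 2]) == pytest.approx([1.0, 1 / 3, 2 / 3])

    def test_all_ties_average(self):
        # average of ranks 1..4 is 2.5; normalized 2.5/4 = 0.625
        assert rank_normalize([7.0] * 4) == pytest.approx([0.625] * 4)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        assert rank_normalize(np.exp(x)) == pytest.approx(rank_normalize(x))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
    def test_matches_pairwise_counting_oracle(self, seed, n):
        values = np.random.default_rng(seed).integers(0, 10, size=n).astype(float)
        assert rank_normalize(values) == pytest.approx(brute_force_ranks(values))

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            rank_normalize([1.0, np.inf])

    def test_single_gene_rejected(self):
        with pytest.raises(ValidationError):
            rank_normalize([1.0])


class TestEnrichmentScore:
    def test_two_gene_extremes(self):
        ranks = rank_normalize([10.0, 1.0])
        top = GeneSet("top", "", ("g0",))
        bottom = GeneSet("bottom", "", ("g1",))
        assert enrichment_score(ranks, ["g0", "g1"], top, weight=0) == pytest.approx(1.0)
        assert enrichment_score(ranks, ["g0", "g1"], bottom, weight=0) == pytest.approx(-1.0)

    def test_interleaved_set_scores_near_zero(self):
        """A set occupying evenly spaced rank positions is unenriched."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        for _ in range(100):
            values = rng.normal(size=100)
            order = np.argsort(-values)  # rank positions, top first
            members = tuple(genes[i] for i in order[4::10])
            gene_set = GeneSet("interleaved", "", members)
            es = enrichment_score(rank_normalize(values), genes, gene_set, weight=0)
            assert abs(es) < 5.0

    @pytest.mark.parametrize("weight", [0.0, 0.75, 1.0])
    def test_matches_brute_force_oracle(self, rng, weight):
        """Implementation equals the double-loop definition to 1e-12."""
        for n, set_size in [(10, 3), (50, 7), (200, 20)]:
            values = rng.normal(size=n)
            genes = [f"g{i}" for i in range(n)]
            members = tuple(rng.choice(genes, size=set_size, replace=False))
            gene_set = GeneSet("S", "", members)
            expected = brute_force_es(values, genes, set(members), weight)
            actual = enrichment_score(rank_normalize(values), genes, gene_set, weight)
            assert actual == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_error_carries_overlap(self):
        ranks = rank_normalize([1.0, 2.0])
        with pytest.raises(OverlapError) as excinfo:
            enrichment_score(ranks, ["g0", "g1"], GeneSet("S", "", ("absent",)))
        assert excinfo.value.overlap == 0

    def test_full_coverage_rejected(self):
        ranks = rank_normalize([1.0, 2.0])
        with pytest.raises(OverlapError, match="every"):
            enrichment_score(ranks, ["g0", "g1"], GeneSet("S", "", ("g0", "g1")))


class TestScoreCollection:
    def test_embryonic_signature_peaks_in_dualpos(self, study):
        matrix, annotation = study
        embryonic = GeneSet("embryonic", "", tuple(f"G{i:04d}" for i in range(300, 600)))
        scores = score_collection(matrix, GeneSetCollection([embryonic]))
        row = scores.scores.loc["embryonic"]
        dual = row[annotation.samples_in("dualpos")].mean()
        assert dual > row[annotation.samples_in("typeI")].mean()
        assert dual > row[annotation.samples_in("typeII")].mean()

    def test_typeI_signature_pattern(self, study):
        """The typeI program is planted in typeI and dualpos, not typeII."""
        matrix, annotation = study
        type1 = GeneSet("typeI_program", "", tuple(f"G{i:04d}" for i in range(0, 150)))
        scores = score_collection(matrix, GeneSetCollection([type1]))
        row = scores.scores.loc["typeI_program"]
        assert row[annotation.samples_in("dualpos")].mean() > row[
            annotation.samples_in("typeII")
        ].mean()

    def test_duplicate_set_scores_identically(self, study):
        matrix, _ = study
        genes = tuple(f"G{i:04d}" for i in range(50))
        twin_sets = GeneSetCollection(
            [GeneSet("a", "", genes), GeneSet("b", "", genes)]
        )
        scores = score_collection(matrix, twin_sets).scores
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_column_separability(self, study):
        matrix, _ = study
        sets = GeneSetCollection(
            [GeneSet("S", "", tuple(f"G{i:04d}" for i in range(40)))]
        )
        batch = score_collection(matrix, sets).scores
        for sample in matrix.sample_ids[:3]:
            single = score_sample(matrix, sample, sets)
            assert single["S"] == pytest.approx(batch.loc["S", sample])

    def test_monotone_per_sample_transform_invariance(self, study):
        matrix, _ = study
        sets = GeneSetCollection(
            [GeneSet("S", "", tuple(f"G{i:04d}" for i in range(300, 400)))]
        )
        transformed = ExpressionMatrix(np.exp(matrix.data * 0.3), "log2")
        a = score_collection(matrix, sets).scores
        b = score_collection(transformed, sets).scores
        assert np.allclose(a, b)

    def test_low_overlap_sets_dropped(self, study, caplog):
        matrix, _ = study
        sets = GeneSetCollection(
            [
                GeneSet("ok", "", tuple(f"G{i:04d}" for i in range(20))),
                GeneSet("tiny", "", ("G0000", "absent1", "absent2")),
            ]
        )
        scores = score_collection(matrix, sets, min_overlap=5)
        assert scores.set_names == ["ok"]

    def test_all_sets_dropped_rejected(self, study):
        matrix, _ = study
        sets = GeneSetCollection([GeneSet("absent", "", ("x", "y", "z"))])
        with pytest.raises(ValidationError, match="overlap threshold"):
            score_collection(matrix, sets)
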