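import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungplast.io import ValidationError
from lungplast.quantify import fold_change
from lungplast.simulate import (
    CellPopulationSpec,
    GeneProgram,
    StudyDesign,
    default_study_design,
    dual_positive_spec,
    simulate_cells,
    simulate_ct_table,
    simulate_kras_panel,
    simulate_reference_panels,
    simulate_study,
)


class TestSimulateStudy:
    def test_default_shape_and_groups(self, study):
        matrix, annotation = study
        assert matrix.shape == (2000, 9)
        assert annotation.groups.value_counts().to_dict() == {
            "typeI": 3,
            "typeII": 3,
            "dualpos": 3,
        }

    def test_deterministic_given_seed(self):
        m1, _ = simulate_study(default_study_design(seed=3))
        m2, _ = simulate_study(default_study_design(seed=3))
        assert np.array_equal(m1.values, m2.values)

    def test_seed_sensitivity(self):
        m1, _ = simulate_study(default_study_design(seed=3))
        m2, _ = simulate_study(default_study_design(seed=4))
        assert np.abs(m1.values - m2.values).max() > 0

    def test_null_design_groups_indistinguishable(self):
        """With all effects zero, program means differ only by noise."""
        indices = tuple(range(50))
        exceed = 0
        n_draws = 100
        for seed in range(n_draws):
            program = GeneProgram(
                "null", indices, {"typeI": 0.0, "typeII": 0.0, "dualpos": 0.0}
            )
            design = StudyDesign(n_genes=200, programs=(program,), seed=seed)
            matrix, annotation = simulate_study(design)
            sub = matrix.values[np.asarray(indices)]
            a = sub[:, annotation.indicator("typeI") == 1].mean(axis=0)
            b = sub[:, annotation.indicator("dualpos") == 1].mean(axis=0)
            _, p = stats.ttest_ind(a, b)
            if p <= 0.001:
                exceed += 1
        assert exceed <= 0.01 * n_draws

    def test_dualpos_shares_both_single_positive_programs(self, study):
        """Planted effect signs: dual-positive is up on typeI AND typeII programs."""
        matrix, annotation = study
        design = default_study_design()
        for program in design.programs[:2]:
            sub = matrix.values[np.asarray(program.gene_indices)]
            dual = sub[:, annotation.indicator("dualpos") == 1].mean()
            others = sub[:, annotation.indicator("dualpos") == 0].mean()
            assert dual > others

    def test_bad_program_index_rejected(self):
        program = GeneProgram("p", (5000,), {"typeI": 0, "typeII": 0, "dualpos": 0})
        with pytest.raises(ValidationError, match="outside"):
            StudyDesign(n_genes=100, programs=(program,))


class TestReferencePanels:
    def test_three_panels_with_enough_samples(self, panels):
        assert len(panels) == 3
        for matrix, annotation in panels.values():
            assert matrix.shape[1] >= 6
            assert len(annotation.sample_ids) == matrix.shape[1]

    def test_within_type_correlation_exceeds_between(self, panels):
        for matrix, annotation in panels.values():
            corr = np.corrcoef(matrix.values.T)
            labels = annotation.groups.to_numpy()
            same = labels[:, None] == labels[None, :]
            off_diag = ~np.eye(len(labels), dtype=bool)
            assert corr[same & off_diag].mean() > corr[~same].mean()

    def test_seed_changes_matrices(self):
        a = simulate_reference_panels(seed=1)
        b = simulate_reference_panels(seed=2)
        name = next(iter(a))
        assert np.abs(a[name][0].values - b[name][0].values).max() > 0


class TestKrasPanel:
    def test_default_module_size(self, kras_panel):
        assert len(kras_panel.module) == 1000
        assert kras_panel.matrix.scale_tag == "raw"
        assert (kras_panel.matrix.values >= 0).all()

    def test_zero_noise_is_exactly_low_rank(self):
        panel = simulate_kras_panel(
            n_cell_lines=12, module_size=30, n_states=3, n_genes=60, noise_sd=0.0, seed=5
        )
        module_values = panel.matrix.subset_genes(list(panel.module.genes)).values
        reconstruction = panel.W_true.to_numpy() @ panel.H_true.to_numpy()
        assert np.allclose(module_values, reconstruction, atol=1e-12)

    def test_module_size_validation(self):
        with pytest.raises(ValidationError, match="exceed"):
            simulate_kras_panel(module_size=5000, n_genes=2000)
        with pytest.raises(ValidationError, match=">= 10"):
            simulate_kras_panel(module_size=5)


class TestSimulateCells:
    def test_label_counts_near_fractions(self):
        spec = CellPopulationSpec(
            n_cells=1000,
            fractions={"typeI": 0.5, "typeII": 0.5},
            marker_means={"typeI": {"m": 5.0}, "typeII": {"m": 1.0}},
            seed=1,
        )
        counts = simulate_cells(spec)["true_label"].value_counts()
        lo, hi = stats.binom.interval(0.999, 1000, 0.5)
        assert lo <= counts["typeI"] <= hi

    def test_degenerate_fraction(self):
        spec = CellPopulationSpec(
            n_cells=50,
            fractions={"dualpos": 1.0},
            marker_means={"dualpos": {"m": 5.0}},
            seed=1,
        )
        assert (simulate_cells(spec)["true_label"] == "dualpos").all()

    def test_deterministic(self):
        spec = dual_positive_spec(0.1, n_cells=500, seed=9)
        pd.testing.assert_frame_equal(simulate_cells(spec), simulate_cells(spec))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            CellPopulationSpec(
                n_cells=10,
                fractions={"a": 0.5, "b": 0.6},
                marker_means={"a": {"m": 1.0}, "b": {"m": 2.0}},
            )

    def test_zero_cells_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            CellPopulationSpec(
                n_cells=0, fractions={"a": 1.0}, marker_means={"a": {"m": 1.0}}
            )


class TestSimulateCT:
    def test_noiseless_inversion_is_exact(self):
        table = simulate_ct_table({"Rage": 4.0, "Aqp5": 1.0}, noise_sd=0.0)
        assert fold_change(table, "Rage") == pytest.approx(4.0, abs=1e-12)
        assert fold_change(table, "Aqp5") == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_monte_carlo(self):
        """log2 fold change recovered within 0.15 at sd 0.1, 50 replicates."""
        recovered = []
        for seed in range(50):
            table = simulate_ct_table({"g": 4.0}, noise_sd=0.1, seed=seed)
            recovered.append(np.log2(fold_change(table, "g")))
        assert abs(np.mean(recovered) - 2.0) < 0.15

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            simulate_ct_table({"g": 0.0})
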