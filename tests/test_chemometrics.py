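import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import ramanclass as rc
from ramanclass.chemometrics import (
    ConfusionMatrix,
    classification_efficiency,
    fit_lda,
    fit_pca,
    fit_pclda,
    group_size_factor_cap,
    lda_predict,
    loocv,
    predict,
    project,
    select_significant_pcs,
)


def _set_from_matrix(X, labels, axis=None):
    axis = axis if axis is not None else 700.0 + np.arange(X.shape[1])
    spectra = [
        rc.Spectrum(axis, X[i], meta={"group": str(g), "spectrum_id": f"s{i}"})
        for i, g in enumerate(labels)
    ]
    return rc.SpectrumSet(spectra, common_axis=axis)


class TestPCA:
    def test_identical_spectra_have_zero_variance(self):
        X = np.tile(np.sin(np.arange(20.0)), (3, 1))
        model = fit_pca(_set_from_matrix(X, ["a", "a", "b"]), n_factors=2)
        assert np.all(model.explained_variance < 1e-20)

    def test_rank_two_data_has_two_components(self):
        rng = np.random.default_rng(0)
        u = np.zeros(30); u[0] = 1.0
        v = np.zeros(30); v[1] = 1.0
        X = np.outer(rng.normal(size=12), u) + np.outer(rng.normal(size=12), v)
        model = fit_pca(_set_from_matrix(X, list("ab" * 6)), n_factors=5)
        total = model.explained_variance.sum()
        assert model.explained_variance[2:].sum() < 1e-10 * total

    def test_total_variance_conserved_and_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 40))
        sset = _set_from_matrix(X, list("ab" * 5))
        model = fit_pca(sset, n_factors=9)  # full rank: n-1 components
        total = np.sum((X - X.mean(0)) ** 2) / (X.shape[0] - 1)
        assert abs(model.explained_variance.sum() - total) < 1e-8 * total
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_full_reconstruction_recovers_centred_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 25))
        sset = _set_from_matrix(X, list("ab" * 4))
        model = fit_pca(sset, n_factors=7)
        scores = project(model, X)
        recon = scores @ model.loadings + model.mean_vector
        assert np.linalg.norm(recon - X) < 1e-8 * np.linalg.norm(X)

    def test_factor_bound_enforced_with_message(self):
        X = np.random.default_rng(0).normal(size=(5, 30))
        with pytest.raises(ValueError, match=r"\[1, 4\]"):
            fit_pca(_set_from_matrix(X, list("aabbb")), n_factors=10)


class TestFactorCap:
    @pytest.mark.parametrize(
        "sizes,expected",
        [([17, 16, 16, 16, 20, 19, 18, 22], 7), ([45, 45], 22), ([4], 1)],
    )
    def test_cap_is_largest_integer_below_half_smallest_group(self, sizes, expected):
        assert group_size_factor_cap(sizes) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_size_factor_cap([])


class TestSelectSignificantPCs:
    def test_constant_factor_excluded(self):
        rng = np.random.default_rng(0)
        scores = np.column_stack([np.ones(40), rng.normal(size=40)])
        labels = ["a"] * 20 + ["b"] * 20
        sel = select_significant_pcs(scores, labels, alpha=0.05, cap=5)
        assert 0 not in sel.selected_indices
        assert sel.p_values[0] > 0.9

    def test_strongly_separated_factor_included(self):
        rng = np.random.default_rng(1)
        f = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        scores = np.column_stack([rng.normal(size=40), f])
        sel = select_significant_pcs(scores, ["a"] * 20 + ["b"] * 20, cap=5)
        assert 1 in sel.selected_indices
        assert sel.p_values[1] < 1e-6

    def test_cap_keeps_smallest_p_first_sorted_ascending(self):
        rng = np.random.default_rng(2)
        n = 40
        labels = ["a"] * 20 + ["b"] * 20
        shift = np.array([0.0] * 20 + [1.0] * 20)
        # 9 factors with decreasing effect size -> increasing p-value
        cols = [rng.normal(size=n) + shift * (9 - j) for j in range(9)]
        sel = select_significant_pcs(np.column_stack(cols), labels, cap=5)
        assert len(sel.selected_indices) == 5
        assert sel.selected_indices == sorted(sel.selected_indices)
        # the retained ones are those with the smallest p-values
        kept_p = sel.p_values[sel.selected_indices]
        dropped = [j for j in range(9) if j not in sel.selected_indices]
        assert kept_p.max() <= sel.p_values[dropped].min() + 1e-12

    def test_group_with_single_spectrum_rejected(self):
        scores = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            select_significant_pcs(scores, ["a", "a", "a", "a", "b"])


class TestPCLDA:
    def test_separated_two_class_training_is_perfect(self):
        sset, _ = rc.simulate_two_class_study(
            rc.SimConfig(seed=5, n_spectra_per_group=20), delta_in_noise_units=10.0
        )
        proc = rc.classification_pipeline(sset, rc.PreprocessConfig())
        model = fit_pclda(proc)
        _, cm = predict(model, proc, kind="training")
        np.testing.assert_array_equal(np.diag(cm.counts), [20, 20])

    def test_duplicated_group_under_two_labels_is_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 30))
        X2 = X + rng.normal(0, 1e-3, X.shape)  # same distribution, two labels
        sset = _set_from_matrix(np.vstack([X, X2]), ["a"] * 15 + ["b"] * 15)
        model = fit_pclda(sset, n_pca_factors=5)
        _, cm = predict(model, sset, kind="training")
        eff = classification_efficiency(cm)["overall"]
        assert eff < 85.0  # indistinguishable classes cannot classify well

    def test_eight_group_model_dimensionality(self):
        cfg = rc.SimConfig(seed=2, n_spectra_per_group=8)
        sset, _ = rc.simulate_cell_study(cfg)
        proc = rc.classification_pipeline(sset, rc.PreprocessConfig())
        model = fit_pclda(proc)
        assert len(model.class_labels) == 8
        assert model.lda.discriminant_axes.shape[0] <= 7
        assert len(model.selection.selected_indices) <= group_size_factor_cap([8] * 8)

    def test_training_spectrum_repredicted_identically(self, toy_processed):
        model = fit_pclda(toy_processed)
        labels_all, _ = predict(model, toy_processed, kind="training")
        one = toy_processed.subset([0])
        labels_one, _ = predict(model, one)
        assert labels_one[0] == labels_all[0]

    def test_class_mean_spectrum_assigned_to_its_class(self, toy_processed):
        model = fit_pclda(toy_processed)
        X = toy_processed.matrix()
        labels = np.array(toy_processed.labels)
        for g in toy_processed.groups:
            mean_spec = X[labels == g].mean(axis=0)
            scores = project(model.pca, mean_spec[None, :])
            pred = lda_predict(model.lda, scores[:, model.selection.selected_indices])
            assert pred[0] == g

    def test_axis_mismatch_names_expected_grid(self, toy_processed):
        model = fit_pclda(toy_processed)
        sset, _ = rc.simulate_two_class_study(
            rc.SimConfig(seed=9, n_spectra_per_group=3, region="high_wavenumber")
        )
        wrong = rc.classification_pipeline(
            sset, rc.PreprocessConfig(region="high_wavenumber")
        )
        with pytest.raises(ValueError, match="axis mismatch"):
            predict(model, wrong)

    def test_serialization_round_trip_predicts_identically(self, toy_processed, tmp_path):
        model = fit_pclda(toy_processed)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = rc.PCLDAModel.from_json(path)
        p1, _ = predict(model, toy_processed)
        p2, _ = predict(back, toy_processed)
        assert p1 == p2

    def test_agrees_with_sklearn_lda_on_selected_scores(self, toy_processed):
        model = fit_pclda(toy_processed)
        scores = project(model.pca, toy_processed.matrix())
        sel = scores[:, model.selection.selected_indices]
        labels = np.array(toy_processed.labels)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(sel, labels)
        ours = lda_predict(model.lda, sel)
        assert list(sk.predict(sel)) == ours


class TestLOOCV:
    def test_matches_naive_refit_loop_exactly(self, toy_processed):
        cm = loocv(toy_processed)
        # independent naive loop: refit + single prediction per fold
        n = len(toy_processed)
        pred, true = [], []
        for i in range(n):
            train = toy_processed.subset([j for j in range(n) if j != i])
            model = fit_pclda(train)
            held = toy_processed.subset([i])
            p, _ = predict(model, held)
            pred.append(p[0])
            true.append(held.spectra[0].group)
        naive = ConfusionMatrix.from_labels(true, pred, toy_processed.groups, kind="loocv")
        np.testing.assert_array_equal(cm.counts, naive.counts)
        assert cm.labels == naive.labels

    def test_row_sums_equal_group_sizes(self, two_class_processed):
        cm = loocv(two_class_processed)
        sizes = two_class_processed.group_sizes()
        for label, rs in zip(cm.labels, cm.row_sums):
            assert rs == sizes[label]

    def test_efficiency_nondecreasing_in_effect_size(self):
        # median LOOCV efficiency must not fall as the class band shift grows
        deltas = [1.0, 4.0, 10.0]
        medians = []
        for d in deltas:
            effs = []
            for seed in range(3):
                sset, _ = rc.simulate_two_class_study(
                    rc.SimConfig(seed=seed, n_spectra_per_group=10), delta_in_noise_units=d
                )
                proc = rc.classification_pipeline(sset, rc.PreprocessConfig())
                effs.append(classification_efficiency(loocv(proc))["overall"])
            medians.append(np.median(effs))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9


class TestConfusionMatrixEfficiency:
    def test_printed_standard_model_matrix_arithmetic(self):
        # 8-group standard-model confusion matrix as published
        counts = np.array(
            [
                [17, 0, 0, 0, 0, 0, 0, 0],
                [0, 16, 0, 0, 0, 0, 0, 0],
                [0, 0, 16, 0, 0, 0, 0, 0],
                [1, 0, 0, 14, 0, 1, 0, 0],
                [0, 0, 0, 0, 20, 0, 0, 0],
                [0, 0, 0, 1, 0, 18, 0, 0],
                [0, 0, 0, 0, 0, 0, 18, 0],
                [0, 0, 0, 5, 0, 0, 1, 16],
            ]
        )
        cm = ConfusionMatrix(labels=list("ABCDEFGH"), counts=counts)
        eff = classification_efficiency(cm)
        assert cm.total == 144
        assert eff["overall"] == pytest.approx(100 * 135 / 144)

    def test_identity_matrix_is_100_percent(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.diag([5, 9]))
        eff = classification_efficiency(cm)
        assert eff["overall"] == 100.0
        assert all(v == 100.0 for v in eff["per_group"].values())

    def test_two_group_tissue_matrix_arithmetic(self):
        cm = ConfusionMatrix(labels=["resp", "nonresp"], counts=np.array([[34, 11], [3, 42]]))
        eff = classification_efficiency(cm)
        assert eff["overall"] == pytest.approx(100 * 76 / 90)
        assert eff["per_group"]["resp"] == pytest.approx(100 * 34 / 45)
        assert eff["per_group"]["nonresp"] == pytest.approx(100 * 42 / 45)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(labels=["a", "b"], counts=np.array([[1, -1], [0, 2]]))


class TestLDAUnit:
    def test_two_gaussians_separated_along_one_axis(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 1.0, size=(50, 2))
        b = rng.normal([6, 0], 1.0, size=(50, 2))
        model = fit_lda(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50)
        pred = lda_predict(model, np.array([[0.5, 0.0], [5.5, 0.0]]))
        assert pred == ["a", "b"]
        assert model.discriminant_axes.shape == (1, 2)
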