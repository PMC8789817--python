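"""Voxel-wise encoding, split-half veRSA, noise ceiling, cv max layer."""
import numpy as np
import pytest

import ipclbrain as ib
from ipclbrain.errors import AlignmentError, ConfigurationError, InputError


def make_world(n_cond=20, n_units=10, n_subjects=6, n_voxels=50, noise_sd=0.6,
               seed=0, n_layers=4, planted=1):
    """Random feature layers with voxels generated from one of them."""
    rng = np.random.default_rng(seed)
    layers = [
        ib.LayerActivations(f"layer{i}", rng.normal(size=(n_cond, n_units + 2 * i)))
        for i in range(n_layers)
    ]
    res = ib.generate_synthetic_subjects(
        ib.SyntheticSubjectSpec(
            generating_features=layers[planted],
            n_subjects=n_subjects,
            n_voxels_per_subject=n_voxels,
            noise_sd=noise_sd,
            seed=seed + 1,
        )
    )
    return layers, res


class TestSplitEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 3), (7, 35), (10, 126)])
    def test_counts(self, n, expected):
        scheme = ib.enumerate_split_halves(n)
        assert scheme.n_splits == expected

    def test_each_subject_once_per_split(self):
        scheme = ib.enumerate_split_halves(7)
        for a, b in scheme.splits:
            assert sorted(a + b) == list(range(7))
            assert len(a) == 3 and len(b) == 4

    def test_subsampling_is_capped_seeded_and_duplicate_free(self):
        scheme = ib.enumerate_split_halves(12, max_splits=50, seed=3)
        assert scheme.n_splits == 50
        keys = {frozenset(a) for a, _ in scheme.splits}
        assert len(keys) == 50
        again = ib.enumerate_split_halves(12, max_splits=50, seed=3)
        assert again.splits == scheme.splits

    def test_single_subject_rejected(self):
        with pytest.raises(InputError):
            ib.enumerate_split_halves(1)


class TestVoxelEncoding:
    def test_noiseless_single_unit_voxel_recovered_in_small_lambda_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 8))  # fewer units than conditions: OLS limit exact
        y = x[:, [2]] * 1.7 + 0.3
        subject = ib.SubjectVoxelData("s", y, [str(i) for i in range(20)])
        fit = ib.fit_voxel_encoding_loo(x, subject, lambda_grid=[1e-8])
        np.testing.assert_allclose(fit.predicted, y, rtol=1e-4)

    def test_single_lambda_matches_refit_per_fold_oracle(self):
        """Dual-space solver vs explicit closed-form primal ridge per fold."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 50))
        y = rng.normal(size=(20, 30))
        subject = ib.SubjectVoxelData("s", y, [str(i) for i in range(20)])
        lam = 2.5
        fit = ib.fit_voxel_encoding_loo(x, subject, lambda_grid=[lam])
        oracle = np.empty_like(y)
        for c in range(20):
            tr = np.delete(np.arange(20), c)
            mu, sd = x[tr].mean(0), x[tr].std(0)
            sd[sd < 1e-12] = 1.0
            xs, xt = (x[tr] - mu) / sd, (x[c] - mu) / sd
            ym = y[tr].mean(0)
            w = np.linalg.solve(xs.T @ xs + lam * np.eye(50), xs.T @ (y[tr] - ym))
            oracle[c] = xt @ w + ym
        np.testing.assert_allclose(fit.predicted, oracle, atol=1e-8)

    def test_pure_noise_prediction_has_no_positive_predictivity(self):
        """With noise voxels and noise features the cross-validated
        predictions carry no spurious positive signal. (Shrinkage toward the
        training-fold mean makes held-out correlations slightly negative, a
        generic leave-one-out property, so the check is one-sided.)"""
        rs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(18, 12))
            y = rng.normal(size=(18, 10))
            subject = ib.SubjectVoxelData("s", y, [str(i) for i in range(18)])
            fit = ib.fit_voxel_encoding_loo(x, subject)
            for v in range(10):
                rs.append(np.corrcoef(fit.predicted[:, v], y[:, v])[0, 1])
        assert np.mean(rs) < 0.05

    def test_leakage_guard_held_out_response_never_affects_prediction(self):
        """Mutating the held-out condition's measured response must not change
        its prediction (the fit excluded it)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 6))
        y = rng.normal(size=(12, 4))
        base = ib.fit_voxel_encoding_loo(
            x, ib.SubjectVoxelData("s", y, [str(i) for i in range(12)]))
        y_mut = y.copy()
        y_mut[5] = 0.0
        mut = ib.fit_voxel_encoding_loo(
            x, ib.SubjectVoxelData("s", y_mut, [str(i) for i in range(12)]))
        np.testing.assert_allclose(base.predicted[5], mut.predicted[5], atol=1e-10)

    def test_lambda_selected_per_voxel_from_grid(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 8))
        y = np.column_stack([x[:, 0], rng.normal(size=15)])  # clean + noise voxel
        fit = ib.fit_voxel_encoding_loo(
            x, ib.SubjectVoxelData("s", y, [str(i) for i in range(15)]))
        assert set(np.unique(fit.lambdas)) <= set(np.asarray(ib.versa.DEFAULT_LAMBDA_GRID))
        # the pure-noise voxel should prefer heavier shrinkage on most folds
        assert np.median(fit.lambdas[:, 1]) >= np.median(fit.lambdas[:, 0])

    def test_invalid_grid_and_conditions(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        s = ib.SubjectVoxelData("s", np.random.default_rng(1).normal(size=(5, 2)),
                                list("abcde"))
        with pytest.raises(ConfigurationError):
            ib.fit_voxel_encoding_loo(x, s, lambda_grid=[])
        with pytest.raises(ConfigurationError):
            ib.fit_voxel_encoding_loo(x, s, lambda_grid=[0.0, 1.0])
        with pytest.raises(AlignmentError):
            ib.fit_voxel_encoding_loo(x[:4], s)


class TestModelPredictedRdm:
    def test_composition_equals_rdm_of_predictions(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=(10, 8))
        fit = ib.fit_voxel_encoding_loo(
            x, ib.SubjectVoxelData("s", y, [str(i) for i in range(10)]))
        rdm = ib.model_predicted_rdm(fit)
        np.testing.assert_allclose(
            rdm.matrix, ib.compute_rdm(fit.predicted).matrix, atol=1e-12)

    def test_identical_predicted_rows_have_zero_distance(self):
        pred = np.random.default_rng(5).normal(size=(6, 7))
        pred[3] = pred[1]
        fit = ib.EncodingFit(predicted=pred, lambdas=np.ones((6, 7)),
                             condition_ids=[str(i) for i in range(6)])
        assert ib.model_predicted_rdm(fit).matrix[1, 3] == pytest.approx(0, abs=1e-12)


class TestVersaCurve:
    def test_noise_free_planted_layer_reaches_one(self):
        layers, res = make_world(noise_sd=0.0, n_subjects=4, seed=10)
        vr = ib.versa_curve(layers[1:2], res.subjects)
        assert vr.curve["layer1"].mean_r == pytest.approx(1.0, abs=1e-4)

    def test_planted_layer_peaks_at_moderate_noise(self):
        layers, res = make_world(noise_sd=0.8, n_subjects=6, seed=11)
        vr = ib.versa_curve(layers, res.subjects)
        means = {k: v.mean_r for k, v in vr.curve.items()}
        assert max(means, key=means.get) == "layer1"

    def test_permutation_null_near_zero(self):
        """Permuting the brain RDMs' condition labels after fitting destroys
        the model-brain correspondence: split-half correlations average ~0."""
        layers, res = make_world(noise_sd=0.5, n_subjects=4, seed=12, n_layers=1,
                                 planted=0)
        scheme = ib.enumerate_split_halves(4)
        pred = ib.versa.predicted_rdms_per_subject(layers[0], res.subjects)
        subj_rdms = ib.brain_rdms(res.subjects)
        rng = np.random.default_rng(0)
        rs = []
        for rep in range(25):
            perm = rng.permutation(20)
            shuffled = [
                ib.RDM(matrix=r.matrix[np.ix_(perm, perm)],
                       condition_ids=r.condition_ids)
                for r in subj_rdms
            ]
            for half_a, half_b in scheme.splits:
                for half in (half_a, half_b):
                    g_hat = ib.mean_rdm([pred[s] for s in half])
                    g = ib.mean_rdm([shuffled[s] for s in half])
                    rs.append(ib.rdm_correlation(g_hat, g))
        assert abs(np.mean(rs)) < 0.05

    def test_invertible_unit_mixing_preserves_versa_correlation(self):
        """veRSA depends on the feature span, not the unit basis."""
        layers, res = make_world(noise_sd=0.5, n_subjects=4, seed=13, n_layers=2)
        base = layers[1].matrix
        rng = np.random.default_rng(1)
        mix = rng.normal(size=(base.shape[1], base.shape[1]))
        mixed = ib.LayerActivations("layer1", base @ mix)
        grid = [1e-8]  # tiny ridge so both solve the same least-squares limit
        r_base = ib.versa_curve([layers[1]], res.subjects,
                                lambda_grid=grid).curve["layer1"].mean_r
        r_mixed = ib.versa_curve([mixed], res.subjects,
                                 lambda_grid=grid).curve["layer1"].mean_r
        assert r_mixed == pytest.approx(r_base, abs=1e-4)

    def test_versa_at_least_classic_at_generating_layer(self):
        """Voxel mixing distorts raw-feature geometry; the encoding model
        re-weights units and recovers it, so veRSA >= classic RSA there.
        Sizes follow the condition-rich regime (40 conditions, hundreds of
        voxels per sector, split-half ceiling around 0.8)."""
        rng = np.random.default_rng(14)
        gen = ib.LayerActivations("gen", rng.normal(size=(40, 12)))
        res = ib.generate_synthetic_subjects(ib.SyntheticSubjectSpec(
            generating_features=gen, n_subjects=6, n_voxels_per_subject=200,
            noise_sd=1.0, seed=114))
        scheme = ib.enumerate_split_halves(6)
        vr = ib.versa_curve([gen], res.subjects, scheme)
        classic = ib.classic_rsa_curve([gen], ib.brain_rdms(res.subjects), scheme)
        assert vr.curve["gen"].mean_r >= classic["gen"].mean_r


class TestNoiseCeiling:
    def test_identical_subjects_reach_one(self):
        rng = np.random.default_rng(6)
        resp = rng.normal(size=(10, 12))
        subs = [ib.SubjectVoxelData(f"s{i}", resp, [str(c) for c in range(10)])
                for i in range(4)]
        assert ib.noise_ceiling(subs).mean_r == pytest.approx(1.0, abs=1e-5)

    def test_anticorrelated_subjects_report_negative_ceiling_unclipped(self):
        # subject A: conditions {0,1} alike and {2,3} alike; subject B pairs
        # them the other way, so the two RDM lower triangles anti-correlate
        rng = np.random.default_rng(7)
        u, v, u2, v2 = rng.normal(size=(4, 10))
        ids = list("abcd")
        a = ib.SubjectVoxelData("a", np.stack([u, u, v, v]), ids)
        b = ib.SubjectVoxelData("b", np.stack([u2, v2, u2, v2]), ids)
        result = ib.noise_ceiling([a, b])
        assert result.mean_r < -0.3  # negative, reported as-is

    def test_single_subject_rejected(self):
        s = ib.SubjectVoxelData("a", np.random.default_rng(0).normal(size=(5, 4)),
                                list("abcde"))
        with pytest.raises(InputError):
            ib.noise_ceiling([s])

    def test_calibrated_estimate_covers_monte_carlo_truth(self):
        """Replicate worlds share one planted voxel model (weight_seed) and
        draw fresh subject noise at a ~0.8-consistency setting; the adjusted
        95% CI covers the Monte-Carlo truth in at least 90% of 20 worlds."""
        rng = np.random.default_rng(8)
        gen = rng.normal(size=(18, 10))
        spec = dict(generating_features=gen, n_subjects=8,
                    n_voxels_per_subject=50, noise_sd=0.6, weight_seed=99)
        truth = np.mean([
            ib.noise_ceiling(ib.generate_synthetic_subjects(
                ib.SyntheticSubjectSpec(**spec, seed=1000 + i)).subjects).mean_r
            for i in range(30)
        ])
        covered = 0
        for i in range(20):
            res = ib.generate_synthetic_subjects(
                ib.SyntheticSubjectSpec(**spec, seed=2000 + i))
            nc = ib.noise_ceiling(res.subjects)
            covered += nc.ci_low <= truth <= nc.ci_high
        assert covered >= 18


class TestCvMaxLayer:
    def test_single_layer_equals_that_layers_mean(self):
        layers, res = make_world(noise_sd=0.5, n_subjects=4, seed=20, n_layers=1,
                                 planted=0)
        vr = ib.versa_curve(layers, res.subjects)
        cv = ib.cv_max_layer(vr.split_correlations, vr.scheme, vr.layer_names)
        assert cv.result.mean_r == pytest.approx(vr.curve["layer0"].mean_r, abs=1e-9)

    def test_planted_layer_selected_in_majority_of_splits(self):
        layers, res = make_world(noise_sd=0.6, n_subjects=8, seed=21)
        vr = ib.versa_curve(layers, res.subjects)
        cv = ib.cv_max_layer(vr.split_correlations, vr.scheme, vr.layer_names)
        assert cv.selection_fraction("layer1") > 0.5

    def test_selection_ties_break_toward_earlier_layer(self):
        scheme = ib.SplitScheme(n_subjects=4, splits=[((0, 1), (2, 3))])
        r = np.array([[[0.5, 0.2]], [[0.5, 0.9]]])  # layers x splits x halves
        cv = ib.cv_max_layer(r, scheme, ["early", "late"])
        # selection on half 0 ties at 0.5 -> earlier layer chosen, evaluated on
        # half 1 giving 0.2; selection on half 1 picks 'late' (0.9) -> eval 0.5
        np.testing.assert_array_equal(cv.selected, [[0, 1]])
        assert cv.result.per_split_r.tolist() == [0.2, 0.5]

    def test_cv_max_not_above_plain_max_on_null_data(self):
        """Cross-validated selection removes the optimistic bias of taking the
        max over layers on the same data."""
        rng = np.random.default_rng(22)
        scheme = ib.enumerate_split_halves(8)
        diffs = []
        for _ in range(50):
            r = rng.normal(0.0, 0.2, size=(6, scheme.n_splits, 2))
            cv = ib.cv_max_layer(r, scheme, [f"l{i}" for i in range(6)])
            plain_max = max(ib.fisher_mean(r[li].ravel()) for li in range(6))
            diffs.append(plain_max - cv.result.mean_r)
        assert np.mean(diffs) > 0

    def test_layer_mismatch_raises(self):
        scheme = ib.SplitScheme(n_subjects=4, splits=[((0, 1), (2, 3))])
        with pytest.raises(AlignmentError):
            ib.cv_max_layer(np.zeros((2, 1, 2)), scheme, ["only_one"])


class TestExplainedProportion:
    def make(self, r):
        return ib.summarize_correlations([r, r, r + 1e-6], correction_ratio=1.0)

    def test_equal_model_and_ceiling_is_100(self):
        assert ib.explained_proportion(self.make(0.7), self.make(0.7)) == pytest.approx(
            100.0, abs=1e-3)

    def test_zero_model_is_zero(self):
        assert ib.explained_proportion(self.make(0.0), self.make(0.9)) == pytest.approx(
            0.0, abs=1e-3)

    def test_ratio_reading_of_published_style_numbers(self):
        assert ib.explained_proportion(self.make(0.79), self.make(0.90)) == pytest.approx(
            87.8, abs=0.2)

    def test_squared_flag(self):
        val = ib.explained_proportion(self.make(0.6), self.make(0.8), squared=True)
        assert val == pytest.approx(100 * 0.5625, abs=0.1)

    def test_nonpositive_ceiling_rejected(self):
        with pytest.raises(InputError):
            ib.explained_proportion(self.make(0.5), self.make(-0.2))


def test_subsample_units_seeded_and_capped():
    acts = ib.LayerActivations("wide", np.random.default_rng(0).normal(size=(6, 100)))
    a = ib.subsample_units(acts, 20, seed=1)
    b = ib.subsample_units(acts, 20, seed=1)
    assert a.unit_count == 20
    np.testing.assert_array_equal(a.matrix, b.matrix)
    assert ib.subsample_units(acts, 200, seed=1).unit_count == 100
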