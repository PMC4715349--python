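import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svarbiter.core import AnnotationTable
from svarbiter.oneclass import (
    DEFAULT_NU_GRID,
    L1OneClassResults,
    SVMOneClassModel,
    TABLE_STRATA,
    default_directions,
    ensemble_rho,
    ensemble_vote,
    fit_l1_model,
    fit_svm_model,
    prefilter_sites,
    roc_curve,
    stratify,
)
from svarbiter.transform import TransformModel, fit_transform_model


def table(arr, columns=None):
    arr = np.asarray(arr, dtype=float)
    cols = columns or [f"a{i}" for i in range(arr.shape[1])]
    return AnnotationTable(
        pd.DataFrame(arr, columns=cols, index=[f"s{i}" for i in range(len(arr))])
    )


def toy_l1(train_distances, n_annotations=2):
    """Results object with prescribed training distances (identity transform)."""
    names = [f"a{i}" for i in range(n_annotations)]
    tm = TransformModel(
        pd.Series(0.0, index=names), pd.Series(1.0, index=names)
    )
    return L1OneClassResults(
        mean=pd.Series(0.0, index=names),
        train_distances=np.sort(np.asarray(train_distances, dtype=float)),
        transform=tm,
    )


def gaussian_training(n=400, d=5, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return table(rng.normal(loc=50, scale=scale, size=(n, d)))


class TestFitL1Model:
    def test_identical_rows_all_distances_zero(self):
        t = table(np.tile([3.0, 4.0, 5.0], (120, 1)))
        # identical rows make every column constant; supply a transform so
        # the fit is well-defined on this degenerate input
        names = ["a0", "a1", "a2"]
        tm = TransformModel(pd.Series(0.0, index=names), pd.Series(1.0, index=names))
        model = fit_l1_model(t, transform=tm)
        assert np.all(model.train_distances < 1e-12)

    def test_centroid_matches_bruteforce_column_means(self):
        t = gaussian_training()
        model = fit_l1_model(t)
        from svarbiter.transform import apply_transform

        z = apply_transform(model.transform, t).values.to_numpy()
        assert np.allclose(model.mean.to_numpy(), z.mean(axis=0), atol=1e-12)

    def test_row_order_invariant(self):
        t = gaussian_training()
        shuffled = AnnotationTable(t.values.sample(frac=1, random_state=1))
        a = fit_l1_model(t, transform=fit_transform_model(t))
        b = fit_l1_model(shuffled, transform=fit_transform_model(t))
        assert np.allclose(a.train_distances, b.train_distances)
        assert np.allclose(a.mean.to_numpy(), b.mean.to_numpy())

    def test_small_training_rejected_unless_overridden(self):
        t = gaussian_training(n=50)
        with pytest.raises(ValueError):
            fit_l1_model(t)
        assert fit_l1_model(t, min_train=50).n_train == 50


class TestRhoScore:
    def test_site_at_centroid_scores_zero(self):
        m = toy_l1([1, 2, 3, 4])
        assert m.rho(np.zeros((1, 2)))[0] == 0.0

    def test_count_oracle(self):
        m = toy_l1([1, 2, 3, 4], n_annotations=1)
        # site vector with |x| = 2.5 -> two training distances strictly below
        assert m.rho(np.array([[2.5]]))[0] == pytest.approx(0.5)

    def test_beyond_all_training_scores_one(self):
        m = toy_l1([1, 2, 3, 4], n_annotations=1)
        assert m.rho(np.array([[99.0]]))[0] == 1.0


class TestClassifyL1:
    def test_training_self_coverage_is_ceiling_rule(self):
        t = gaussian_training(n=400)
        model = fit_l1_model(t)
        for p in (0.9, 0.95, 0.99):
            non_sv = (~model.classify(t, p)).sum()
            assert non_sv == math.ceil(p * 400)

    def test_tie_with_threshold_is_non_sv(self):
        m = toy_l1([1, 2, 3, 4], n_annotations=1)
        t_p = m.threshold(0.5)  # = 2
        assert t_p == 2.0
        assert not m.classify(np.array([[2.0]]), 0.5)[0]   # d == t_p: non-SV
        assert m.classify(np.array([[2.0001]]), 0.5)[0]

    def test_monotone_in_p(self):
        t = gaussian_training(n=300)
        model = fit_l1_model(t)
        rng = np.random.default_rng(7)
        x = table(rng.normal(loc=50, scale=25, size=(50, 5)))
        grid = [0.5, 0.8, 0.9, 0.95, 0.99]
        calls = np.column_stack([model.classify(x, p) for p in grid])
        # SV at p implies SV at all smaller p: no 0 -> 1 transitions rightward
        for row in calls:
            assert all(row[i] or not row[i + 1] for i in range(len(grid) - 1))


class TestSvmModel:
    def test_directional_ecdf_transform(self):
        t = gaussian_training(n=201, d=1, seed=3)
        model = SVMOneClassModel(t, {"a0": "low_is_deviant"})
        res = model.fit()
        u = model._ecdf_transform(
            model._deviations(t), res.train_deviations
        ).to_numpy()
        # the training median sits near u = 0.5
        med_idx = np.argsort(t.values["a0"].to_numpy())[100]
        assert u[med_idx, 0] == pytest.approx(0.5, abs=0.01)
        # the most deviant (lowest) training value maps to the minimum u = 1/n
        lo_idx = np.argmin(t.values["a0"].to_numpy())
        assert u[lo_idx, 0] == pytest.approx(1 / 201, abs=1e-9)
        assert u.min() > 0 and u.max() <= 1.0

    def test_nu_controls_training_outlier_fraction(self):
        t = gaussian_training(n=400, d=4, seed=4)
        res = fit_svm_model(t)
        inside = res.inside(t)
        for j, nu in enumerate(res.nu_grid):
            frac_out = 1 - inside[:, j].mean()
            assert frac_out <= nu + 0.02

    def test_score_extremes_and_grid_scan_consistency(self):
        t = gaussian_training(n=300, d=3, seed=5)
        res = fit_svm_model(t)
        # directions default to high_is_deviant, so a site below the training
        # minimum is maximally benign (u = 1 per annotation): inside every
        # boundary, score at the grid floor; a site far above is outside all
        benign = table(np.full((1, 3), -1e4), columns=t.annotation_names)
        outlier = table(np.full((1, 3), 1e4), columns=t.annotation_names)
        tnr = 1 - np.asarray(res.nu_grid)
        assert res.score(benign)[0] == pytest.approx(tnr.min())  # inside all
        assert res.score(outlier)[0] == 1.0                      # outside all
        # score equals exhaustive per-nu membership evaluation
        rng = np.random.default_rng(6)
        x = table(rng.normal(50, 30, size=(40, 3)), columns=t.annotation_names)
        ins = res.inside(x)
        scores = res.score(x)
        for i in range(40):
            expect = tnr[ins[i]].min() if ins[i].any() else 1.0
            assert scores[i] == pytest.approx(expect)

    def test_invalid_nu_rejected(self):
        t = gaussian_training(n=120)
        with pytest.raises(ValueError):
            SVMOneClassModel(t, nu_grid=(0.1, 1.5))

    def test_default_directions_by_name(self):
        d = default_directions(["M_Cov", "L_SoftClip", "M_DelMinusIns", "ds__R_InsertSD"])
        assert d["M_Cov"] == "low_is_deviant"
        assert d["L_SoftClip"] == "high_is_deviant"
        assert d["M_DelMinusIns"] == "two_sided"
        assert d["ds__R_InsertSD"] == "high_is_deviant"


class TestEnsemble:
    @pytest.mark.parametrize(
        "votes, k, expected",
        [
            ([True, True, True, False], 3, True),
            ([True, True, False, False], 3, False),
            ([True], 1, True),
        ],
    )
    def test_vote_examples(self, votes, k, expected):
        assert ensemble_vote(votes, k) is expected

    def test_kth_largest_rho_reproduces_vote_at_every_level(self):
        rng = np.random.default_rng(8)
        rhos = rng.random((200, 4))
        for k in (1, 2, 3, 4):
            ens = ensemble_rho(rhos, k)
            for p in (0.1, 0.5, 0.9, 0.99):
                votes = (rhos > p).sum(axis=1) >= k
                assert np.array_equal(ens > p, votes)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            ensemble_vote([True, False], 3)


class TestPrefilter:
    def make_stats(self, rows):
        return pd.DataFrame(rows, columns=["L_Cov", "R_Cov", "L_MapQ", "R_MapQ"])

    def test_coverage_requires_both_flanks(self):
        stats_df = self.make_stats([[400, 50, 60, 60], [400, 400, 60, 60]])
        flags = prefilter_sites(stats_df)
        assert list(flags["high_flank_coverage"]) == [False, True]

    def test_mapq_triggers_on_either_flank(self):
        stats_df = self.make_stats([[100, 100, 10, 60], [100, 100, 60, 60]])
        flags = prefilter_sites(stats_df)
        assert list(flags["low_flank_mapq"]) == [True, False]

    def test_default_thresholds(self):
        stats_df = self.make_stats([[300.0, 300.0, 30.0, 30.0]])
        flags = prefilter_sites(stats_df)  # strict > and <: boundaries pass
        assert not flags["high_flank_coverage"][0]
        assert not flags["low_flank_mapq"][0]

    def test_missing_stats_flagged_unfilterable(self):
        stats_df = self.make_stats([[np.nan, 100, 60, 60]])
        flags = prefilter_sites(stats_df)
        assert flags["unfilterable"][0]
        assert not flags["high_flank_coverage"][0]


class TestStratify:
    def test_table_bins(self):
        labels = stratify([0.995, 0.0, 0.68, 0.9995, 0.5])
        assert labels == ["0.99-0.997", "<0.68", "0.68-0.9", ">0.999", "<0.68"]

    def test_every_site_in_exactly_one_stratum(self):
        rng = np.random.default_rng(9)
        rhos = rng.random(500)
        labels = stratify(rhos)
        names = [f"<{TABLE_STRATA[0]}"] + [
            f"{a}-{b}" for a, b in zip(TABLE_STRATA[:-1], TABLE_STRATA[1:])
        ] + [f">{TABLE_STRATA[-1]}"]
        assert set(labels) <= set(names)
        assert len(labels) == 500


class TestRocCurve:
    def test_perfect_separation(self):
        fpr, tpr, auc = roc_curve([0.9, 0.95, 1.0], [0.1, 0.2, 0.3])
        assert auc == pytest.approx(1.0)

    def test_identical_distributions_match_mann_whitney(self):
        rng = np.random.default_rng(10)
        pos = rng.normal(size=400)
        neg = rng.normal(size=400)
        _, _, auc = roc_curve(pos, neg)
        u = stats.mannwhitneyu(pos, neg).statistic / (len(pos) * len(neg))
        assert auc == pytest.approx(u, abs=1e-9)
        assert abs(auc - 0.5) < 0.06

    def test_curve_monotone(self):
        rng = np.random.default_rng(11)
        fpr, tpr, _ = roc_curve(rng.normal(1, 1, 100), rng.normal(0, 1, 100))
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)


class TestCalibrationOnSyntheticVectors:
    def test_held_out_rho_close_to_uniform(self):
        """P(rho > p) ~ 1-p for held-out draws from the training process."""
        train = gaussian_training(n=2000, d=6, seed=12)
        held = gaussian_training(n=2000, d=6, seed=13)
        model = fit_l1_model(train)
        rho = model.rho(held)
        for p in (0.9, 0.95, 0.99):
            frac = (rho > p).mean()
            se = math.sqrt(p * (1 - p) / 2000)
            assert abs(frac - (1 - p)) < 4 * se

    def test_rho_fixed_under_frozen_transform(self):
        """Scores depend only on the frozen transform, not the candidate batch."""
        train = gaussian_training(n=300, d=4, seed=14)
        model = fit_l1_model(train)
        x = gaussian_training(n=20, d=4, seed=15)
        alone = model.rho(x.subset(x.annotation_names))
        batched = model.rho(x)
        assert np.array_equal(alone, batched)
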