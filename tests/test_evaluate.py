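import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import faceimprint as fi
from faceimprint import ConfigError
from faceimprint.evaluate import (
    bh_select,
    compute_auc,
    count_significant,
    make_cv_plan,
    percent_increase,
    ranking_table,
    run_cv,
    summarize_auc,
    two_se_select,
    welch_onesided,
    AUCResult,
)
from faceimprint.features import EmbeddingInput
from faceimprint.synthetic import make_attributes


def brute_force_auc(scores, labels):
    """O(n1*n0) pairwise concordance oracle; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeAUC:
    def test_perfect_separation_is_one(self):
        scores = np.concatenate([np.full(20, 2.0), np.full(30, 1.0)])
        labels = np.concatenate([np.ones(20), np.zeros(30)])
        assert compute_auc(scores, labels) == 1.0

    def test_all_ties_is_half(self):
        assert compute_auc(np.ones(10), np.arange(10) % 2) == 0.5

    def test_hand_worked_four_observations(self):
        # pairs: (0.9 vs 0.4), (0.9 vs 0.6), (0.2 vs 0.4), (0.2 vs 0.6)
        # concordant: 2 of 4 -> 0.5
        auc = compute_auc([0.9, 0.4, 0.6, 0.2], [1, 0, 0, 1])
        assert auc == 0.5

    def test_single_class_returns_none(self):
        assert compute_auc([0.1, 0.2], [1, 1]) is None
        assert compute_auc([0.1, 0.2], [0, 0]) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        # coarse grid forces plenty of ties
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=25)
        labels = rng.integers(0, 2, size=25)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = compute_auc(scores, labels)
        b = compute_auc(np.exp(3.0 * scores) + 2.0, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestCVPlan:
    def test_twenty_by_five_yields_hundred_cells(self, small_dataset):
        _, attrs, _ = small_dataset
        plan = make_cv_plan(attrs, n_repeats=20, n_folds=5, seed=0)
        assert sum(1 for _ in plan.cells()) == 100

    def test_individual_in_exactly_one_fold_per_repeat(self, small_dataset):
        _, attrs, _ = small_dataset
        plan = make_cv_plan(attrs, n_repeats=3, n_folds=5, seed=1)
        for r in range(3):
            folds = plan.fold_of_rows(attrs.individual_id, r)
            for ind in np.unique(attrs.individual_id):
                assert len(np.unique(folds[attrs.individual_id == ind])) == 1
            # folds partition all rows
            covered = np.concatenate(
                [plan.split_rows(attrs.individual_id, r, f)[1] for f in range(5)]
            )
            assert sorted(covered) == list(range(attrs.n_rows))

    def test_fold_sizes_differ_by_at_most_one(self, small_dataset):
        _, attrs, _ = small_dataset
        plan = make_cv_plan(attrs, n_repeats=4, n_folds=4, seed=2)
        for r in range(4):
            sizes = np.bincount(plan.assignment[r], minlength=4)
            assert sizes.max() - sizes.min() <= 1

    def test_shuffling_image_order_preserves_fold_membership(self, small_dataset):
        _, attrs, _ = small_dataset
        plan = make_cv_plan(attrs, n_repeats=2, n_folds=5, seed=3)
        perm = np.random.default_rng(0).permutation(attrs.n_rows)
        orig = plan.fold_of_rows(attrs.individual_id, 0)
        shuffled = plan.fold_of_rows(attrs.individual_id[perm], 0)
        assert np.array_equal(orig[perm], shuffled)

    def test_too_few_individuals_rejected(self):
        cfg = fi.SyntheticConfig(
            n_individuals=3, m_attributes=2, n_active=0, image_size=16,
            n_demographic=0, seed=4
        )
        attrs = make_attributes(cfg)
        with pytest.raises(ConfigError):
            make_cv_plan(attrs, n_folds=5)


class TestSummarizeAUC:
    def test_two_se_above_half_gives_p_near_0023(self):
        # mean exactly 2 SE above 0.5 -> p = Phi(-2) ~ 0.0228 (cutoff 0.023)
        measures = 0.6 + 0.01 * np.array([-1.0, 1.0, -1.0, 1.0])
        se = measures.std(ddof=1) / 2
        mean, se_out, p = summarize_auc(0.5 + 2 * se + (measures - 0.6))
        assert p == pytest.approx(norm.cdf(-2.0), rel=1e-9)
        assert round(p, 3) == 0.023

    def test_mean_half_gives_p_half(self):
        assert summarize_auc([0.4, 0.6])[2] == 0.5

    def test_hand_computed_four_measures(self):
        mean, se, p = summarize_auc([0.62, 0.58, 0.60, 0.60])
        assert mean == pytest.approx(0.60)
        assert se == pytest.approx(np.sqrt(8 / 3) * 0.01 / 2, rel=1e-9)
        assert se == pytest.approx(0.00816, abs=5e-5)
        assert p == pytest.approx(norm.cdf((0.5 - 0.6) / se), rel=1e-9)
        assert p < 1e-30

    def test_fewer_than_two_measures_undefined(self):
        assert summarize_auc([0.7]) is None
        assert summarize_auc([]) is None

    def test_p_monotone_in_mean_and_se(self):
        base = np.array([0.58, 0.60, 0.62])
        _, _, p1 = summarize_auc(base)
        _, _, p2 = summarize_auc(base + 0.05)
        assert p2 < p1  # higher mean at equal SE -> smaller p
        wide = 0.60 + 3 * (base - 0.60)
        _, _, p3 = summarize_auc(wide)
        assert p3 > p1  # larger SE at equal mean > 0.5 -> larger p


class TestBHSelect:
    def test_step_up_worked_example(self):
        res = bh_select([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert res.n_rejected == 3
        assert res.cutoff == pytest.approx(0.03)

    def test_all_ones_rejects_nothing(self):
        res = bh_select([1.0, 1.0, 1.0], q=0.05)
        assert res.n_rejected == 0 and res.cutoff is None

    def test_expected_false_positives_scaling(self):
        # 82 rejections at q=0.05 imply ~4 expected false positives
        res = bh_select([1e-6] * 82 + [1.0] * 267, q=0.05)
        assert res.n_rejected == 82
        assert res.expected_false_positives == pytest.approx(4.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 60)) ** 2
        ours = bh_select(list(p), q=0.05)
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert ours.n_rejected == int(reject.sum())
        assert sorted(ours.rejected) == sorted(np.flatnonzero(reject).tolist())

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ConfigError):
            bh_select([0.0, 0.5])


class TestTwoSE:
    def test_bound_above_half_is_significant(self):
        assert two_se_select(0.60, 0.04)  # 0.60 - 0.08 = 0.52 > 0.5

    def test_boundary_is_not_significant(self):
        assert not two_se_select(0.55, 0.025)  # bound exactly 0.5

    def test_bh_set_within_two_se_set_when_cutoff_below_0023(self):
        rng = np.random.default_rng(5)
        results = {}
        for i in range(60):
            mean = rng.uniform(0.45, 0.75)
            se = rng.uniform(0.005, 0.05)
            z = (0.5 - mean) / se
            p = min(max(norm.cdf(z), 1e-300), 1 - 1e-12)
            results[f"v{i}"] = (mean, se, p)
        bh = bh_select([v[2] for v in results.values()], q=0.05, names=list(results))
        if bh.cutoff is not None and bh.cutoff <= norm.cdf(-2):
            for name in bh.rejected:
                mean, se, _ = results[name]
                assert two_se_select(mean, se)


class TestWelch:
    def test_identical_samples_give_half(self):
        assert welch_onesided([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == pytest.approx(0.5)

    def test_clearly_separated_samples(self):
        a = [0.5, 0.5, 0.5, 0.5 + 1e-6]
        b = [0.9, 0.9, 0.9, 0.9 + 1e-6]
        assert welch_onesided(a, b) < 1e-6

    def test_matches_hand_formula(self):
        a = np.array([0.52, 0.55, 0.50, 0.58, 0.54])
        b = np.array([0.61, 0.66, 0.59, 0.63])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (b.mean() - a.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as tdist

        expected = tdist.sf(t, df)
        assert welch_onesided(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_sign_convention(self):
        assert welch_onesided([0.5, 0.5], [0.9, 0.9]) == 0.0
        assert welch_onesided([0.9, 0.9], [0.5, 0.5]) == 1.0


class TestRunCV:
    @pytest.fixture(scope="class")
    def cv_results(self):
        cfg = fi.SyntheticConfig(
            n_individuals=40, m_attributes=4, n_active=1, image_size=16,
            effect_scale=0.4, noise_sigma=0.02, seed=30,
        )
        imgs, attrs, _ = fi.make_dataset(cfg)
        plan = make_cv_plan(attrs, n_repeats=3, n_folds=5, seed=0)
        spec = EmbeddingInput(fi.make_backend("pixel_pca", d=10, seed=1))
        return run_cv(imgs, attrs, plan, spec)

    def test_planted_imprint_is_predictable(self, cv_results):
        assert cv_results["attr_000"].mean > 0.9

    def test_pure_noise_variable_near_half(self, cv_results):
        # attributes 1..3 have zero imprints; they can still correlate with
        # attr_000 through the latent factors, so only mild bounds apply
        nulls = [cv_results[f"attr_{j:03d}"] for j in range(1, 4)]
        weakest = min(nulls, key=lambda r: r.mean)
        assert abs(weakest.mean - 0.5) < 2.5 * weakest.se + 0.1

    def test_sparse_variable_reduces_k(self):
        cfg = fi.SyntheticConfig(
            n_individuals=20, m_attributes=2, n_active=0, image_size=16,
            n_demographic=0, seed=31
        )
        attrs = make_attributes(cfg, allow_constant=True)
        # one positive individual only: most test folds miss the positive class
        attrs.y[:, 1] = 0
        attrs.y[attrs.individual_id == attrs.individual_id[0], 1] = 1
        imgs = fi.render_images(
            attrs, fi.make_prototypes(cfg), noise_sigma=0.05, seed=31
        )
        plan = make_cv_plan(attrs, n_repeats=4, n_folds=5, seed=2)
        spec = EmbeddingInput(fi.make_backend("pixel_pca", d=5, seed=3))
        res = run_cv(imgs, attrs, plan, spec)
        assert res["attr_001"].k == 4  # one fold per repeat holds the positive
        assert res["attr_000"].k == 20


class TestCounts:
    def test_percent_increase_worked_example(self):
        assert percent_increase(92, 127) == pytest.approx(38.04, abs=0.01)
        assert percent_increase(92, 114) == pytest.approx(23.91, abs=0.01)

    def test_count_significant_reports_per_level(self):
        def fake(name, p):
            return AUCResult(
                name=name, measures=np.array([0.6, 0.6]), mean=0.6, se=0.01,
                p_value=p,
            )

        nested = {
            "demographics": {"a": fake("a", 1e-6), "b": fake("b", 0.9)},
            "all": {"a": fake("a", 1e-6), "b": fake("b", 1e-6)},
        }
        df = count_significant(nested, q=0.05)
        assert df["n_significant"].tolist() == [1, 2]
        assert df["pct_increase_vs_reference"].iloc[1] == pytest.approx(100.0)


def test_ranking_table_sorted_by_p(small_dataset):
    imgs, attrs, _ = small_dataset
    plan = make_cv_plan(attrs, n_repeats=2, n_folds=5, seed=0)
    spec = EmbeddingInput(fi.make_backend("pixel_pca", d=8, seed=0))
    res = run_cv(imgs, attrs, plan, spec)
    table = ranking_table(res)
    ps = table["p_value"].to_numpy()
    assert np.all(np.diff(ps[~np.isnan(ps)]) >= 0)
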