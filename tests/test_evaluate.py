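"""Cross-validation harness, AUROC, Wilcoxon, and confusion matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wsimil.classify import PROBA_COLUMNS
from wsimil.evaluate import (
    assign_folds,
    auroc_one_vs_rest,
    biopsy_level_probs,
    confusion_matrix,
    run_cross_validation,
    weighted_mean_auroc,
    wilcoxon_one_sided,
)
from wsimil.pipelines import PipelineSpec, fit_predict_fn
from wsimil.synthetic import CLASSES, SyntheticConfig, generate_cohort


def brute_force_auroc(scores, labels):
    """Oracle: exhaustive pair counting, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_wilcoxon(d):
    """Oracle: exact one-sided p over all 2^n sign assignments of the ranks."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** len(d)


class TestAssignFolds:
    def test_exact_stratification_with_ten_patients_per_class(self):
        cfg = SyntheticConfig(seed=0, n_patients_per_class=(10, 10, 10, 10))
        manifest = generate_cohort(cfg)
        folds = assign_folds(manifest, k=5, seed=1)
        df = manifest.patients.merge(folds.mapping, on="patient_id")
        counts = df.groupby(["fold", "patient_label"]).size()
        assert (counts == 2).all()

    def test_published_cohort_scc_patients_split_four_per_fold(self):
        manifest = generate_cohort(SyntheticConfig(seed=0, table2_mode=True))
        folds = assign_folds(manifest, k=5, seed=0)
        df = manifest.patients.merge(folds.mapping, on="patient_id")
        scc = df[df["patient_label"] == "SCC"].groupby("fold").size()
        assert (scc == 4).all()

    def test_all_biopsies_of_a_patient_share_a_fold(self, small_manifest):
        folds = assign_folds(small_manifest, seed=2)
        fmap = folds.fold_of()
        merged = small_manifest.slides.merge(small_manifest.biopsies, on="biopsy_id")
        merged["fold"] = merged["patient_id"].map(fmap)
        assert (merged.groupby("patient_id")["fold"].nunique() == 1).all()

    def test_under_k_patients_in_a_class_rejected_by_name(self):
        cfg = SyntheticConfig(seed=0, n_patients_per_class=(10, 10, 10, 3))
        manifest = generate_cohort(cfg)
        with pytest.raises(ValueError, match="SCC"):
            assign_folds(manifest, k=5)

    def test_no_patient_in_two_folds_over_many_cohorts(self):
        # stratification balance within one of perfect, for 20 random cohorts
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed, n_patients_per_class=(7, 9, 6, 8))
            manifest = generate_cohort(cfg)
            folds = assign_folds(manifest, k=5, seed=seed)
            assert folds.mapping["patient_id"].is_unique
            df = manifest.patients.merge(folds.mapping, on="patient_id")
            for cls, grp in df.groupby("patient_label"):
                per_fold = grp.groupby("fold").size().reindex(range(5), fill_value=0)
                assert per_fold.max() - per_fold.min() <= 1


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc_one_vs_rest([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc_one_vs_rest([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_one_vs_rest([1, 2], [1, 1])

    def test_matches_pair_counting_oracle_on_500_instances(self, rng):
        for _ in range(500):
            n = int(rng.integers(4, 31))
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
            assert auroc_one_vs_rest(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )


class TestWeightedMean:
    def test_constant_aurocs(self):
        assert weighted_mean_auroc([0.9] * 4, [0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.9)

    def test_two_class_example(self):
        assert weighted_mean_auroc([1, 0, 1, 0], [0.5, 0.5, 0, 0]) == pytest.approx(0.5)

    def test_published_biopsy_proportions_dot_product(self, rng):
        props = np.array([229, 171, 116, 37]) / 553
        aurocs = rng.random(4)
        expected = sum(p * a for p, a in zip(props, aurocs))
        assert weighted_mean_auroc(aurocs, props) == pytest.approx(expected)

    def test_off_simplex_proportions_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_auroc([0.5] * 4, [0.5, 0.5, 0.5, 0.5])

    def test_lies_between_min_and_max(self, rng):
        for _ in range(50):
            a = rng.random(4)
            p = rng.dirichlet(np.ones(4))
            wm = weighted_mean_auroc(a, p)
            assert a.min() - 1e-12 <= wm <= a.max() + 1e-12


class TestWilcoxon:
    def test_twenty_positive_differences_give_two_to_minus_twenty(self):
        a = np.arange(20, dtype=float) + 1.0
        assert wilcoxon_one_sided(a, np.zeros(20)) == pytest.approx(0.5**20)

    def test_single_nonzero_pair(self):
        a = np.zeros(5)
        b = np.zeros(5)
        a[2] = 1.0
        assert wilcoxon_one_sided(a, b) == pytest.approx(0.5)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([1.0, 2.0], [1.0, 2.0])

    def test_matches_exact_enumeration_for_small_n(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            d = rng.choice([-2.0, -1.0, 1.0, 2.0, 3.0], size=n)  # ties in |d|
            assert wilcoxon_one_sided(d, np.zeros(n)) == pytest.approx(
                enumerate_wilcoxon(d), abs=1e-12
            )

    def test_exact_branch_agrees_with_scipy_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.standard_normal(15)
        expected = scipy_wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert wilcoxon_one_sided(d, np.zeros(15)) == pytest.approx(expected, rel=1e-10)

    def test_large_n_normal_approximation_close_to_scipy(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.standard_normal(40) + 0.3
        expected = scipy_wilcoxon(
            d, alternative="greater", mode="approx", correction=True
        ).pvalue
        assert wilcoxon_one_sided(d, np.zeros(40)) == pytest.approx(expected, rel=1e-6)


def make_preds(probs, labels, fold=0):
    df = pd.DataFrame(probs, columns=PROBA_COLUMNS)
    df.insert(0, "unit_id", [f"u{i}" for i in range(len(df))])
    df.insert(1, "level", "biopsy")
    df["label"] = labels
    df["fold"] = fold
    return df


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        probs = np.eye(4)
        cm = confusion_matrix(make_preds(probs, list(CLASSES)))
        np.testing.assert_array_equal(cm, np.eye(4, dtype=int))

    def test_total_count_conserved(self, rng):
        probs = rng.dirichlet(np.ones(4), size=37)
        labels = rng.choice(CLASSES, size=37)
        assert confusion_matrix(make_preds(probs, labels)).sum() == 37

    def test_matches_brute_force_tally(self, rng):
        probs = rng.dirichlet(np.ones(4), size=50)
        labels = rng.choice(CLASSES, size=50)
        cm = confusion_matrix(make_preds(probs, labels))
        expected = np.zeros((4, 4), dtype=int)
        for p, l in zip(probs, labels):
            expected[CLASSES.index(l), int(np.argmax(p))] += 1
        np.testing.assert_array_equal(cm, expected)


class TestBiopsyAggregation:
    def test_single_slide_biopsy_is_identity(self, small_manifest):
        sid = small_manifest.slides["slide_id"].iloc[0]
        bid = small_manifest.slides["biopsy_id"].iloc[0]
        label = small_manifest.biopsies.set_index("biopsy_id")["biopsy_label"][bid]
        preds = make_preds(np.array([[0.7, 0.1, 0.1, 0.1]]), [label])
        preds["unit_id"] = [sid]
        out = biopsy_level_probs(preds, small_manifest)
        np.testing.assert_allclose(
            out[PROBA_COLUMNS].to_numpy(), [[0.7, 0.1, 0.1, 0.1]]
        )

    def test_two_slide_mean(self, small_manifest):
        counts = small_manifest.slides.groupby("biopsy_id").size()
        bid = counts[counts >= 2].index[0]
        sids = small_manifest.slides[small_manifest.slides["biopsy_id"] == bid][
            "slide_id"
        ].iloc[:2]
        preds = make_preds(np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float), ["Benign"] * 2)
        preds["unit_id"] = list(sids)
        out = biopsy_level_probs(preds, small_manifest)
        row = out[out["unit_id"] == bid][PROBA_COLUMNS].to_numpy()[0]
        np.testing.assert_allclose(row, [0.5, 0.5, 0, 0])

    def test_matches_groupby_oracle(self, small_manifest, rng):
        sids = small_manifest.slides["slide_id"]
        probs = rng.dirichlet(np.ones(4), size=len(sids))
        labels = small_manifest.slide_labels()[sids].to_numpy()
        preds = make_preds(probs, labels)
        preds["unit_id"] = list(sids)
        out = biopsy_level_probs(preds, small_manifest).set_index("unit_id")
        s2b = small_manifest.slides.set_index("slide_id")["biopsy_id"]
        for bid in out.index:
            members = [i for i, sid in enumerate(sids) if s2b[sid] == bid]
            np.testing.assert_allclose(
                out.loc[bid, PROBA_COLUMNS].to_numpy(dtype=float),
                probs[members].mean(axis=0),
            )

    def test_unknown_slide_rejected(self, small_manifest):
        preds = make_preds(np.array([[1.0, 0, 0, 0]]), ["Benign"])
        preds["unit_id"] = ["S99999"]
        with pytest.raises(ValueError, match="S99999"):
            biopsy_level_probs(preds, small_manifest)


@pytest.fixture(scope="module")
def cv_result(small_manifest, small_bags):
    bags = {s: p[0] for s, p in small_bags.items()}
    folds = assign_folds(small_manifest, seed=3)
    spec = PipelineSpec(aggregator="gap", classifier="lr")
    return run_cross_validation(small_manifest, bags, fit_predict_fn(spec), folds)


class TestCrossValidation:
    def test_exactly_twenty_class_fold_entries(self, cv_result):
        assert len(cv_result.per_class_fold) == 20
        assert set(cv_result.per_class_fold["class"]) == set(CLASSES)

    def test_weighted_mean_between_min_and_max_class_auroc(self, cv_result):
        vals = [v for v in cv_result.per_class_auroc.values() if not np.isnan(v)]
        assert min(vals) - 1e-9 <= cv_result.weighted_mean_auroc <= max(vals) + 1e-9

    def test_rerun_reproduces_aurocs_bitwise(self, small_manifest, small_bags, cv_result):
        bags = {s: p[0] for s, p in small_bags.items()}
        folds = assign_folds(small_manifest, seed=3)
        spec = PipelineSpec(aggregator="gap", classifier="lr")
        again = run_cross_validation(small_manifest, bags, fit_predict_fn(spec), folds)
        pd.testing.assert_frame_equal(again.per_class_fold, cv_result.per_class_fold)
        assert again.weighted_mean_auroc == cv_result.weighted_mean_auroc

    def test_validation_sets_partition_biopsies(self, cv_result, small_manifest):
        assert sorted(cv_result.predictions["unit_id"]) == sorted(
            small_manifest.biopsies["biopsy_id"]
        )

    def test_experiment_comparison_pairs_class_fold_entries(self, cv_result):
        from wsimil.evaluate import compare_experiments

        # an experiment compared against a uniformly worse copy of itself
        import copy

        worse = copy.deepcopy(cv_result)
        worse.per_class_fold = worse.per_class_fold.assign(
            auroc=worse.per_class_fold["auroc"] - 0.05
        )
        p = compare_experiments(cv_result, worse)
        assert p == pytest.approx(0.5**20)
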