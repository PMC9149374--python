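"""Copula synthesizer and the three synthetic-quality stability scores."""

import numpy as np
import pandas as pd
import pytest

from mwlindex import (
    augment_feature_table,
    deep_structure_stability,
    field_correlation_stability,
    field_distribution_stability,
    fit_synthesizer,
    overall_quality,
    quality_report,
    sample_synthetic,
)
from mwlindex.augmentation import grade_for, jensen_shannon_divergence
from tests.conftest import make_labeled_table
from mwlindex.features import FEATURE_NAMES


def _table(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestFitSynthesizer:
    def test_iid_uniform_columns_near_identity(self):
        rng = np.random.default_rng(0)
        table = _table({f"f{j}": rng.uniform(size=200) for j in range(5)})
        model = fit_synthesizer(table)
        off = model.correlation[np.triu_indices(5, k=1)]
        assert np.abs(off).max() < 0.2

    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 50)
        model = fit_synthesizer(_table({"a": x, "b": 2 * x + 1}))
        assert model.correlation[0, 1] > 0.99

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        table = _table({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        m1 = fit_synthesizer(table, seed=5)
        m2 = fit_synthesizer(table, seed=5)
        np.testing.assert_array_equal(m1.correlation, m2.correlation)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_synthesizer(_table({"a": np.arange(5.0)}))


class TestSampleSynthetic:
    def test_marginal_means_close_at_large_n(self):
        rng = np.random.default_rng(2)
        table = _table(
            {"a": rng.normal(10, 2, size=300), "b": rng.exponential(5, size=300)}
        )
        model = fit_synthesizer(table)
        synth = sample_synthetic(model, 10_000, seed=3)
        for col in table:
            assert abs(synth[col].mean() - table[col].mean()) < 0.1 * abs(
                table[col].mean()
            )

    def test_samples_bounded_by_observed_range(self):
        rng = np.random.default_rng(3)
        table = _table({"a": rng.normal(size=50), "b": rng.uniform(size=50)})
        synth = sample_synthetic(fit_synthesizer(table), 2000, seed=1)
        for col in table:
            assert synth[col].min() >= table[col].min()
            assert synth[col].max() <= table[col].max()

    def test_dependence_structure_preserved(self):
        """Refitted normal-score correlation of a large sample stays within
        0.1 of the model's (normalized Frobenius)."""
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal(
            np.zeros(3), [[1, 0.7, 0.2], [0.7, 1, -0.4], [0.2, -0.4, 1]], size=400
        )
        table = _table({"a": z[:, 0], "b": np.exp(z[:, 1]), "c": z[:, 2] ** 3})
        model = fit_synthesizer(table)
        synth = sample_synthetic(model, 10_000, seed=6)
        refit = fit_synthesizer(synth)
        diff = np.linalg.norm(refit.correlation - model.correlation) / 3
        assert diff < 0.1


class TestFieldCorrelationStability:
    def test_identical_tables_score_100(self):
        table = make_labeled_table(seed=5)
        assert field_correlation_stability(table, table) == pytest.approx(100.0)

    def test_flipped_perfect_correlation_scores_0(self):
        x = np.linspace(0, 1, 40)
        orig = _table({"a": x, "b": x})
        synth = _table({"a": x, "b": -x})
        assert field_correlation_stability(orig, synth) == pytest.approx(0.0)

    def test_shuffle_destroys_correlation(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(200)
        orig = _table(
            {"a": base, "b": base + 0.1 * rng.standard_normal(200), "c": -base}
        )
        shuffled = orig.apply(
            lambda col: rng.permutation(col.to_numpy()), axis=0, result_type="expand"
        )
        shuffled.columns = orig.columns
        assert field_correlation_stability(orig, shuffled) < field_correlation_stability(
            orig, orig
        )

    def test_constant_columns_contribute_zero_difference(self):
        orig = _table({"a": np.ones(20), "b": np.arange(20.0)})
        synth = _table({"a": np.ones(20), "b": np.arange(20.0) ** 2})
        assert field_correlation_stability(orig, synth) == pytest.approx(100.0)


class TestDistributionStability:
    def test_identical_distributions_score_100(self):
        table = make_labeled_table(seed=7)
        assert field_distribution_stability(table, table) == pytest.approx(100.0)

    def test_disjoint_supports_score_0(self):
        orig = _table({"a": np.random.default_rng(8).uniform(0, 1, 100)})
        synth = _table({"a": np.random.default_rng(9).uniform(10, 11, 100)})
        assert field_distribution_stability(orig, synth) == pytest.approx(0.0, abs=1e-6)

    def test_jsd_bounded_in_bits(self):
        p = np.array([1.0, 0, 0, 0])
        q = np.array([0, 0, 0, 1.0])
        assert jensen_shannon_divergence(p, q) == pytest.approx(1.0, abs=1e-6)
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_degradation_with_noise(self):
        """More noise added to the synthetic copy lowers the score (20 seeds,
        3 noise levels, in expectation)."""
        means = []
        for scale in (0.5, 2.0, 8.0):
            scores = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                base = rng.standard_normal(150)
                orig = _table({"a": base})
                synth = _table({"a": base + scale * rng.standard_normal(150)})
                scores.append(field_distribution_stability(orig, synth))
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


class TestDeepStructureStability:
    def test_identical_tables_score_100(self):
        table = make_labeled_table(n_per_class=30, n_features=6, seed=10)
        assert deep_structure_stability(table, table) == pytest.approx(100.0)

    def test_negated_dominant_column_lowers_score(self):
        rng = np.random.default_rng(11)
        orig = _table(
            {"a": 10 * rng.standard_normal(100) + 3, "b": rng.standard_normal(100)}
        )
        synth = orig.copy()
        synth["a"] = -synth["a"]
        assert deep_structure_stability(orig, synth) < 100.0

    def test_score_bounded(self):
        rng = np.random.default_rng(12)
        orig = _table({"a": rng.standard_normal(60), "b": rng.uniform(size=60)})
        synth = _table({"a": rng.exponential(size=60), "b": rng.normal(5, 9, size=60)})
        assert 0.0 <= deep_structure_stability(orig, synth) <= 100.0


class TestOverallQuality:
    def test_table_style_example(self):
        report = overall_quality(100.0, 95.0, 78.0)
        assert report.overall == pytest.approx(91.0)
        assert report.grade == "Excellent"

    @pytest.mark.parametrize(
        "score,grade",
        [
            (0.0, "Very Poor"),
            (19.99, "Very Poor"),
            (20.0, "Poor"),
            (39.99, "Poor"),
            (40.0, "Moderate"),
            (60.0, "Good"),
            (79.99, "Good"),
            (80.0, "Excellent"),
            (100.0, "Excellent"),
        ],
    )
    def test_grade_bins(self, score, grade):
        assert grade_for(score) == grade

    def test_mean_is_exact_and_symmetric(self):
        a = overall_quality(10.0, 50.0, 90.0)
        b = overall_quality(90.0, 10.0, 50.0)
        assert a.overall == b.overall == pytest.approx(50.0)
        assert a.grade == "Moderate"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overall_quality(-1.0, 50.0, 50.0)
        with pytest.raises(ValueError):
            overall_quality(50.0, 101.0, 50.0)


class TestRowOrderInvariance:
    def test_scores_ignore_row_order(self):
        rng = np.random.default_rng(13)
        orig = make_labeled_table(n_per_class=25, n_features=5, seed=14)
        synth = make_labeled_table(n_per_class=25, n_features=5, seed=15)
        shuffled = synth.sample(frac=1.0, random_state=1)
        for fn in (
            field_correlation_stability,
            field_distribution_stability,
            deep_structure_stability,
        ):
            assert fn(orig, synth) == pytest.approx(fn(orig, shuffled))


class TestAugmentTable:
    def test_228_subjects_after_adding_180(self):
        # 48 subjects, one row per condition (the study's instance layout)
        rng = np.random.default_rng(16)
        rows = []
        for sid in range(1, 49):
            for cond, label in (("Rest", "suboptimal"), ("Simkap", "superoptimal")):
                rows.append({"subject_id": sid, "condition": cond, "label": label,
                             **{f: rng.standard_normal() for f in FEATURE_NAMES[:5]}})
        table = pd.DataFrame(rows)
        combined, models = augment_feature_table(table, 180, seed=2)
        assert combined["subject_id"].nunique() == 48 + 180
        assert set(models) == {"Rest", "Simkap"}
        synth = combined[combined["subject_id"] < 0]
        assert len(synth) == 180
        assert synth["label"].notna().all()

    def test_synthetic_ids_negative_and_disjoint(self):
        table = make_labeled_table(n_per_class=20, n_features=4, seed=17)
        combined, _ = augment_feature_table(table, 30, seed=3)
        synth_ids = set(combined.loc[combined["subject_id"] < 0, "subject_id"])
        orig_ids = set(table["subject_id"])
        assert len(synth_ids) == 30
        assert synth_ids.isdisjoint(orig_ids)

    def test_quality_report_grades(self):
        table = make_labeled_table(n_per_class=30, n_features=6, seed=18)
        combined, _ = augment_feature_table(table, 60, seed=4)
        synth = combined[combined["subject_id"] < 0]
        report = quality_report(table, synth)
        assert 0.0 <= report.overall <= 100.0
        assert report.grade == grade_for(report.overall)
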