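"""Ct parsing, the expression transform, ratio features and prefilters."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stavarsel import (
    CtMatrix,
    RatioFeature,
    build_ratio_features,
    cov_filter,
    detectability_filter,
    mwu_prefilter,
    read_ct_table,
    relative_expression,
)
from stavarsel.ct import dedupe_reciprocals, mannwhitney_pvalues


class TestReadCtTable:
    def test_toy_file_parses_with_missing_cells(self, toy_ct_files):
        ct = read_ct_table(*toy_ct_files)
        assert ct.n_assays == 3 and ct.n_samples == 4
        assert ct.missing.sum() == 2  # "Undetermined" and an empty cell
        assert ct.missing[1, 1] and ct.missing[2, 2]
        assert ct.ct[0, 0] == pytest.approx(25.1)
        assert ct.group_of_sample == {
            "s1": "control", "s2": "GORD", "s3": "cancer", "s4": "cancer"
        }

    def test_duplicate_assay_row_names_error(self, tmp_path, toy_ct_files):
        bad = tmp_path / "dup.csv"
        bad.write_text("assay_id,s1,s2\na1,25,26\na1,30,31\n")
        with pytest.raises(ValueError, match="a1"):
            read_ct_table(bad, toy_ct_files[1])

    def test_missing_metadata_names_the_sample(self, tmp_path, toy_ct_files):
        meta = tmp_path / "meta2.csv"
        meta.write_text("sample_id,cohort\ns1,control\ns2,GORD\ns3,cancer\n")
        with pytest.raises(ValueError, match="s4"):
            read_ct_table(toy_ct_files[0], meta)

    def test_unparseable_and_negative_ct_raise(self, tmp_path, toy_ct_files):
        for cell in ("banana", "-3.0"):
            bad = tmp_path / "bad.csv"
            bad.write_text(f"assay_id,s1,s2,s3,s4\na1,{cell},26,27,28\n")
            with pytest.raises(ValueError):
                read_ct_table(bad, toy_ct_files[1])

    def test_cohort_counts_propagate(self, small_dataset):
        ct, _ = small_dataset
        counts = {}
        for g in ct.group_of_sample.values():
            counts[g] = counts.get(g, 0) + 1
        assert counts == {"control": 8, "GORD": 8, "cancer": 16}


class TestRelativeExpression:
    @pytest.mark.parametrize("ct_val,expected", [(40.0, 1.0), (30.0, 1024.0), (25.0, 32768.0)])
    def test_anchor_values_exact(self, toy_ct, ct_val, expected):
        toy_ct.ct[0, 0] = ct_val
        expr = relative_expression(toy_ct)
        assert expr.expr[0, 0] == expected

    def test_missing_imputed_to_expression_one(self, toy_ct):
        expr = relative_expression(toy_ct)
        assert expr.expr[2, 1] == 1.0

    def test_doubling_per_cycle(self, toy_ct):
        expr = relative_expression(toy_ct)
        shifted = CtMatrix(
            toy_ct.assay_ids, toy_ct.sample_ids, toy_ct.ct + 1.0, toy_ct.group_of_sample
        )
        expr2 = relative_expression(shifted)
        mask = ~toy_ct.missing
        assert np.array_equal(expr.expr[mask], 2.0 * expr2.expr[mask])

    def test_low_undetected_ct_warns(self, toy_ct):
        with pytest.warns(UserWarning, match="largest observed"):
            relative_expression(toy_ct, undetected_ct=30.0)


class TestDetectabilityFilter:
    def _ct_with_detection(self, det_noncancer, det_cancer, n0=19, n1=39):
        samples = [f"s{i}" for i in range(n0 + n1)]
        groups = {s: ("control" if i < n0 else "cancer") for i, s in enumerate(samples)}
        row = np.full(n0 + n1, np.nan)
        row[:det_noncancer] = 25.0
        row[n0 : n0 + det_cancer] = 25.0
        all_detected = np.full(n0 + n1, 25.0)
        return CtMatrix(["a", "b"], samples, np.vstack([row, all_detected]), groups)

    def test_detectable_in_one_group_suffices(self):
        ct = self._ct_with_detection(10, 0)  # 52.6% vs 0%
        assert "a" in detectability_filter(ct)

    def test_below_threshold_in_both_groups_drops(self):
        ct = self._ct_with_detection(9, 19)  # 47.4% vs 48.7%
        assert "a" not in detectability_filter(ct)

    def test_fully_detected_kept(self):
        ct = self._ct_with_detection(0, 0)
        assert "b" in detectability_filter(ct)


class TestRatioFeatures:
    def test_feature_count_is_m_times_m_minus_1(self, toy_ct):
        expr = relative_expression(toy_ct)
        assert build_ratio_features(expr).n_features == 3 * 2

    def test_ratio_equals_two_to_delta_ct(self, toy_ct):
        expr = relative_expression(toy_ct)
        ratios = build_ratio_features(expr)
        i = ratios.feature_names.index("a1/a2")
        # Ct a1=28, a2=30 on sample s0 -> 2**(30-28) = 4
        assert ratios.values[i, 0] == pytest.approx(4.0)

    def test_reciprocal_product_is_one(self, small_dataset):
        ct, _ = small_dataset
        expr = relative_expression(ct)
        ratios = build_ratio_features(expr, expr.assay_ids[:6])
        by_name = {f.name: i for i, f in enumerate(ratios.features)}
        for f in ratios.features:
            j = by_name[f"{f.denominator_assay}/{f.numerator_assay}"]
            prod = ratios.values[by_name[f.name]] * ratios.values[j]
            assert np.allclose(prod, 1.0)

    def test_self_ratio_rejected(self):
        with pytest.raises(ValueError):
            RatioFeature("a", "a")

    def test_dedupe_halves_feature_count(self, toy_ct):
        ratios = build_ratio_features(relative_expression(toy_ct))
        assert dedupe_reciprocals(ratios).n_features == 3


class TestCovFilter:
    def _ratios(self, values, y):
        from stavarsel import RatioMatrix

        feats = [RatioFeature(f"n{i}", f"d{i}") for i in range(values.shape[0])]
        samples = [f"s{i}" for i in range(values.shape[1])]
        return RatioMatrix(feats, values, samples, np.asarray(y))

    def test_removed_only_if_high_in_both_classes(self):
        # one dominant spike per class drives the sample CoV near its
        # upper bound sqrt(n); n = 50 per class allows CoV well above 3
        n = 50
        y = np.array([0] * n + [1] * n)
        spiky = np.full(2 * n, 0.01)
        spiky[0] = spiky[n] = 1e4
        one_sided = np.concatenate([np.full(n, 5.0), spiky[n:]])
        constant = np.full(2 * n, 2.0)
        ratios = self._ratios(np.vstack([spiky, one_sided, constant]), y)
        for cls in (0, 1):
            v = spiky[y == cls]
            assert v.std(ddof=1) / v.mean() > 3.0
        kept = cov_filter(ratios, max_cov=3.0)
        names = kept.feature_names
        assert "n0/d0" not in names  # CoV > 3 in both -> removed
        assert "n1/d1" in names  # CoV > 3 in one class only -> retained
        assert "n2/d2" in names  # constant, CoV = 0 -> retained


class TestMannWhitney:
    def test_exact_example_disjoint_groups(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        p = mannwhitney_pvalues(np.array([[4.0, 5, 6, 1, 2, 3]]), np.array([1, 1, 1, 0, 0, 0]))
        assert p[0] == pytest.approx(0.1)

    def test_u_statistic_by_brute_force(self):
        x, y = [1, 2, 3], [4, 5, 6]
        u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        assert u == 0

    def test_identical_vectors_give_p_one(self):
        vals = np.array([[1.0, 2, 3, 1, 2, 3]])
        p = mannwhitney_pvalues(vals, np.array([0, 0, 0, 1, 1, 1]))
        assert p[0] == 1.0

    def test_exact_agrees_with_enumeration_oracle(self):
        """Implementation vs independent itertools pair-count enumeration."""
        rng = np.random.default_rng(42)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (8, 7)]:
            x = np.round(rng.normal(size=n1), 1)
            z = np.round(rng.normal(size=n2), 1)
            pooled = np.concatenate([x, z])
            ranks = stats.rankdata(pooled)
            center = n1 * n2 / 2.0
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            hits = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
                total += 1
                if abs(u - center) >= abs(u_obs - center) - 1e-12:
                    hits += 1
            p_oracle = hits / total
            vals = np.concatenate([x, z])[None, :]
            labels = np.array([1] * n1 + [0] * n2)
            assert mannwhitney_pvalues(vals, labels)[0] == pytest.approx(p_oracle, abs=0.01)

    def test_reciprocal_feature_has_identical_pvalue(self, small_dataset):
        ct, _ = small_dataset
        ratios = build_ratio_features(relative_expression(ct), ct.assay_ids[:5])
        p = mannwhitney_pvalues(ratios.values, ratios.y)
        by_name = {f.name: i for i, f in enumerate(ratios.features)}
        for f in ratios.features:
            j = by_name[f"{f.denominator_assay}/{f.numerator_assay}"]
            assert p[by_name[f.name]] == pytest.approx(p[j], abs=1e-12)

    def test_prefilter_drops_uninformative(self):
        from stavarsel import RatioMatrix

        rng = np.random.default_rng(1)
        y = np.array([0] * 12 + [1] * 12)
        strong = np.where(y == 1, 8.0, 1.0) + rng.normal(0, 0.2, 24) ** 2
        noise = np.abs(rng.normal(5, 1, 24)) + 0.1
        ratios = RatioMatrix(
            [RatioFeature("a", "b"), RatioFeature("c", "d")],
            np.vstack([strong, noise]),
            [f"s{i}" for i in range(24)],
            y,
        )
        kept, p = mwu_prefilter(ratios, alpha=0.05)
        assert kept.feature_names == ["a/b"]
        assert p[0] < 0.05 <= p[1]
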