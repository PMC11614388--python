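"""Fold change, enrichment calls, exact rank-sum, BH FDR, pooled summaries."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from midtrace.datasets import load_csf_reference, load_media_reference
from midtrace.diffstats import (
    NOT_SIG,
    bh_fdr,
    classify_enrichment,
    differential_table,
    fold_change,
    log2fc,
    pooled_summary,
    student_t_two_tailed,
    wilcoxon_rank_sum,
    wilcoxon_rank_sum_enumerated,
)
from midtrace.simulate import NoiseModel, StudyDesign, simulate_two_group_table


class TestFoldChange:
    def test_examples(self):
        assert fold_change(2.27, 1.0) == pytest.approx(2.27)
        assert fold_change(3.0, 3.0) == 1.0

    def test_pseudo_abundance_floor(self):
        assert fold_change(0.0, 1.0, pseudo=0.01) == pytest.approx(0.01)
        assert fold_change(1.0, 0.0, pseudo=0.01) == pytest.approx(100.0)

    def test_both_zero_without_pseudo_is_nan(self):
        assert math.isnan(fold_change(0.0, 0.0))


class TestLog2FC:
    @pytest.mark.parametrize(
        "fc, printed", [(2.27, 1.18), (2.17, 1.12), (1.80, 0.85), (1.0, 0.0)]
    )
    def test_matches_printed_tables(self, fc, printed):
        assert round(log2fc(fc), 2) == printed

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2fc(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_antisymmetry(self, a, b):
        assert log2fc(fold_change(a, b)) == pytest.approx(
            -log2fc(fold_change(b, a)), abs=1e-9
        )


class TestStudentT:
    def test_identical_groups(self):
        assert student_t_two_tailed([1.0, 2.0], [1.0, 2.0])[1] == pytest.approx(1.0)

    def test_pooled_oracle(self):
        t, p = student_t_two_tailed([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_null_calibration_n10(self, rng):
        from scipy import stats

        reps = 10_000
        _, p = stats.ttest_ind(
            rng.normal(size=(reps, 10)), rng.normal(size=(reps, 10)), axis=1
        )
        assert abs(np.mean(p < 0.05) - 0.05) < 0.007


class TestClassifyEnrichment:
    @pytest.mark.parametrize(
        "lfc, p, expected",
        [
            (1.18, 0.01, "HFD 3d"),  # enriched in treated
            (-1.14, 0.02, "CT"),  # enriched in control
            (1.83, 0.24, NOT_SIG),  # big FC, not significant
            (0.68, 0.004, NOT_SIG),  # significant, small FC
            (1.0, 0.01, NOT_SIG),  # threshold is strict
        ],
    )
    def test_rule(self, lfc, p, expected):
        label = classify_enrichment(lfc, p, treated_label="HFD 3d", control_label="CT")
        assert label == expected

    def test_rule_reproduces_every_reference_call(self):
        # the |log2FC| > 1 and p < 0.05 rule must match all 34 bundled calls
        ref = load_csf_reference()
        for met, row in ref.iterrows():
            assert classify_enrichment(
                row["log2FC"], row["p_value"], treated_label="HFD 3d", control_label="CT"
            ) == row["enrichment"], met


class TestWilcoxon:
    def test_complete_separation_n6(self):
        p = wilcoxon_rank_sum(range(1, 7), range(7, 13), mode="exact")
        assert p == pytest.approx(2 / 924, rel=1e-12)

    def test_complete_separation_n2(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4], mode="exact") == pytest.approx(1 / 3)

    def test_balanced_ranks_give_p_one(self):
        assert wilcoxon_rank_sum([1, 4, 5, 8], [2, 3, 6, 7], mode="exact") == 1.0

    def test_exact_with_ties_raises(self):
        with pytest.raises(ValueError, match="auto"):
            wilcoxon_rank_sum([1, 1, 2], [1, 3, 4], mode="exact")

    def test_auto_falls_back_on_ties(self):
        p = wilcoxon_rank_sum([1, 1, 2, 2, 3, 3], [3, 4, 4, 5, 5, 6], mode="auto")
        assert 0 < p < 1

    def test_matches_enumeration_oracle(self, rng):
        # exhaustive over all group sizes up to 6, tie-free random data
        for n1 in range(1, 7):
            for n2 in range(n1, 7):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                a, b = vals[:n1], vals[n1:]
                assert wilcoxon_rank_sum(a, b, mode="exact") == pytest.approx(
                    wilcoxon_rank_sum_enumerated(a, b), rel=1e-12
                ), (n1, n2)

    def test_minimum_exact_p_at_n6(self):
        # no two-sided exact p below 2/C(12,6) is achievable
        assert 2 / math.comb(12, 6) == pytest.approx(0.002165, abs=5e-7)


class TestBhFdr:
    def test_step_up_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @staticmethod
    def step_up_oracle(p):
        # independent implementation of the BH step-up adjustment
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), self.step_up_oracle(p), atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPooledSummary:
    def test_reference_lactate_row(self):
        mean, sd = pooled_summary(
            7315358105.8, 237880097.3, 6, 8220829758.2, 398345524.3, 6
        )
        assert mean == pytest.approx(7768093932.0, abs=0.05)
        assert sd == pytest.approx(566966988.5, abs=0.05)

    def test_reference_glutamine_row(self):
        ref = load_media_reference()
        row = ref.loc["b_D..Glutamine"]
        mean, sd = pooled_summary(
            row["bsa_mean"], row["bsa_sd"], 6, row["pa_mean"], row["pa_sd"], 6
        )
        assert mean == pytest.approx(row["overall_mean"], abs=0.05)
        # group means/SDs are printed to 0.1, so the recomputed SD carries
        # slightly more rounding error than the mean
        assert sd == pytest.approx(row["overall_sd"], abs=0.5)

    def test_identical_groups(self):
        # equal-mean groups: overall variance is the within-group sum of
        # squares over n1+n2-1, exactly as for the concatenated raw data
        mean, sd = pooled_summary(5.0, 2.0, 4, 5.0, 2.0, 4)
        assert mean == 5.0
        assert sd == pytest.approx(math.sqrt((3 * 4 + 3 * 4) / 7))

    def test_equals_summary_of_concatenation(self, rng):
        for _ in range(20):
            a = rng.normal(10, 3, size=rng.integers(2, 12))
            b = rng.normal(12, 5, size=rng.integers(2, 12))
            mean, sd = pooled_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            both = np.concatenate([a, b])
            assert mean == pytest.approx(both.mean(), abs=1e-9)
            assert sd == pytest.approx(both.std(ddof=1), abs=1e-9)

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            pooled_summary(1.0, 0.0, 1, 2.0, 1.0, 6)


class TestDifferentialTable:
    @staticmethod
    def table_and_groups(rng, n=10, cv=0.2, effects=None, n_null=10, seed=0):
        baselines = {f"met{i}": 100.0 * (i + 1) for i in range(n_null)}
        design = StudyDesign(groups={"CT": n, "HFD 3d": n}, effects=effects or {})
        table, truth = simulate_two_group_table(
            design, NoiseModel(cv=cv), baselines, seed=seed
        )
        groups = pd.Series({s: s.rsplit("_", 1)[0] for s in table.columns})
        return table, groups

    def test_reference_filter_yields_two_fatty_acids(self):
        ref = load_csf_reference()
        hits = ref[(ref["FC"] > 2) & (ref["p_value"] < 0.05)]
        assert set(hits.index) == {"Hexadecanoic acid", "Octadecanoic acid"}

    def test_power_on_true_effect(self, rng):
        # a genuine 2.5-fold metabolite at n=10, CV 20% should be called
        # enriched nearly always
        calls = 0
        n_sims = 200
        for s in range(n_sims):
            table, groups = self.table_and_groups(
                rng, effects={"met0": 2.5}, seed=1000 + s
            )
            out = differential_table(table, groups, control="CT", treated="HFD 3d")
            row = out[out["metabolite"] == "met0"].iloc[0]
            calls += row["enrichment"] == "HFD 3d"
        assert calls / n_sims >= 0.95

    def test_permutation_null_call_rate(self, rng):
        # enriched calls on label-permuted data stay at or below alpha
        table, groups = self.table_and_groups(rng, effects={"met0": 2.5}, seed=7)
        n_reps, calls, total = 300, 0, 0
        labels = groups.to_numpy()
        for _ in range(n_reps):
            perm = pd.Series(rng.permutation(labels), index=groups.index)
            out = differential_table(table, perm, control="CT", treated="HFD 3d")
            calls += (out["enrichment"] != NOT_SIG).sum()
            total += len(out)
        rate = calls / total
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total)

    def test_sort_orders(self, rng):
        table, groups = self.table_and_groups(rng, seed=3)
        by_lfc = differential_table(table, groups, "CT", "HFD 3d", sort="log2fc")
        assert by_lfc["log2FC"].abs().is_monotonic_decreasing
        by_p = differential_table(table, groups, "CT", "HFD 3d", sort="p")
        assert by_p["p"].is_monotonic_increasing

    def test_wilcoxon_with_fdr(self, rng):
        table, groups = self.table_and_groups(rng, n=6, seed=4)
        out = differential_table(
            table, groups, "CT", "HFD 3d", test="wilcoxon", with_fdr=True, sort="p"
        )
        assert "q" in out.columns
        assert np.all(out["q"].to_numpy() >= out["p"].to_numpy() - 1e-12)

    def test_all_zero_row_flagged_not_fatal(self, rng):
        table, groups = self.table_and_groups(rng, seed=5)
        table.loc["dead"] = 0.0
        out = differential_table(table, groups, "CT", "HFD 3d")
        row = out[out["metabolite"] == "dead"].iloc[0]
        assert row["flag"] == "all-zero" and row["enrichment"] == NOT_SIG

    def test_unlabeled_sample_rejected(self, rng):
        table, groups = self.table_and_groups(rng, seed=6)
        with pytest.raises(ValueError):
            differential_table(table, groups.iloc[:-1], "CT", "HFD 3d")
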