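"""Tests for mixing effects, one-sample tests, extinction and contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from oracles import fisher_oracle

from myxomorph.social_stats import (
    MixAssay,
    SurvivalLedger,
    assays_from_table,
    contrasts_among_categories,
    contrasts_evolved_vs_anc,
    extinction_table,
    extinction_test,
    mixing_effect_one_way,
    mixing_effect_total,
    one_sample_test,
    survival_curves,
)


def make_assay(pure_i, pure_j, mix_i, mix_j, f_i=0.5):
    arr = lambda x: np.atleast_1d(np.asarray(x, dtype=float))
    return MixAssay("i", "j", arr(pure_i), arr(pure_j), arr(mix_i), arr(mix_j),
                    f_i=f_i, f_j=1 - f_i)


class TestMixingEffects:
    def test_no_effect_inputs_give_exact_zero(self):
        # mix output equals initial frequency times monoculture output
        a = make_assay(1e6, 4e5, 5e5, 2e5)
        ci = mixing_effect_one_way(a, "i")
        cj = mixing_effect_one_way(a, "j")
        b = mixing_effect_total(a)
        assert ci.values[0] == 0.0
        assert cj.values[0] == 0.0
        assert b.values[0] == 0.0

    def test_hundredfold_suppression_is_minus_two(self):
        a = make_assay(1e6, 1e6, 5e3, 5e5)
        res = mixing_effect_one_way(a, "i")
        assert res.values[0] == pytest.approx(-2.0)

    def test_total_effect_forced_arithmetic(self):
        # both monocultures 1e6, mix total 2e6 -> B = log10(2)
        a = make_assay(1e6, 1e6, 1.2e6, 0.8e6)
        res = mixing_effect_total(a)
        assert res.values[0] == pytest.approx(math.log10(2.0))

    def test_scale_invariance_under_common_rescaling(self, rng):
        pure_i, pure_j = rng.uniform(1e5, 1e7, 2)
        mix_i, mix_j = rng.uniform(1e3, 1e6, 2)
        a1 = make_assay(pure_i, pure_j, mix_i, mix_j)
        a2 = make_assay(17 * pure_i, 17 * pure_j, 17 * mix_i, 17 * mix_j)
        for focal in ("i", "j"):
            v1 = mixing_effect_one_way(a1, focal).values[0]
            v2 = mixing_effect_one_way(a2, focal).values[0]
            assert v2 == pytest.approx(v1)
        assert mixing_effect_total(a2).values[0] == pytest.approx(
            mixing_effect_total(a1).values[0]
        )

    def test_monotone_in_focal_mix_count(self):
        vals = [
            mixing_effect_one_way(make_assay(1e6, 1e6, m, 1e5), "i").values[0]
            for m in (1e3, 1e4, 1e5, 1e6)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_zero_monoculture_rejected(self):
        a = make_assay(0.0, 1e6, 1e3, 1e3)
        with pytest.raises(ValueError, match="monoculture"):
            mixing_effect_one_way(a, "i")

    def test_zero_mix_count_flagged_below_detection(self):
        a = make_assay([1e6, 1e6, 1e6], [1e6] * 3, [0.0, 1e4, 1e4], [1e5] * 3)
        res = mixing_effect_one_way(a, "i")
        assert np.isneginf(res.values[0])
        assert res.n_below_detection == 1
        assert res.n_used == 2

    def test_assays_from_table_roundtrip(self):
        rows = []
        for rep in (1, 2):
            rows += [
                {"assay_id": "x", "replicate": rep, "strain": "a",
                 "partner_or_NA": "NA", "culture": "pure",
                 "spore_count": 1e6, "initial_frequency": 0.5},
                {"assay_id": "x", "replicate": rep, "strain": "b",
                 "partner_or_NA": "NA", "culture": "pure",
                 "spore_count": 2e6, "initial_frequency": 0.5},
                {"assay_id": "x", "replicate": rep, "strain": "a",
                 "partner_or_NA": "b", "culture": "mix",
                 "spore_count": 5e5, "initial_frequency": 0.5},
                {"assay_id": "x", "replicate": rep, "strain": "b",
                 "partner_or_NA": "a", "culture": "mix",
                 "spore_count": 1e6, "initial_frequency": 0.5},
            ]
        assays = assays_from_table(pd.DataFrame(rows))
        assert len(assays) == 1
        res = mixing_effect_one_way(assays[0], "a")
        np.testing.assert_allclose(res.values, 0.0)


class TestOneSampleTest:
    def test_zero_mean_symmetric_values(self):
        res = one_sample_test([-1.0, 0.0, 1.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_values_degenerate(self):
        res = one_sample_test([1.0, 1.0, 1.0])
        assert res.degenerate
        assert res.p == 0.0

    def test_constant_at_null_degenerate_p_one(self):
        res = one_sample_test([0.0, 0.0, 0.0])
        assert res.degenerate
        assert res.p == 1.0

    def test_matches_textbook_formula(self):
        values = [0.9, 1.0, 1.1]
        res = one_sample_test(values)
        sd = np.std(values, ddof=1)
        expect_t = np.mean(values) / (sd / math.sqrt(3))
        assert expect_t == pytest.approx(17.3205, abs=1e-3)
        assert res.t == pytest.approx(expect_t, rel=1e-9)

    def test_type_i_error_near_nominal_at_n3(self):
        rng = np.random.default_rng(31)
        rejections = 0
        n_sim = 10_000
        for _ in range(n_sim):
            if one_sample_test(rng.normal(size=3)).p < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)


def reported_ledger():
    """Survival ledger reconstructed from the reported extinction record:
    64 populations in 8 treatments, 17 extinct of which 16 partnered with
    an antagonist; all 8 populations of one antagonist treatment extinct
    by cycle 6."""
    rows = []
    treatments = {
        "no_dp": "none", "coop": "cooperator",
        "cheat_a": "cheater", "cheat_b": "cheater", "cheat_c": "cheater",
        "antag_a": "antagonist", "antag_b": "antagonist",
        "antag_lethal": "antagonist",
    }
    # the lethal antagonist: all 8 gone by cycle 6
    lethal_cycles = [2, 3, 3, 4, 5, 5, 6, 6]
    # remaining antagonist extinctions: 8 more across the two other
    # antagonist treatments; one extinction elsewhere (a cheater pop)
    other_ant = {"antag_a": [5, 7, 8, 9], "antag_b": [6, 8, 9, 10]}
    for trt, cat in treatments.items():
        for p in range(1, 9):
            cyc = None
            if trt == "antag_lethal":
                cyc = lethal_cycles[p - 1]
            elif trt in other_ant and p <= 4:
                cyc = other_ant[trt][p - 1]
            elif trt == "cheat_b" and p == 1:
                cyc = 9
            rows.append({"treatment": trt, "population_id": f"{trt}_P{p}",
                         "extinction_cycle": cyc})
    table = pd.DataFrame(rows).astype({"extinction_cycle": "float64"})
    return SurvivalLedger(table=table), {t: c for t, c in treatments.items()}


class TestExtinction:
    def test_reported_extinction_record_reproduced(self):
        ledger, cats = reported_ledger()
        curves = survival_curves(ledger)
        assert curves["n_total"] == 64
        assert curves["n_extinct"] == 17
        assert curves["percent_extinct"] == 27
        lethal = curves["series"]["antag_lethal"]
        assert lethal[0] == 8
        assert lethal[6] == 0 and lethal[5] > 0

    def test_reported_association_is_significant(self):
        ledger, cats = reported_ledger()
        res = extinction_test(ledger, cats)
        np.testing.assert_array_equal(res["table"], [[16, 8], [1, 39]])
        assert res["p"] <= 0.0001

    def test_no_association_gives_p_one(self):
        rows = []
        for trt, cat in (("a", "antagonist"), ("b", "none")):
            for p in range(8):
                rows.append({"treatment": trt, "population_id": f"{trt}{p}",
                             "extinction_cycle": 5.0 if p < 4 else None})
        ledger = SurvivalLedger(pd.DataFrame(rows).astype({"extinction_cycle": "float64"}))
        res = extinction_test(ledger, {"a": "antagonist", "b": "none"})
        assert res["p"] == pytest.approx(1.0)

    def test_two_by_two_oracle_value(self):
        assert fisher_oracle([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_fisher_matches_enumeration_on_all_small_tables(self):
        from scipy.stats import fisher_exact

        for N in range(2, 13):
            for a, b, c in itertools.product(range(N + 1), repeat=3):
                d = N - a - b - c
                if d < 0 or (a + b) == 0 or (c + d) == 0:
                    continue
                table = [[a, b], [c, d]]
                p_lib = fisher_exact(table, alternative="two-sided").pvalue
                p_or = fisher_oracle(table)
                assert p_lib == pytest.approx(p_or, rel=1e-7, abs=1e-12), table

    def test_fisher_p_invariant_to_transposition(self):
        from scipy.stats import fisher_exact

        for table in ([[16, 8], [1, 39]], [[3, 5], [7, 2]], [[0, 4], [6, 1]]):
            p1 = fisher_exact(table, alternative="two-sided").pvalue
            p2 = fisher_exact(np.transpose(table), alternative="two-sided").pvalue
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_no_extinctions_constant_series(self):
        rows = [{"treatment": "a", "population_id": f"p{i}", "extinction_cycle": None}
                for i in range(8)]
        ledger = SurvivalLedger(pd.DataFrame(rows).astype({"extinction_cycle": "float64"}))
        curves = survival_curves(ledger)
        assert np.all(curves["series"]["a"] == 8)
        assert curves["percent_extinct"] == 0

    def test_out_of_range_extinction_cycle_rejected(self):
        rows = [{"treatment": "a", "population_id": "p1", "extinction_cycle": 12.0},
                {"treatment": "a", "population_id": "p2", "extinction_cycle": None}]
        with pytest.raises(ValueError, match="extinction cycles"):
            SurvivalLedger(pd.DataFrame(rows).astype({"extinction_cycle": "float64"}))

    def test_empty_category_rejected(self):
        ledger, _ = reported_ledger()
        with pytest.raises(ValueError):
            extinction_table(ledger, {t: "other" for t in
                                      ledger.table["treatment"].unique()})


class TestContrasts:
    def test_identical_groups_t_zero_p_one(self):
        res = contrasts_evolved_vs_anc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            contrasts_evolved_vs_anc([1.0], [1.0, 2.0])

    def test_null_anova_f_near_one_in_expectation(self):
        rng = np.random.default_rng(23)
        n_sim, fs = 2000, []
        for _ in range(n_sim):
            groups = {g: rng.normal(size=5) for g in "abc"}
            fs.append(contrasts_among_categories(groups, tukey=False)["F"])
        fs = np.array(fs)
        se = fs.std(ddof=1) / math.sqrt(n_sim)
        # mean of F(2, 12) is df2/(df2-2) = 1.2
        assert abs(fs.mean() - 1.2) < 3 * se

    def test_planted_shift_flagged_by_tukey(self):
        """A 5-SD shift in one of three groups (n = 3) is detected by the
        two Tukey pairs involving that group in >= 90% of runs."""
        rng = np.random.default_rng(29)
        n_runs, hits = 200, 0
        for _ in range(n_runs):
            groups = {
                "a": rng.normal(0, 1, 3),
                "b": rng.normal(0, 1, 3),
                "shifted": rng.normal(5, 1, 3),
            }
            res = contrasts_among_categories(groups)
            p = res["tukey_p"]
            flag_ab = p[("a", "b")] < 0.05
            flag_as = p[("a", "shifted")] < 0.05
            flag_bs = p[("b", "shifted")] < 0.05
            if flag_as and flag_bs and not flag_ab:
                hits += 1
        assert hits >= 0.9 * n_runs
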