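"""Evaluation statistics: Kendall tau-b against independent oracles,
correlation grids on simulated series, ANOVA + Tukey letter displays."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ratioamp.errors import DomainError, InsufficientDataError
from ratioamp.ramp_core import UNDEFINED
from ratioamp.stats_eval import (
    compact_letter_display,
    correlate_indexes,
    kendall_tau_b,
    oneway_anova_tukey,
)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, loop-based)
# ---------------------------------------------------------------------------

def tau_b_pair_count_oracle(x, y):
    """O(n^2) pair classification, integer counts, textbook tau-b formula."""
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            a = int(x[i] > x[j]) - int(x[i] < x[j])
            b = int(y[i] > y[j]) - int(y[i] < y[j])
            if a == 0:
                tx += 1
            if b == 0:
                ty += 1
            if a != 0 and b != 0:
                if a == b:
                    concordant += 1
                else:
                    discordant += 1
    n0 = n * (n - 1) // 2
    return (concordant - discordant) / math.sqrt((n0 - tx) * (n0 - ty))


def exact_p_enumeration_oracle(x, y):
    """Two-sided permutation p by enumerating every ordering of y and
    recomputing tau with the pair-count oracle."""
    tau_obs = abs(tau_b_pair_count_oracle(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(tau_b_pair_count_oracle(x, list(perm))) >= tau_obs - 1e-12:
            hits += 1
    return hits / total


def anova_f_oracle(groups):
    """Hand-computed one-way ANOVA F from sums of squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestKendallTauB:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 1.0 / 3.0),
        ],
    )
    def test_textbook_examples(self, x, y, expected):
        result = kendall_tau_b(x, y)
        assert result.tau == pytest.approx(expected, rel=1e-12)

    def test_matches_pair_count_oracle_exactly_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 50))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 8, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            result = kendall_tau_b(x, y, method="asymptotic")
            assert result.tau == tau_b_pair_count_oracle(x, y)

    def test_matches_scipy_tau_b(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(y == y[0]):
                continue
            ours = kendall_tau_b(x, y, method="asymptotic")
            ref = sps.kendalltau(x, y)
            assert ours.tau == pytest.approx(ref.statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            result = kendall_tau_b(x, y, method="exact")
            assert result.method == "exact"
            assert result.p_value == pytest.approx(
                exact_p_enumeration_oracle(list(x), list(y)), abs=1e-12
            )

    def test_zero_variance_is_undefined(self):
        result = kendall_tau_b([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert result.tau is UNDEFINED
        assert not result.defined

    def test_contract_violations(self):
        with pytest.raises(DomainError):
            kendall_tau_b([1, 2, 3], [1, 2])
        with pytest.raises(DomainError):
            kendall_tau_b([1, 2], [1, 2])
        with pytest.raises(DomainError):
            kendall_tau_b([1, 2, 3, 4, 5, 6, 7, 8, 9], [9, 8, 7, 6, 5, 4, 3, 2, 1],
                          method="exact")


def _index_table(mechanism_models, seed=9):
    """Per-sample table of index values and reference Cts from the simulator."""
    from ratioamp.degradation_sim import (
        default_panel, default_pool, pseudo_rin, simulate_plate,
    )
    from ratioamp.qpcr_io import aggregate_table
    from ratioamp.ramp_core import build_pairs, compute_ramp_series

    panel, pool = default_panel(), default_pool()
    pair = build_pairs(panel)[0]
    rows = []
    for name, model in mechanism_models.items():
        plate = simulate_plate(pool, panel, model, seed=seed)
        aggs = aggregate_table(plate.observations, panel)
        series = {}
        for (_, assay_id), agg in aggs.items():
            series.setdefault(agg.degradation_level, {})[assay_id] = agg
        ramps = compute_ramp_series(series, pair, level_order=list(model.levels))
        for level, ramp in zip(model.levels, ramps):
            rows.append({
                "experiment": name,
                "ramp": float(ramp.value),
                "rin": pseudo_rin(model, pool, level),
                "ct_amoA": series[level]["amoA_491"].mean_ct,
                "ct_16S": series[level]["rrs_143"].mean_ct,
            })
    return pd.DataFrame(rows)


class TestCorrelateIndexes:
    def test_strand_break_series_ramp_tracks_cts(self):
        # pooled heat + nuclease series (n = 8): a perfectly monotone
        # 4-point series alone cannot reach exact-permutation significance
        from ratioamp.degradation_sim import demo_models

        models = demo_models()
        table = _index_table({"heat": models["heat"],
                              "nuclease": models["nuclease"]})
        report = correlate_indexes(table, ["ramp"], ["ct_amoA", "ct_16S"])
        for target in ("ct_amoA", "ct_16S"):
            entry = report.get("ramp", target)
            assert float(entry.tau) < 0
            assert entry.significant

    def test_blocking_lesion_rin_undefined_while_ramp_tracks(self):
        from ratioamp.degradation_sim import demo_models

        table = _index_table({"uv": demo_models()["uv"]})
        report = correlate_indexes(table, ["ramp", "rin"], ["ct_amoA"])
        rin_entry = report.get("rin", "ct_amoA")
        assert rin_entry.tau is UNDEFINED
        assert not rin_entry.significant
        ramp_entry = report.get("ramp", "ct_amoA")
        assert float(ramp_entry.tau) < 0

    def test_subset_filter_changes_n(self):
        from ratioamp.degradation_sim import demo_models

        models = demo_models()
        table = _index_table({"heat": models["heat"], "uv": models["uv"]})
        full = correlate_indexes(table, ["ramp"], ["ct_amoA"])
        no_uv = correlate_indexes(table, ["ramp"], ["ct_amoA"], subset=["heat"])
        assert full.get("ramp", "ct_amoA").n == 8
        assert no_uv.get("ramp", "ct_amoA").n == 4

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            correlate_indexes(table, ["a"], ["b"])


class TestAnovaTukey:
    def test_indistinguishable_levels_share_one_letter(self):
        rng = np.random.default_rng(21)
        groups = {
            "0min": list(0.00 + rng.normal(0, 5, 3)),
            "10min": list(0.01 + rng.normal(0, 5, 3)),
            "45min": list(0.02 + rng.normal(0, 5, 3)),
        }
        assert anova_f_oracle(list(groups.values())) < 1.0  # oracle sanity
        result = oneway_anova_tukey(groups)
        assert result.p_value > 0.05
        assert not result.posthoc_run
        assert set(result.display.letters.values()) == {"a"}

    def test_separated_levels_get_distinct_letters(self):
        rng = np.random.default_rng(22)
        groups = {
            "0min": list(0.0 + rng.normal(0, 0.01, 3)),
            "10min": list(10.0 + rng.normal(0, 0.01, 3)),
            "45min": list(20.0 + rng.normal(0, 0.01, 3)),
        }
        result = oneway_anova_tukey(groups)
        assert result.p_value <= 0.05
        letters = result.display.letters
        assert len({letters[k] for k in groups}) == 3
        assert all(len(v) == 1 for v in letters.values())
        # studentized-range oracle: every pairwise adjusted p is small
        assert all(p < 0.05 for p in result.display.pairwise_p.values())

    def test_identical_groups_f_zero_same_letter(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        result = oneway_anova_tukey(groups)
        assert result.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.display.letters["a"] == result.display.letters["b"]

    def test_f_matches_hand_computed_oracle(self):
        rng = np.random.default_rng(23)
        groups = {k: list(rng.normal(m, 1.0, 4)) for k, m in
                  [("a", 0.0), ("b", 1.5), ("c", 3.0)]}
        result = oneway_anova_tukey(groups)
        assert result.f_statistic == pytest.approx(
            anova_f_oracle(list(groups.values())), rel=1e-9
        )

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(24)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(2.0, 1.0, 9)
        result = oneway_anova_tukey({"a": a, "b": b})
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert result.f_statistic == pytest.approx(t**2, rel=1e-9)

    def test_single_replicate_level_rejected(self):
        with pytest.raises(DomainError):
            oneway_anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestCompactLetterDisplay:
    def test_sharing_relation_matches_thresholded_p(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            levels = [f"L{i}" for i in range(k)]
            pairwise = {
                (a, b): float(rng.uniform(0, 1))
                for a, b in itertools.combinations(levels, 2)
            }
            letters = compact_letter_display(levels, pairwise, alpha=0.05)
            for (a, b), p in pairwise.items():
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (p > 0.05), (pairwise, letters)

    def test_every_level_gets_a_letter(self):
        levels = ["a", "b", "c"]
        pairwise = {("a", "b"): 0.001, ("a", "c"): 0.001, ("b", "c"): 0.001}
        letters = compact_letter_display(levels, pairwise)
        assert all(letters[lv] for lv in levels)
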