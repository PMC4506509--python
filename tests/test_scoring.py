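"""Unit and property tests for the AP-MS scoring operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poldiff.errors import (
    DesignError,
    ImputationError,
    NormalizationError,
    ValidationError,
)
from poldiff.errors import TestError as DiffTestError  # alias: not a test class
from poldiff.io import IMPUTED
from poldiff.scoring import (
    DifferentialResult,
    ScoringConfig,
    adjust_bh,
    analysis_universe,
    build_display_matrix,
    classify_interactions,
    differential_interaction_test,
    flag_high_confidence,
    impute_zero_counts,
    normalize_by_bait,
)

from conftest import make_table

CFG = ScoringConfig(bait_id="BAIT")


def bh_oracle(p):
    """Brute-force step-up: sort, scale by n/rank, enforce monotone from top."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


class TestNormalizeByBait:
    def test_counts_scaled_by_run_bait(self):
        t = make_table([("BAIT", "r1", 50), ("X", "r1", 25)])
        out = normalize_by_bait(t, "BAIT")
        assert out.matrix().loc["X", "r1"] == 0.5
        assert out.matrix().loc["BAIT", "r1"] == 1.0

    def test_scale_invariance_across_runs(self):
        rows = [("BAIT", f"r{i}", b) for i, b in enumerate((40, 50, 60), 1)]
        rows += [("X", f"r{i}", b // 2) for i, b in enumerate((40, 50, 60), 1)]
        out = normalize_by_bait(make_table(rows), "BAIT")
        assert set(out.matrix().loc["X"]) == {0.5}

    def test_missing_bait_names_run(self):
        t = make_table([("BAIT", "r1", 50), ("X", "r1", 2), ("X", "r3", 2)])
        with pytest.raises(NormalizationError, match="r3"):
            normalize_by_bait(t, "BAIT")


class TestImputeZeroCounts:
    def test_noise_floor_distribution_matches_lowest_quintile(self, rng):
        # nonzero counts {2,3,5,8,13,21,40,100}: lowest 20% of m=8 -> {2,3},
        # so draws should follow Normal(2.5, sd=0.7071) (truncation negligible)
        counts = [2, 3, 5, 8, 13, 21, 40, 100]
        rows = [(f"p{i}", "r1", c) for i, c in enumerate(counts)]
        universe = [f"p{i}" for i in range(len(counts))] + [
            f"z{i}" for i in range(10_000)
        ]
        out = impute_zero_counts(
            make_table(rows), CFG, rng, universe=universe, runs=["r1"]
        )
        mat = out.matrix()
        draws = mat.loc[[f"z{i}" for i in range(10_000)], "r1"].to_numpy()
        sd = math.sqrt(((2 - 2.5) ** 2 + (3 - 2.5) ** 2) / 1)  # ddof=1 -> 0.7071
        floor = 2.5 - 3 * sd
        assert (draws >= floor).all()
        # clipping puts a tiny atom exactly at the floor; above it the draws
        # must follow the truncated Normal(2.5, 0.7071)
        above = draws[draws > floor]
        assert draws.size - above.size < 50  # P(clip) = Phi(-3) ~ 0.00135
        norm = stats.norm(loc=2.5, scale=sd)
        p_lo = norm.cdf(floor)
        ks = stats.kstest(above, lambda x: (norm.cdf(x) - p_lo) / (1 - p_lo))
        assert ks.pvalue > 1e-3
        assert np.mean(draws) == pytest.approx(2.5, abs=0.03)   # se ~ 0.007
        assert np.std(draws) == pytest.approx(sd, abs=0.02)     # se ~ 0.005

    def test_no_zeros_means_identity(self, rng):
        t = make_table([("p1", "r1", 4), ("p2", "r1", 9)])
        out = impute_zero_counts(t, CFG, rng)
        assert out.matrix().equals(t.matrix())

    def test_same_seed_same_output(self):
        t = make_table([("p1", "r1", 4), ("p2", "r1", 9), ("p3", "r2", 2),
                        ("p1", "r2", 6)])
        a = impute_zero_counts(t, CFG, np.random.default_rng(7))
        b = impute_zero_counts(t, CFG, np.random.default_rng(7))
        assert a == b

    def test_nonzero_counts_untouched_and_all_positive(self, rng):
        t = make_table([("p1", "r1", 4), ("p2", "r1", 9), ("p3", "r1", 0)])
        out = impute_zero_counts(t, CFG, rng)
        mat = out.matrix()
        assert mat.loc["p1", "r1"] == 4
        assert mat.loc["p2", "r1"] == 9
        assert (mat.to_numpy() > 0).all()

    def test_fewer_than_two_nonzero_is_error(self, rng):
        t = make_table([("p1", "r1", 4), ("p2", "r1", 0)])
        with pytest.raises(ImputationError, match="r1"):
            impute_zero_counts(t, CFG, rng)


def _hci_fixture(mean_wt, mean_ev, present_all_wt=True):
    """One protein with chosen WT/EV means; bait-free minimal trio layout."""
    rows = []
    for k in (1, 2, 3):
        wt = mean_wt if present_all_wt or k != 2 else 0
        rows += [("P", f"WT_{k}", wt), ("P", f"N32I_{k}", 1), ("P", f"EV_{k}", mean_ev)]
        rows += [("F", f"WT_{k}", 5), ("F", f"N32I_{k}", 5), ("F", f"EV_{k}", 5)]
    raw = make_table([(p, r, int(c)) for p, r, c in rows])
    counts = make_table(
        [(p, r, float(c) if c else 0.5) for p, r, c in rows], kind=IMPUTED
    )
    return raw, counts


class TestFlagHighConfidence:
    def test_ratio_above_threshold_flagged(self, reference_design):
        raw, counts = _hci_fixture(mean_wt=6, mean_ev=1)
        out = flag_high_confidence(raw, counts, reference_design, "N32I", CFG)
        p = next(s for s in out if s.protein_id == "P")
        assert p.high_confidence and p.basis == "WT"
        assert p.ratio_wt_ev == pytest.approx(6.0)

    def test_ratio_exactly_five_not_flagged(self, reference_design):
        raw, counts = _hci_fixture(mean_wt=5, mean_ev=1)
        out = flag_high_confidence(raw, counts, reference_design, "N32I", CFG)
        p = next(s for s in out if s.protein_id == "P")
        assert not p.high_confidence

    def test_missing_replicate_blocks_flag(self, reference_design):
        raw, counts = _hci_fixture(mean_wt=30, mean_ev=1, present_all_wt=False)
        out = flag_high_confidence(raw, counts, reference_design, "N32I", CFG)
        p = next(s for s in out if s.protein_id == "P")
        assert not p.high_confidence

    def test_missing_ev_runs_is_design_error(self):
        from conftest import make_design

        design = make_design(
            [("WT_1", "WT", 1, "p1"), ("WT_2", "WT", 2, "p2"),
             ("WT_3", "WT", 3, "p3"),
             ("N32I_1", "MUT:N32I", 1, "p1"), ("N32I_2", "MUT:N32I", 2, "p2"),
             ("N32I_3", "MUT:N32I", 3, "p3")]
        )
        raw, counts = _hci_fixture(6, 1)
        with pytest.raises(DesignError, match="EV"):
            flag_high_confidence(raw, counts, design, "N32I", CFG)


def _results_for_ratios(ratios, reference_design, scale="raw"):
    cfg = ScoringConfig(bait_id="BAIT", ratio_scale=scale)
    rows = [("BAIT", r, 1.0) for r in
            [f"WT_{k}" for k in (1, 2, 3)] + [f"N32I_{k}" for k in (1, 2, 3)]]
    for k, r in enumerate(ratios, 1):
        rows += [("P", f"WT_{k}", 1.0), ("P", f"N32I_{k}", float(r))]
    table = make_table(rows, kind=IMPUTED)
    return differential_interaction_test(table, reference_design, "N32I", ["P"], cfg)


class TestDifferentialTest:
    def test_known_triplet(self, reference_design):
        (res,) = _results_for_ratios((2.0, 2.2, 1.8), reference_design)
        assert res.t_statistic == pytest.approx(8.6603, abs=1e-4)
        assert res.degrees_of_freedom == 2
        assert res.p_raw == pytest.approx(0.013072, abs=5e-5)
        assert res.mean_ratio == pytest.approx(2.0)

    def test_zero_variance_at_null_gives_p_one(self, reference_design):
        (res,) = _results_for_ratios((1.0, 1.0, 1.0), reference_design)
        assert res.mean_ratio == 1.0
        assert res.p_raw == 1.0

    def test_zero_variance_off_null_gives_p_zero(self, reference_design):
        (res,) = _results_for_ratios((2.0, 2.0, 2.0), reference_design)
        assert res.p_raw == 0.0
        assert math.isinf(res.t_statistic)

    def test_log2_scale_symmetric_in_inversion(self, reference_design):
        (up,) = _results_for_ratios((2.0, 2.0, 2.0), reference_design, scale="log2")
        (down,) = _results_for_ratios((0.5, 0.5, 0.5), reference_design, scale="log2")
        assert up.p_raw == down.p_raw

    def test_closed_form_df2(self, reference_design, rng):
        """Two-tailed p for df=2 equals F(t) = 1/2 (1 + t/sqrt(2+t^2))."""
        for _ in range(25):
            ratios = rng.lognormal(0.3, 0.2, size=3)
            (res,) = _results_for_ratios(tuple(ratios), reference_design)
            t = res.t_statistic
            expected = 2.0 * (1.0 - 0.5 * (1.0 + abs(t) / math.sqrt(2 + t * t)))
            assert res.p_raw == pytest.approx(expected, abs=1e-9)

    def test_non_positive_count_rejected(self, reference_design):
        rows = [("BAIT", r, 1.0) for r in
                [f"WT_{k}" for k in (1, 2, 3)] + [f"N32I_{k}" for k in (1, 2, 3)]]
        rows += [("P", "WT_1", 1.0), ("P", "N32I_1", 2.0), ("P", "WT_2", 1.0),
                 ("P", "N32I_2", 2.0), ("P", "WT_3", 0.0), ("P", "N32I_3", 2.0)]
        with pytest.raises(DiffTestError, match="impute"):
            differential_interaction_test(
                make_table(rows, kind=IMPUTED), reference_design, "N32I", ["P"],
                ScoringConfig(bait_id="BAIT"),
            )


class TestAdjustBH:
    def test_worked_example(self):
        assert list(adjust_bh([0.01, 0.02, 0.03, 0.04])) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_oracle_and_dominates_input(self, p):
        adj = adjust_bh(p)
        assert np.allclose(adj, bh_oracle(p), rtol=0, atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


def _res(p_adj, mean_ratio):
    return DifferentialResult(
        protein_id="P", ratios=(mean_ratio,) * 3, mean_ratio=mean_ratio,
        log2_mean_ratio=math.log2(mean_ratio), t_statistic=0.0,
        degrees_of_freedom=2, p_raw=p_adj, p_adjusted=p_adj,
    )


class TestClassifyAndDisplay:
    @pytest.mark.parametrize(
        "p_adj,ratio,label",
        [
            (0.01, 0.30, "decreased"),
            (0.001, 1.20, "not_significant"),  # fold-change gate fails
            (0.06, 3.00, "not_significant"),   # alpha gate fails
            (0.01, 3.00, "increased"),
        ],
    )
    def test_dual_criterion(self, p_adj, ratio, label):
        (out,) = classify_interactions([_res(p_adj, ratio)], CFG)
        assert out.label == label

    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.02, -4.5), (1.0, 0.0), (0.5, -1.0)],
    )
    def test_display_cap(self, ratio, expected):
        results = classify_interactions([_res(0.01, ratio)], CFG)
        heat, volcano = build_display_matrix({"N32I": results}, CFG)
        assert heat.loc["P", "N32I"] == pytest.approx(expected, abs=1e-6)
        assert volcano.loc[0, "log2_mean_ratio"] == pytest.approx(
            math.log2(ratio)
        )


def test_analysis_universe_is_observed_proteins():
    t = make_table([("a", "r1", 3), ("b", "r1", 0), ("c", "r2", 1)])
    assert analysis_universe(t) == ["a", "c"]
    assert analysis_universe(t, runs=["r1"]) == ["a"]
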