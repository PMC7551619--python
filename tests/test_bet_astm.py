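"""Best-estimate threshold decision rule, group summaries, comparisons."""

import itertools
import math

import numpy as np
import pytest

from threshpanel.bet_astm import (
    BETResult,
    RULE_ADAPTATION,
    RULE_IMPUTED,
    RULE_LOWEST,
    RULE_STANDARD,
    classify_and_estimate,
    compare_log_bets,
    summarize_group,
)
from threshpanel.core_data import ConcentrationSeries
from threshpanel.errors import InsufficientDataError, IntegrityError

# ---------------------------------------------------------------------------
# Independent brute-force oracle, written before the implementation and kept
# deliberately different in mechanism (string patterns, rstrip-based run
# detection) from the package's index arithmetic.
# ---------------------------------------------------------------------------


def oracle_bet(pattern: str, levels: tuple[float, ...]):
    """Three-branch rule on a 'C'/'W' pattern; returns (bet, rule)."""
    lo_ext = levels[0] / (levels[1] / levels[0])
    hi_ext = levels[-1] * (levels[-1] / levels[-2])
    extended = (lo_ext,) + tuple(levels)

    if pattern.endswith("C"):
        start = len(pattern.rstrip("C"))  # first index of the trailing run
        bet = math.sqrt(extended[start] * extended[start + 1])
        return bet, (RULE_STANDARD if start > 0 else RULE_LOWEST)
    if "CCC" in pattern:
        start = pattern.index("CCC")
        bet = math.sqrt(extended[start] * extended[start + 1])
        return bet, RULE_ADAPTATION
    return math.sqrt(levels[-1] * hi_ext), RULE_IMPUTED


LADDER5 = (0.2, 2.0, 20.0, 200.0, 2000.0)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "pattern,bet,rule",
        [
            ("WWWCC", math.sqrt(20 * 200), RULE_STANDARD),
            ("CCCCC", math.sqrt(0.02 * 0.2), RULE_LOWEST),
            ("WCCCW", math.sqrt(0.2 * 2), RULE_ADAPTATION),
            ("CWCWW", math.sqrt(2000 * 20000), RULE_IMPUTED),
            ("WWWWC", math.sqrt(200 * 2000), RULE_STANDARD),
            ("CCCWW", math.sqrt(0.02 * 0.2), RULE_ADAPTATION),
        ],
    )
    def test_worked_examples(self, pattern, bet, rule):
        series = ConcentrationSeries(LADDER5)
        result = classify_and_estimate([c == "C" for c in pattern], series)
        assert result.bet == pytest.approx(bet)
        assert result.rule == rule
        assert result.responder == (rule != RULE_IMPUTED)

    @pytest.mark.parametrize("n_levels", [5, 6])
    def test_all_patterns_match_brute_force_oracle(self, n_levels):
        """Exhaustive agreement over every outcome pattern of the ladder."""
        levels = LADDER5 if n_levels == 5 else (0.2, 2.0, 20.0, 200.0, 2000.0, 20000.0)
        series = ConcentrationSeries(levels)
        for bits in itertools.product([True, False], repeat=n_levels):
            pattern = "".join("C" if b else "W" for b in bits)
            expected_bet, expected_rule = oracle_bet(pattern, levels)
            got = classify_and_estimate(bits, series)
            assert got.bet == pytest.approx(expected_bet), pattern
            assert got.rule == expected_rule, pattern

    def test_adaptation_uses_lowest_qualifying_run(self):
        # Two runs of three (levels 1-3 and 5-7); the lower one defines the BET.
        levels = (1, 10, 100, 1000, 1e4, 1e5, 1e6, 1e7)
        series = ConcentrationSeries(levels)
        outcomes = [True, True, True, False, True, True, True, False]
        result = classify_and_estimate(outcomes, series)
        assert result.rule == RULE_ADAPTATION
        assert result.bet == pytest.approx(math.sqrt(0.1 * 1))

    def test_bet_scales_with_the_ladder(self):
        series = ConcentrationSeries(LADDER5)
        scaled = ConcentrationSeries(tuple(7.0 * c for c in LADDER5))
        for bits in itertools.product([True, False], repeat=5):
            a = classify_and_estimate(bits, series)
            b = classify_and_estimate(bits, scaled)
            assert b.bet == pytest.approx(7.0 * a.bet)
            assert b.rule == a.rule

    def test_length_mismatch_raises(self):
        with pytest.raises(IntegrityError):
            classify_and_estimate([True, False], ConcentrationSeries(LADDER5))


def _bets(values, responder=True):
    return [BETResult(f"P{i}", v, RULE_STANDARD if responder else RULE_IMPUTED, responder)
            for i, v in enumerate(values)]


class TestGroupSummary:
    def test_geometric_mean_is_antilog_of_mean_log(self):
        summary = summarize_group(_bets([10.0, 1000.0]))
        assert summary.geometric_mean_bet == pytest.approx(100.0)
        assert summary.sd_log_bet == pytest.approx(np.std([1, 3], ddof=1))

    def test_responder_counting_matches_printed_percentages(self):
        # 34 responders of 56 -> 61%; 31 of 54 -> 57%.
        for n_resp, n_total, pct in ((34, 56, 61), (31, 54, 57)):
            bets = _bets(range(1, n_resp + 1)) + _bets(
                [6324.6] * (n_total - n_resp), responder=False
            )
            summary = summarize_group(bets)
            assert summary.n_responders == n_resp
            assert summary.n_anosmic == n_total - n_resp
            assert round(100 * summary.responder_fraction) == pct

    def test_imputed_bets_excluded_from_statistics(self):
        bets = _bets([10.0, 1000.0]) + _bets([6324.6] * 5, responder=False)
        assert summarize_group(bets).geometric_mean_bet == pytest.approx(100.0)

    def test_all_anosmic_group_has_no_geometric_mean(self):
        summary = summarize_group(_bets([6324.6] * 4, responder=False))
        assert summary.n_responders == 0
        assert summary.geometric_mean_bet is None
        assert summary.sd_log_bet is None

    def test_geometric_mean_between_extremes(self):
        summary = summarize_group(_bets([2.0, 30.0, 500.0]))
        assert 2.0 < summary.geometric_mean_bet < 500.0


class TestLogBETComparison:
    def test_identical_groups_give_t_zero_p_one(self):
        group = _bets([1.0, 10.0, 100.0])
        cmp = compare_log_bets(group, list(group))
        assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # log10 {1,10,100} = {0,1,2} vs log10 {10,100,1000} = {1,2,3}:
        # pooled variance 1, se = sqrt(2/3), t = -sqrt(3/2), df = 4.
        cmp = compare_log_bets(_bets([1.0, 10.0, 100.0]), _bets([10.0, 100.0, 1000.0]))
        assert cmp.t_statistic == pytest.approx(-math.sqrt(1.5))
        assert cmp.degrees_of_freedom == 4

    def test_degrees_of_freedom_from_responder_counts(self):
        cmp = compare_log_bets(_bets(range(1, 35)), _bets(range(1, 32)))
        assert (cmp.n_a, cmp.n_b) == (34, 31)
        assert cmp.degrees_of_freedom == 63

    def test_antisymmetry(self):
        a, b = _bets([1.0, 5.0, 40.0]), _bets([3.0, 90.0, 700.0])
        fwd, rev = compare_log_bets(a, b), compare_log_bets(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_imputed_non_responders_do_not_count_toward_minimum(self):
        sparse = _bets([10.0]) + _bets([6324.6] * 3, responder=False)
        with pytest.raises(InsufficientDataError):
            compare_log_bets(sparse, _bets([1.0, 2.0, 3.0]))
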