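import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cisnat.expression_stats import (
    Concordance,
    ConditionProfile,
    DEStatus,
    ResponsePattern,
    call_de,
    classify_pi_response,
    detect_nat_pairs,
    fisher_de,
    fold_change,
    fpkm,
    pearson_r,
    select_robust_replicates,
)
from cisnat.io_formats import CONDITIONS, ValidationError
from cisnat.nat_classify import NATCall, OverlapClass, Thresholds
from cisnat.transcript_model import UndefinedValueError


def enumerate_fisher_oracle(c1, n1, c2, n2):
    """Full hypergeometric enumeration with exact rational arithmetic."""
    from fractions import Fraction

    M, K = n1 + n2, c1 + c2
    denom = math.comb(M, K)
    probs = {
        k: Fraction(math.comb(n1, k) * math.comb(n2, K - k), denom)
        for k in range(max(0, K - n2), min(K, n1) + 1)
    }
    p_obs = probs[c1]
    return float(sum(p for p in probs.values() if p <= p_obs))


def profile(fpkms, length=1000, lib=10_000_000, counts=True):
    """ConditionProfile with counts reconstituted from the FPKM values."""
    fpkm_map = dict(zip(CONDITIONS, fpkms))
    count_map = None
    if counts:
        count_map = {
            c: (int(round(v * length * lib / 1e9)), lib) for c, v in fpkm_map.items()
        }
    return ConditionProfile("t", fpkm=fpkm_map, counts=count_map, exonic_length=length)


class TestFpkm:
    def test_formula(self):
        assert fpkm(100, 10**6, 1000) == pytest.approx(100.0)
        assert fpkm(0, 10**6, 1000) == 0.0

    def test_scale_invariance(self):
        assert fpkm(100, 10**6, 500) == pytest.approx(fpkm(200, 2 * 10**6, 500))

    @pytest.mark.parametrize("args", [(1, 0, 100), (1, 100, 0), (-1, 100, 100)])
    def test_invalid(self, args):
        with pytest.raises(ValidationError):
            fpkm(*args)


class TestReplicatePooling:
    def test_identical_pair_selected(self):
        df = pd.DataFrame(
            {"r1": [10, 20, 5], "r2": [10, 20, 5], "r3": [20, 5, 10]}
        )
        (a, b), pooled, r = select_robust_replicates(df)
        assert {a, b} == {"r1", "r2"}
        assert r == pytest.approx(1.0)
        assert pooled.tolist() == [20, 40, 10]

    def test_two_replicates_trivial(self):
        df = pd.DataFrame({"r1": [10, 30], "r2": [12, 28]})
        (a, b), pooled, _ = select_robust_replicates(df)
        assert (a, b) == ("r1", "r2")
        assert pooled.tolist() == [22, 58]

    def test_fpkm_pooling_is_mean(self):
        df = pd.DataFrame({"r1": [10.0, 30.0], "r2": [20.0, 10.0]})
        with pytest.warns(UserWarning):  # anticorrelated pair triggers QC
            _, pooled, _ = select_robust_replicates(df, kind="fpkm")
        assert pooled.tolist() == [15.0, 20.0]

    def test_low_correlation_warns(self):
        df = pd.DataFrame({"r1": [1, 2, 3, 4], "r2": [4, 1, 3, 2]})
        with pytest.warns(UserWarning, match="correlates"):
            select_robust_replicates(df)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            select_robust_replicates(pd.DataFrame({"r1": [1, 2]}))


class TestFisher:
    def test_enumerated_example(self):
        # table [[2,0],[0,2]]: probabilities 1/6, 4/6, 1/6 over the support
        assert fisher_de(2, 2, 0, 2) == pytest.approx(1 / 3)

    def test_symmetric_table_is_one(self):
        assert fisher_de(5, 20, 5, 20) == pytest.approx(1.0)

    def test_sample_swap_symmetry(self):
        assert fisher_de(3, 15, 9, 22) == pytest.approx(fisher_de(9, 22, 3, 15))

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            fisher_de(5, 3, 0, 2)

    def test_enumeration_oracle_small_margins(self):
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for c1 in range(n1 + 1):
                    for c2 in range(n2 + 1):
                        assert fisher_de(c1, n1, c2, n2) == pytest.approx(
                            enumerate_fisher_oracle(c1, n1, c2, n2), abs=1e-12
                        )

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n1, n2 = rng.integers(1, 500, size=2)
            c1, c2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            expected = stats.fisher_exact([[c1, n1 - c1], [c2, n2 - c2]])[1]
            assert fisher_de(int(c1), int(n1), int(c2), int(n2)) == pytest.approx(
                expected, rel=1e-9
            )


class TestFoldChange:
    def test_exact_when_well_measured(self):
        assert fold_change(10, 20, 0.1) == 2.0
        assert fold_change(10, 10, 0.1) == 1.0

    def test_pseudocount_near_zero(self):
        assert fold_change(0, 1, 0.1) == pytest.approx(11.0)

    def test_both_zero_without_pseudocount(self):
        with pytest.raises(UndefinedValueError):
            fold_change(0, 0, 0)


class TestCallDe:
    TH = Thresholds()

    def test_up(self):
        call = call_de(10.0, 40.0, self.TH, counts=(100, 10**6, 400, 10**6))
        assert call.status == DEStatus.UP and call.fold_change == 4.0

    def test_p_gate_fails(self):
        # fold change 4 but counts far too small for significance
        call = call_de(10.0, 40.0, self.TH, counts=(1, 10**6, 4, 10**6))
        assert call.status == DEStatus.UNCHANGED and call.p_value > 0.05

    def test_fold_gate_fails(self):
        call = call_de(10.0, 19.0, self.TH, counts=(1000, 10**6, 1900, 10**6))
        assert call.status == DEStatus.UNCHANGED and call.p_value < 0.05

    def test_boundary_fold_two_passes(self):
        call = call_de(10.0, 20.0, self.TH, counts=(1000, 10**6, 2000, 10**6))
        assert call.fold_change == 2.0 and call.status == DEStatus.UP

    def test_down(self):
        call = call_de(40.0, 10.0, self.TH, counts=(400, 10**6, 100, 10**6))
        assert call.status == DEStatus.DOWN

    def test_fpkm_only_mode_warns_and_disables_p(self):
        with pytest.warns(UserWarning, match="fold change only"):
            call = call_de(10.0, 40.0, self.TH)
        assert call.status == DEStatus.UP and math.isnan(call.p_value)

    def test_monotone_in_fold_change(self):
        # with a significant p, status moves DOWN -> UNCHANGED -> UP
        order = []
        for alt in (5.0, 15.0, 40.0):
            c = call_de(
                10.0, alt, self.TH, counts=(1000, 10**6, int(alt * 100), 10**6)
            )
            order.append(c.status)
        assert order == [DEStatus.DOWN, DEStatus.UNCHANGED, DEStatus.UP]


class TestPiResponse:
    def test_up_responsive_return_to_control(self):
        p = profile([10, 40, 40, 10, 10])
        assert classify_pi_response(p) == ResponsePattern.UP_PI_RESPONSIVE

    def test_up_depletion_only(self):
        p = profile([10, 40, 40, 45, 10])
        assert classify_pi_response(p) == ResponsePattern.UP_DEPLETION_ONLY

    def test_up_responsive_via_drop_from_depleted(self):
        # R4 is DOWN vs P4 even though still elevated above C4's level
        p = profile([10, 80, 80, 25, 10])
        assert classify_pi_response(p) == ResponsePattern.UP_PI_RESPONSIVE

    def test_down_responsive(self):
        p = profile([40, 10, 10, 40, 40])
        assert classify_pi_response(p) == ResponsePattern.DOWN_PI_RESPONSIVE

    def test_down_depletion_only(self):
        p = profile([40, 10, 10, 8, 40])
        assert classify_pi_response(p) == ResponsePattern.DOWN_DEPLETION_ONLY

    def test_flat_is_none(self):
        p = profile([10, 10, 10, 10, 10])
        assert classify_pi_response(p) == ResponsePattern.NONE

    def test_missing_condition_rejected(self):
        with pytest.raises(ValidationError):
            ConditionProfile("t", fpkm={"C4": 1.0, "P4": 2.0})

    def test_label_stable_under_rescaling_in_fold_only_mode(self):
        base = [10, 40, 40, 10, 10]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in (0.5, 1.0, 7.0):
                p = profile([k * v for v in base], counts=False)
                assert classify_pi_response(p) == ResponsePattern.UP_PI_RESPONSIVE


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson_r([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3, 4, 5], [10, 8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedValueError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.floats(0.1, 50), b=st.floats(-10, 10), flip=st.booleans()
    )
    def test_affine_invariance(self, a, b, flip):
        x = np.array([1.0, 2.0, 4.0, 8.0, 3.0])
        y = np.array([2.0, 1.0, 5.0, 7.0, 4.0])
        r0 = pearson_r(x, y)
        scale = -a if flip else a
        r1 = pearson_r(scale * x + b, y)
        assert r1 == pytest.approx(-r0 if flip else r0, abs=1e-6)


class TestPairDetection:
    def _call(self, nat="nat1", gene="gA"):
        return NATCall(nat, gene, 200, OverlapClass.FULL)

    def test_concordant_and_discordant(self):
        profiles = {
            "nat1": profile([10, 40, 45, 12, 11], counts=False),
            "gA": profile([20, 85, 90, 22, 25], counts=False),
            "nat2": profile([10, 40, 45, 12, 11], counts=False),
            "gB": profile([50, 12, 10, 48, 49], counts=False),
        }
        calls = [self._call(), NATCall("nat2", "gB", 100, OverlapClass.HEAD_TO_HEAD)]
        responses = {
            "nat1": ResponsePattern.UP_PI_RESPONSIVE,
            "nat2": ResponsePattern.UP_PI_RESPONSIVE,
        }
        pairs = detect_nat_pairs(calls, profiles, responses)
        assert len(pairs) == 2
        by_id = {p.nat_id: p for p in pairs}
        assert by_id["nat1"].concordance == Concordance.CONCORDANT
        assert by_id["nat1"].r > 0.9
        assert by_id["nat2"].concordance == Concordance.DISCORDANT
        assert by_id["nat2"].r < -0.9

    def test_low_r2_excluded(self):
        profiles = {
            "nat1": profile([10, 40, 10, 40, 10], counts=False),
            "gA": profile([10, 12, 30, 9, 28], counts=False),
        }
        responses = {"nat1": ResponsePattern.UP_PI_RESPONSIVE}
        r = pearson_r(profiles["nat1"].series(), profiles["gA"].series())
        assert r * r < 0.6  # sanity: the fixture really is sub-threshold
        assert detect_nat_pairs([self._call()], profiles, responses) == []

    def test_non_responsive_nat_skipped(self):
        profiles = {
            "nat1": profile([10, 40, 45, 12, 11], counts=False),
            "gA": profile([20, 85, 90, 22, 25], counts=False),
        }
        assert (
            detect_nat_pairs([self._call()], profiles, {"nat1": ResponsePattern.NONE})
            == []
        )

    def test_constant_partner_skipped(self):
        profiles = {
            "nat1": profile([10, 40, 45, 12, 11], counts=False),
            "gA": profile([5, 5, 5, 5, 5], counts=False),
        }
        responses = {"nat1": ResponsePattern.UP_PI_RESPONSIVE}
        assert detect_nat_pairs([self._call()], profiles, responses) == []

    def test_inclusive_r2_threshold(self):
        profiles = {
            "nat1": profile([1, 2, 3, 4, 5], counts=False),
            "gA": profile([2, 1, 1, 4, 6], counts=False),
        }
        responses = {"nat1": ResponsePattern.UP_PI_RESPONSIVE}
        r = pearson_r(profiles["nat1"].series(), profiles["gA"].series())
        r2 = r * r
        at = Thresholds(pair_r2=r2)
        above = Thresholds(pair_r2=min(1.0, np.nextafter(r2, 1.0)))
        assert len(detect_nat_pairs([self._call()], profiles, responses, th=at)) == 1
        assert detect_nat_pairs([self._call()], profiles, responses, th=above) == []
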