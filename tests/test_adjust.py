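"""Mixture inversion, call classification and arm-level aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purecna.adjust import (
    AdjustedSegment,
    adjust_profile,
    arm_call,
    classify_cn,
    mixture_adjust,
    observed_cn_from_log2,
)
from purecna.genome import Segment
from tests.conftest import make_profile


class TestTransforms:
    @pytest.mark.parametrize("log2,expected", [(0.0, 2.0), (1.0, 4.0), (-1.0, 1.0)])
    def test_log2_to_copies(self, log2, expected):
        assert observed_cn_from_log2(log2) == pytest.approx(expected)

    def test_purity_one_is_identity(self):
        for c in (0.0, 1.3, 2.0, 5.7):
            assert mixture_adjust(c, 1.0) == pytest.approx(c)

    def test_diploid_is_fixed_point_at_any_purity(self):
        for p in np.linspace(0.05, 1.0, 20):
            assert mixture_adjust(2.0, float(p)) == pytest.approx(2.0)

    def test_worked_example(self):
        assert mixture_adjust(2.5, 0.5) == pytest.approx(3.0)  # (2.5-1)/0.5

    def test_purity_below_floor_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = mixture_adjust(2.0, 0.01)
        assert out == pytest.approx(2.0)

    def test_nonpositive_purity_is_error(self):
        with pytest.raises(ValueError):
            mixture_adjust(2.0, 0.0)

    def test_adjusted_cn_clipped_at_zero(self):
        assert mixture_adjust(0.1, 0.9) == 0.0

    @given(
        cn=st.floats(min_value=0.0, max_value=8.0),
        p=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_forward_then_invert_round_trips(self, cn, p):
        observed = p * cn + 2.0 * (1.0 - p)
        assert mixture_adjust(observed, p) == pytest.approx(cn, abs=1e-9)

    def test_bias_amplification_identity_on_grid(self):
        # adjusting with p_hat instead of p gives 2 + (p/p_hat)*(cn - 2)
        for p in np.linspace(0.1, 1.0, 10):
            for p_hat in np.linspace(0.1, 1.0, 10):
                for cn in range(0, 7):
                    observed = p * cn + 2.0 * (1.0 - p)
                    expected = max(0.0, 2.0 + (p / p_hat) * (cn - 2.0))
                    got = mixture_adjust(observed, float(p_hat))
                    assert got == pytest.approx(expected, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("cn,call", [
        (3.0, "gain"), (1.0, "loss"), (2.0, "neutral"),
        (2.4, "neutral"), (2.6, "gain"),   # forced by round-half-away
        (1.6, "neutral"), (1.4, "loss"),
        (0.0, "loss"), (6.0, "gain"), (2.5, "gain"), (1.5, "neutral"),
    ])
    def test_integer_rule_after_rounding(self, cn, call):
        assert classify_cn(cn) == call

    def test_matches_threshold_form_oracle(self):
        # round-then-threshold is equivalent to cut-points at 1.5 and 2.5
        for cn in np.linspace(0, 6, 601):
            cn = float(cn)
            oracle = "gain" if cn >= 2.5 else ("loss" if cn < 1.5 else "neutral")
            assert classify_cn(cn) == oracle

    def test_monotone_in_copy_number(self):
        order = {"loss": 0, "neutral": 1, "gain": 2}
        grid = [classify_cn(float(c)) for c in np.linspace(0, 6, 301)]
        assert all(order[a] <= order[b] for a, b in zip(grid, grid[1:]))

    def test_negative_copy_number_is_error(self):
        with pytest.raises(ValueError):
            classify_cn(-0.1)


def adj(call, chrom="1", start=0, end=10):
    seg = Segment(chrom=chrom, start=start, end=end, log2_ratio=0.0)
    cn = {"loss": 1.0, "neutral": 2.0, "gain": 3.0}[call]
    return AdjustedSegment(segment=seg, purity_used=1.0, cn_observed=cn,
                           cn_tumour=cn, call=call)


class TestArmCall:
    def test_single_covering_segment_wins(self):
        assert arm_call([(adj("gain"), 100)]) == "gain"

    def test_length_weighted_plurality(self):
        assert arm_call([(adj("loss"), 60), (adj("neutral"), 40)]) == "loss"

    def test_empty_overlap_is_neutral(self):
        assert arm_call([]) == "neutral"

    def test_tie_breaks_toward_neutral(self):
        assert arm_call([(adj("loss"), 50), (adj("gain"), 50)]) == "neutral"
        assert arm_call([(adj("loss"), 50), (adj("neutral"), 50)]) == "neutral"

    def test_matches_basepair_majority_oracle(self):
        # toy arm of length 1000 tiled by random-call segments
        rng = np.random.default_rng(23)
        calls = ["loss", "neutral", "gain"]
        for _ in range(50):
            cuts = sorted(set([0, 1000] + list(rng.integers(1, 1000, size=5))))
            pieces = [
                (calls[rng.integers(0, 3)], lo, hi)
                for lo, hi in zip(cuts, cuts[1:])
            ]
            overlaps = [(adj(c, start=lo, end=hi), hi - lo) for c, lo, hi in pieces]
            per_bp = {"loss": 0, "neutral": 0, "gain": 0}
            for c, lo, hi in pieces:  # basepair-resolution vote
                per_bp[c] += hi - lo
            best = max(per_bp.values())
            winners = [c for c in calls if per_bp[c] == best]
            oracle = winners[0] if len(winners) == 1 else "neutral"
            assert arm_call(overlaps) == oracle


class TestAdjustProfile:
    def test_uniform_diploid_profile_is_all_neutral(self, toy_arms):
        profile = make_profile("s", [("1", 0, 100, 0.0)])
        for purity in (20.0, 55.0, 100.0):
            _, callset = adjust_profile(profile, purity, toy_arms)
            assert set(callset.calls.values()) == {"neutral"}

    def test_single_gain_arm_called_at_exact_purity(self, toy_arms):
        p = 0.6
        log2_gain = float(np.log2((p * 3 + 2 * (1 - p)) / 2))
        profile = make_profile("s", [("1", 0, 60, log2_gain), ("1", 60, 100, 0.0)])
        _, callset = adjust_profile(profile, 60.0, toy_arms)
        assert callset.calls == {"1p": "gain", "1q": "neutral"}

    def test_every_arm_gets_exactly_one_call(self, karyotype):
        profile = make_profile("s", [("5", 0, 40_000_000, 0.4)])
        _, callset = adjust_profile(profile, 80.0, karyotype)
        assert set(callset.calls) == set(karyotype.names)

    def test_mixed_toy_profile_matches_hand_computation(self, toy_arms):
        # six segments over two arms at purity 50%; hand-worked:
        # cn_obs = 2*2^l; cn_t = (cn_obs - 1)/0.5
        p = 50.0
        specs = [
            # (chrom, start, end, log2) -> cn_obs -> cn_t -> call
            ("1", 0, 30, np.log2(2.5 / 2)),    # obs 2.5 -> 3.0 gain, 30bp
            ("1", 30, 50, 0.0),                # obs 2.0 -> 2.0 neutral, 20bp
            ("1", 50, 60, np.log2(1.5 / 2)),   # obs 1.5 -> 1.0 loss, 10bp
            ("1", 60, 70, np.log2(1.5 / 2)),   # loss 10bp
            ("1", 70, 85, 0.0),                # neutral 15bp
            ("1", 85, 100, np.log2(1.6 / 2)),  # obs 1.6 -> 1.2 -> loss 15bp
        ]
        profile = make_profile("s", [(c, s, e, float(l)) for c, s, e, l in specs])
        adjusted, callset = adjust_profile(profile, p, toy_arms)
        by_start = {a.segment.start: a for a in adjusted}
        assert by_start[0].cn_tumour == pytest.approx(3.0)
        assert by_start[85].cn_tumour == pytest.approx(1.2)
        assert [by_start[s].call for s in (0, 30, 50, 60, 70, 85)] == [
            "gain", "neutral", "loss", "loss", "neutral", "loss"]
        # arm 1p: gain 30 vs neutral 20 vs loss 10 -> gain
        # arm 1q: loss 10+15=25 vs neutral 15 -> loss
        assert callset.calls == {"1p": "gain", "1q": "loss"}

    def test_overestimated_purity_never_creates_cna_noise_free(self, toy_arms):
        # shrinking deviations cannot convert neutral into a CNA
        for cn in (1, 3, 4):
            for p in (0.4, 0.7):
                obs = p * cn + 2 * (1 - p)
                profile = make_profile("s", [("1", 0, 100, float(np.log2(obs / 2)))])
                for p_hat in (p * 1.2, p * 1.5, 1.0):
                    _, cs = adjust_profile(profile, min(100.0, p_hat * 100), toy_arms)
                    if cs.calls["1p"] != "neutral":
                        true_call = "gain" if cn >= 3 else "loss"
                        assert cs.calls["1p"] == true_call

    def test_underestimated_purity_preserves_cna_sign_noise_free(self, toy_arms):
        # amplified deviations keep their direction; neutral stays neutral
        for cn, want in ((1, "loss"), (3, "gain"), (0, "loss"), (4, "gain")):
            p = 0.6
            obs = p * cn + 2 * (1 - p)
            profile = make_profile("s", [("1", 0, 100, float(np.log2(obs / 2)))])
            for p_hat in (0.5, 0.3, 0.15):
                _, cs = adjust_profile(profile, p_hat * 100, toy_arms)
                assert cs.calls["1p"] == want
        neutral = make_profile("s", [("1", 0, 100, 0.0)])
        _, cs = adjust_profile(neutral, 10.0, toy_arms)
        assert cs.calls["1p"] == "neutral"


class TestArmCallMatrixIO:
    def test_round_trip(self, tmp_path, toy_arms):
        from purecna.adjust import ArmCallSet, read_arm_call_matrix, write_arm_call_matrix

        callsets = [
            ArmCallSet(sample_id="a", calls={"1p": "gain", "1q": "neutral"}),
            ArmCallSet(sample_id="b", calls={"1p": "loss", "1q": "loss"}),
        ]
        path = tmp_path / "calls.tsv"
        write_arm_call_matrix(callsets, toy_arms, path)
        back = read_arm_call_matrix(path)
        assert [(c.sample_id, c.calls) for c in back] == [
            ("a", {"1p": "gain", "1q": "neutral"}),
            ("b", {"1p": "loss", "1q": "loss"}),
        ]
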