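"""Segment sampling, per-segment consistency, and the RA/URA reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trandaug import (
    AugmentPolicy,
    apply_plan,
    randaugment,
    sample_segment_plan,
    trandaugment,
    uniform_randaugment,
)


def _check_partition(plan):
    cursor = 0
    for start, end in plan.boundaries:
        assert start == cursor and end > start
        cursor = end
    assert cursor == plan.n_frames
    assert len(plan.boundaries) == plan.t_prime == len(plan.ops)
    assert all(len(ops) == len(plan.ops[0]) for ops in plan.ops)


class TestSegmentPlanSampling:
    def test_t_equals_one_forces_single_segment(self, rng):
        plan = sample_segment_plan(100, AugmentPolicy(T=1), rng)
        assert plan.t_prime == 1 and plan.boundaries == [(0, 100)]

    def test_single_frame_video_cannot_split(self, rng):
        plan = sample_segment_plan(1, AugmentPolicy(T=5), rng)
        assert plan.t_prime == 1 and plan.boundaries == [(0, 1)]

    def test_invalid_frame_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_segment_plan(0, AugmentPolicy(), rng)

    @pytest.mark.parametrize("mode", ["equal", "random"])
    def test_partition_property_bruteforce(self, mode, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 80))
            t = int(rng.integers(1, 10))
            plan = sample_segment_plan(
                n, AugmentPolicy(T=t, N=1, boundary_mode=mode), rng
            )
            _check_partition(plan)
            assert plan.t_prime <= min(t, n)

    @settings(max_examples=60, derandomize=True)
    @given(n=st.integers(1, 200), t=st.integers(1, 12), seed=st.integers(0, 2**16))
    def test_partition_property_hypothesis(self, n, t, seed):
        plan = sample_segment_plan(
            n, AugmentPolicy(T=t, N=2), np.random.default_rng(seed)
        )
        _check_partition(plan)

    def test_t_prime_distribution_uniform(self):
        rng = np.random.default_rng(77)
        draws = [
            sample_segment_plan(10, AugmentPolicy(T=5, N=0), rng).t_prime
            for _ in range(10_000)
        ]
        observed = np.bincount(draws, minlength=6)[1:6]
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01

    def test_ops_resolved_from_subset_only(self, rng):
        pol = AugmentPolicy(M=30, N=3, T=4, subset=("rotate", "brightness"))
        plan = sample_segment_plan(40, pol, rng)
        names = {name for ops in plan.ops for name, _, _ in ops}
        assert names <= {"rotate", "brightness"}

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            AugmentPolicy(M=31)
        with pytest.raises(ValueError):
            AugmentPolicy(N=-1)
        with pytest.raises(ValueError):
            AugmentPolicy(T=0)
        with pytest.raises(ValueError):
            AugmentPolicy(subset=())

    def test_policy_yaml_round_trip(self, tmp_path):
        pol = AugmentPolicy(M=12, N=2, T=3, subset=("rotate",), seed=9, boundary_mode="random")
        path = tmp_path / "policy.yaml"
        pol.save(path)
        assert AugmentPolicy.load(path) == pol


class TestApplyPlan:
    def test_empty_composition_is_identity(self, textured_video, rng):
        plan = sample_segment_plan(20, AugmentPolicy(N=0, T=5), rng)
        out = apply_plan(textured_video, plan)
        assert np.array_equal(out, textured_video)
        assert out is not textured_video

    def test_length_mismatch_rejected(self, textured_video, rng):
        plan = sample_segment_plan(10, AugmentPolicy(), rng)
        with pytest.raises(ValueError):
            apply_plan(textured_video, plan)

    def test_within_segment_frames_identical(self, textured_video, rng):
        plan = sample_segment_plan(20, AugmentPolicy(M=25, N=2, T=4), rng)
        out = apply_plan(textured_video, plan)
        for start, end in plan.boundaries:
            for t in range(start + 1, end):
                assert np.array_equal(out[t], out[start])

    def test_different_segments_generally_differ(self, textured_video):
        # construct both cases explicitly: differing vs identical compositions
        from trandaug import SegmentPlan

        differing = SegmentPlan(
            n_frames=20, t_prime=2, boundaries=[(0, 10), (10, 20)],
            ops=[[("rotate", 20.0, 1)], [("brightness", 1.9, 1)]],
        )
        out = apply_plan(textured_video, differing)
        assert not np.array_equal(out[0], out[19])

        identical = SegmentPlan(
            n_frames=20, t_prime=2, boundaries=[(0, 10), (10, 20)],
            ops=[[("rotate", 20.0, 1)], [("rotate", 20.0, 1)]],
        )
        out = apply_plan(textured_video, identical)
        assert np.array_equal(out[0], out[19])

    def test_list_input_returns_list(self, textured_frame, rng):
        frames = [textured_frame.copy() for _ in range(6)]
        plan = sample_segment_plan(6, AugmentPolicy(N=1, T=2), rng)
        out = apply_plan(frames, plan)
        assert isinstance(out, list) and len(out) == 6


class TestReductionsAndDeterminism:
    @pytest.mark.parametrize("seed", range(10))
    def test_t1_reduces_to_ura_byte_exact(self, tiny_synth_samples, seed):
        _, samples = tiny_synth_samples
        frames = samples[seed % len(samples)].frames
        a = trandaugment(frames, AugmentPolicy(M=30, N=2, T=1, seed=seed))
        b = uniform_randaugment(frames, AugmentPolicy(M=30, N=2, T=7, seed=seed))
        assert a.tobytes() == b.tobytes()

    @pytest.mark.parametrize("seed", range(10))
    def test_forced_per_frame_plan_reduces_to_ra_byte_exact(self, tiny_synth_samples, seed):
        _, samples = tiny_synth_samples
        frames = samples[seed % len(samples)].frames
        pol = AugmentPolicy(M=30, N=1, T=3, seed=seed)
        plan = sample_segment_plan(
            len(frames), pol, np.random.default_rng(seed), force_t_prime=len(frames)
        )
        a = apply_plan(frames, plan)
        b = randaugment(frames, pol)
        assert a.tobytes() == b.tobytes()

    def test_single_frame_video_collapses_all_methods(self, textured_frame):
        frames = textured_frame[None]
        pol = AugmentPolicy(M=30, N=2, T=5, seed=3)
        outs = [fn(frames, pol) for fn in (trandaugment, uniform_randaugment, randaugment)]
        assert outs[0].tobytes() == outs[1].tobytes() == outs[2].tobytes()

    def test_same_seed_byte_identical_different_seed_differs(self, textured_video):
        pol = AugmentPolicy(M=30, N=2, T=5, seed=42)
        a = trandaugment(textured_video, pol)
        b = trandaugment(textured_video, pol)
        assert a.tobytes() == b.tobytes()
        _, plan_a = trandaugment(textured_video, pol, return_plan=True)
        _, plan_c = trandaugment(
            textured_video, AugmentPolicy(M=30, N=2, T=5, seed=43), return_plan=True
        )
        assert plan_a.to_json() != plan_c.to_json()

    def test_distinct_compositions_bounded_by_t_prime(self, textured_video):
        out, plan = trandaugment(
            textured_video, AugmentPolicy(M=30, N=1, T=5, seed=0), return_plan=True
        )
        comp_keys = {plan.composition_key(i) for i in range(plan.t_prime)}
        distinct_frames = {out[t].tobytes() for t in range(out.shape[0])}
        assert len(comp_keys) <= plan.t_prime
        assert len(distinct_frames) <= plan.t_prime

    def test_ra_distinct_outputs_match_distinct_draws(self, textured_video):
        pol = AugmentPolicy(M=30, N=1, T=5, seed=5)
        out, plan = randaugment(textured_video, pol, return_plan=True)
        distinct_comps = {plan.composition_key(i) for i in range(plan.t_prime)}
        distinct_frames = {out[t].tobytes() for t in range(out.shape[0])}
        assert len(distinct_frames) == len(distinct_comps)

    def test_shape_and_length_conserved(self, tiny_synth_samples):
        _, samples = tiny_synth_samples
        for fn in (trandaugment, uniform_randaugment, randaugment):
            out = fn(samples[0].frames, AugmentPolicy(M=20, N=2, T=4, seed=1))
            assert out.shape == samples[0].frames.shape
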