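import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsmmseg import (
    GenomicProfile,
    SegmentConfig,
    SegmentationResult,
    auto_group,
    compress_runs,
    expand_runs,
    intersect_extreme,
    segment_profile,
    states_to_segments,
)
from hsmmseg.simulate import simulate_cnv


class TestStatesToSegments:
    def test_run_splitting(self):
        segs = states_to_segments([1, 1, 2, 2], [1, 2, 3, 4])
        assert segs[["start", "end", "state"]].values.tolist() == [[1, 2, 1], [3, 4, 2]]

    def test_max_gap_splits_runs(self):
        segs = states_to_segments([1, 1, 1], [1, 50, 200], max_gap=100)
        assert segs[["start", "end"]].values.tolist() == [[1, 50], [200, 200]]

    def test_no_max_gap_keeps_runs_whole(self):
        segs = states_to_segments([1, 1, 1], [1, 50, 200])
        assert len(segs) == 1 and segs.loc[0, "end"] == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            states_to_segments([1, 2], [1])


@given(
    states=st.lists(st.integers(0, 2), min_size=1, max_size=60),
    gaps=st.lists(st.integers(1, 150), min_size=60, max_size=60),
    max_gap=st.one_of(st.none(), st.integers(1, 120)),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_segments_tile_positions_without_overlap(states, gaps, max_gap):
    """Every position is covered by exactly one segment, in order."""
    positions = np.cumsum(gaps[: len(states)])
    segs = states_to_segments(states, positions, max_gap)
    covered = np.concatenate(
        [np.arange(s.i0, s.i1 + 1) for _, s in segs.iterrows()]
    )
    assert np.array_equal(covered, np.arange(len(states)))
    assert (segs["start"].to_numpy()[1:] > segs["end"].to_numpy()[:-1]).all()


class TestCompressRuns:
    def test_direct_example(self):
        v, l = compress_runs([0, 0, 0, 5, 5])
        assert v.tolist() == [0, 5] and l.tolist() == [3, 2]

    @given(st.lists(st.integers(0, 4), min_size=0, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, vec):
        v, l = compress_runs(vec)
        assert expand_runs(v, l).tolist() == vec

    def test_compressed_profile_matches_expanded_loglik(self, rng):
        """Run-compressed counts yield the same fit as the expanded track."""
        counts = rng.poisson([1] * 120 + [8] * 40 + [1] * 120).astype(np.int64)
        vals, lens = compress_runs(counts)
        pos_start = np.concatenate(([1], 1 + np.cumsum(lens)[:-1]))
        compressed = GenomicProfile(
            np.full(vals.size, "c"), pos_start, vals[:, None].astype(float),
            samples=["x"], weights=lens,
        )
        expanded = GenomicProfile(
            np.full(counts.size, "c"), np.arange(1, counts.size + 1),
            counts[:, None].astype(float), samples=["x"],
        )
        cfg = SegmentConfig(J=2, emission_family="pois")
        ra = segment_profile(compressed, cfg)
        rb = segment_profile(expanded, cfg)
        assert ra.logliks[("c", "x")][-1] == pytest.approx(
            rb.logliks[("c", "x")][-1], abs=1e-9
        )
        pd.testing.assert_frame_equal(ra.segments, rb.segments)


class TestAutoGroup:
    def test_perfect_correlation_structure(self, rng):
        base = rng.normal(0, 1, 400)
        profile = GenomicProfile(
            np.full(400, "chr1"), np.arange(1, 401),
            np.column_stack([base, base, -base]),
        )
        labels = auto_group(profile)
        assert labels[0] == labels[1] != labels[2]

    def test_identical_columns_single_group(self, rng):
        base = rng.normal(0, 1, 200)
        profile = GenomicProfile(
            np.full(200, "chr1"), np.arange(1, 201),
            np.column_stack([base, base, base]),
        )
        assert len(set(auto_group(profile))) == 1

    def test_single_column_noop(self, rng):
        profile = GenomicProfile(
            np.full(50, "chr1"), np.arange(1, 51), rng.normal(0, 1, (50, 1))
        )
        assert auto_group(profile) == ["g1"]

    def test_two_latent_profiles_recovered(self, rng):
        """Columns driven by two latent tracks are grouped correctly in >=95%
        of replicates."""
        hits = 0
        for _ in range(100):
            a, b = rng.normal(0, 1, (2, 150))
            cols = np.column_stack(
                [a + rng.normal(0, 0.4, 150) for _ in range(3)]
                + [b + rng.normal(0, 0.4, 150) for _ in range(3)]
            )
            profile = GenomicProfile(np.full(150, "c"), np.arange(1, 151), cols)
            lab = auto_group(profile)
            ok = len({lab[0], lab[1], lab[2]}) == 1 and len({lab[3], lab[4], lab[5]}) == 1
            hits += ok and lab[0] != lab[3]
        assert hits >= 95

    def test_deterministic(self, rng):
        vals = rng.normal(0, 1, (100, 4))
        profile = GenomicProfile(np.full(100, "c"), np.arange(1, 101), vals)
        assert auto_group(profile) == auto_group(profile)


class TestSegmentProfile:
    def test_constant_input_single_segment(self):
        profile = GenomicProfile(
            np.full(60, "chr1"), np.arange(1, 61), np.full((60, 1), 3.0)
        )
        with pytest.warns(UserWarning):
            res = segment_profile(profile, SegmentConfig(J=3))
        assert len(res.segments) == 1
        assert res.segments.loc[0, ["start", "end"]].tolist() == [1, 60]

    def test_simulation_truth_recovered_at_high_snr(self):
        sim = simulate_cnv(3.0, seed=5)
        profile = GenomicProfile(
            np.full(sim.T, "sim"), sim.positions, sim.values[:, None]
        )
        res = segment_profile(profile, SegmentConfig(J=3, emission_family="norm"))
        decoded = res.states[("sim", "sample1")]
        assert (decoded == sim.true_states).mean() >= 0.95

    def test_short_sequence_skipped(self, rng):
        profile = GenomicProfile(
            np.array(["a", "a", "b", "b", "b", "b", "b", "b", "b", "b"]),
            np.array([1, 2, 1, 2, 3, 4, 5, 6, 7, 8]),
            rng.normal(0, 1, (10, 1)),
        )
        with pytest.warns(UserWarning, match="fewer than J"):
            res = segment_profile(profile, SegmentConfig(J=3))
        assert set(res.segments["seqname"]) == {"b"}

    def test_count_family_rejects_floats(self, rng):
        profile = GenomicProfile(
            np.full(30, "c"), np.arange(1, 31), rng.normal(0, 1, (30, 1))
        )
        with pytest.raises(ValueError):
            segment_profile(profile, SegmentConfig(J=2, emission_family="pois"))

    def test_seqname_order_invariance(self, rng):
        vals = {
            "chrA": rng.normal(0, 1, 80) + np.repeat([0.0, 4.0], 40),
            "chrB": rng.normal(0, 1, 80) + np.repeat([4.0, 0.0], 40),
        }
        frames = {}
        for order in (["chrA", "chrB"], ["chrB", "chrA"]):
            seq = np.concatenate([[s] * 80 for s in order])
            pos = np.concatenate([np.arange(1, 81)] * 2)
            v = np.concatenate([vals[s] for s in order])
            profile = GenomicProfile(seq, pos, v[:, None])
            res = segment_profile(profile, SegmentConfig(J=2))
            frames[order[0]] = (
                res.segments.sort_values(["seqname", "start"]).reset_index(drop=True)
            )
        pd.testing.assert_frame_equal(frames["chrA"], frames["chrB"])

    def test_mvnorm_column_permutation_permutes_means(self, rng):
        base = np.repeat([0.0, 5.0, 0.0], 40)
        X = np.column_stack([base + rng.normal(0, 0.5, 120) for _ in range(2)])
        p1 = GenomicProfile(np.full(120, "c"), np.arange(1, 121), X,
                            samples=["s1", "s2"], groups=["g", "g"])
        p2 = GenomicProfile(np.full(120, "c"), np.arange(1, 121), X[:, ::-1],
                            samples=["s2", "s1"], groups=["g", "g"])
        cfg = SegmentConfig(J=2, emission_family="mvnorm")
        r1 = segment_profile(p1, cfg).segments
        r2 = segment_profile(p2, cfg).segments
        m1 = r1[r1["sample"] == "s1"]["mean"].to_numpy()
        m2 = r2[r2["sample"] == "s1"]["mean"].to_numpy()
        assert m1 == pytest.approx(m2)


def _manual_result(segs, positions=None, values=None):
    frame = pd.DataFrame(
        segs, columns=["seqname", "start", "end", "state"]
    ).assign(group="g", sample="s", mean=0.0, n_features=1)
    res = SegmentationResult(segments=frame)
    if positions is not None:
        res.positions["chr1"] = np.asarray(positions)
        res.track_values[("chr1", "s")] = np.asarray(values, dtype=float)
    return res


class TestIntersectExtreme:
    def test_interval_overlap(self):
        a = _manual_result([("chr1", 1, 100, 3)], [10, 60, 120], [1.0, 2.0, 3.0])
        b = _manual_result([("chr1", 50, 150, 1)], [10, 60, 120], [9.0, 8.0, 7.0])
        out = intersect_extreme(a, {3}, b, {1})
        assert out[["start", "end"]].values.tolist() == [[50, 100]]

    def test_disjoint_segments_empty(self):
        a = _manual_result([("chr1", 1, 10, 3)])
        b = _manual_result([("chr1", 50, 60, 1)])
        assert len(intersect_extreme(a, {3}, b, {1})) == 0

    def test_disjoint_seqnames_empty(self):
        a = _manual_result([("chr1", 1, 10, 3)])
        b = _manual_result([("chr2", 1, 10, 1)])
        assert len(intersect_extreme(a, {3}, b, {1})) == 0
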