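"""Tests of CWM instance calling, PWM p-value scoring, summit distances and
the conservation contrast."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosechrom.motifs import (
    CWM,
    PWM,
    ContributionTrack,
    MotifInstance,
    ScoreTrack,
    call_instances,
    conservation_contrast,
    continuous_jaccard,
    one_hot,
    pwm_match,
    pwm_threshold,
    revcomp_matrix,
    summit_distance,
)
from tests.conftest import match_counts


def make_track(seq: str, values: np.ndarray, summit: int | None = None) -> ContributionTrack:
    contrib = np.zeros((len(seq), 4))
    idx = [("ACGT".index(c)) for c in seq]
    contrib[np.arange(len(seq)), idx] = values
    return ContributionTrack("r1", seq, contrib, summit if summit is not None else len(seq) // 2)


class TestContinuousJaccard:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.m = rng.normal(size=(6, 4))

    def test_identity_scores_one(self):
        assert continuous_jaccard(self.m, self.m) == pytest.approx(1.0)

    def test_negation_scores_minus_one(self):
        assert continuous_jaccard(-self.m, self.m) == pytest.approx(-1.0)

    def test_scaling_invariant_after_normalization(self):
        assert continuous_jaccard(0.5 * self.m, self.m) == pytest.approx(1.0)

    def test_raw_formula_halves_on_scaling(self):
        assert continuous_jaccard(0.5 * self.m, self.m, normalize=False) == pytest.approx(0.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            continuous_jaccard(self.m[:4], self.m)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(size=(2, 5, 4))
            assert -1.0 <= continuous_jaccard(a, b) <= 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=16, max_size=16),
           st.lists(st.floats(-5, 5, allow_nan=False), min_size=16, max_size=16))
    def test_bounded_and_symmetric_property(self, xs, ys):
        a = np.array(xs).reshape(4, 4)
        b = np.array(ys).reshape(4, 4)
        s = continuous_jaccard(a, b)
        assert -1.0 <= s <= 1.0
        assert s == pytest.approx(continuous_jaccard(b, a), abs=1e-12)


class TestCallInstances:
    def plant(self, cwm: CWM, seq_len=200, offset=60, strand="+", rng=None):
        """Track with one noiseless planted CWM occurrence."""
        rng = rng or np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=seq_len))
        values = np.zeros(seq_len)
        mat = cwm.matrix if strand == "+" else revcomp_matrix(cwm.matrix)
        for k in range(len(cwm)):
            b = int(np.argmax(np.abs(mat[k])))
            seq[offset + k] = "ACGT"[b]
            values[offset + k] = mat[k, b]
        return make_track("".join(seq), values)

    def make_cwm(self, length=10, seed=2, cls="buffering"):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(length, 4)) * 0.2
        m[np.arange(length), rng.integers(0, 4, size=length)] += 2.0
        return CWM("toy", np.abs(m), cls)

    def test_single_noiseless_plant_called_exactly(self):
        cwm = self.make_cwm()
        track = self.plant(cwm)
        (inst,) = call_instances([track], [cwm])
        assert (inst.start, inst.end, inst.strand) == (60, 70, "+")

    def test_minus_strand_plant_recovered(self):
        cwm = self.make_cwm()
        track = self.plant(cwm, strand="-")
        (inst,) = call_instances([track], [cwm])
        assert (inst.start, inst.strand) == (60, "-")

    def test_nested_cwm_tiebreak_prefers_jaccard_times_length(self):
        long_cwm = self.make_cwm(length=12, seed=5)
        sub = CWM("sub", long_cwm.matrix[2:10].copy(), "other")
        track = self.plant(long_cwm, offset=80)
        instances = call_instances([track], [sub, long_cwm])
        assert len(instances) == 1
        # the full-length motif matches perfectly: jaccard*12 beats jaccard*8
        assert instances[0].cwm_id == "toy"
        assert instances[0].end - instances[0].start == 12

    def test_strand_symmetry(self):
        cwm = self.make_cwm()
        rng = np.random.default_rng(7)
        track = self.plant(cwm, rng=rng)
        track.contrib += np.where(one_hot(track.sequence) > 0,
                                  rng.normal(0, 0.05, size=track.contrib.shape), 0.0)
        fwd = call_instances([track], [cwm])
        rc_track = track.reverse_complement()
        rev = call_instances([rc_track], [cwm])
        L = len(track.sequence)
        flipped = sorted((L - i.end, L - i.start, {"+": "-", "-": "+"}[i.strand])
                         for i in rev)
        assert flipped == sorted((i.start, i.end, i.strand) for i in fwd)

    def test_threshold_monotonicity(self, track_benchmark):
        _, tracks, _, cwms = track_benchmark
        subset = tracks[:30]
        loose = call_instances(subset, cwms, jaccard_pct=0, contrib_pct=0)
        mid = call_instances(subset, cwms, jaccard_pct=50, contrib_pct=50)
        tight = call_instances(subset, cwms, jaccard_pct=100, contrib_pct=100)
        assert len(loose) >= len(mid) >= len(tight)

    def test_benchmark_precision_recall(self, track_benchmark):
        _, tracks, truth, cwms = track_benchmark
        instances = call_instances(tracks, cwms)
        tp = match_counts(instances, truth)
        assert tp / len(instances) >= 0.9  # precision
        assert tp / len(truth) >= 0.9      # recall

    def test_empty_cwm_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_instances([], [])


class TestPWMMatch:
    def test_uniform_pwm_all_pass(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        score, ok = pwm_match("ACGTACGT", pwm, p=0.01)
        assert score == 0.0 and ok
        assert pwm_threshold(pwm, p=0.001) == 0.0

    def test_single_position_quantile(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]])
        pwm = PWM("a", probs)
        thr = pwm_threshold(pwm, p=0.25)
        a_score = float(np.log2(0.97 / 0.25))
        assert thr == pytest.approx(a_score, abs=0.011)
        assert pwm_match("A", pwm, p=0.25)[1]
        assert not pwm_match("C", pwm, p=0.25)[1]

    def test_two_position_consensus_only(self):
        probs = np.array([[0.85, 0.05, 0.05, 0.05], [0.05, 0.85, 0.05, 0.05]])
        pwm = PWM("ac", probs)
        thr = pwm_threshold(pwm, p=1 / 16)
        assert thr == pytest.approx(2 * np.log2(0.85 / 0.25), abs=0.021)
        assert pwm_match("AC", pwm, p=1 / 16)[1]
        assert not pwm_match("AA", pwm, p=1 / 16)[1]
        # reverse strand consensus also passes
        assert pwm_match("GT", pwm, p=1 / 16)[1]

    @pytest.mark.parametrize("p", [0.5, 0.1, 0.01])
    def test_dp_equals_enumeration(self, p):
        rng = np.random.default_rng(11)
        for length in (3, 5, 8):
            probs = rng.dirichlet(np.ones(4) * 2, size=length)
            pwm = PWM("r", probs, pseudocount=0.01)
            bins = np.rint(pwm.log_odds / 0.01).astype(int)
            totals = {}
            for word in itertools.product(range(4), repeat=length):
                s = sum(int(bins[i, b]) for i, b in enumerate(word))
                totals[s] = totals.get(s, 0.0) + 0.25**length
            tail = 0.0
            expected = None
            for s in sorted(totals, reverse=True):
                tail += totals[s]
                if tail >= p:
                    expected = s
                    break
            assert round(pwm_threshold(pwm, p) / 0.01) == expected

    def test_sequence_shorter_than_pwm(self):
        pwm = PWM("x", np.full((6, 4), 0.25))
        with pytest.raises(ValueError, match="shorter"):
            pwm_match("ACG", pwm)

    def test_non_acgt_scored_as_background(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]])
        pwm = PWM("a", probs)
        score, _ = pwm_match("N", pwm)
        assert score == 0.0


class TestSummitAndConservation:
    def test_summit_distance_geometry(self):
        track = make_track("ACGT" * 100, np.zeros(400), summit=200)
        centered = MotifInstance("r1", 195, 205, "+", "m", "buffering", 1.0, 1.0)
        edge = MotifInstance("r1", 0, 10, "+", "m", "buffering", 1.0, 1.0)
        d = summit_distance([centered, edge], [track])
        assert d[0] == 0
        assert d[1] == pytest.approx(195)

    def test_synthetic_truth_distance_ordering(self, track_benchmark):
        _, tracks, truth, cwms = track_benchmark
        instances = call_instances(tracks, cwms)
        d = summit_distance(instances, tracks)
        cls = np.array([i.cls for i in instances])
        assert np.median(d[cls == "sensitizing"]) > np.median(d[cls == "buffering"])

    def test_constant_score_track(self):
        insts = [MotifInstance("r1", 10, 20, "+", "m", "buffering", 1.0, 1.0),
                 MotifInstance("r1", 50, 60, "+", "m", "sensitizing", 1.0, 1.0)]
        tracks = [ScoreTrack("r1", np.full(200, 0.7))]
        out = conservation_contrast(insts, tracks, threshold=0.5, n_shuffle=3, seed=0)
        assert out["buffering"]["mean"] == pytest.approx(0.7)
        assert out["control"]["mean"] == pytest.approx(0.7)
        assert out["buffering"]["frac_ge"] == 1.0

    def test_elevated_scores_inside_instances(self):
        rng = np.random.default_rng(2)
        scores = np.full(500, 0.2) + rng.normal(0, 0.01, 500)
        insts = []
        for k, start in enumerate((50, 150, 300)):
            scores[start: start + 10] = 0.9
            insts.append(MotifInstance("r1", start, start + 10, "+", "m",
                                       "buffering", 1.0, 1.0))
        out = conservation_contrast(insts, [ScoreTrack("r1", scores)],
                                    threshold=0.5, n_shuffle=20, seed=1)
        assert out["buffering"]["mean"] > out["control"]["mean"] + 0.5

    def test_control_reproducible_and_avoids_instances(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=300)
        insts = [MotifInstance("r1", 100, 120, "+", "m", "buffering", 1.0, 1.0)]
        a = conservation_contrast(insts, [ScoreTrack("r1", scores)], n_shuffle=50, seed=9)
        b = conservation_contrast(insts, [ScoreTrack("r1", scores)], n_shuffle=50, seed=9)
        assert a == b

    def test_instance_outside_region_skipped(self):
        insts = [MotifInstance("r1", 250, 260, "+", "m", "buffering", 1.0, 1.0)]
        out = conservation_contrast(insts, [ScoreTrack("r1", np.ones(100))], seed=0)
        assert out["meta"]["n_skipped"] == 1
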