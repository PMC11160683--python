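"""CWM motif-instance calling from per-base contribution tracks.

A contribution weight matrix (CWM) is a signed motif representation built
from attribution scores; instances are called by sliding the CWM over a
region's contribution track and scoring with a continuous Jaccard
similarity that rewards magnitude agreement and penalizes sign disagreement.
Thresholds are percentile-based against a reference distribution of
high-attribution ("seqlet-like") windows, mirroring how CWM mapping is
thresholded against seqlet sets from motif discovery.  Called instances can
be re-scored against conventional position weight matrices (PWMs) with an
exact p-value-derived log-odds cutoff, and contrasted on summit distance
and per-base conservation against a shuffled control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "ContributionTrack",
    "CWM",
    "PWM",
    "MotifInstance",
    "ScoreTrack",
    "continuous_jaccard",
    "call_instances",
    "pwm_threshold",
    "pwm_match",
    "summit_distance",
    "conservation_contrast",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G column permutation


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) one-hot; non-ACGT rows are all-zero."""
    out = np.zeros((len(seq), 4))
    for i, ch in enumerate(seq.upper()):
        j = _BASE_IDX.get(ch)
        if j is not None:
            out[i, j] = 1.0
    return out


def revcomp_matrix(m: np.ndarray) -> np.ndarray:
    """Reverse-complement an (L, 4) matrix: reverse rows, swap A/T and C/G."""
    return m[::-1, _COMPLEMENT]


def revcomp_seq(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class ContributionTrack:
    """Per-base attribution scores for one region.

    ``contrib`` is (L, 4) and nonzero only at the observed base of each
    position (where ``onehot`` is 1); ``summit`` is the offset (bp from
    region start) of maximal accessibility signal.
    """

    region_id: str
    sequence: str
    contrib: np.ndarray
    summit: int

    def __post_init__(self) -> None:
        self.contrib = np.asarray(self.contrib, dtype=float)
        if self.contrib.shape != (len(self.sequence), 4):
            raise ValueError("contribution matrix shape must be (len(sequence), 4)")
        oh = one_hot(self.sequence)
        if np.any((self.contrib != 0) & (oh == 0)):
            raise ValueError("contributions must be zero at unobserved bases")

    @property
    def onehot(self) -> np.ndarray:
        return one_hot(self.sequence)

    def reverse_complement(self) -> "ContributionTrack":
        L = len(self.sequence)
        return ContributionTrack(
            region_id=self.region_id,
            sequence=revcomp_seq(self.sequence),
            contrib=revcomp_matrix(self.contrib),
            summit=L - 1 - self.summit,
        )


@dataclass
class CWM:
    """Signed contribution weight matrix with a response-class label."""

    id: str
    matrix: np.ndarray
    cls: str = "other"  # buffering | sensitizing | other

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("CWM matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("CWM length must be >= 4")
        if not np.any(self.matrix):
            raise ValueError("CWM must not be all-zero")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "CWM":
        return CWM(self.id, revcomp_matrix(self.matrix), self.cls)


@dataclass
class PWM:
    """Position probability matrix scored as background-relative log-odds."""

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PWM must be (L, 4)")
        if self.pseudocount > 0:
            p = (p + self.pseudocount * self.background) / (1 + self.pseudocount)
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            raise ValueError("PWM rows must sum to 1 (after pseudocount)")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("PWM probabilities must lie strictly in (0, 1)")
        self.probs = p
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/background) in bits."""
        return np.log2(self.probs / self.background)


@dataclass
class MotifInstance:
    """A called CWM occurrence in region coordinates (0-based, half-open)."""

    region_id: str
    start: int
    end: int
    strand: str
    cwm_id: str
    cls: str
    jaccard: float
    total_contrib: float
    pwm_score: float = math.nan
    pwm_pass: bool | None = None


@dataclass
class ScoreTrack:
    """Per-base scalar scores (e.g. conservation) for one region; NaN = missing."""

    region_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def _l1_normalize(m: np.ndarray) -> np.ndarray:
    s = np.abs(m).sum()
    return m / s if s > 0 else m


def continuous_jaccard(window: np.ndarray, cwm: np.ndarray, normalize: bool = True) -> float:
    """Continuous Jaccard similarity between two signed matrices, in [-1, 1].

    score = sum_ij sgn_ij * min(|x|,|y|) / sum_ij max(|x|,|y|), with
    sgn_ij = +1 where signs agree and -1 where they disagree.  Both inputs
    are L1-normalized first unless ``normalize=False``.
    """
    x = np.asarray(window, dtype=float)
    y = np.asarray(cwm, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if normalize:
        x, y = _l1_normalize(x), _l1_normalize(y)
    ax, ay = np.abs(x), np.abs(y)
    sgn = np.where(np.sign(x) == np.sign(y), 1.0, -1.0)
    denom = np.maximum(ax, ay).sum()
    if denom == 0:
        return 0.0
    return float((sgn * np.minimum(ax, ay)).sum() / denom)


def _jaccard_profile(contrib: np.ndarray, cwm_matrix: np.ndarray) -> np.ndarray:
    """Continuous Jaccard of the CWM against every sliding window (vectorized)."""
    m = cwm_matrix.shape[0]
    L = contrib.shape[0]
    if L < m:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(contrib, (m, 4)).reshape(L - m + 1, m, 4)
    norms = np.abs(win).sum(axis=(1, 2), keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    x = win / norms
    y = _l1_normalize(cwm_matrix)[None, :, :]
    ax, ay = np.abs(x), np.abs(y)
    sgn = np.where(np.sign(x) == np.sign(y), 1.0, -1.0)
    denom = np.maximum(ax, ay).sum(axis=(1, 2))
    num = (sgn * np.minimum(ax, ay)).sum(axis=(1, 2))
    return np.where(denom > 0, num / denom, 0.0)


def _window_contrib_sums(contrib: np.ndarray, m: int) -> np.ndarray:
    per_base = np.abs(contrib).sum(axis=1)
    c = np.concatenate([[0.0], np.cumsum(per_base)])
    return c[m:] - c[:-m]


def call_instances(
    tracks: list[ContributionTrack],
    cwms: list[CWM],
    jaccard_pct: float = 10.0,
    contrib_pct: float = 0.5,
    seqlet_mad_factor: float = 8.0,
) -> list[MotifInstance]:
    """Call CWM instances across a set of contribution tracks.

    Every CWM is slid over both strands of every track.  Per CWM, a
    reference distribution stands in for a discovered seqlet set: windows
    whose total absolute contribution exceeds the robust background level
    (median + ``seqlet_mad_factor`` x MAD over all windows, strictly).  A
    window is then a candidate when its Jaccard similarity is at or above
    the ``jaccard_pct``-th percentile and its total absolute contribution at
    or above the ``contrib_pct``-th percentile of that reference (permissive
    thresholds, to keep degenerate low-affinity occurrences).  Overlapping
    candidates are resolved greedily by jaccard x CWM-length (then higher
    jaccard, then leftmost); coincident forward/reverse calls of a
    palindromic CWM keep the + strand.
    """
    if not cwms:
        raise ValueError("empty CWM list")
    if not 0 <= jaccard_pct <= 100 or not 0 <= contrib_pct <= 100:
        raise ValueError("percentile thresholds must lie in [0, 100]")

    candidates: list[MotifInstance] = []
    for cwm in cwms:
        m = len(cwm)
        fwd, rev = cwm.matrix, revcomp_matrix(cwm.matrix)
        per_track = []
        all_jf, all_jr, all_contrib = [], [], []
        for tr in tracks:
            if len(tr.sequence) < m:
                continue
            jf = _jaccard_profile(tr.contrib, fwd)
            jr = _jaccard_profile(tr.contrib, rev)
            cs = _window_contrib_sums(tr.contrib, m)
            per_track.append((tr, jf, jr, cs))
            all_jf.append(jf)
            all_jr.append(jr)
            all_contrib.append(cs)
        if not per_track:
            continue
        contrib_all = np.concatenate(all_contrib)
        med = np.median(contrib_all)
        mad = np.median(np.abs(contrib_all - med))
        ref_mask = contrib_all > med + seqlet_mad_factor * mad
        if not ref_mask.any():
            continue
        ref_contrib = contrib_all[ref_mask]
        ref_jacc = np.concatenate(
            [np.concatenate(all_jf)[ref_mask], np.concatenate(all_jr)[ref_mask]]
        )
        jacc_thr = float(np.percentile(ref_jacc, jaccard_pct))
        contrib_thr = float(np.percentile(ref_contrib, contrib_pct))

        for tr, jf, jr, cs in per_track:
            passing = cs >= contrib_thr
            for i in np.nonzero(passing)[0]:
                jp, jm = jf[i], jr[i]
                if jp < jacc_thr and jm < jacc_thr:
                    continue
                # palindome rule: ties go to the + strand
                strand, j = ("+", jp) if jp >= jm else ("-", jm)
                candidates.append(
                    MotifInstance(tr.region_id, int(i), int(i) + m, strand,
                                  cwm.id, cwm.cls, float(j), float(cs[i]))
                )

    return _dedup(candidates)


def _dedup(candidates: list[MotifInstance]) -> list[MotifInstance]:
    """Greedy overlap resolution by jaccard x length, then jaccard, then leftmost."""
    by_region: dict[str, list[MotifInstance]] = {}
    for c in candidates:
        by_region.setdefault(c.region_id, []).append(c)
    kept: list[MotifInstance] = []
    for region in sorted(by_region):
        pool = sorted(
            by_region[region],
            key=lambda c: (-(c.jaccard * (c.end - c.start)), -c.jaccard, c.start, c.strand),
        )
        taken: list[tuple[int, int]] = []
        for c in pool:
            if any(c.start < e and s < c.end for s, e in taken):
                continue
            taken.append((c.start, c.end))
            kept.append(c)
    kept.sort(key=lambda c: (c.region_id, c.start, c.cwm_id))
    return kept


def pwm_threshold(pwm: PWM, p: float = 0.01, bin_bits: float = 0.01) -> float:
    """Exact p-value score threshold for a PWM under its background model.

    Per-position log-odds scores are discretized to ``bin_bits`` bins and the
    distribution of the total score under the background is built by dynamic
    programming (exact convolution).  Returns the largest achievable score t
    with P(score >= t) >= p, so a match at score >= t has background
    probability at most ~p (the standard scanning convention).
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    bins = np.rint(pwm.log_odds / bin_bits).astype(np.int64)
    dist = _score_distribution(bins, pwm.background)
    # walk the support from the top; accumulate tail probability
    scores = sorted(dist, reverse=True)
    tail = 0.0
    for s in scores:
        tail += dist[s]
        if tail >= p:
            return s * bin_bits
    return scores[-1] * bin_bits


def _score_distribution(bins: np.ndarray, background: np.ndarray) -> dict[int, float]:
    dist = {0: 1.0}
    for row in bins:
        nxt: dict[int, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                t = s + int(row[b])
                nxt[t] = nxt.get(t, 0.0) + pr * background[b]
        dist = nxt
    return dist


def pwm_match(
    sequence: str,
    pwm: PWM,
    p: float = 0.01,
    bin_bits: float = 0.01,
) -> tuple[float, bool]:
    """Best log-odds score of a PWM over all offsets/strands, with pass flag.

    Scores are computed on the same discretized grid as the threshold so the
    pass decision is exact.  Non-ACGT bases contribute the background score
    (log-odds 0).
    """
    seq = sequence.upper()
    m = len(pwm)
    if len(seq) < m:
        raise ValueError("sequence shorter than PWM")
    bins = np.rint(pwm.log_odds / bin_bits).astype(np.int64)
    thr_bins = int(round(pwm_threshold(pwm, p, bin_bits) / bin_bits))

    best = -np.inf
    for s in (seq, revcomp_seq(seq)):
        idx = np.array([_BASE_IDX.get(ch, -1) for ch in s])
        for off in range(len(s) - m + 1):
            window = idx[off: off + m]
            total = 0
            for i, b in enumerate(window):
                if b >= 0:
                    total += int(bins[i, b])
            best = max(best, total)
    return best * bin_bits, best >= thr_bins


def summit_distance(instances: list[MotifInstance], tracks: list[ContributionTrack]) -> np.ndarray:
    """|instance center - summit| in bp; center = start + floor(length/2)."""
    summits = {t.region_id: t.summit for t in tracks}
    out = np.empty(len(instances))
    for k, inst in enumerate(instances):
        center = inst.start + (inst.end - inst.start) // 2
        out[k] = abs(center - summits[inst.region_id])
    return out


def conservation_contrast(
    instances: list[MotifInstance],
    score_tracks: list[ScoreTrack],
    threshold: float = 0.5,
    n_shuffle: int = 10,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-class mean conservation of instances versus a shuffled control.

    Each instance is summarized by the mean of its per-base scores (missing
    bases skipped).  Classes are compared with a control of same-length
    intervals placed uniformly at random within the scored regions,
    excluding any overlap with true instances (n_shuffle placements per
    instance; seeded).  Returns {class: {mean, frac_ge, n}} including a
    "control" entry; instances outside scored regions are skipped and
    counted under "n_skipped".
    """
    if n_shuffle < 1:
        raise ValueError("n_shuffle must be >= 1")
    rng = np.random.default_rng(seed)
    scores = {t.region_id: t.scores for t in score_tracks}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for inst in instances:
        occupied.setdefault(inst.region_id, []).append((inst.start, inst.end))

    per_class: dict[str, list[float]] = {}
    n_skipped = 0
    for inst in instances:
        s = scores.get(inst.region_id)
        if s is None or inst.end > s.size:
            n_skipped += 1
            continue
        vals = s[inst.start: inst.end]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            n_skipped += 1
            continue
        per_class.setdefault(inst.cls, []).append(float(vals.mean()))

    control: list[float] = []
    region_ids = sorted(scores)
    for inst in instances:
        if inst.region_id not in scores:
            continue
        length = inst.end - inst.start
        for _ in range(n_shuffle):
            for _attempt in range(200):
                rid = region_ids[rng.integers(len(region_ids))]
                s = scores[rid]
                if s.size < length:
                    continue
                start = int(rng.integers(s.size - length + 1))
                if any(start < e and b < start + length for b, e in occupied.get(rid, [])):
                    continue
                vals = s[start: start + length]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    control.append(float(vals.mean()))
                break

    out: dict[str, dict[str, float]] = {}
    for cls, vals in sorted(per_class.items()):
        arr = np.array(vals)
        out[cls] = {"mean": float(arr.mean()),
                    "frac_ge": float((arr >= threshold).mean()),
                    "n": float(arr.size)}
    arr = np.array(control) if control else np.array([math.nan])
    out["control"] = {"mean": float(np.nanmean(arr)),
                      "frac_ge": float((arr >= threshold).mean()),
                      "n": float(len(control))}
    out["meta"] = {"n_skipped": float(n_skipped)}
    return out
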