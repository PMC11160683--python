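"""Synthetic data emulating a TF dosage-titration chromatin study.

Three generators with exact ground truth:

* ``simulate_dose_counts`` — an RE x sample ATAC-like count matrix over a
  five-level TF dosage titration (default dosages 100/60/30/12/0% with four
  biological replicates per level across two differentiation batches).
  Each RE's expected CPM follows a Hill curve of dosage parameterized by a
  true ED50, Hill exponent and full-depletion log2 fold-change; counts are
  negative-binomial with multiplicative (log-additive) batch effects.
* ``simulate_contribution_tracks`` — per-base attribution tracks with
  planted motif instances: high-affinity "buffering" motifs concentrated
  near the region summit and degenerate "sensitizing" motifs dispersed
  throughout, mirroring the spatial segregation seen in attribution maps.
* ``simulate_nmc_curves`` — normalized accessibility dose-response curves
  drawn from the TF-nucleosome competition model with known (nHA, nLA, c,
  r, a100), for parameter-recovery studies.

Every generator is a pure function of its config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .motifs import CWM, PWM, ContributionTrack, revcomp_matrix
from .nmc import DoseCurve, nmc_response

__all__ = [
    "SimDoseConfig",
    "SimTrackConfig",
    "SimCurveConfig",
    "default_motif_library",
    "hill_cpm_factor",
    "simulate_dose_counts",
    "simulate_contribution_tracks",
    "simulate_nmc_curves",
    "cwm_from_pwm",
]

BASES = "ACGT"


def _draw(dist, rng: np.random.Generator, integer: bool = False, log: bool = False):
    """Sample from a flexible distribution spec.

    A scalar is a constant; a 2-tuple is a uniform range (log-uniform when
    ``log``); a list/array is a uniform choice.
    """
    if isinstance(dist, (list, np.ndarray)):
        return dist[rng.integers(len(dist))]
    if isinstance(dist, tuple):
        lo, hi = dist
        if integer:
            return int(rng.integers(lo, hi + 1))
        if log:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))
    return dist


# ---------------------------------------------------------------------------
# dosage-series count matrices


@dataclass
class SimDoseConfig:
    """Design of the simulated dosage titration."""

    n_res: int = 200
    dosage_levels: tuple[float, ...] = (100.0, 60.0, 30.0, 12.0, 0.0)
    replicates_per_level: int = 4
    n_batches: int = 2
    ed50_range: tuple[float, float] = (5.0, 95.0)
    hill_range: tuple[float, float] = (0.8, 4.0)
    log2fc_range: tuple[float, float] = (-4.0, -1.0)  # full-depletion effect (down REs)
    # roughly a third of REs respond to the TF; most are stable (null), which
    # also keeps composition-sensitive TMM normalization well behaved
    direction_probs: tuple[float, float, float] = (0.30, 0.05, 0.65)  # down, up, null
    nb_dispersion: float = 0.05
    batch_sd: float = 0.1  # additive sd on log2 scale
    lib_size_range: tuple[float, float] = (8e6, 12e6)
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage_levels, float)
        if np.any((d < 0) | (d > 100)):
            raise ValueError("dosage levels must lie in [0, 100]")
        if np.any(np.diff(d) >= 0):
            raise ValueError("dosage levels must be strictly decreasing from 100")
        if self.replicates_per_level < 2:
            raise ValueError("need >= 2 replicates per level for downstream fitting")
        if self.nb_dispersion < 0 or self.batch_sd < 0:
            raise ValueError("dispersion and batch_sd must be nonnegative")
        if abs(sum(self.direction_probs) - 1) > 1e-9:
            raise ValueError("direction_probs must sum to 1")


def hill_cpm_factor(dosage, log2fc: float, ed50: float, h: float):
    """Relative CPM at a dosage: 1 at ~100%, 2^log2fc at full depletion.

    factor(d) = 1 + (2^log2fc - 1) * (1 - d^h/(d^h + ed50^h)).
    """
    d = np.asarray(dosage, dtype=float)
    with np.errstate(divide="ignore"):
        g = expit(h * (np.log(d) - np.log(ed50)))
    g = np.where(d == 0, 0.0, g)
    return 1.0 + (2.0**log2fc - 1.0) * (1.0 - g)


def simulate_dose_counts(
    config: SimDoseConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (counts, sample sheet, truth table) for a dosage titration."""
    rng = np.random.default_rng(config.seed)
    levels = list(config.dosage_levels)
    n_samples = len(levels) * config.replicates_per_level

    sample_rows = []
    for li, dose in enumerate(levels):
        for rep in range(config.replicates_per_level):
            sample_rows.append(
                dict(sample=f"d{dose:g}_r{rep + 1}", dosage_pct=dose,
                     batch=f"b{rep % config.n_batches + 1}", replicate=rep + 1)
            )
    samples = pd.DataFrame(sample_rows)

    directions = rng.choice(["down", "up", "null"], size=config.n_res,
                            p=config.direction_probs)
    ed50 = rng.uniform(*config.ed50_range, size=config.n_res)
    h = rng.uniform(*config.hill_range, size=config.n_res)
    lfc = rng.uniform(*config.log2fc_range, size=config.n_res)
    lfc = np.where(directions == "up", -lfc, lfc)  # up REs gain on depletion
    lfc = np.where(directions == "null", 0.0, lfc)

    # baseline CPM: log-normal around an even split of the library
    base_cpm = np.exp(rng.normal(np.log(1e6 / config.n_res), 1.0, size=config.n_res))
    lib_sizes = rng.uniform(*config.lib_size_range, size=n_samples)
    batch_labels = samples["batch"].to_numpy()
    batches = sorted(set(batch_labels))
    # per (RE, batch) multiplicative effect, additive on log2 scale
    batch_eff = rng.normal(0.0, config.batch_sd, size=(config.n_res, len(batches)))
    batch_idx = np.array([batches.index(b) for b in batch_labels])

    dose_vec = samples["dosage_pct"].to_numpy(float)
    mean = np.empty((config.n_res, n_samples))
    for i in range(config.n_res):
        cpm_true = base_cpm[i] * hill_cpm_factor(dose_vec, lfc[i], ed50[i], h[i])
        mean[i] = cpm_true / 1e6 * lib_sizes * 2.0 ** batch_eff[i, batch_idx]

    if config.nb_dispersion > 1e-12:
        lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                        scale=mean * config.nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)

    re_ids = [f"re_{i + 1}" for i in range(config.n_res)]
    counts_df = pd.DataFrame(counts, index=re_ids, columns=samples["sample"])
    counts_df.index.name = "re_id"
    truth = pd.DataFrame(
        dict(re_id=re_ids, true_ed50=ed50, true_h=h, true_log2fc=lfc,
             direction=directions)
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# contribution tracks with planted motifs


def _make_pwm(id_: str, consensus: str, p_major: float) -> PWM:
    probs = np.full((len(consensus), 4), (1 - p_major) / 3)
    for i, ch in enumerate(consensus):
        probs[i, BASES.index(ch)] = p_major
    return PWM(id=id_, probs=probs)


def default_motif_library() -> list[tuple[PWM, str, float]]:
    """(PWM, class, amplitude) triples for the default generator.

    A strong composite-style motif stands in for high-affinity buffering
    sites (sharp letter preferences, high amplitude); a degenerate variant
    stands in for low-affinity sensitizing sites (soft preferences, lower
    amplitude), mirroring how degenerate motif variants bind weakly and
    contribute less attribution signal.
    """
    return [
        (_make_pwm("buf_motif", "CAGCTGTCAT", 0.85), "buffering", 1.0),
        (_make_pwm("sens_motif", "CATCTGAAAT", 0.60), "sensitizing", 0.5),
    ]


def cwm_from_pwm(pwm: PWM, cls: str, amplitude: float = 1.0) -> CWM:
    """Expected-contribution CWM of a planted motif: p * amplitude * log-odds."""
    return CWM(id=pwm.id, matrix=amplitude * pwm.probs * pwm.log_odds, cls=cls)


@dataclass
class SimTrackConfig:
    """Design of the simulated contribution tracks."""

    n_regions: int = 200
    region_len: int = 400
    motif_library: list[tuple[PWM, str, float]] = field(default_factory=default_motif_library)
    placement_sd_by_class: dict[str, float] = field(
        default_factory=lambda: {"buffering": 30.0, "sensitizing": 120.0}
    )
    instances_per_region: tuple[int, int] = (1, 3)  # uniform inclusive range
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motif_library:
            raise ValueError("motif library must be nonempty")
        longest = max(len(p) for p, _, _ in self.motif_library)
        if self.region_len < longest:
            raise ValueError("region_len must be >= longest motif")
        for _, cls, amp in self.motif_library:
            if amp <= 0:
                raise ValueError("amplitudes must be positive")
            if cls not in self.placement_sd_by_class:
                raise ValueError(f"no placement sd for class {cls!r}")


def simulate_contribution_tracks(
    config: SimTrackConfig,
) -> tuple[list[ContributionTrack], pd.DataFrame]:
    """Simulate contribution tracks and the truth table of planted instances.

    Planted instances never overlap (placement is resampled on collision and
    the instance is dropped if no free slot is found), keeping the truth
    unambiguous.  Sequence letters at planted positions are drawn from the
    motif's PWM (strand-aware); the planted contribution at each position is
    amplitude * log2-odds of the sampled letter.
    """
    rng = np.random.default_rng(config.seed)
    tracks: list[ContributionTrack] = []
    truth_rows = []
    L = config.region_len
    summit = L // 2

    for g in range(config.n_regions):
        rid = f"region_{g + 1}"
        seq = list(rng.choice(list(BASES), size=L))
        contrib_val = np.zeros(L)
        planted: list[tuple[int, int]] = []
        n_inst = int(rng.integers(config.instances_per_region[0],
                                  config.instances_per_region[1] + 1))
        for _ in range(n_inst):
            pwm, cls, amp = config.motif_library[rng.integers(len(config.motif_library))]
            m = len(pwm)
            sd = config.placement_sd_by_class[cls]
            strand = "+" if rng.random() < 0.5 else "-"
            start = None
            for _attempt in range(50):
                cand = int(np.clip(round(rng.normal(summit - m / 2, sd)), 0, L - m))
                if not any(cand < e and s < cand + m for s, e in planted):
                    start = cand
                    break
            if start is None:
                continue  # region too crowded; drop instance, truth stays clean
            planted.append((start, start + m))
            probs = pwm.probs if strand == "+" else revcomp_matrix(pwm.probs)
            lodds = np.log2(probs / pwm.background)
            for k in range(m):
                b = int(rng.choice(4, p=probs[k]))
                seq[start + k] = BASES[b]
                contrib_val[start + k] = amp * lodds[k, b]
            truth_rows.append(
                dict(region_id=rid, start=start, end=start + m, strand=strand,
                     motif_id=pwm.id, cls=cls,
                     summit_distance=abs(start + m // 2 - summit))
            )
        if config.noise_sd > 0:
            contrib_val = contrib_val + rng.normal(0.0, config.noise_sd, size=L)
        seq_str = "".join(seq)
        contrib = np.zeros((L, 4))
        contrib[np.arange(L), [BASES.index(ch) for ch in seq_str]] = contrib_val
        tracks.append(ContributionTrack(rid, seq_str, contrib, summit))

    truth = pd.DataFrame(
        truth_rows,
        columns=["region_id", "start", "end", "strand", "motif_id", "cls",
                 "summit_distance"],
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# model-generated dose-response curves


@dataclass
class SimCurveConfig:
    """Design of simulated TF-nucleosome competition response curves.

    Distribution specs follow ``_draw``: scalar constant, (lo, hi) uniform
    range, or list of choices.  ``r_dist`` is the K_D ratio KD_LA/KD_HA
    (>= 1); ``c_dist`` must stay within [0, 1].
    """

    n_curves: int = 200
    nha_dist: object = 3
    nla_dist: object = 0
    c_dist: object = 0.022
    r_dist: object = (5.0, 50.0)
    a100_dist: object = (10.0, 100.0)
    L: float = 1e3
    dosage_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 5))
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dosage_grid) <= 0):
            raise ValueError("dosage grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_nmc_curves(
    config: SimCurveConfig,
) -> tuple[list[DoseCurve], pd.DataFrame]:
    """Simulate normalized competition-model curves with known parameters.

    Curves are the normalized accessibility rise evaluated on the dosage
    grid plus Gaussian noise, truncated to [0, 1].  Degenerate parameter
    draws (c = 1, where the curve is identically flat) are flagged in the
    truth table.
    """
    rng = np.random.default_rng(config.seed)
    curves: list[DoseCurve] = []
    rows = []
    grid = np.asarray(config.dosage_grid, float)
    for i in range(config.n_curves):
        n_ha = int(_draw(config.nha_dist, rng, integer=True))
        n_la = int(_draw(config.nla_dist, rng, integer=True))
        c = float(_draw(config.c_dist, rng))
        r = float(_draw(config.r_dist, rng, log=True)) if n_la > 0 else 1.0
        a100 = float(_draw(config.a100_dist, rng, log=True))
        if not 0 <= c <= 1:
            raise ValueError("c_dist produced a value outside [0, 1]")
        if r < 1:
            raise ValueError("r_dist produced a ratio < 1")
        degenerate = c == 1.0
        y = nmc_response(grid, c, a100, r, n_ha=n_ha, n_la=n_la, L=config.L)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=grid.size)
        y = np.clip(y, 0.0, 1.0)
        cid = f"curve_{i + 1}"
        curves.append(DoseCurve(grid=grid, response=y, curve_id=cid))
        rows.append(dict(curve_id=cid, n_ha=n_ha, n_la=n_la, c=c, r=r,
                         a100=a100, degenerate=degenerate))
    truth = pd.DataFrame(rows)
    return curves, truth
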