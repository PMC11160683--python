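"""End-to-end orchestration: synthetic data -> Hill fits -> competition-model
fits -> motif instances.

A run is configured by a YAML file (see ``RunConfig``), executes the enabled
stages in a fixed order, and writes every artifact plus a manifest of SHA256
hashes and the fully resolved configuration into the output directory.
Identical config + seed produces byte-identical artifacts; the run log
(timestamped) is the only file excluded from the manifest.  Each stage draws
its randomness from a seed derived from the global seed and the stage name,
so toggling one stage does not shift another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dose_response as dr
from . import io as dio
from . import motifs as mot
from . import nmc
from . import simulate as sim

log = logging.getLogger("dosechrom")

STAGES = ("synthetic", "dose_response", "nmc", "motifs")


@dataclass
class RunConfig:
    """Run configuration; unknown keys in the YAML are rejected."""

    seed: int = 0
    out_dir: str = "run_out"
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: dict = field(default_factory=dict)   # SimDoseConfig/SimTrackConfig/SimCurveConfig overrides
    dose_response: dict = field(default_factory=dict)  # z_cut, min_points, counts, samples
    nmc: dict = field(default_factory=dict)         # n_ha, n_la, L, curves
    motifs: dict = field(default_factory=dict)      # jaccard_pct, contrib_pct, seqlet_mad_factor, threshold, n_shuffle

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad_stages = set(cfg.stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a stable hash of the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    artifacts: list[Path] = []

    try:
        if config.stages.get("synthetic", False):
            _stage_synthetic(config, out, artifacts)
        if config.stages.get("dose_response", False):
            _stage_dose_response(config, out, artifacts)
        if config.stages.get("nmc", False):
            _stage_nmc(config, out, artifacts)
        if config.stages.get("motifs", False):
            _stage_motifs(config, out, artifacts)
    except Exception as exc:
        log.error("pipeline halted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    artifacts.append(out / "config.yaml")
    manifest = {
        "config": asdict(config),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _stage_synthetic(config: RunConfig, out: Path, artifacts: list[Path]) -> None:
    log.info("stage synthetic: generating dose counts, tracks, and model curves")
    seed = stage_seed(config.seed, "synthetic")
    p = dict(config.synthetic)
    dose_cfg = sim.SimDoseConfig(seed=seed, **p.get("dose", {}))
    counts, samples, truth_dose = sim.simulate_dose_counts(dose_cfg)
    dio.write_counts(counts, out / "counts.tsv")
    dio.write_samples(samples, out / "samples.tsv")
    dio.write_table(truth_dose, out / "truth_dose.tsv", "truth_dose")

    track_cfg = sim.SimTrackConfig(seed=seed + 1, **p.get("tracks", {}))
    tracks, truth_inst = sim.simulate_contribution_tracks(track_cfg)
    dio.write_tracks(tracks, out / "tracks.fasta", out / "contrib.tsv")
    dio.write_table(truth_inst, out / "truth_instances.tsv", "truth_instances")
    cwms = [sim.cwm_from_pwm(pwm, cls, amp) for pwm, cls, amp in track_cfg.motif_library]
    dio.write_cwms_json(cwms, out / "cwms.json")
    dio.write_meme_pwms([pwm for pwm, _, _ in track_cfg.motif_library], out / "pwms.meme")

    curve_cfg = sim.SimCurveConfig(seed=seed + 2, **p.get("curves", {}))
    curves, truth_curves = sim.simulate_nmc_curves(curve_cfg)
    dio.write_curves(curves, out / "curves.tsv")
    dio.write_table(truth_curves, out / "truth_curves.tsv", "truth_curves")
    artifacts.extend(out / n for n in (
        "counts.tsv", "samples.tsv", "truth_dose.tsv", "tracks.fasta", "contrib.tsv",
        "truth_instances.tsv", "cwms.json", "pwms.meme", "curves.tsv", "truth_curves.tsv"))


def _stage_dose_response(config: RunConfig, out: Path, artifacts: list[Path]) -> None:
    p = dict(config.dose_response)
    counts_path = p.get("counts", out / "counts.tsv")
    samples_path = p.get("samples", out / "samples.tsv")
    log.info("stage dose_response: fitting Hill curves from %s", counts_path)
    counts = dio.read_counts(counts_path)
    samples = dio.read_samples(samples_path)
    cm = dr.CountMatrix(counts, samples)
    fits = dr.fit_all(cm, z_cut=p.get("z_cut", 3.0), min_points=p.get("min_points", 4))
    dio.write_table(fits, out / "hill_fits.tsv", "hill_fits")
    artifacts.append(out / "hill_fits.tsv")
    log.info("fitted %d REs (%d converged)", len(fits), int(fits["converged"].sum()))


def _stage_nmc(config: RunConfig, out: Path, artifacts: list[Path]) -> None:
    p = dict(config.nmc)
    curves_path = p.get("curves", out / "curves.tsv")
    log.info("stage nmc: fitting competition model to curves from %s", curves_path)
    curves = dio.read_curves(curves_path)
    n_ha, n_la, L = p.get("n_ha", 3), p.get("n_la", 0), p.get("L", 1e3)
    fits = [nmc.fit_nmc(c, n_ha=n_ha, n_la=n_la, L=L) for c in curves]
    rows = [dict(curve_id=f.curve_id, model=f.model, n_ha=f.n_ha, n_la=f.n_la,
                 c=f.c, a100=f.a100, r=f.r, mse=f.mse, converged=f.converged,
                 accepted=f.accepted) for f in fits]
    dio.write_table(pd.DataFrame(rows), out / "nmc_fits.tsv", "nmc_fits")
    summary = nmc.summarize_nmc(fits)
    dio.write_table(
        pd.DataFrame([dict(model=s.model, n_total=s.n_total, n_accepted=s.n_accepted,
                           median_c=s.median_c, median_r=s.median_r) for s in summary]),
        out / "nmc_summary.tsv", "nmc_summary")
    artifacts.extend([out / "nmc_fits.tsv", out / "nmc_summary.tsv"])


def _stage_motifs(config: RunConfig, out: Path, artifacts: list[Path]) -> None:
    p = dict(config.motifs)
    log.info("stage motifs: calling CWM instances")
    tracks = dio.read_tracks(p.get("fasta", out / "tracks.fasta"),
                             p.get("contrib", out / "contrib.tsv"))
    cwms = dio.read_cwms_json(p.get("cwms", out / "cwms.json"))
    instances = mot.call_instances(
        tracks, cwms,
        jaccard_pct=p.get("jaccard_pct", 10.0),
        contrib_pct=p.get("contrib_pct", 0.5),
        seqlet_mad_factor=p.get("seqlet_mad_factor", 8.0),
    )
    pwms = {w.id: w for w in dio.read_meme_pwms(p.get("pwms", out / "pwms.meme"))}
    seqs = {t.region_id: t.sequence for t in tracks}
    for inst in instances:
        pwm = pwms.get(inst.cwm_id)
        if pwm is not None:
            score, ok = mot.pwm_match(seqs[inst.region_id][inst.start:inst.end], pwm,
                                      p=p.get("pwm_p", 0.01))
            inst.pwm_score, inst.pwm_pass = score, ok
    dio.write_instances_bed(instances, out / "instances.tsv")

    dist = mot.summit_distance(instances, tracks)
    dio.write_table(
        pd.DataFrame(dict(cls=[i.cls for i in instances], summit_distance=dist)),
        out / "summit_distances.tsv", "summit_distances")

    # demo conservation: synthetic stand-in score track, elevated at planted truth
    seed = stage_seed(config.seed, "motifs")
    rng = np.random.default_rng(seed)
    truth_path = p.get("truth_instances", out / "truth_instances.tsv")
    score_tracks = []
    if Path(truth_path).exists():
        truth = dio.read_table(truth_path)
        for t in tracks:
            s = np.clip(rng.normal(0.2, 0.05, size=len(t.sequence)), 0, 1)
            for _, row in truth[truth["region_id"] == t.region_id].iterrows():
                s[int(row["start"]): int(row["end"])] += 0.6
            score_tracks.append(mot.ScoreTrack(t.region_id, np.clip(s, 0, 1)))
        dio.write_score_tracks(score_tracks, out / "synthetic_conservation.tsv")
        contrast = mot.conservation_contrast(
            instances, score_tracks, threshold=p.get("threshold", 0.5),
            n_shuffle=p.get("n_shuffle", 5), seed=seed)
        with open(out / "conservation.json", "w") as fh:
            json.dump(contrast, fh, indent=1, sort_keys=True)
            fh.write("\n")
        artifacts.extend([out / "synthetic_conservation.tsv", out / "conservation.json"])
    artifacts.extend([out / "instances.tsv", out / "summit_distances.tsv"])
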