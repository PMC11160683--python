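"""Readers and writers for the package's text formats.

Coordinates are 0-based half-open (BED convention) everywhere internally;
1-based formats would be converted at the boundary.  Tables written here
carry a one-line schema header comment (``# dosechrom table=... schema=1``)
that readers skip; round-trips are byte-identical up to that documented
normalization (tabs, uppercase FASTA sequence).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import CWM, PWM, ContributionTrack, ScoreTrack

__all__ = [
    "IntervalRecord",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_meme_pwms",
    "write_meme_pwms",
    "read_cwms_json",
    "write_cwms_json",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_tracks",
    "write_tracks",
    "read_curves",
    "write_curves",
    "read_table",
    "write_table",
    "write_instances_bed",
]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""


@dataclass
class IntervalRecord:
    """One BED6 interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end ({self.chrom}:{self.start}-{self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"strand must be one of + - . (got {self.strand!r})")


def read_bed(path) -> list[IntervalRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                records.append(IntervalRecord(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_bed(records: list[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def read_fasta(path) -> dict[str, dict]:
    """id -> {'seq': uppercased sequence, 'masked': had lowercase, 'desc': header rest}."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        out[rec.id] = {
            "seq": raw.upper(),
            "masked": any(ch.islower() for ch in raw),
            "desc": rec.description[len(rec.id):].strip(),
        }
    return out


def write_fasta(seqs: dict[str, str], path, descriptions: dict[str, str] | None = None) -> None:
    records = []
    for rid, seq in seqs.items():
        desc = (descriptions or {}).get(rid, "")
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


# --- MEME minimal motif format (probability matrices) ----------------------

_ROW_SUM_WARN = 1e-2  # rows off by <= this are renormalized with a warning


def read_meme_pwms(path, pseudocount: float = 0.0) -> list[PWM]:
    """Parse a MEME minimal-format motif file into PWMs.

    Rows summing to 1 within 1e-2 are renormalized (with a warning beyond
    1e-9); larger deviations raise a FormatError with the line number.
    """
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    background = np.full(4, 0.25)

    def flush(lineno):
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise FormatError(f"{path}:{lineno}: motif {name!r} has no matrix rows")
        mat = np.array(rows)
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1) > _ROW_SUM_WARN
        if bad.any():
            raise FormatError(
                f"{path}:{lineno}: motif {name!r} rows sum to {sums[bad][0]:.4g} (tolerance {_ROW_SUM_WARN})"
            )
        if np.any(np.abs(sums - 1) > 1e-9):
            warnings.warn(f"motif {name!r}: rows renormalized to sum to 1")
        mat = mat / sums[:, None]
        pwms.append(PWM(id=name, probs=mat, background=background.copy(),
                        pseudocount=pseudocount))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("Background letter frequencies"):
                continue
            if s.startswith("A ") and "C " in s and name is None and rows == []:
                parts = s.split()
                try:
                    background = np.array([float(parts[i]) for i in (1, 3, 5, 7)])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad background line") from exc
                continue
            if s.startswith("MOTIF"):
                flush(lineno)
                parts = s.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: MOTIF line without a name")
                name = parts[1]
                continue
            if s.startswith("letter-probability matrix") or not s or s.startswith(("MEME version", "ALPHABET", "strands", "URL")):
                continue
            if name is not None:
                vals = s.split()
                if len(vals) != 4:
                    raise FormatError(f"{path}:{lineno}: matrix row needs 4 columns")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric matrix entry") from exc
        flush("EOF")
    return pwms


def write_meme_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.3f} C {bg[1]:.3f} G {bg[2]:.3f} T {bg[3]:.3f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")
            fh.write("\n")


def read_cwms_json(path) -> list[CWM]:
    with open(path) as fh:
        payload = json.load(fh)
    return [CWM(id=d["id"], matrix=np.array(d["matrix"]), cls=d.get("cls", "other"))
            for d in payload]


def write_cwms_json(cwms: list[CWM], path) -> None:
    payload = [dict(id=c.id, cls=c.cls, matrix=c.matrix.tolist()) for c in cwms]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# --- tables ----------------------------------------------------------------


def write_table(df: pd.DataFrame, path, name: str, index: bool = False) -> None:
    """TSV with a one-line versioned schema comment."""
    cols = (list(df.index.names) if index and df.index.name else []) + list(df.columns)
    with open(path, "w") as fh:
        fh.write(f"# dosechrom table={name} schema=1 columns={','.join(map(str, cols))}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_counts(counts: pd.DataFrame, path) -> None:
    write_table(counts, path, "counts", index=True)


def read_counts(path) -> pd.DataFrame:
    df = read_table(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    write_table(samples, path, "samples")


def read_samples(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("sample", "dosage_pct", "batch", "replicate"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    dose = pd.to_numeric(df["dosage_pct"], errors="coerce")
    if dose.isna().any():
        row = int(df.index[dose.isna()][0])
        # +3: one schema comment line, one header line, 1-based
        raise FormatError(f"{path}:{row + 3}: non-numeric dosage_pct")
    df["dosage_pct"] = dose
    return df


def write_curves(curves, path) -> None:
    rows = []
    for c in curves:
        for d, y in zip(c.grid, c.response):
            rows.append(dict(curve_id=c.curve_id, dosage=d, response=y))
    write_table(pd.DataFrame(rows), path, "curves")


def read_curves(path):
    from .nmc import DoseCurve

    df = read_table(path)
    curves = []
    for cid, grp in df.groupby("curve_id", sort=False):
        grp = grp.sort_values("dosage")
        curves.append(DoseCurve(grid=grp["dosage"].to_numpy(),
                                response=grp["response"].to_numpy(), curve_id=str(cid)))
    return curves


# --- contribution tracks: FASTA + per-base bedGraph-style TSV --------------


def write_tracks(tracks: list[ContributionTrack], fasta_path, contrib_path) -> None:
    write_fasta({t.region_id: t.sequence for t in tracks}, fasta_path,
                descriptions={t.region_id: f"summit={t.summit}" for t in tracks})
    rows = []
    for t in tracks:
        vals = t.contrib.sum(axis=1)  # nonzero only at the observed base
        for i, v in enumerate(vals):
            rows.append((t.region_id, i, i + 1, v))
    df = pd.DataFrame(rows, columns=["region_id", "start", "end", "value"])
    write_table(df, contrib_path, "contrib_bedgraph")


def read_tracks(fasta_path, contrib_path) -> list[ContributionTrack]:
    seqs = read_fasta(fasta_path)
    df = read_table(contrib_path)
    tracks = []
    for rid, info in seqs.items():
        summit = 0
        for token in info["desc"].split():
            if token.startswith("summit="):
                summit = int(token.split("=", 1)[1])
        seq = info["seq"]
        sub = df[df["region_id"] == rid]
        vals = np.zeros(len(seq))
        vals[sub["start"].to_numpy(int)] = sub["value"].to_numpy(float)
        contrib = np.zeros((len(seq), 4))
        base_idx = np.array(["ACGT".index(ch) if ch in "ACGT" else 0 for ch in seq])
        contrib[np.arange(len(seq)), base_idx] = vals
        tracks.append(ContributionTrack(rid, seq, contrib, summit))
    return tracks


def write_score_tracks(tracks: list[ScoreTrack], path) -> None:
    rows = []
    for t in tracks:
        for i, v in enumerate(t.scores):
            rows.append((t.region_id, i, i + 1, v))
    write_table(pd.DataFrame(rows, columns=["region_id", "start", "end", "value"]),
                path, "score_bedgraph")


def read_score_tracks(path) -> list[ScoreTrack]:
    df = read_table(path)
    out = []
    for rid, grp in df.groupby("region_id", sort=False):
        length = int(grp["end"].max())
        scores = np.full(length, np.nan)
        scores[grp["start"].to_numpy(int)] = grp["value"].to_numpy(float)
        out.append(ScoreTrack(str(rid), scores))
    return out


def write_instances_bed(instances, path) -> None:
    """BED6 + cwm_id, jaccard, contrib, pwm_score, pwm_pass columns."""
    with open(path, "w") as fh:
        fh.write("# dosechrom table=instances schema=1 columns=region,start,end,name,score,strand,cwm_id,cls,jaccard,contrib,pwm_score,pwm_pass\n")
        for k, inst in enumerate(instances):
            pwm_score = "" if inst.pwm_score != inst.pwm_score else f"{inst.pwm_score:.4f}"
            pwm_pass = "" if inst.pwm_pass is None else str(int(inst.pwm_pass))
            fh.write(
                f"{inst.region_id}\t{inst.start}\t{inst.end}\tinst_{k + 1}\t"
                f"{inst.jaccard:.6f}\t{inst.strand}\t{inst.cwm_id}\t{inst.cls}\t"
                f"{inst.jaccard:.6f}\t{inst.total_contrib:.6f}\t{pwm_score}\t{pwm_pass}\n"
            )
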