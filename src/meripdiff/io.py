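"""File formats for the pipeline.

All coordinates are 0-based half-open (BED/bedGraph convention) in
transcript space, sense strand only. Coverage tracks are run-length
encoded bedGraph; peaks are BED6 with a companion TSV carrying exact
summits and unscaled scores; transcript annotation is a TSV of region
lengths; sequences are FASTA.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import Peak
from .simulate import CoverageTrack, TranscriptModel

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_bedgraph",
    "write_bedgraph",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_yaml",
    "write_yaml",
]

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len"]


class ParseError(ValueError):
    """A malformed record, reported with file and line number."""

    def __init__(self, path: str, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


def read_fasta(path: str) -> dict[str, str]:
    """id -> sequence, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str] | list[TranscriptModel]) -> None:
    if isinstance(sequences, list):
        sequences = {m.transcript_id: m.sequence for m in sequences}
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def write_annotation(path: str, models: list[TranscriptModel]) -> None:
    df = pd.DataFrame(
        [
            (m.transcript_id, m.gene_id, m.utr5_len, m.cds_len, m.utr3_len)
            for m in models
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str, sequences: dict[str, str] | None = None) -> list[TranscriptModel]:
    """Annotation TSV -> TranscriptModels; sequences supplied separately
    (or synthesized as N-free placeholders are not allowed: a sequence is
    required for every transcript when ``sequences`` is given)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    models = []
    for i, row in df.iterrows():
        length = int(row.utr5_len) + int(row.cds_len) + int(row.utr3_len)
        if sequences is not None:
            if row.transcript_id not in sequences:
                raise ParseError(path, i + 2, f"no sequence for {row.transcript_id}")
            seq = sequences[row.transcript_id]
        else:
            seq = "A" * length
        models.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
                sequence=seq,
            )
        )
    return models


def write_bedgraph(path: str, coverage: dict[str, np.ndarray]) -> None:
    """Run-length encoded per-position coverage, one transcript per block."""
    with open(path, "w") as fh:
        for tx in coverage:
            vals = np.asarray(coverage[tx])
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                fh.write(f"{tx}\t{s}\t{e}\t{vals[s]:g}\n")


def read_bedgraph(path: str, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """bedGraph -> per-position arrays (gaps are zero coverage).

    Overlapping intervals on one transcript are an error: a track must
    partition its coverage.
    """
    out = {tx: np.zeros(n) for tx, n in lengths.items()}
    seen_end: dict[str, int] = {}
    last_tx_rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, ln, f"expected 4 columns, got {len(parts)}")
            tx, s_, e_, v_ = parts
            try:
                s, e, v = int(s_), int(e_), float(v_)
            except ValueError as exc:
                raise ParseError(path, ln, f"bad record: {exc}") from None
            if s >= e:
                raise ParseError(path, ln, f"start {s} >= end {e}")
            if tx not in out:
                raise ParseError(path, ln, f"unknown transcript {tx}")
            if e > lengths[tx]:
                raise ParseError(path, ln, f"interval end {e} beyond transcript length")
            rows = last_tx_rows.setdefault(tx, [])
            for ps, pe in rows:
                if s < pe and ps < e:
                    raise ParseError(
                        path, ln, f"interval [{s},{e}) overlaps [{ps},{pe}) on {tx}"
                    )
            rows.append((s, e))
            out[tx][s:e] = v
    return out


def write_peaks_bed(path: str, peaks: list[Peak], summit_path: str | None = None) -> None:
    """BED6 (score = enrichment x100, capped at 1000) plus a companion
    TSV with exact summits and unscaled scores."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            bed_score = min(1000, int(round(p.score * 100)))
            name = f"{p.sample_id or 'peak'}:{i}"
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\t{name}\t{bed_score}\t+\n"
            )
    if summit_path:
        df = pd.DataFrame(
            [
                (p.transcript_id, p.start, p.end, p.summit, p.score, p.sample_id)
                for p in peaks
            ],
            columns=["transcript_id", "start", "end", "summit", "score", "sample_id"],
        )
        df.to_csv(summit_path, sep="\t", index=False)


def read_peaks_bed(path: str, summit_path: str | None = None) -> list[Peak]:
    summits = {}
    if summit_path and os.path.exists(summit_path):
        df = pd.read_csv(summit_path, sep="\t")
        for _, r in df.iterrows():
            summits[(r.transcript_id, int(r.start), int(r.end))] = (
                int(r.summit),
                float(r.score),
                str(r.sample_id),
            )
    peaks = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, ln, f"expected 6 columns, got {len(parts)}")
            tx, s_, e_, name, score_, _strand = parts[:6]
            try:
                s, e = int(s_), int(e_)
            except ValueError as exc:
                raise ParseError(path, ln, f"bad record: {exc}") from None
            if s >= e:
                raise ParseError(path, ln, f"start {s} >= end {e}")
            summit, score, sample = summits.get(
                (tx, s, e), ((s + e) // 2, float(score_) / 100.0, name.split(":")[0])
            )
            peaks.append(
                Peak(
                    transcript_id=tx,
                    start=s,
                    end=e,
                    summit=summit,
                    score=score,
                    sample_id=sample,
                )
            )
    return peaks


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(path: str, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
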