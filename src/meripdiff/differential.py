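"""Differential methylation peak (DMP) calling.

The procedure: peaks overlapping between two samples of a group are
"common peaks"; common peaks of the case and control groups are merged
into a union peak reference; each sample gets an enrichment score per
union peak (library-normalized IP reads over input reads); and a union
peak is a DMP for a contrast when the group-mean scores clear both an
absolute-enrichment threshold and a log2 fold-change threshold. The
filter is purely threshold-based — no replicate-aware test is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import pandas as pd

from .peaks import Peak
from .simulate import CoverageTrack

__all__ = [
    "UnionPeak",
    "Contrast",
    "common_peaks",
    "common_peaks_by_transcript",
    "group_common_peaks",
    "build_union_reference",
    "compute_enrichment",
    "enrichment_matrix",
    "call_dmps",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class UnionPeak:
    """A disjoint interval of the union peak reference."""

    transcript_id: str
    start: int
    end: int
    provenance: tuple[tuple[str, int, int], ...] = ()

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Contrast:
    """Case-vs-control comparison; log2fc = log2(mean_case / mean_control)."""

    case: str
    control: str

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValueError("case and control groups must differ")


def _check_intervals(ivs: list[Interval]) -> list[Interval]:
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"malformed interval [{s}, {e})")
    return sorted(ivs)


def common_peaks(
    peaks_a: list[Interval],
    peaks_b: list[Interval],
    mode: str = "union",
) -> list[Interval]:
    """Common peaks between two samples on one transcript.

    Overlap components (chains of intervals linked by >= 1 nt overlap;
    adjacency does not link) containing at least one interval from each
    sample are emitted — as the component's spanning union interval by
    default, or as the merged pairwise intersections in ``mode="intersection"``.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    a = _check_intervals(list(peaks_a))
    b = _check_intervals(list(peaks_b))
    tagged = sorted([(s, e, 0) for s, e in a] + [(s, e, 1) for s, e in b])

    out: list[Interval] = []
    comp: list[tuple[int, int, int]] = []
    comp_end = -1

    def flush() -> None:
        labels = {t for _, _, t in comp}
        if labels == {0, 1}:
            if mode == "union":
                out.append((comp[0][0], max(e for _, e, _ in comp)))
            else:
                ints = [
                    (max(s1, s2), min(e1, e2))
                    for s1, e1, t1 in comp
                    for s2, e2, t2 in comp
                    if t1 == 0 and t2 == 1 and max(s1, s2) < min(e1, e2)
                ]
                out.extend(merge_intervals(ints, adjacent=True))

    for s, e, t in tagged:
        if comp and s < comp_end:
            comp.append((s, e, t))
            comp_end = max(comp_end, e)
        else:
            if comp:
                flush()
            comp = [(s, e, t)]
            comp_end = e
    if comp:
        flush()
    return out


def merge_intervals(ivs: list[Interval], adjacent: bool = True) -> list[Interval]:
    """Merge overlapping (and, if ``adjacent``, 0-gap touching) intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        touches = merged and (s < merged[-1][1] or (adjacent and s == merged[-1][1]))
        if touches:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _by_transcript(peaks: list[Peak]) -> dict[str, list[Interval]]:
    d: dict[str, list[Interval]] = {}
    for p in peaks:
        d.setdefault(p.transcript_id, []).append((p.start, p.end))
    return d


def common_peaks_by_transcript(
    peaks_a: list[Peak], peaks_b: list[Peak], mode: str = "union"
) -> dict[str, list[Interval]]:
    """``common_peaks`` applied per transcript to two samples' Peak lists."""
    da, db = _by_transcript(peaks_a), _by_transcript(peaks_b)
    out = {}
    for tx in sorted(set(da) & set(db)):
        ivs = common_peaks(da[tx], db[tx], mode=mode)
        if ivs:
            out[tx] = ivs
    return out


def group_common_peaks(
    per_sample_peaks: list[list[Peak]], mode: str = "union"
) -> dict[str, list[Interval]]:
    """Common peaks across all samples of a group (pairwise fold).

    With one sample the sample's own peaks are returned (nothing to
    intersect against).
    """
    if not per_sample_peaks:
        return {}
    if len(per_sample_peaks) == 1:
        return {
            tx: merge_intervals(ivs, adjacent=False)
            for tx, ivs in _by_transcript(per_sample_peaks[0]).items()
        }
    common = common_peaks_by_transcript(per_sample_peaks[0], per_sample_peaks[1], mode)
    for nxt in per_sample_peaks[2:]:
        dn = _by_transcript(nxt)
        merged = {}
        for tx in sorted(set(common) & set(dn)):
            ivs = common_peaks(common[tx], dn[tx], mode=mode)
            if ivs:
                merged[tx] = ivs
        common = merged
    return common


def build_union_reference(
    common_by_group: dict[str, dict[str, list[Interval]]],
) -> list[UnionPeak]:
    """Merge each group's common peaks into a disjoint, sorted reference.

    Overlapping or exactly adjacent intervals merge; the contributing
    (group, start, end) triples are kept as provenance.
    """
    by_tx: dict[str, list[tuple[int, int, str]]] = {}
    for group, d in common_by_group.items():
        for tx, ivs in d.items():
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"malformed interval [{s}, {e})")
                by_tx.setdefault(tx, []).append((s, e, group))

    out: list[UnionPeak] = []
    for tx in sorted(by_tx):
        entries = sorted(by_tx[tx])
        cur: list[tuple[int, int, str]] = []
        cur_end = -1
        for s, e, g in entries:
            if cur and s <= cur_end:
                cur.append((s, e, g))
                cur_end = max(cur_end, e)
            else:
                if cur:
                    out.append(
                        UnionPeak(tx, cur[0][0], cur_end, tuple((g, s, e) for s, e, g in cur))
                    )
                cur = [(s, e, g)]
                cur_end = e
        if cur:
            out.append(
                UnionPeak(tx, cur[0][0], cur_end, tuple((g, s, e) for s, e, g in cur))
            )
    return out


def compute_enrichment(
    peak: UnionPeak, track: CoverageTrack, pseudocount: float = 0.5
) -> float:
    """Library-normalized IP-over-input read ratio within a union peak."""
    if track.ip_library_size <= 0 or track.input_library_size <= 0:
        raise ValueError("zero library size")
    n = len(track.ip_counts)
    if not 0 <= peak.start < peak.end <= n:
        raise ValueError(
            f"peak {peak.key} outside transcript bounds [0, {n})"
        )
    ip = float(np.sum(track.ip_counts[peak.start : peak.end])) + pseudocount
    inp = float(np.sum(track.input_counts[peak.start : peak.end])) + pseudocount
    return (ip / track.ip_library_size) / (inp / track.input_library_size)


def enrichment_matrix(
    reference: list[UnionPeak],
    tracks: list[CoverageTrack],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Union peaks x samples matrix of enrichment scores.

    Index: ``transcript:start-end``; columns: sample ids. Every referenced
    (transcript, sample) track must be present.
    """
    by_key = {(t.transcript_id, t.sample_id): t for t in tracks}
    samples = sorted({t.sample_id for t in tracks})
    data = {}
    for peak in reference:
        row = []
        for s in samples:
            track = by_key.get((peak.transcript_id, s))
            if track is None:
                raise ValueError(
                    f"missing coverage track for {peak.transcript_id}/{s}"
                )
            row.append(compute_enrichment(peak, track, pseudocount))
        data[peak.key] = row
    mat = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    mat.index.name = "peak"
    return mat


def call_dmps(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    contrast: Contrast,
    min_score: float = 6.0,
    min_abs_log2fc: float = 1.0,
    score_mode: str = "max",
    floor: float = 1e-8,
) -> pd.DataFrame:
    """Thresholded DMP calls for one contrast.

    Parameters
    ----------
    matrix
        Enrichment matrix (union peaks x samples).
    groups
        sample_id -> group label.
    score_mode
        How "average enrichment score higher than ``min_score`` in the
        groups" is evaluated: ``"max"`` (default) requires the higher of
        the two group means to exceed it, so a peak fully erased in one
        condition remains callable; ``"both"`` requires both means;
        ``"pooled"`` the mean over all samples of the two groups.

    Returns every union peak with mean_case, mean_control, log2fc,
    status (hyper/hypo) and the passed_filters flag; the DMP set is the
    passing subset.
    """
    if score_mode not in ("max", "both", "pooled"):
        raise ValueError("score_mode must be 'max', 'both' or 'pooled'")
    case_samples = [s for s in matrix.columns if groups.get(s) == contrast.case]
    ctrl_samples = [s for s in matrix.columns if groups.get(s) == contrast.control]
    if not case_samples or not ctrl_samples:
        raise ValueError(
            f"contrast {contrast.case} vs {contrast.control} has an empty group"
        )

    mean_case = matrix[case_samples].mean(axis=1)
    mean_ctrl = matrix[ctrl_samples].mean(axis=1)
    log2fc = np.log2(np.maximum(mean_case, floor) / np.maximum(mean_ctrl, floor))

    if score_mode == "max":
        score_ok = np.maximum(mean_case, mean_ctrl) > min_score
    elif score_mode == "both":
        score_ok = (mean_case > min_score) & (mean_ctrl > min_score)
    else:
        pooled = matrix[case_samples + ctrl_samples].mean(axis=1)
        score_ok = pooled > min_score

    passed = score_ok & (np.abs(log2fc) > min_abs_log2fc)
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": log2fc,
            "status": np.where(log2fc > 0, "hyper", "hypo"),
            "passed_filters": passed,
        },
        index=matrix.index,
    )
    return out
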