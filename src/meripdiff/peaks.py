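"""Per-sample m6A peak calling from IP vs input coverage.

A windowed Poisson enrichment test: within each fixed-width window the
IP read count is tested against a Poisson null whose mean is the
library-size-scaled input count. Significant windows are merged into
peaks. This is a deliberately simple, fully parameterised caller for
transcript-coordinate coverage; it makes no claim of equivalence with
HMM-based exome peak callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import CoverageTrack

__all__ = ["Peak", "PeakCallerParams", "call_peaks", "select_top_peaks"]


@dataclass(frozen=True)
class Peak:
    """A half-open enriched interval on a transcript.

    ``score`` is the mean per-position normalized IP/input ratio within
    the peak; ``summit`` the position where that ratio is maximal.
    """

    transcript_id: str
    start: int
    end: int
    summit: int
    score: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"malformed peak interval [{self.start}, {self.end})")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass(frozen=True)
class PeakCallerParams:
    window: int = 25
    step: int = 25
    p_threshold: float = 1e-5
    merge_gap: int = 50
    min_width: int = 50
    min_input_cpm: float = 1.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_width < self.window:
            raise ValueError("min_width must be >= window")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def _window_sums(x: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(x)])
    ends = np.minimum(starts + window, len(x))
    return csum[ends] - csum[starts]


def significant_windows(track: CoverageTrack, params: PeakCallerParams) -> list[tuple[int, int]]:
    """Windows whose IP count beats the scaled-input Poisson null.

    The null mean is the window input count times the IP/input library
    size ratio, floored at the pseudocount to avoid zero-mean degeneracy.
    """
    n = len(track.ip_counts)
    starts = np.arange(0, n, params.step)
    ip_w = _window_sums(np.asarray(track.ip_counts), starts, params.window)
    in_w = _window_sums(np.asarray(track.input_counts), starts, params.window)
    ratio = track.ip_library_size / track.input_library_size
    mu = np.maximum(in_w * ratio, params.pseudocount)
    # P(X >= ip_w) under Poisson(mu)
    pvals = stats.poisson.sf(ip_w - 1, mu)
    ends = np.minimum(starts + params.window, n)
    return [
        (int(s), int(e))
        for s, e, p in zip(starts, ends, pvals)
        if p < params.p_threshold
    ]


def _merge_windows(wins: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(wins):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _position_ratio(track: CoverageTrack, pseudocount: float) -> np.ndarray:
    ip = (np.asarray(track.ip_counts, dtype=float) + pseudocount) / track.ip_library_size
    inp = (np.asarray(track.input_counts, dtype=float) + pseudocount) / track.input_library_size
    return ip / inp


def call_peaks(track: CoverageTrack, params: PeakCallerParams | None = None) -> list[Peak]:
    """Call enriched peaks on one coverage track.

    Returns disjoint peaks sorted by start. Transcripts whose input CPM
    falls below ``min_input_cpm`` are treated as unexpressed and skipped.
    """
    params = params or PeakCallerParams()
    n = len(track.ip_counts)
    if n == 0:
        raise ValueError("empty coverage track")
    if track.ip_library_size <= 0 or track.input_library_size <= 0:
        raise ValueError("zero library size")

    input_cpm = np.sum(track.input_counts) / track.input_library_size * 1e6
    if input_cpm < params.min_input_cpm:
        return []

    wins = significant_windows(track, params)
    regions = [
        (s, e)
        for s, e in _merge_windows(wins, params.merge_gap)
        if e - s >= params.min_width
    ]
    if not regions:
        return []

    ratio = _position_ratio(track, params.pseudocount)
    peaks = []
    for s, e in regions:
        summit = s + int(np.argmax(ratio[s:e]))
        peaks.append(
            Peak(
                transcript_id=track.transcript_id,
                start=s,
                end=e,
                summit=summit,
                score=float(np.mean(ratio[s:e])),
                sample_id=track.sample_id,
            )
        )
    return peaks


def select_top_peaks(peaks: list[Peak], n: int) -> list[Peak]:
    """The n highest-scoring peaks; ties broken by (transcript_id, start)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = sorted(peaks, key=lambda p: (-p.score, p.transcript_id, p.start))
    return ranked[:n]
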