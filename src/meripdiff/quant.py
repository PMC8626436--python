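"""Small downstream quantification formulas.

2^-ddCt qPCR expression fold change, gene-specific m6A-IP qPCR relative
level, and first-order mRNA decay half-life from an actinomycin-D
transcription-shutoff time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QpcrMeasurement",
    "MeripQpcrPair",
    "DecayCurve",
    "DecayFit",
    "ddct_fold_change",
    "m6a_ip_relative",
    "decay_halflife",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One sample's quantification cycles for target and reference genes
    (the reference is the internal control, e.g. Gapdh)."""

    sample_id: str
    group: str
    target_cq: float
    reference_cq: float

    def __post_init__(self) -> None:
        for v in (self.target_cq, self.reference_cq):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("Cq values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.target_cq - self.reference_cq


@dataclass(frozen=True)
class MeripQpcrPair:
    """Cq of the m6A IP portion and of the input portion for one gene."""

    ip_cq: float
    input_cq: float

    def __post_init__(self) -> None:
        for v in (self.ip_cq, self.input_cq):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("Cq values must be positive and finite")


@dataclass(frozen=True)
class DecayCurve:
    """Relative mRNA abundance (fraction of the t=0 level) over time.

    Timepoints in hours; the default design samples 0, 3 and 6 h after
    transcription shutoff.
    """

    timepoints: tuple[float, ...]
    abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.abundance):
            raise ValueError("timepoints and abundance differ in length")
        if len(set(self.timepoints)) < 2:
            raise ValueError("need >= 2 distinct timepoints")
        if any(a <= 0 for a in self.abundance):
            raise ValueError("abundances must be positive")

    def normalized(self) -> "DecayCurve":
        """Rescale so abundance at the earliest timepoint equals 1."""
        order = np.argsort(self.timepoints)
        t0 = self.abundance[int(order[0])]
        return DecayCurve(self.timepoints, tuple(a / t0 for a in self.abundance))


@dataclass(frozen=True)
class DecayFit:
    rate_per_hour: float
    halflife_hours: float
    non_decaying: bool


def ddct_fold_change(case: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Expression fold change by the 2^-ddCt method."""
    ddct = case.delta_ct - control.delta_ct
    return 2.0 ** -ddct


def m6a_ip_relative(pair: MeripQpcrPair, mode: str = "paper") -> float:
    """Relative m6A level of a gene from IP and input qPCR.

    ``"paper"`` (default) is the literal Cq(IP) / Cq(input) ratio of
    cycle numbers; ``"percent_input"`` is the conventional quantity
    ratio 2^(Cq_input - Cq_IP).
    """
    if mode == "paper":
        if pair.input_cq == 0:
            raise ZeroDivisionError("input Cq is zero")
        return pair.ip_cq / pair.input_cq
    if mode == "percent_input":
        return 2.0 ** (pair.input_cq - pair.ip_cq)
    raise ValueError("mode must be 'paper' or 'percent_input'")


def decay_halflife(curve: DecayCurve) -> DecayFit:
    """First-order decay fit: least squares of ln(abundance) on time.

    k is minus the slope; half-life is ln(2)/k. A non-positive k (no
    decay) yields an infinite half-life with the non_decaying flag set.
    """
    t = np.asarray(curve.timepoints, dtype=float)
    y = np.log(np.asarray(curve.abundance, dtype=float))
    slope = np.polyfit(t, y, 1)[0]
    k = -float(slope)
    if k <= 0:
        return DecayFit(rate_per_hour=k, halflife_hours=math.inf, non_decaying=True)
    return DecayFit(rate_per_hour=k, halflife_hours=math.log(2) / k, non_decaying=False)
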