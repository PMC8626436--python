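"""Demethylase-target discovery and peak annotation.

Maps differentially methylated peaks to genes and transcript regions,
intersects the hyper/hypo gene sets of the three perturbation contrasts
(hypermethylated under knockdown and knockout, hypomethylated under
overexpression), builds metagene profiles over normalized 5'UTR/CDS/3'UTR
coordinates, and provides the Fisher's-exact set-enrichment statistic
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import TranscriptModel

__all__ = [
    "GeneAssignment",
    "TargetGene",
    "MetageneProfile",
    "assign_peaks_to_genes",
    "intersect_targets",
    "metagene_profile",
    "enrichment_test",
]

REGIONS = ("5'UTR", "CDS", "3'UTR", "stop_codon_vicinity")


@dataclass(frozen=True)
class GeneAssignment:
    transcript_id: str
    start: int
    end: int
    gene_id: str
    region: str
    summit: int


@dataclass(frozen=True)
class TargetGene:
    """A gene hypermethylated in both loss-of-function contrasts and
    hypomethylated in the gain-of-function contrast."""

    gene_id: str
    support: dict[str, tuple[str, ...]] = field(default_factory=dict)


def classify_region(
    summit: int, model: TranscriptModel, stop_window: int = 50
) -> str:
    """Region label for a position; stop-codon vicinity takes precedence.

    The vicinity is ``summit`` within +/- ``stop_window`` nt of the
    CDS/3'UTR boundary (the first nt of the 3'UTR).
    """
    if not 0 <= summit < model.length:
        raise ValueError(f"summit {summit} outside transcript {model.transcript_id}")
    if abs(summit - model.stop_codon_pos) <= stop_window:
        return "stop_codon_vicinity"
    if summit < model.utr5_len:
        return "5'UTR"
    if summit < model.stop_codon_pos:
        return "CDS"
    return "3'UTR"


def assign_peaks_to_genes(
    peaks,
    models: list[TranscriptModel],
    stop_window: int = 50,
) -> list[GeneAssignment]:
    """One gene/region assignment per peak, by its summit position.

    ``peaks`` may be Peak objects, UnionPeaks, or (transcript_id, start,
    end[, summit]) tuples; peaks without a summit use their midpoint as
    the representative position.
    """
    by_tx = {m.transcript_id: m for m in models}
    out = []
    for p in peaks:
        if isinstance(p, tuple):
            tx, start, end = p[0], p[1], p[2]
            summit = p[3] if len(p) > 3 else (start + end) // 2
        else:
            tx, start, end = p.transcript_id, p.start, p.end
            summit = getattr(p, "summit", None)
            if summit is None:
                summit = (start + end) // 2
        model = by_tx.get(tx)
        if model is None:
            raise KeyError(f"unknown transcript {tx}")
        out.append(
            GeneAssignment(
                transcript_id=tx,
                start=start,
                end=end,
                gene_id=model.gene_id,
                region=classify_region(summit, model, stop_window),
                summit=summit,
            )
        )
    return out


def intersect_targets(
    hyper_kd: set[str],
    hyper_cko: set[str],
    hypo_oe: set[str],
    support: dict[str, dict[str, tuple[str, ...]]] | None = None,
) -> list[TargetGene]:
    """Genes with >= 1 hyper DMP in each loss-of-function contrast and
    >= 1 hypo DMP in the gain-of-function contrast, lexicographic order.

    ``support`` optionally maps contrast label -> gene -> supporting peak
    keys, carried onto the TargetGene records.
    """
    genes = sorted(set(hyper_kd) & set(hyper_cko) & set(hypo_oe))
    support = support or {}
    return [
        TargetGene(
            gene_id=g,
            support={c: tuple(d.get(g, ())) for c, d in support.items()},
        )
        for g in genes
    ]


@dataclass(frozen=True)
class MetageneProfile:
    """Peak-summit density over concatenated normalized mRNA coordinates."""

    density: np.ndarray
    bins: tuple[int, int, int]

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.density)) - 1.0) > 1e-9:
            raise ValueError("density must sum to 1")
        if (self.density < 0).any():
            raise ValueError("density must be non-negative")

    @property
    def region_slices(self) -> dict[str, slice]:
        b5, bc, b3 = self.bins
        return {
            "5'UTR": slice(0, b5),
            "CDS": slice(b5, b5 + bc),
            "3'UTR": slice(b5 + bc, b5 + bc + b3),
        }

    @property
    def modal_bin(self) -> int:
        return int(np.argmax(self.density))


def _normalized_bin(summit: int, model: TranscriptModel, bins: tuple[int, int, int]) -> int:
    b5, bc, b3 = bins
    if summit < model.utr5_len:
        frac = summit / model.utr5_len
        return min(int(frac * b5), b5 - 1)
    if summit < model.stop_codon_pos:
        frac = (summit - model.utr5_len) / model.cds_len
        return b5 + min(int(frac * bc), bc - 1)
    frac = (summit - model.stop_codon_pos) / model.utr3_len
    return b5 + bc + min(int(frac * b3), b3 - 1)


def metagene_profile(
    peaks,
    models: list[TranscriptModel],
    bins: tuple[int, int, int] = (20, 50, 30),
) -> MetageneProfile:
    """Summit density over tri-region normalized coordinates.

    Each region of each transcript is rescaled to a fixed bin count
    (defaults 20/50/30 for 5'UTR/CDS/3'UTR) so transcripts of different
    region lengths are comparable; densities sum to 1.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("metagene profile needs at least one peak")
    by_tx = {m.transcript_id: m for m in models}
    counts = np.zeros(sum(bins))
    for p in peaks:
        if isinstance(p, tuple):
            tx, summit = p[0], p[1]
        else:
            tx = p.transcript_id
            summit = getattr(p, "summit", None)
            if summit is None:
                summit = (p.start + p.end) // 2
        model = by_tx.get(tx)
        if model is None:
            raise KeyError(f"unknown transcript {tx}")
        if not 0 <= summit < model.length:
            raise ValueError(f"summit {summit} outside transcript {tx}")
        counts[_normalized_bin(summit, model, bins)] += 1
    return MetageneProfile(density=counts / counts.sum(), bins=tuple(bins))


def plot_metagene(profile: MetageneProfile, path: str | None = None):
    """Line plot of the metagene density with region boundaries marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(profile.density))
    ax.plot(x, profile.density, lw=1.5)
    b5, bc, _ = profile.bins
    for boundary, label in ((b5, "start codon"), (b5 + bc, "stop codon")):
        ax.axvline(boundary - 0.5, color="grey", ls="--", lw=0.8)
        ax.text(boundary, ax.get_ylim()[1] * 0.95, label, ha="center", fontsize=8)
    ax.set_xlabel("normalized mRNA position (5'UTR | CDS | 3'UTR)")
    ax.set_ylabel("peak density")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def enrichment_test(
    query_genes: set[str],
    categories: dict[str, set[str]] | set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher's exact set enrichment with BH correction across categories.

    Each category is tested on the 2x2 table of query/category membership
    over the universe; q-values are Benjamini-Hochberg adjusted over all
    categories of the call.
    """
    if not universe:
        raise ValueError("empty universe")
    if isinstance(categories, set):
        categories = {"category": categories}
    query = set(query_genes)
    if not query <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, cat in categories.items():
        cat = set(cat)
        if not cat <= set(universe):
            raise ValueError(f"category {name!r} not a subset of the universe")
        a = len(query & cat)
        b = len(query - cat)
        c = len(cat - query)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, len(cat), odds, p))
    out = pd.DataFrame(
        rows, columns=["category", "overlap", "category_size", "odds_ratio", "p"]
    ).set_index("category")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
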