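"""DRACH motif scanning, mutagenesis design, and k-mer enrichment.

The DRACH consensus is implemented with the letter sets D = A/G,
R = A/G, central A, C, H = A/C/T (a strict-IUPAC mode with D = A/G/T is
available). Mutagenesis replaces the methylatable central A of selected
motif hits with T, the standard way to ablate an m6A site in reporter
constructs. Motif discovery over summit-centered windows is approximated
by k-mer counting against dinucleotide-preserving shuffles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MotifHit",
    "scan_drach",
    "design_mutant",
    "diff_sequences",
    "summit_window",
    "kmer_enrichment",
    "dinucleotide_shuffle",
    "load_adrb2_fragments",
]

_PATTERNS = {
    # the source definition: D = A/G (T deliberately omitted there)
    "paper": re.compile(r"(?=([AG][AG]AC[ACT]))"),
    # conventional IUPAC D = A/G/T
    "iupac": re.compile(r"(?=([AGT][AG]AC[ACT]))"),
}
_VALID = re.compile(r"[ACGT]*\Z")


@dataclass(frozen=True)
class MotifHit:
    """A DRACH match: 0-based start of the 5-mer and its sequence."""

    position: int
    kmer: str

    @property
    def central_a(self) -> int:
        """Position of the methylatable A (motif start + 2)."""
        return self.position + 2


def _normalize(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    if not _VALID.fullmatch(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    return seq


def scan_drach(sequence: str, mode: str = "paper") -> list[MotifHit]:
    """All (overlapping) DRACH 5-mer matches, in ascending position."""
    if mode not in _PATTERNS:
        raise ValueError("mode must be 'paper' or 'iupac'")
    seq = _normalize(sequence)
    return [MotifHit(m.start(), m.group(1)) for m in _PATTERNS[mode].finditer(seq)]


def design_mutant(
    sequence: str, hits: list[MotifHit]
) -> tuple[str, list[tuple[int, str, str]]]:
    """A-to-T substitution at the central A of each selected motif hit.

    Returns the mutant sequence and the design table of
    (position, wild-type base, mutant base) records.
    """
    seq = list(_normalize(sequence))
    design = []
    for hit in hits:
        pos = hit.central_a
        if not 0 <= pos < len(seq):
            raise ValueError(f"hit at {hit.position} out of bounds")
        if seq[pos] != "A":
            raise ValueError(
                f"central base at {pos} is {seq[pos]}, expected A"
            )
        seq[pos] = "T"
        design.append((pos, "A", "T"))
    return "".join(seq), design


def diff_sequences(seq_a: str, seq_b: str) -> list[tuple[int, str, str]]:
    """All mismatching positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    return [(i, a, b) for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]


def summit_window(transcript, summit: int, width: int = 100) -> str:
    """Sense subsequence [summit - width/2, summit + width/2), clipped at
    the transcript ends (never padded).

    ``transcript`` is a TranscriptModel or a plain sequence string.
    """
    sequence = getattr(transcript, "sequence", transcript)
    if not 0 <= summit < len(sequence):
        raise ValueError(f"summit {summit} outside sequence of length {len(sequence)}")
    half = width // 2
    return sequence[max(0, summit - half) : min(len(sequence), summit + half)]


def _count_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
    return counts


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: a uniform random sequence with exactly
    the original's dinucleotide (and hence mononucleotide) composition.

    Builds the edge multigraph of adjacent-base transitions, fixes a
    random last-exit edge per vertex forming an arborescence into the
    terminal base, permutes the remaining out-edges, and reads off the
    resulting Eulerian walk.
    """
    seq = _normalize(sequence)
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    for _attempt in range(1000):
        last_exit: dict[str, str] = {}
        for v in vertices:
            if v != last:
                last_exit[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen last-exit edges must connect every vertex to `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA
        raise RuntimeError("failed to sample a connected arborescence")

    pools: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        pools[v] = pool

    out = [seq[0]]
    idx = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def kmer_enrichment(
    windows: list[str],
    k: int = 5,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed k-mer counts vs dinucleotide-preserving shuffled windows.

    For each k-mer seen in the windows: total observed count, mean count
    over ``n_shuffles`` per-window shuffles, fold enrichment, and the
    empirical upper-tail p-value. Sorted by fold descending (ties by
    observed count then k-mer for determinism).
    """
    windows = [_normalize(w) for w in windows]
    if not windows:
        raise ValueError("need at least one window")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if k > min(len(w) for w in windows):
        raise ValueError("k exceeds the shortest window")

    observed: dict[str, int] = {}
    for w in windows:
        for km, c in _count_kmers(w, k).items():
            observed[km] = observed.get(km, 0) + c

    rng = np.random.default_rng(seed)
    kmers = sorted(observed)
    shuf_counts = np.zeros((n_shuffles, len(kmers)))
    index = {km: i for i, km in enumerate(kmers)}
    for s in range(n_shuffles):
        for w in windows:
            shuffled = dinucleotide_shuffle(w, rng)
            for km, c in _count_kmers(shuffled, k).items():
                if km in index:
                    shuf_counts[s, index[km]] += c

    mean_shuf = shuf_counts.mean(axis=0)
    obs = np.array([observed[km] for km in kmers], dtype=float)
    fold = obs / np.maximum(mean_shuf, 1.0 / n_shuffles)
    pvals = (1.0 + (shuf_counts >= obs).sum(axis=0)) / (n_shuffles + 1.0)
    out = pd.DataFrame(
        {
            "kmer": kmers,
            "observed": obs.astype(int),
            "mean_shuffled": mean_shuf,
            "fold": fold,
            "empirical_p": pvals,
        }
    )
    out = out.sort_values(
        ["fold", "observed", "kmer"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


def load_adrb2_fragments() -> tuple[str, str]:
    """The bundled wild-type and site-mutant Adrb2 3'UTR reporter
    fragments (607 nt each), as plain sequences."""
    from Bio import SeqIO

    seqs = []
    for name in ("adrb2_3utr_wt.fa", "adrb2_3utr_mut.fa"):
        path = resources.files("meripdiff.data") / name
        with path.open() as fh:
            seqs.append(str(next(SeqIO.parse(fh, "fasta")).seq))
    return seqs[0], seqs[1]
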