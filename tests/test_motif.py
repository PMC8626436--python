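"""DRACH scanning, mutagenesis design, and k-mer enrichment, anchored on
the bundled Adrb2 3'UTR reporter fragments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripdiff.motif import (
    MotifHit,
    design_mutant,
    diff_sequences,
    dinucleotide_shuffle,
    kmer_enrichment,
    scan_drach,
    summit_window,
)

DRACH_SETS = {
    "paper": [set("AG"), set("AG"), set("A"), set("C"), set("ACT")],
    "iupac": [set("AGT"), set("AG"), set("A"), set("C"), set("ACT")],
}


def brute_scan(seq, mode="paper"):
    sets = DRACH_SETS[mode]
    return [
        (i, seq[i : i + 5])
        for i in range(len(seq) - 4)
        if all(seq[i + j] in sets[j] for j in range(5))
    ]


dna = st.text(alphabet="ACGT", min_size=0, max_size=500)


class TestScanDrach:
    def test_single_hit(self):
        assert scan_drach("GGACT") == [MotifHit(0, "GGACT")]

    def test_mutant_kmer_no_hit(self):
        assert scan_drach("AGTCC") == []

    def test_empty_sequence(self):
        assert scan_drach("") == []

    def test_u_normalized_to_t(self):
        assert scan_drach("GGACU") == [MotifHit(0, "GGACT")]

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            scan_drach("GGACN")

    def test_overlapping_hits_reported(self):
        # AGGACA: GGACA at 1; prefix AGGAC not a hit (C at position 3 req.)
        seq = "AAGAACAGGACA"
        assert [h.position for h in scan_drach(seq)] == [2, 7]

    def test_wt_fragment_contains_the_four_reporter_sites(self, adrb2):
        wt, _ = adrb2
        hits = {h.position: h.kmer for h in scan_drach(wt)}
        assert hits[272] == "AGACC"
        assert hits[318] == "GGACT"
        assert hits[515] == "GAACT"
        assert hits[524] == "GGACC"

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_matches_bruteforce(self, seq):
        assert [(h.position, h.kmer) for h in scan_drach(seq)] == brute_scan(seq)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_iupac_mode_superset(self, seq):
        paper = {h.position for h in scan_drach(seq)}
        iupac = {h.position for h in scan_drach(seq, mode="iupac")}
        assert paper <= iupac
        assert [(h.position, h.kmer) for h in scan_drach(seq, "iupac")] == brute_scan(
            seq, "iupac"
        )


class TestDesignMutant:
    def test_single_site(self):
        mut, design = design_mutant("GGACT", scan_drach("GGACT"))
        assert mut == "GGTCT"
        assert design == [(2, "A", "T")]

    def test_empty_hits_identity(self):
        assert design_mutant("GGACT", [])[0] == "GGACT"

    def test_central_base_must_be_a(self):
        with pytest.raises(ValueError, match="expected A"):
            design_mutant("GGTCT", [MotifHit(0, "GGTCT")])

    def test_out_of_bounds_hit(self):
        with pytest.raises(ValueError, match="out of bounds"):
            design_mutant("GGA", [MotifHit(5, "GGACT")])

    def test_reproduces_printed_mutant(self, adrb2):
        wt, printed_mut = adrb2
        four = [h for h in scan_drach(wt) if h.position in (272, 318, 515, 524)]
        mut, design = design_mutant(wt, four)
        assert mut == printed_mut
        assert [p for p, _, _ in design] == [274, 320, 517, 526]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_mutation_removes_exactly_selected_site_centers(self, seq):
        hits = scan_drach(seq)
        mut, design = design_mutant(seq, hits)
        assert len(mut) == len(seq)
        changed = {p for p, _, _ in design}
        assert changed == {h.central_a for h in hits}
        # no surviving DRACH centered on a mutated A
        for h in scan_drach(mut):
            assert h.central_a not in changed


class TestDiffSequences:
    def test_printed_pair_has_four_a_to_t(self, adrb2):
        wt, mut = adrb2
        diffs = diff_sequences(wt, mut)
        assert len(diffs) == 4
        assert all(a == "A" and b == "T" for _, a, b in diffs)

    def test_identity_and_simple_case(self):
        assert diff_sequences("ACGT", "ACGT") == []
        assert diff_sequences("AC", "AT") == [(1, "C", "T")]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            diff_sequences("AC", "ACG")


class TestSummitWindow:
    def test_centered(self):
        seq = "A" * 200
        assert summit_window(seq, 50, 100) == seq[0:100]

    def test_clipped_left(self):
        seq = "ACGT" * 50
        assert summit_window(seq, 10, 100) == seq[0:60]

    def test_clipped_right(self):
        seq = "ACGT" * 50
        assert summit_window(seq, 199, 100) == seq[149:200]

    def test_out_of_bounds(self):
        with pytest.raises(ValueError, match="outside"):
            summit_window("ACGT", 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300), data=st.data())
    def test_always_substring(self, seq, data):
        summit = data.draw(st.integers(0, len(seq) - 1))
        win = summit_window(seq, summit)
        assert win in seq
        assert len(win) <= 100


class TestDinucleotideShuffle:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=120))
    def test_preserves_dinucleotide_counts(self, seq):
        rng = np.random.default_rng(1)
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

        def dinucs(s):
            d = {}
            for a, b in zip(s, s[1:]):
                d[a + b] = d.get(a + b, 0) + 1
            return d

        assert dinucs(shuf) == dinucs(seq)


class TestKmerEnrichment:
    def test_planted_motif_ranks_first(self):
        rng = np.random.default_rng(42)
        windows = []
        for _ in range(200):
            w = list(rng.choice(list("ACGT"), size=100))
            pos = int(rng.integers(0, 96))
            w[pos : pos + 5] = "GGACT"
            windows.append("".join(w))
        table = kmer_enrichment(windows, k=5, n_shuffles=20, seed=0)
        top = table.iloc[0].kmer
        # the plant itself or a 5-mer overlapping it on the DRACH core
        assert "GAC" in top or top == "GGACT"
        assert table[table.kmer == "GGACT"].index[0] <= 2

    def test_degenerate_single_window(self):
        table = kmer_enrichment(["AAAAA"], k=5, n_shuffles=10, seed=1)
        assert len(table) == 1
        assert table.iloc[0].fold == pytest.approx(1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="n_shuffles"):
            kmer_enrichment(["ACGTACGT"], n_shuffles=0)
        with pytest.raises(ValueError, match="shortest window"):
            kmer_enrichment(["ACG"], k=5, n_shuffles=5)
        with pytest.raises(ValueError, match="at least one window"):
            kmer_enrichment([], k=5, n_shuffles=5)

    def test_deterministic_for_seed(self):
        windows = ["ACGTAGGACTTT", "TTGGACTACGAA"]
        t1 = kmer_enrichment(windows, n_shuffles=10, seed=3)
        t2 = kmer_enrichment(windows, n_shuffles=10, seed=3)
        assert t1.equals(t2)
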