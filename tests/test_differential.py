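"""Interval algebra and DMP filtering against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripdiff.differential import (
    Contrast,
    UnionPeak,
    build_union_reference,
    call_dmps,
    common_peaks,
    compute_enrichment,
    enrichment_matrix,
    merge_intervals,
)
from meripdiff.simulate import CoverageTrack

# ---------------------------------------------------------------- oracles


def brute_common(a, b, length):
    """Quadratic brute-force oracle: connect intervals that share >= 1 nt
    (checked per nucleotide), take connected components, and emit the
    span of every component containing both samples."""
    nodes = [(s, e, "a") for s, e in a] + [(s, e, "b") for s, e in b]
    n = len(nodes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    masks = []
    for s, e, _ in nodes:
        mask = np.zeros(length, bool)
        mask[s:e] = True
        masks.append(mask)

    for i in range(n):
        for j in range(i + 1, n):
            if (masks[i] & masks[j]).any():
                parent[find(i)] = find(j)

    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(nodes[i])
    out = []
    for members in comps.values():
        if {t for _, _, t in members} == {"a", "b"}:
            out.append((min(s for s, _, _ in members), max(e for _, e, _ in members)))
    return sorted(out)


def brute_union(interval_lists, length):
    cov = np.zeros(length, bool)
    for ivs in interval_lists:
        for s, e in ivs:
            cov[s:e] = True
    out, i = [], 0
    while i < length:
        if not cov[i]:
            i += 1
            continue
        j = i
        while j < length and cov[j]:
            j += 1
        out.append((i, j))
        i = j
    return out


def random_disjoint_intervals(rng, length, max_n):
    cuts = np.sort(rng.choice(length, size=min(2 * max_n, length // 2), replace=False))
    ivs = [(int(s), int(e)) for s, e in zip(cuts[::2], cuts[1::2]) if s < e]
    return ivs[: rng.integers(0, max_n + 1)]


# ------------------------------------------------------- spec'd examples


def test_common_peaks_examples():
    assert common_peaks([(0, 10)], [(20, 30)]) == []
    same = [(5, 15), (40, 60)]
    assert common_peaks(same, same) == same
    assert common_peaks([(10, 50)], [(40, 80)]) == [(10, 80)]


def test_common_peaks_adjacency_does_not_merge():
    assert common_peaks([(0, 10)], [(10, 20)]) == []


def test_common_peaks_intersection_mode():
    assert common_peaks([(10, 50)], [(40, 80)], mode="intersection") == [(40, 50)]


def test_common_peaks_rejects_malformed():
    with pytest.raises(ValueError):
        common_peaks([(10, 10)], [(0, 5)])


def test_union_reference_examples():
    one = build_union_reference({"g1": {"tx": [(0, 100), (200, 300)]}})
    assert [(u.start, u.end) for u in one] == [(0, 100), (200, 300)]
    two = build_union_reference(
        {"g1": {"tx": [(0, 100)]}, "g2": {"tx": [(50, 150)]}}
    )
    assert [(u.start, u.end) for u in two] == [(0, 150)]
    assert build_union_reference({}) == []


def test_union_reference_merges_adjacent():
    ref = build_union_reference({"g1": {"tx": [(0, 50)]}, "g2": {"tx": [(50, 90)]}})
    assert [(u.start, u.end) for u in ref] == [(0, 90)]


def test_union_reference_provenance_covers_inputs():
    ref = build_union_reference(
        {"g1": {"tx": [(0, 100), (300, 400)]}, "g2": {"tx": [(50, 150)]}}
    )
    for peak in ref:
        for _, s, e in peak.provenance:
            assert peak.start <= s and e <= peak.end


def test_interval_oracle_random():
    rng = np.random.default_rng(123)
    for _ in range(300):
        length = int(rng.integers(100, 5000))
        a = random_disjoint_intervals(rng, length, 25)
        b = random_disjoint_intervals(rng, length, 25)
        assert common_peaks(a, b) == brute_common(a, b, length)
        groups = {"ga": {"tx": a}, "gb": {"tx": b}} if a and b else {}
        if groups:
            got = [(u.start, u.end) for u in build_union_reference(groups)]
            assert got == brute_union([a, b], length)
            for s, e in got:  # disjoint, sorted
                assert s < e
            assert got == sorted(got)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.lists(st.tuples(st.integers(0, 480), st.integers(1, 40)), max_size=12),
    b=st.lists(st.tuples(st.integers(0, 480), st.integers(1, 40)), max_size=12),
)
def test_common_peaks_matches_oracle_property(a, b):
    a = merge_intervals([(s, s + w) for s, w in a], adjacent=False)
    b = merge_intervals([(s, s + w) for s, w in b], adjacent=False)
    assert common_peaks(a, b) == brute_common(a, b, 560)


# ------------------------------------------------------------ enrichment


def track_with(ip_total, input_total, n=100, lib_ip=1_000_000, lib_in=1_000_000):
    ip = np.zeros(n, int)
    inp = np.zeros(n, int)
    ip[0] = ip_total
    inp[0] = input_total
    return CoverageTrack("tx", "s", ip, inp, lib_ip, lib_in)


def test_enrichment_ratio_arithmetic():
    peak = UnionPeak("tx", 0, 100)
    t = track_with(600, 100)
    assert compute_enrichment(peak, t) == pytest.approx(600.5 / 100.5)
    assert compute_enrichment(peak, t, pseudocount=0) == pytest.approx(6.0)


def test_enrichment_identity_and_zero_input():
    peak = UnionPeak("tx", 0, 100)
    assert compute_enrichment(peak, track_with(250, 250), pseudocount=0) == 1.0
    t = track_with(10, 0)
    score = compute_enrichment(peak, t)  # finite via pseudocount
    assert score == pytest.approx(10.5 / 0.5)


def test_enrichment_library_normalization():
    peak = UnionPeak("tx", 0, 100)
    t = track_with(100, 100, lib_ip=2_000_000, lib_in=1_000_000)
    assert compute_enrichment(peak, t, pseudocount=0) == pytest.approx(0.5)


def test_enrichment_rescaling_invariance():
    """Multiplying a sample's counts and library sizes by a constant
    changes its score only through the pseudocount (< 1e-6 relative)."""
    peak = UnionPeak("tx", 0, 100)
    base = track_with(6_000_000, 3_000_000, lib_ip=10_000_000, lib_in=10_000_000)
    scaled = track_with(
        6_000_000 * 7, 3_000_000 * 7, lib_ip=70_000_000, lib_in=70_000_000
    )
    s1 = compute_enrichment(peak, base)
    s2 = compute_enrichment(peak, scaled)
    assert abs(s2 - s1) / s1 < 1e-6


def test_enrichment_errors():
    peak = UnionPeak("tx", 0, 200)
    with pytest.raises(ValueError, match="bounds"):
        compute_enrichment(peak, track_with(1, 1, n=100))
    t = CoverageTrack("tx", "s", np.ones(10, int), np.ones(10, int), 1, 1)
    object.__setattr__(t, "ip_library_size", 0)
    with pytest.raises(ValueError, match="library"):
        compute_enrichment(UnionPeak("tx", 0, 10), t)


def test_enrichment_matrix_missing_track():
    ref = [UnionPeak("tx", 0, 10)]
    t = CoverageTrack("other", "s1", np.ones(10, int), np.ones(10, int), 100, 100)
    with pytest.raises(ValueError, match="missing coverage track"):
        enrichment_matrix(ref, [t])


# ------------------------------------------------------------------ DMPs


def dmp_oracle(mean_case, mean_ctrl, min_score, min_lfc, floor=1e-8):
    lfc = np.log2(max(mean_case, floor) / max(mean_ctrl, floor))
    passed = max(mean_case, mean_ctrl) > min_score and abs(lfc) > min_lfc
    return passed, ("hyper" if lfc > 0 else "hypo")


def matrix_of(case_scores, ctrl_scores):
    data = {}
    for i, (c, k) in enumerate(zip(case_scores, ctrl_scores)):
        data[f"p{i}"] = list(c) + list(k)
    cols = [f"case_{j}" for j in range(len(case_scores[0]))] + [
        f"ctl_{j}" for j in range(len(ctrl_scores[0]))
    ]
    mat = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    groups = {c: ("A" if c.startswith("case") else "B") for c in cols}
    return mat, groups


def test_call_dmps_examples():
    mat, groups = matrix_of([(12, 12), (8, 8), (4, 4)], [(3, 3), (8, 8), (1.5, 1.5)])
    out = call_dmps(mat, groups, Contrast("A", "B"))
    assert out.loc["p0", "passed_filters"] and out.loc["p0", "status"] == "hyper"
    assert out.loc["p0", "log2fc"] == pytest.approx(2.0)
    assert not out.loc["p1", "passed_filters"]  # log2fc = 0
    assert not out.loc["p2", "passed_filters"]  # |lfc|>1 but max mean 4 <= 6


def test_call_dmps_oracle_and_monotonicity():
    rng = np.random.default_rng(99)
    for _ in range(300):
        n_peaks = int(rng.integers(1, 21))
        case = rng.uniform(0, 15, size=(n_peaks, 4))
        ctrl = rng.uniform(0, 15, size=(n_peaks, 4))
        mat, groups = matrix_of(case, ctrl)
        out = call_dmps(mat, groups, Contrast("A", "B"))
        strict = call_dmps(
            mat, groups, Contrast("A", "B"), min_score=8, min_abs_log2fc=1.5
        )
        for i in range(n_peaks):
            exp_pass, exp_status = dmp_oracle(case[i].mean(), ctrl[i].mean(), 6, 1)
            row = out.iloc[i]
            assert bool(row.passed_filters) == exp_pass
            assert row.status == exp_status
            # tightening thresholds never adds a DMP
            assert not (strict.iloc[i].passed_filters and not row.passed_filters)


def test_call_dmps_score_modes():
    mat, groups = matrix_of([(12, 12)], [(0.5, 0.5)])
    c = Contrast("A", "B")
    assert call_dmps(mat, groups, c, score_mode="max").passed_filters.all()
    assert not call_dmps(mat, groups, c, score_mode="both").passed_filters.any()


def test_call_dmps_empty_group_raises():
    mat, groups = matrix_of([(1, 1)], [(1, 1)])
    with pytest.raises(ValueError, match="empty group"):
        call_dmps(mat, groups, Contrast("A", "C"))


def test_contrast_requires_distinct_groups():
    with pytest.raises(ValueError):
        Contrast("A", "A")
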