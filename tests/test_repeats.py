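"""Repeat detectors against regex / brute-force / construction oracles."""

import re

import numpy as np
import pytest

from plastevo.intervals import CircularInterval
from plastevo.plastome_io import reverse_complement
from plastevo.repeats import (
    TandemParams,
    find_dispersed_repeats,
    find_mononucleotide_repeats,
    find_tandem_repeats,
    spacer_at_content,
    summarize_occupancy,
)
from plastevo.structure import detect_inverted_repeat, partition_quadripartite
from plastevo.synthetic_data import GeneStub, PlastomeSpec, generate_plastome

from conftest import random_dna


# ---------------------------------------------------------------------------
# mononucleotide


def mono_regex_oracle(seq, min_run=8):
    return [
        (m.start(), m.end(), m.group()[0])
        for m in re.finditer(r"A{%d,}|C{%d,}|G{%d,}|T{%d,}" % ((min_run,) * 4), seq)
    ]


def test_mono_single_run():
    feats = find_mononucleotide_repeats("GGGAAAAAAAATTC")
    assert [(f.span, f.unit) for f in feats] == [((3, 11), "A")]


def test_mono_below_threshold_is_empty(rng):
    # a 7-base run embedded in GC-only background: no run of 8 anywhere
    seq = "GCGCGCGC" + "A" * 7 + "GCGCGCGC"
    assert find_mononucleotide_repeats(seq) == []


def test_mono_n_breaks_runs():
    # linearly, N splits the run into two sub-threshold halves
    assert find_mononucleotide_repeats("AAAANAAAA", circular=False) == []
    assert len(find_mononucleotide_repeats("AAAAAAAANAAAAAAAA", circular=False)) == 2
    # on the circle the two halves are one 8-bp run through the origin
    assert len(find_mononucleotide_repeats("AAAANAAAA", circular=True)) == 1


def test_mono_circular_wrap_merge():
    seq = "AAAA" + "GCGC" * 4 + "AAAA"
    feats = find_mononucleotide_repeats(seq, circular=True)
    assert len(feats) == 1
    f = feats[0]
    assert f.unit == "A" and f.length == 8
    assert f.span == (len(seq) - 4, len(seq) + 4)
    # linear mode: both ends below threshold
    assert find_mononucleotide_repeats(seq, circular=False) == []


@pytest.mark.parametrize("seed", range(20))
def test_mono_matches_regex_oracle_on_random_strings(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("AACGTN"), size=500))  # A-rich to create runs
    feats = find_mononucleotide_repeats(seq, circular=False)
    assert [(f.span[0], f.span[1], f.unit) for f in feats] == mono_regex_oracle(seq)


# ---------------------------------------------------------------------------
# tandem


def test_tandem_absence_in_random_background(rng):
    seq = random_dna(rng, 10000, at=0.5)
    assert find_tandem_repeats(seq) == []


def test_tandem_planted_14bp_array(rng):
    bg = random_dna(rng, 5000)
    unit = "ATTATAAATTGCAT"
    seq = bg[:2000] + unit * 22 + bg[2000:]
    feats = find_tandem_repeats(seq)
    hits = [f for f in feats if f.span[0] <= 2014 and f.span[1] >= 2000 + 22 * 14 - 14]
    assert len(hits) == 1
    f = hits[0]
    assert f.period == 14
    assert abs(f.copies - 22) <= 0.5
    assert abs(f.length - 308) <= 14


def test_tandem_harmonic_collapsed_to_fundamental(rng):
    bg = random_dna(rng, 3000)
    seq = bg[:1000] + "ACGGAT" * 30 + bg[1000:]
    feats = find_tandem_repeats(seq)
    in_locus = [f for f in feats if f.span[0] < 1000 + 180 and f.span[1] > 1000]
    assert len(in_locus) == 1
    assert in_locus[0].period == 6


def test_tandem_short_sequence_skipped():
    assert find_tandem_repeats("ACG") == []


# ---------------------------------------------------------------------------
# dispersed: brute-force oracle


def brute_force_dispersed(seq, word=16, min_identity=0.95):
    """Quadratic diagonal scan, re-deriving the segment rule independently."""
    import plastevo.repeats as R

    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes[codes == ord("N")] = 0
    found = set()
    # direct: every positive diagonal
    for d in range(1, n - word + 1):
        m = (codes[: n - d] == codes[d:]) & (codes[: n - d] != 0)
        for s, e in R._segments_on_diagonal(m, word, min_identity):
            found.add((("direct"), (s, e), (s + d, e + d)))
    # inverted: every anti-diagonal via the reverse complement
    rc = reverse_complement(seq)
    rcodes = np.frombuffer(rc.encode(), dtype=np.uint8).copy()
    rcodes[rcodes == ord("N")] = 0
    for d in range(-(n - word), n - word + 1):
        a_lo = max(0, -d)
        length = n - abs(d) if d >= 0 else n + d
        length = n - d - a_lo if d >= 0 else n + d
        seg_len = min(n - a_lo, n - (a_lo + d))
        m = (codes[a_lo : a_lo + seg_len] == rcodes[a_lo + d : a_lo + d + seg_len]) & (
            codes[a_lo : a_lo + seg_len] != 0
        )
        for s, e in R._segments_on_diagonal(m, word, min_identity):
            a_s, a_e = a_lo + s, a_lo + e
            b_s, b_e = n - (a_e + d), n - (a_s + d)
            first, second = sorted([(a_s, a_e), (b_s, b_e)])
            if first == second or first[1] > second[0]:
                continue
            found.add(("inverted", first, second))
    return found


def test_dispersed_all_distinct_words_empty(rng):
    # a de-Bruijn-free short random sequence: just check detector agrees w/ oracle
    seq = random_dna(rng, 300, at=0.5)
    feats = find_dispersed_repeats(seq)
    assert {(f.orientation, f.span, f.span2) for f in feats} == brute_force_dispersed(seq)


def test_dispersed_planted_inverted_pair(rng):
    bg = random_dna(rng, 4000, at=0.5)
    seg = bg[100:140]
    seq = bg[:1500] + seg + bg[1500:2500] + reverse_complement(seg) + bg[2500:]
    feats = find_dispersed_repeats(seq)
    inv = [f for f in feats if f.orientation == "inverted" and f.identity == 1.0 and f.length >= 40]
    assert any(
        f.span[0] <= 1500 <= f.span[0] + 5 or abs(f.span[0] - 1500) < 50 for f in inv
    )
    # implementation == oracle, exact pair set
    assert {(f.orientation, f.span, f.span2) for f in feats} == brute_force_dispersed(seq)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dispersed_equals_brute_force_with_planted_repeats(seed):
    rng = np.random.default_rng(seed)
    bg = random_dna(rng, 2500, at=0.5)
    seg = random_dna(rng, 60, at=0.5)
    # one direct pair (with a mismatch) and one inverted pair
    seg2 = list(seg)
    seg2[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg2[30]]
    seq = bg[:500] + seg + bg[500:1200] + "".join(seg2) + bg[1200:1800] + reverse_complement(seg) + bg[1800:]
    impl = {(f.orientation, f.span, f.span2) for f in find_dispersed_repeats(seq)}
    assert impl == brute_force_dispersed(seq)
    assert any(o == "direct" for o, _, _ in impl)
    assert any(o == "inverted" for o, _, _ in impl)


def test_dispersed_exclude_masks_hits(rng):
    bg = random_dna(rng, 2000, at=0.5)
    seg = random_dna(rng, 40, at=0.5)
    seq = bg[:500] + seg + bg[500:1200] + seg + bg[1200:]
    n = len(seq)
    all_hits = find_dispersed_repeats(seq)
    assert any(f.span[0] >= 495 and f.span[0] <= 505 for f in all_hits)
    masked = find_dispersed_repeats(seq, exclude=[CircularInterval(480, 100, n)])
    assert not any(480 <= f.span[0] < 580 or 480 <= f.span2[0] < 580 for f in masked)


# ---------------------------------------------------------------------------
# occupancy


def _mk(klass, s, e, **kw):
    from plastevo.repeats import RepeatFeature

    defaults = dict(unit="A", copies=1.0, score=1.0)
    defaults.update(kw)
    return RepeatFeature(klass=klass, span=(s, e), **defaults)


def test_occupancy_empty_is_zero():
    occ = summarize_occupancy([], [], [], None, 10000)
    for klass in ("mono", "tandem", "dispersed"):
        assert occ.per_class[klass] == {"count": 0, "total_bp": 0, "percent_of_genome": 0.0}


def test_occupancy_union_of_overlapping_spans():
    t1 = _mk("tandem", 100, 200)
    t2 = _mk("tandem", 160, 260)  # overlap of 40 -> union 160
    occ = summarize_occupancy([], [t1, t2], [], None, 10000)
    assert occ.per_class["tandem"]["total_bp"] == 160
    assert occ.per_class["tandem"]["percent_of_genome"] == pytest.approx(1.6)


def test_occupancy_dispersed_counts_both_loci_and_reports_one_copy_convention():
    d = _mk("dispersed", 100, 150, span2=(300, 350), orientation="direct")
    occ = summarize_occupancy([], [], [d], None, 1000)
    assert occ.per_class["dispersed"]["total_bp"] == 100
    assert occ.dispersed_one_copy_bp == 50


def test_occupancy_per_region_localization(small_plastome):
    p, truth = small_plastome
    ir = detect_inverted_repeat(p, min_len=10000, max_mismatch_frac=0.0)
    part = partition_quadripartite(p, ir)
    t_lsc = _mk("tandem", 1000, 1300)
    t_ssc = _mk("tandem", truth.region_intervals["SSC"].start + 10, truth.region_intervals["SSC"].start + 110)
    occ = summarize_occupancy([], [t_lsc, t_ssc], [], part, p.length)
    assert occ.per_region["tandem"]["LSC"]["bp"] == 300
    assert occ.per_region["tandem"]["SSC"]["bp"] == 100
    assert occ.per_region["tandem"]["LSC"]["percent_of_class_bp"] == pytest.approx(75.0)


def test_occupancy_monotone_in_mono_threshold(rng):
    seq = "".join(rng.choice(list("AACGT"), size=20000))
    prev = -1.0
    for min_run in (12, 10, 8, 6):
        feats = find_mononucleotide_repeats(seq, min_run=min_run)
        occ = summarize_occupancy(feats, [], [], None, len(seq))
        assert occ.per_class["mono"]["percent_of_genome"] >= prev
        prev = occ.per_class["mono"]["percent_of_genome"]


# ---------------------------------------------------------------------------
# spacer AT content


def _spacer_plastome(spacer):
    genes = [GeneStub("trnT-UGA", "LSC", 100, 60), GeneStub("trnL-UAA", "LSC", 160 + len(spacer), 60)]
    spec = PlastomeSpec(lsc_len=20000, ir_len=6000, ssc_len=4000, seed=9, genes=genes)
    p, _ = generate_plastome(spec)
    seq = list(p.sequence)
    seq[160 : 160 + len(spacer)] = spacer
    p.sequence = "".join(seq)
    return p


def test_spacer_pure_at():
    p = _spacer_plastome("AT" * 50)
    length, at = spacer_at_content(p, "trnT-UGA", "trnL-UAA")
    assert length == 100
    assert at == 1.0


def test_spacer_matches_base_count_oracle(rng):
    spacer = random_dna(rng, 240, at=0.86)
    p = _spacer_plastome(spacer)
    length, at = spacer_at_content(p, "trnT-UGA", "trnL-UAA")
    assert length == 240
    assert at == pytest.approx((spacer.count("A") + spacer.count("T")) / 240)


def test_spacer_not_adjacent_raises():
    genes = [
        GeneStub("gA", "LSC", 100, 60),
        GeneStub("between", "LSC", 300, 60),
        GeneStub("gB", "LSC", 500, 60),
        GeneStub("far", "SSC", 200, 60),  # blocks the long way around the circle
    ]
    spec = PlastomeSpec(lsc_len=5000, ir_len=1500, ssc_len=1200, seed=2, genes=genes)
    p, _ = generate_plastome(spec)
    with pytest.raises(ValueError, match="between"):
        spacer_at_content(p, "gA", "gB")
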