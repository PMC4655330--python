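"""Three-class repeat landscape: mononucleotide, tandem and dispersed repeats.

* Mononucleotide repeats are maximal homopolymer runs above a length
  threshold (default 8 bp), with circular wrap-merging at the origin.
* Tandem repeats are found by a Tandem-Repeats-Finder-style lag scan: for
  every candidate period the sequence is compared with itself at that lag,
  stretches of high match density become candidate arrays, a majority-rule
  consensus unit is built, and arrays are scored with TRF's default alignment
  weights (match +2, mismatch -7) against the repeated consensus. Arrays
  reported at harmonic periods over the same locus are collapsed to the
  highest-scoring one (ties to the smaller period).
* Dispersed repeats are pairs of loci sharing an exact word seed (default
  16 bp), extended along the ungapped diagonal while identity stays above the
  cutoff (default 0.95), in direct or inverted orientation.

The dispersed self-scan normally masks one IR copy (``exclude``): the two IR
copies are themselves a >25 kb inverted "repeat" that would otherwise
dominate every occupancy statistic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import CircularInterval, union_length
from .plastome_io import AnnotatedPlastome, reverse_complement
from .structure import QuadripartitePartition

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatFeature",
    "RepeatOccupancy",
    "TandemParams",
    "find_mononucleotide_repeats",
    "find_tandem_repeats",
    "find_dispersed_repeats",
    "summarize_occupancy",
    "spacer_at_content",
]


@dataclass(frozen=True)
class RepeatFeature:
    """A detected repeat of any class.

    ``span`` is the primary locus; dispersed repeats additionally carry the
    partner locus in ``span2`` and an ``orientation`` (direct / inverted).
    ``copies`` is the homopolymer run length for mono repeats and the (real)
    copy number for tandem arrays.
    """

    klass: str  # mono | tandem | dispersed
    span: tuple[int, int]  # 0-based half-open; end may exceed genome length (wrap)
    unit: str  # mono: base; tandem: consensus unit; dispersed: ""
    copies: float
    score: float
    identity: float = 1.0
    span2: tuple[int, int] | None = None
    orientation: str | None = None  # dispersed only

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def period(self) -> int:
        return len(self.unit)


# ---------------------------------------------------------------------------
# mononucleotide repeats


def find_mononucleotide_repeats(seq: str, min_run: int = 8, circular: bool = True) -> list[RepeatFeature]:
    """Maximal homopolymer runs of length >= ``min_run``.

    N never counts toward a run. With ``circular=True`` a run crossing the
    origin (same base at the end and start of the sequence) is merged into a
    single wrapped feature.
    """
    n = len(seq)
    feats = []
    runs = [(m.start(), m.end(), m.group()[0]) for m in re.finditer(r"A+|C+|G+|T+", seq)]

    head = runs[0] if runs and runs[0][0] == 0 else None
    tail = runs[-1] if runs and runs[-1][1] == n else None
    wrapped = None
    if (
        circular
        and head is not None
        and tail is not None
        and head is not tail
        and head[2] == tail[2]
        and (head[1] - head[0]) + (tail[1] - tail[0]) >= min_run
    ):
        wrapped = RepeatFeature(
            klass="mono",
            span=(tail[0], n + head[1]),
            unit=head[2],
            copies=float((head[1] - head[0]) + (tail[1] - tail[0])),
            score=float((head[1] - head[0]) + (tail[1] - tail[0])),
        )
        runs = [r for r in runs if r is not head and r is not tail]

    for s, e, base in runs:
        if e - s >= min_run:
            feats.append(
                RepeatFeature(klass="mono", span=(s, e), unit=base, copies=float(e - s), score=float(e - s))
            )
    if wrapped is not None:
        feats.append(wrapped)
    feats.sort(key=lambda f: f.span)
    return feats


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass(frozen=True)
class TandemParams:
    """Tandem-array detection parameters (TRF web defaults)."""

    match: int = 2
    mismatch: int = 7
    indel: int = 7  # retained for interface parity; the scan is ungapped
    match_probability: int = 80
    indel_probability: int = 10
    minscore: int = 50
    maxperiod: int = 500
    min_period: int = 1
    max_join_gap: int = 5  # mismatch run length that still joins two match runs


def _lag_candidates(
    codes: np.ndarray, p: int, max_join_gap: int, min_span: int = 0
) -> list[tuple[int, int]]:
    """Candidate array intervals [i, j) (match-region coordinates) at lag ``p``.

    Match runs at lag ``p`` separated by mismatch runs of at most
    ``max_join_gap`` are chained; a chain whose matched extent is at least
    ``p`` (two unit copies) and whose full span could reach the score
    threshold (``min_span``) becomes a candidate. Fully vectorized: the
    run/chain bookkeeping is diff/cumsum arithmetic on the match vector.
    """
    m = (codes[:-p] == codes[p:]).astype(np.int8)
    if not m.any():
        return []
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    gaps = starts[1:] - ends[:-1]
    breaks = np.flatnonzero(gaps > max_join_gap)
    chain_first = np.concatenate(([0], breaks + 1))
    chain_last = np.concatenate((breaks, [starts.size - 1]))
    cs, ce = starts[chain_first], ends[chain_last]
    span = ce - cs
    run_lens = ends - starts
    cum = np.concatenate(([0], np.cumsum(run_lens)))
    matched = cum[chain_last + 1] - cum[chain_first]
    # match-probability filter (TRF's pm criterion, with slack for divergence)
    keep = (span >= p) & (span + p >= min_span) & (matched >= 0.6 * span)
    return [(int(s), int(e)) for s, e in zip(cs[keep], ce[keep])]


def _best_subsegment(m: np.ndarray, wplus: int, wminus: int) -> tuple[int, int]:
    """Maximal-scoring subsegment of a match vector (+wplus / -wminus), Kadane."""
    best_s = best_e = cur_s = 0
    best = cur = 0.0
    for idx, hit in enumerate(m):
        cur += wplus if hit else -wminus
        if cur <= 0:
            cur = 0.0
            cur_s = idx + 1
        elif cur > best:
            best = cur
            best_s, best_e = cur_s, idx + 1
    return best_s, best_e


def _consensus_and_score(seg: np.ndarray, p: int, params: TandemParams) -> tuple[str, float, float]:
    """Majority consensus unit, TRF-weight score, identity for one array."""
    ncol = p
    ncopies = int(np.ceil(seg.size / p))
    padded = np.full(ncopies * p, 255, dtype=np.uint8)
    padded[: seg.size] = seg
    grid = padded.reshape(ncopies, ncol)
    # majority vote per column via one bincount over (column, base) cells
    lut = np.zeros(256, dtype=np.intp)  # base byte -> 0..3; padding -> bin 4
    for bi, b in enumerate(b"ACGT"):
        lut[b] = bi
    lut[255] = 4
    col_idx = np.tile(np.arange(ncol), ncopies)
    counts = np.bincount(col_idx * 5 + lut[padded], minlength=ncol * 5).reshape(ncol, 5)
    consensus_base = counts[:, :4].argmax(axis=1)
    consensus = np.frombuffer(b"ACGT", dtype=np.uint8)[consensus_base]
    matches = int((grid == consensus[None, :]).sum())
    total = seg.size
    mismatches = total - matches
    score = params.match * matches - params.mismatch * mismatches
    unit = consensus.tobytes().decode()
    return unit, float(score), matches / total


def find_tandem_repeats(seq: str, params: TandemParams | None = None) -> list[RepeatFeature]:
    """Detect tandem arrays with period up to ``params.maxperiod``.

    Returns arrays with alignment score >= ``params.minscore`` after harmonic
    collapse. The scan is substitution-aware but ungapped; see the methods
    note for the consequences.
    """
    params = params or TandemParams()
    n = len(seq)
    if n < 2 * params.min_period:
        return []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes[codes == ord("N")] = 0  # N matches nothing (0 is not a base code)

    raw: list[RepeatFeature] = []
    min_span = -(-params.minscore // params.match)
    for p in range(params.min_period, min(params.maxperiod, n // 2) + 1):
        for i, j in _lag_candidates(codes, p, params.max_join_gap, min_span):
            # trim the chain to its best-scoring stretch at this lag
            m = codes[i:j] == codes[i + p : j + p]
            s_rel, e_rel = _best_subsegment(m, params.match, params.mismatch)
            if e_rel - s_rel < p:
                continue
            start, end = i + s_rel, i + e_rel + p  # matched region plus one unit
            seg = codes[start:end]
            unit, score, identity = _consensus_and_score(seg, p, params)
            copies = (end - start) / p
            if score >= params.minscore and copies >= 2:
                raw.append(
                    RepeatFeature(
                        klass="tandem",
                        span=(int(start), int(end)),
                        unit=unit,
                        copies=round(copies, 2),
                        score=score,
                        identity=round(identity, 4),
                    )
                )
    return _collapse_harmonics(raw)


def _collapse_harmonics(feats: list[RepeatFeature], tie_band: float = 0.05) -> list[RepeatFeature]:
    """Collapse overlapping reports of one locus to the best-scoring period.

    Overlap of more than half the shorter span counts as "same locus"; the
    higher score wins, with scores within ``tie_band`` treated as tied —
    ties go to the smaller period. The tie band absorbs the consensus
    overfit of few-copy harmonics (a 2-copy consensus trivially matches half
    the divergence of the fundamental, inflating its score by a few
    mismatch-weights).
    """
    feats = sorted(feats, key=lambda f: (-f.score, f.period, f.span))
    kept: list[RepeatFeature] = []
    for f in feats:
        replaced = False
        redundant = False
        for i, g in enumerate(kept):
            ov = min(f.span[1], g.span[1]) - max(f.span[0], g.span[0])
            if ov > 0 and ov >= 0.5 * min(f.length, g.length):
                harmonic = (
                    f.period < g.period
                    and min(g.period % f.period, f.period - g.period % f.period) <= 1
                )
                if f.period < g.period and (
                    f.score >= (1.0 - tie_band) * g.score
                    or (harmonic and f.score >= 0.7 * g.score)
                ):
                    kept[i] = f  # fundamental period wins the locus
                    replaced = True
                else:
                    redundant = True
                break
        if not redundant and not replaced:
            kept.append(f)
    kept.sort(key=lambda f: f.span)
    return kept


# ---------------------------------------------------------------------------
# dispersed repeats


def _extend_segment(m: np.ndarray, u: int, v: int, min_identity: float) -> tuple[int, int]:
    """Extend exact run ``[u, v)`` of the match vector ``m`` in both directions.

    A mismatch run followed by a match is absorbed iff the running identity
    from the current start stays >= ``min_identity``; segments always begin
    and end on a match.
    """
    n = m.size
    matches = v - u
    start, end = u, v
    # right
    while True:
        g = 0
        while end + g < n and not m[end + g]:
            g += 1
        if end + g >= n:
            break
        if (matches + 1) / (end - start + g + 1) < min_identity:
            break
        matches += 1
        end = end + g + 1
    # left
    while True:
        g = 0
        while start - 1 - g >= 0 and not m[start - 1 - g]:
            g += 1
        if start - 1 - g < 0:
            break
        if (matches + 1) / (end - (start - 1 - g)) < min_identity:
            break
        matches += 1
        start = start - 1 - g
    return start, end


def _segments_on_diagonal(m: np.ndarray, word: int, min_identity: float) -> list[tuple[int, int]]:
    """All maximal reported segments of one diagonal's match vector.

    Seeds are exact match runs >= ``word``; each is extended, overlapping
    extents keep the longest, and only segments strictly longer than ``word``
    are reported.
    """
    if m.size <= word:
        return []
    mm = np.flatnonzero(~m)
    boundaries = np.concatenate(([-1], mm, [m.size]))
    seeds = [
        (boundaries[i] + 1, boundaries[i + 1])
        for i in range(boundaries.size - 1)
        if boundaries[i + 1] - (boundaries[i] + 1) >= word
    ]
    segs: list[tuple[int, int]] = []
    for u, v in seeds:
        s, e = _extend_segment(m, u, v, min_identity)
        if e - s > word:
            segs.append((s, e))
    # drop contained duplicates, keep longest per overlapping family
    segs = sorted(set(segs), key=lambda se: (se[0], -(se[1] - se[0])))
    kept: list[tuple[int, int]] = []
    for s, e in segs:
        if kept and s >= kept[-1][0] and e <= kept[-1][1]:
            continue
        kept.append((s, e))
    return kept


def find_dispersed_repeats(
    seq: str,
    word: int = 16,
    min_identity: float = 0.95,
    exclude: list[CircularInterval] | None = None,
) -> list[RepeatFeature]:
    """Self-scan for dispersed repeat pairs (> ``word`` bp, direct + inverted).

    ``exclude`` masks intervals (typically one IR copy) before scanning.
    Symmetric duplicates and the trivial self-diagonal are suppressed.
    """
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if exclude:
        for iv in exclude:
            for s, e in iv.linear_pieces():
                codes[s:e] = 0
    codes[codes == ord("N")] = 0

    masked = codes.tobytes().decode("latin1")
    feats: list[RepeatFeature] = []

    # --- direct orientation: diagonals d = j - i > 0 with a shared word
    index: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        w = masked[i : i + word]
        if "\x00" in w:
            continue
        index.setdefault(w, []).append(i)
    direct_diags: set[int] = set()
    for positions in index.values():
        if len(positions) > 1:
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    direct_diags.add(positions[b] - positions[a])
    for d in sorted(direct_diags):
        m = (codes[: n - d] == codes[d:]) & (codes[: n - d] != 0)
        for s, e in _segments_on_diagonal(m, word, min_identity):
            ident = float(m[s:e].mean())
            feats.append(
                RepeatFeature(
                    klass="dispersed",
                    span=(int(s), int(e)),
                    unit="",
                    copies=2.0,
                    score=float(e - s),
                    identity=round(ident, 4),
                    span2=(int(s + d), int(e + d)),
                    orientation="direct",
                )
            )

    # --- inverted orientation: compare against the reverse complement
    rc = reverse_complement(masked.replace("\x00", "N"))
    rcodes = np.frombuffer(rc.encode(), dtype=np.uint8).copy()
    rcodes[rcodes == ord("N")] = 0
    rindex: dict[str, list[int]] = {}
    rmasked = rcodes.tobytes().decode("latin1")
    for j in range(n - word + 1):
        w = rmasked[j : j + word]
        if "\x00" in w:
            continue
        rindex.setdefault(w, []).append(j)
    inv_diags: set[int] = set()
    for w, positions in index.items():
        for j in rindex.get(w, ()):
            for i in positions:
                inv_diags.add(j - i)  # offset in the (seq, rc) linear comparison
    seen_pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for d in sorted(inv_diags):
        if d >= 0:
            a_lo, length = 0, n - d
        else:
            a_lo, length = -d, n + d
        m = (codes[a_lo : a_lo + length] == rcodes[a_lo + d : a_lo + d + length]) & (
            codes[a_lo : a_lo + length] != 0
        )
        for s, e in _segments_on_diagonal(m, word, min_identity):
            a_s, a_e = int(a_lo + s), int(a_lo + e)
            # rc interval [a_s + d, a_e + d) maps back to forward coordinates
            b_s, b_e = int(n - (a_e + d)), int(n - (a_s + d))
            first, second = sorted([(a_s, a_e), (b_s, b_e)])
            if first == second or first[1] > second[0]:
                continue  # palindromic self-overlap
            key = (first, second)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            ident = float(m[s:e].mean())
            feats.append(
                RepeatFeature(
                    klass="dispersed",
                    span=first,
                    unit="",
                    copies=2.0,
                    score=float(first[1] - first[0]),
                    identity=round(ident, 4),
                    span2=second,
                    orientation="inverted",
                )
            )
    feats.sort(key=lambda f: (f.span, f.span2 or (0, 0)))
    return feats


# ---------------------------------------------------------------------------
# occupancy summaries


@dataclass
class RepeatOccupancy:
    """Per-class and per-region repeat occupancy of one genome."""

    genome_length: int
    per_class: dict = field(default_factory=dict)
    per_region: dict = field(default_factory=dict)
    #: dispersed occupancy counting only one copy of each pair (alternative
    #: convention; the primary numbers count both copies)
    dispersed_one_copy_bp: int = 0

    def percent(self, klass: str) -> float:
        return self.per_class[klass]["percent_of_genome"]


def _spans_to_intervals(spans: list[tuple[int, int]], n: int) -> list[CircularInterval]:
    return [CircularInterval(s % n, e - s, n) for s, e in spans if e > s]


def summarize_occupancy(
    mono: list[RepeatFeature],
    tandem: list[RepeatFeature],
    dispersed: list[RepeatFeature],
    part: QuadripartitePartition | None,
    genome_length: int,
) -> RepeatOccupancy:
    """Union-based occupancy per class, localized per region.

    Mono and tandem repeats are assigned to the region containing their start
    position; each dispersed pair contributes both loci, each assigned to its
    own region. ``part`` may be ``None`` for genomes without an IR (no
    per-region breakdown is then produced).
    """
    n = genome_length
    occ = RepeatOccupancy(genome_length=n)
    class_spans = {
        "mono": [f.span for f in mono],
        "tandem": [f.span for f in tandem],
        "dispersed": [f.span for f in dispersed] + [f.span2 for f in dispersed if f.span2],
    }
    for klass, spans in class_spans.items():
        ivs = _spans_to_intervals(spans, n)
        bp = union_length(ivs)
        occ.per_class[klass] = {
            "count": int(len(spans) if klass != "dispersed" else len(class_spans[klass]) // 2),
            "total_bp": int(bp),
            "percent_of_genome": 100.0 * bp / n,
        }
    occ.dispersed_one_copy_bp = union_length(_spans_to_intervals([f.span for f in dispersed], n))

    if part is not None:
        region_of = part.region_of
        for klass, feats_spans in class_spans.items():
            by_region: dict[str, list[tuple[int, int]]] = {r: [] for r in ("LSC", "IRa", "SSC", "IRb")}
            counts = {r: 0 for r in by_region}
            for s, e in feats_spans:
                r = region_of(s % n)
                by_region[r].append((s, e))
                counts[r] += 1
            total = occ.per_class[klass]["total_bp"] or 1
            occ.per_region[klass] = {
                r: {
                    "count": int(counts[r]),
                    "bp": int(union_length(_spans_to_intervals(by_region[r], n))),
                    "percent_of_class_bp": 100.0
                    * union_length(_spans_to_intervals(by_region[r], n))
                    / total,
                }
                for r in by_region
            }
    return occ


def spacer_at_content(p: AnnotatedPlastome, geneA: str, geneB: str) -> tuple[int, float]:
    """Length and AT fraction of the intergenic spacer between adjacent genes.

    The spacer is the arc between the two genes that contains no other
    annotated gene; if both arcs contain genes an error lists the intervening
    features.
    """
    fa = p.feature_by_name(geneA)
    fb = p.feature_by_name(geneB)
    n = p.length
    others = [f for f in p.features if f.name not in (geneA, geneB)]
    for first, second in ((fa, fb), (fb, fa)):
        start = first.interval.end_unwrapped % n
        length = (second.interval.start - start) % n
        if length == 0:
            return 0, 0.0
        arc = CircularInterval(start, length, n)
        intervening = [f.name for f in others if arc.contains(f.interval.midpoint)]
        if not intervening:
            sub = "".join(p.sequence[s:e] for s, e in arc.linear_pieces())
            at = (sub.count("A") + sub.count("T")) / len(sub)
            return length, at
    blockers = sorted(
        {f.name for f in others if CircularInterval.from_coords(fa.interval.end_unwrapped % n, fb.interval.start, n).contains(f.interval.midpoint)}
    )
    raise ValueError(f"{geneA} and {geneB} are not adjacent; intervening: {blockers}")
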