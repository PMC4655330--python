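"""Quadripartite structure: inverted-repeat detection and boundary comparison.

The large inverted repeat (IR) of a typical plastome is a pair of 20-40 kb
near-identical segments in opposite orientation that separate the large and
small single-copy regions (LSC, SSC). Detection is exact and sequence-level:
all 31-mers of the forward strand are indexed, matches against the reverse
complement are grouped by anti-diagonal (an ungapped inverted match keeps
``startA + endB`` constant), and the best candidate is extended base-by-base
under a mismatch budget until no extension keeps identity above the
threshold.

The IR pair is assumed not to span the sequence origin: published plastome
records conventionally open inside the LSC. Rotate the sequence first if this
does not hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import CircularInterval
from .plastome_io import AnnotatedPlastome, extract_subsequence, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "IRPair",
    "QuadripartitePartition",
    "BoundaryShiftReport",
    "detect_inverted_repeat",
    "partition_quadripartite",
    "classify_gene_regions",
    "GeneRegionClassification",
    "compare_boundaries",
    "gc_fraction",
]

REGIONS = ("LSC", "IRa", "SSC", "IRb")


@dataclass(frozen=True)
class IRPair:
    """A detected inverted-repeat pair; ``copyA`` precedes ``copyB``."""

    copyA: CircularInterval
    copyB: CircularInterval
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRa/SSC/IRb intervals tiling the genome, with per-region GC."""

    lsc: CircularInterval
    ira: CircularInterval
    ssc: CircularInterval
    irb: CircularInterval
    gc: dict = field(default_factory=dict)  # region name (+ 'genome') -> GC fraction

    @property
    def lengths(self) -> dict:
        return {
            "LSC": self.lsc.length,
            "IRa": self.ira.length,
            "SSC": self.ssc.length,
            "IRb": self.irb.length,
        }

    def region_interval(self, name: str) -> CircularInterval:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}[name]

    def region_of(self, pos: int) -> str:
        for name in REGIONS:
            if self.region_interval(name).contains(pos):
                return name
        raise ValueError(f"position {pos} not covered")  # pragma: no cover


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; N residues are excluded from the denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def _seed_hits_by_diagonal(seq: str, k: int) -> dict[int, list[int]]:
    """Map anti-diagonal (a + b) -> forward positions a of inverted k-mer hits.

    A hit at forward position ``a`` and partner position ``b`` means
    ``seq[a:a+k] == revcomp(seq[b:b+k])``; along an ungapped inverted repeat
    the quantity ``a + b`` is constant.
    """
    n = len(seq)
    index: dict[str, list[int]] = {}
    for a in range(n - k + 1):
        kmer = seq[a : a + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(a)
    rc = reverse_complement(seq)
    diagonals: dict[int, list[int]] = {}
    for j in range(n - k + 1):
        kmer = rc[j : j + k]
        hits = index.get(kmer)
        if not hits:
            continue
        b = n - j - k  # partner start on the forward strand
        for a in hits:
            if a >= b:  # keep one orientation; (a, b) and (b, a) are the same pair
                continue
            diagonals.setdefault(a + b, []).append(a)
    return diagonals


def _extend_inverted(seq: str, a0: int, a1: int, diag: int, max_mismatch_frac: float) -> tuple[int, int, int]:
    """Extend the exact match block ``[a0, a1)`` on anti-diagonal ``diag``.

    Partner of forward position ``a`` is ``diag + k_adjust - a`` handled by the
    caller's convention: position ``a`` matches position ``diag - a + (k-1)``…
    here we use base-level pairing: forward base at ``a`` pairs with the
    complement of the base at ``diag - a`` where ``diag = a + b`` for k-mer
    starts, i.e. base-level partner of ``a`` is ``diag + (k - 1) - a``.
    Returns ``(start, end, mismatches)`` for the A copy at base level.
    """
    # Work at base level: pair(a) = diag_base - a, with diag_base = a_start + b_end - 1.
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "X"}

    def match(a: int, partner: int) -> bool:
        if partner <= a or partner >= n or a < 0:
            return False
        return comp[seq[a]] == seq[partner]

    start, end = a0, a1  # [start, end) all matching by construction
    mismatches = 0

    def identity_ok(extra_len: int, extra_mm: int) -> bool:
        ln = (end - start) + extra_len
        return (mismatches + extra_mm) <= max_mismatch_frac * ln

    # Extend right (A copy grows right, partner shrinks from the left).
    while True:
        a = end
        partner = diag - a
        run_mm = 0
        # absorb mismatches while a later match keeps identity within budget
        while not match(a + run_mm, diag - (a + run_mm)):
            run_mm += 1
            if run_mm > 50 or a + run_mm >= partner - run_mm:
                run_mm = -1
                break
        if run_mm < 0 or a + run_mm >= diag - (a + run_mm):
            break
        if not identity_ok(run_mm + 1, run_mm):
            break
        end = a + run_mm + 1
        mismatches += run_mm
    # Extend left.
    while True:
        a = start - 1
        run_mm = 0
        while not match(a - run_mm, diag - (a - run_mm)):
            run_mm += 1
            if run_mm > 50 or a - run_mm < 0:
                run_mm = -1
                break
        if run_mm < 0 or a - run_mm < 0 or (a - run_mm) >= diag - (a - run_mm):
            break
        if not identity_ok(run_mm + 1, run_mm):
            break
        start = a - run_mm
        mismatches += run_mm
    return start, end, mismatches


def detect_inverted_repeat(
    p: AnnotatedPlastome,
    min_len: int = 10000,
    max_mismatch_frac: float = 0.001,
    k: int = 31,
) -> IRPair | None:
    """Find the maximal disjoint inverted-repeat pair, or ``None``.

    Returns the longest pair of disjoint segments whose sequences are reverse
    complements of each other within the mismatch budget; ties are broken by
    smallest start coordinate (with a structural-ambiguity warning).
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000")
    if p.length <= 2 * min_len:
        return None
    seq = p.sequence
    diagonals = _seed_hits_by_diagonal(seq, k)

    candidates: list[tuple[int, int, int, int, int]] = []  # (length, startA, endA, mismatches, diag)
    for diag_kmer, positions in diagonals.items():
        positions.sort()
        # merge seed starts into exact blocks, then extend the longest block
        blocks: list[tuple[int, int]] = []
        bs = be = positions[0]
        for a in positions[1:]:
            if a <= be + 1:
                be = a
            else:
                blocks.append((bs, be + k))
                bs = be = a
        blocks.append((bs, be + k))
        diag_base = diag_kmer + k - 1  # base-level anti-diagonal
        best_block = max(blocks, key=lambda blk: blk[1] - blk[0])
        start, end, mm = _extend_inverted(seq, best_block[0], best_block[1], diag_base, max_mismatch_frac)
        length = end - start
        b_start, b_end = diag_base - (end - 1), diag_base - start + 1
        if length >= min_len and b_start >= end:  # disjoint copies
            candidates.append((length, start, end, mm, diag_base))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0] and candidates[0][1] != candidates[1][1]:
        logger.warning("%s: multiple maximal inverted-repeat candidates; reporting smallest start", p.id)
    length, start, end, mm, diag_base = candidates[0]
    b_start, b_end = diag_base - (end - 1), diag_base - start + 1
    n = p.length
    return IRPair(
        copyA=CircularInterval(start, length, n),
        copyB=CircularInterval(b_start, b_end - b_start, n),
        length=length,
        mismatches=mm,
    )


def partition_quadripartite(p: AnnotatedPlastome, ir: IRPair) -> QuadripartitePartition:
    """Partition the circle into LSC / IRa / SSC / IRb given a detected IR.

    The two arcs between the IR copies become the single-copy regions; the
    longer is the LSC. ``IRa`` denotes the IR copy immediately following the
    LSC in forward orientation.
    """
    n = p.length
    arc1 = CircularInterval.from_coords(ir.copyA.end_unwrapped % n, ir.copyB.start, n) \
        if (ir.copyB.start - ir.copyA.end_unwrapped) % n != 0 else None
    arc2 = CircularInterval.from_coords(ir.copyB.end_unwrapped % n, ir.copyA.start, n) \
        if (ir.copyA.start - ir.copyB.end_unwrapped) % n != 0 else None
    if arc1 is None or arc2 is None:
        raise ValueError("IR copies are adjacent; no single-copy regions")
    if arc1.length > arc2.length:
        lsc, ssc = arc1, arc2
    elif arc2.length > arc1.length:
        lsc, ssc = arc2, arc1
    else:
        # equal arcs: prefer the arc containing rbcL, else lower start
        rbcl = next((f for f in p.features if f.name == "rbcL"), None)
        if rbcl is not None and arc1.contains(rbcl.interval.midpoint):
            lsc, ssc = arc1, arc2
        elif rbcl is not None and arc2.contains(rbcl.interval.midpoint):
            lsc, ssc = arc2, arc1
        else:
            lsc, ssc = (arc1, arc2) if arc1.start < arc2.start else (arc2, arc1)
        logger.warning("%s: equal-length single-copy arcs; LSC chosen by rule", p.id)
    ira = ir.copyA if ir.copyA.start == lsc.end_unwrapped % n else ir.copyB
    irb = ir.copyB if ira is ir.copyA else ir.copyA

    gc = {}
    for name, iv in (("LSC", lsc), ("IRa", ira), ("SSC", ssc), ("IRb", irb)):
        gc[name] = gc_fraction(extract_subsequence(p, iv))
    gc["genome"] = gc_fraction(p.sequence)
    part = QuadripartitePartition(lsc=lsc, ira=ira, ssc=ssc, irb=irb, gc=gc)
    total = sum(part.lengths.values())
    if total != n:  # pragma: no cover - tiling invariant
        raise AssertionError(f"partition does not tile genome: {total} != {n}")
    return part


@dataclass
class GeneRegionClassification:
    """Midpoint region per gene, plus junction-straddling (boundary) genes."""

    regions: dict  # gene name -> region of its midpoint
    boundary_genes: dict  # gene name -> sorted list of regions it overlaps


def classify_gene_regions(part: QuadripartitePartition, p: AnnotatedPlastome) -> GeneRegionClassification:
    """Assign each gene the region containing its midpoint.

    Genes overlapping a junction are additionally flagged with every region
    they touch.
    """
    regions: dict[str, str] = {}
    boundary: dict[str, list[str]] = {}
    for f in p.features:
        mid_region = part.region_of(f.interval.midpoint)
        regions[f.name] = mid_region
        touched = sorted(
            {
                name
                for name in REGIONS
                if part.region_interval(name).overlaps(f.interval)
            }
        )
        if len(touched) > 1:
            boundary[f.name] = touched
    return GeneRegionClassification(regions=regions, boundary_genes=boundary)


@dataclass
class BoundaryShiftReport:
    """Region diff of two annotated, partitioned plastomes."""

    genome_a: str
    genome_b: str
    regions_a: dict
    regions_b: dict
    genes_relocated: list  # (gene, region in A, region in B)
    unshared_a: list  # genes only in A
    unshared_b: list
    junction_context: dict  # (genome id, junction) -> context dict


def _junction_contexts(part: QuadripartitePartition, p: AnnotatedPlastome) -> dict:
    """Gene context of the four region junctions of one genome.

    For each junction point: the gene containing it (if any) and the nearest
    gene on either side along the circle.
    """
    n = p.length
    contexts = {}
    junctions = {
        "LSC/IRa": part.ira.start,
        "IRa/SSC": part.ssc.start,
        "SSC/IRb": part.irb.start,
        "IRb/LSC": part.lsc.start,
    }
    for jname, pos in junctions.items():
        straddling = [f.name for f in p.features if f.interval.contains(pos - 1) and f.interval.contains(pos % n)]
        upstream = min(
            (f for f in p.features if not f.interval.contains(pos % n)),
            key=lambda f: (pos - f.interval.end_unwrapped) % n,
            default=None,
        )
        downstream = min(
            (f for f in p.features if not f.interval.contains(pos - 1)),
            key=lambda f: (f.interval.start - pos) % n,
            default=None,
        )
        contexts[jname] = {
            "position": pos,
            "straddling": straddling,
            "upstream": upstream.name if upstream else None,
            "downstream": downstream.name if downstream else None,
        }
    return contexts


def compare_boundaries(
    a: tuple[QuadripartitePartition, AnnotatedPlastome],
    b: tuple[QuadripartitePartition, AnnotatedPlastome],
) -> BoundaryShiftReport:
    """Diff gene-region assignments between two genomes (IR expansion/shifts).

    IR copies are collapsed to a single "IR" label so that a gene moving from
    SSC into the (duplicated) IR is reported once regardless of copy.
    """
    part_a, pa = a
    part_b, pb = b
    cls_a = classify_gene_regions(part_a, pa)
    cls_b = classify_gene_regions(part_b, pb)

    def collapse(r: str) -> str:
        return "IR" if r in ("IRa", "IRb") else r

    ra = {g: collapse(r) for g, r in cls_a.regions.items()}
    rb = {g: collapse(r) for g, r in cls_b.regions.items()}
    shared = sorted(set(ra) & set(rb))
    relocated = [(g, ra[g], rb[g]) for g in shared if ra[g] != rb[g]]
    report = BoundaryShiftReport(
        genome_a=pa.id,
        genome_b=pb.id,
        regions_a=ra,
        regions_b=rb,
        genes_relocated=relocated,
        unshared_a=sorted(set(ra) - set(rb)),
        unshared_b=sorted(set(rb) - set(ra)),
        junction_context={
            pa.id: _junction_contexts(part_a, pa),
            pb.id: _junction_contexts(part_b, pb),
        },
    )
    return report
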