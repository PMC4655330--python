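"""Reading, writing and slicing annotated plastome records.

GenBank flat files are parsed with Biopython; gene/tRNA/rRNA features are
mapped onto :class:`GeneFeature` objects with 0-based half-open coordinates
(GenBank's 1-based inclusive locations are converted on read). Sequences are
normalized to the ACGTN alphabet: IUPAC ambiguity codes other than N are
mapped to N with a logged warning, since every downstream scan and likelihood
defines its behaviour only over ACGTN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .intervals import CircularInterval

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "AnnotatedPlastome",
    "load_plastome",
    "write_plastome",
    "extract_subsequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

#: GenBank feature type -> GeneFeature.kind
_KIND_BY_TYPE = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A gene annotation on the circular plastome.

    ``interval`` covers the full extent of the gene (exons plus introns);
    ``introns`` lists intron sub-intervals where annotated.
    """

    name: str
    kind: str  # protein | tRNA | rRNA
    strand: int  # +1 / -1
    interval: CircularInterval
    introns: list[CircularInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be nonempty")
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")


@dataclass
class AnnotatedPlastome:
    """A circular plastid genome: accession, ACGTN sequence, gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"sequence contains non-ACGTN residues: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID
    if bad:
        logger.warning(
            "%s: %d non-ACGTN residues (%s) mapped to N",
            record_id,
            sum(seq.count(b) for b in bad),
            "".join(sorted(bad)),
        )
        seq = seq.translate(str.maketrans({b: "N" for b in bad}))
    return seq


def _location_to_interval(loc, genome_length: int) -> tuple[CircularInterval, list[CircularInterval]]:
    """Convert a Biopython location to (full interval, introns).

    A CompoundLocation whose parts run up to the sequence end and resume at 0
    is treated as a single origin-wrapping feature; other part gaps are
    introns.
    """
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    # Detect origin wrap: last part ends at genome end, first begins at 0.
    raw = [(int(p.start), int(p.end)) for p in parts]
    if len(raw) >= 2 and raw[-1][1] == genome_length and raw[0][0] == 0:
        # unwrap: shift the leading parts past the genome end
        raw = [(s, e) for s, e in raw[1:]] + [(raw[0][0] + genome_length, raw[0][1] + genome_length)]
        raw.sort()
    start, end = raw[0][0], raw[-1][1]
    interval = CircularInterval(start % genome_length, end - start, genome_length)
    introns = []
    for (s1, e1), (s2, e2) in zip(raw, raw[1:]):
        if s2 > e1:
            introns.append(CircularInterval(e1 % genome_length, s2 - e1, genome_length))
    return interval, introns


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def load_plastome(path: str | Path, format: str = "genbank") -> AnnotatedPlastome:
    """Load a plastome from a GenBank or FASTA file.

    FASTA input yields an empty feature list. Exactly one record per file is
    expected; multi-record files raise a parse error naming the file.
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    record = records[0]
    seq = _normalize_sequence(str(record.seq), record.id)
    plastome = AnnotatedPlastome(id=record.id, sequence=seq)
    if format == "fasta":
        return plastome

    genome_length = len(seq)
    seen: set[tuple[str, int]] = set()
    for feat in record.features:
        kind = _KIND_BY_TYPE.get(feat.type)
        if kind is None:
            continue
        name = _feature_name(feat)
        if name is None:
            logger.warning("%s: unnamed %s feature skipped", record.id, feat.type)
            continue
        interval, introns = _location_to_interval(feat.location, genome_length)
        key = (name, interval.start)
        if key in seen:
            continue
        seen.add(key)
        strand = -1 if feat.location.strand == -1 else 1
        plastome.features.append(
            GeneFeature(name=name, kind=kind, strand=strand, interval=interval, introns=introns)
        )
    return plastome


def _interval_to_location(iv: CircularInterval, strand: int) -> SimpleLocation | CompoundLocation:
    if not iv.wraps:
        return SimpleLocation(iv.start, iv.start + iv.length, strand=strand)
    pieces = iv.linear_pieces()
    locs = [SimpleLocation(s, e, strand=strand) for s, e in pieces]
    return CompoundLocation(locs)


def write_plastome(p: AnnotatedPlastome, path: str | Path, format: str = "genbank") -> None:
    """Write a plastome to GenBank (with features) or FASTA (sequence only)."""
    record = SeqRecord(Seq(p.sequence), id=p.id, name=p.id[:16].replace(".", "_"), description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    if format == "genbank":
        for f in p.features:
            ftype = {v: k for k, v in _KIND_BY_TYPE.items()}[f.kind]
            loc = _interval_to_location(f.interval, f.strand)
            record.features.append(SeqFeature(loc, type="gene", qualifiers={"gene": [f.name]}))
            record.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]}))
    SeqIO.write([record], str(path), format)


def extract_subsequence(p: AnnotatedPlastome, interval: CircularInterval | None, strand: int = 1) -> str:
    """Residues of ``interval``; reverse-complemented when ``strand == -1``.

    Wrapping intervals concatenate tail + head. ``interval=None`` (the
    degenerate zero-length case) returns the empty string.
    """
    if interval is None:
        return ""
    if interval.genome_length != p.length:
        raise ValueError("interval genome_length does not match plastome")
    out = "".join(p.sequence[s:e] for s, e in interval.linear_pieces())
    return reverse_complement(out) if strand == -1 else out
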