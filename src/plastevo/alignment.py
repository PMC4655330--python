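"""Gapped multiple-alignment container with FASTA/PHYLIP I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "read_alignment", "write_alignment"]


@dataclass
class Alignment:
    """An ordered set of equal-length gapped rows over {A,C,G,T,N,-}."""

    taxa: list[str]
    rows: list[str]
    gene: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset_columns(self, cols: list[int]) -> "Alignment":
        return Alignment(
            taxa=list(self.taxa),
            rows=["".join(r[c] for c in cols) for r in self.rows],
            gene=self.gene,
        )


def read_alignment(path: str | Path, format: str = "fasta", gene: str = "") -> Alignment:
    """Read a FASTA or (relaxed) PHYLIP alignment."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[format]
    aln = AlignIO.read(str(path), fmt)
    return Alignment(
        taxa=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        gene=gene or Path(path).stem,
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    records = [SeqRecord(Seq(row), id=taxon, description="") for taxon, row in zip(aln.taxa, aln.rows)]
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[format]
    SeqIO.write(records, str(path), fmt)
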