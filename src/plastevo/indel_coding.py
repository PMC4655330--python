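"""Simple indel coding of gapped alignments into binary character matrices.

Each distinct *internal* gap extent (start, end) observed in at least one
taxon becomes one binary character. A taxon scores 1 if it carries exactly
that gap extent as a maximal gap run, 0 if it has residues across the whole
extent, and missing ('?') if it has a different, overlapping gap (including
terminal gap runs, which are treated as missing data throughout).

Constant characters (the same gap in every taxon) are retained and flagged;
per-gene matrices can be concatenated into a supermatrix with a partition
table, filling missing taxa with '?'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import Alignment, read_alignment, write_alignment  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "IndelCharacterMatrix",
    "simple_indel_coding",
    "concatenate_matrices",
    "concatenate_alignments",
    "write_binary_phylip",
    "write_binary_nexus",
]

MISSING = "?"


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters; states per taxon are '0', '1' or '?'."""

    taxa: list[str]
    characters: list[tuple]  # (gene, gap_start_col, gap_end_col)
    states: list[str]  # one string of len(characters) per taxon
    constant_characters: list[int] = field(default_factory=list)  # indices, flagged

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, idx: int) -> str:
        return "".join(row[idx] for row in self.states)


def _gap_runs(row: str) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Maximal gap runs of one row, split into internal runs and the terminal mask.

    Returns ``(internal_runs, (lead_end, tail_start))`` where columns
    ``< lead_end`` or ``>= tail_start`` are terminal gaps (missing data).
    """
    n = len(row)
    lead = 0
    while lead < n and row[lead] == "-":
        lead += 1
    tail = n
    while tail > lead and row[tail - 1] == "-":
        tail -= 1
    runs = []
    i = lead
    while i < tail:
        if row[i] == "-":
            j = i
            while j < tail and row[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs, (lead, tail)


def simple_indel_coding(aln: Alignment) -> IndelCharacterMatrix:
    """Code one gapped alignment into binary indel characters.

    Terminal gap runs never define characters and score missing for every
    character they overlap.
    """
    per_taxon_runs = []
    per_taxon_core = []
    for row in aln.rows:
        runs, core = _gap_runs(row)
        per_taxon_runs.append(set(runs))
        per_taxon_core.append(core)

    extents = sorted({run for runs in per_taxon_runs for run in runs})
    characters = [(aln.gene, s, e) for s, e in extents]

    states_rows = []
    for t, row in enumerate(aln.rows):
        runs = per_taxon_runs[t]
        lead, tail = per_taxon_core[t]
        symbols = []
        for s, e in extents:
            if (s, e) in runs:
                symbols.append("1")
            elif s < lead or e > tail:
                symbols.append(MISSING)  # extent reaches into this taxon's terminal gap
            elif any(rs < e and s < re for rs, re in runs):
                symbols.append(MISSING)  # different overlapping gap
            else:
                symbols.append("0")
        states_rows.append("".join(symbols))

    matrix = IndelCharacterMatrix(taxa=list(aln.taxa), characters=characters, states=states_rows)
    for idx in range(matrix.n_characters):
        col = matrix.column(idx)
        if "0" not in col and "?" not in col:
            matrix.constant_characters.append(idx)
    if matrix.constant_characters:
        logger.warning(
            "%s: %d constant indel character(s) (identical gap in all taxa) retained",
            aln.gene or "<alignment>",
            len(matrix.constant_characters),
        )
    return matrix


def concatenate_matrices(
    matrices: list[IndelCharacterMatrix], taxa_union: list[str] | None = None
) -> tuple[IndelCharacterMatrix, list[tuple[str, int, int]]]:
    """Concatenate per-gene indel matrices; absent taxa are filled with '?'.

    Returns the combined matrix and a partition table of
    ``(gene, first_col, last_col_exclusive)`` entries in input order.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    if taxa_union is None:
        taxa_union = sorted({t for m in matrices for t in m.taxa})
    rows = {t: [] for t in taxa_union}
    characters: list[tuple] = []
    constant: list[int] = []
    partition = []
    col = 0
    for m in matrices:
        if len(set(m.taxa)) != len(m.taxa):
            raise ValueError("duplicate taxon within one input matrix")
        gene = m.characters[0][0] if m.characters else ""
        idx_of = {t: i for i, t in enumerate(m.taxa)}
        for t in taxa_union:
            if t in idx_of:
                rows[t].append(m.states[idx_of[t]])
            else:
                rows[t].append(MISSING * m.n_characters)
        characters.extend(m.characters)
        constant.extend(col + c for c in m.constant_characters)
        partition.append((gene, col, col + m.n_characters))
        col += m.n_characters
    combined = IndelCharacterMatrix(
        taxa=list(taxa_union),
        characters=characters,
        states=["".join(rows[t]) for t in taxa_union],
        constant_characters=constant,
    )
    return combined, partition


def concatenate_alignments(
    alignments: list[Alignment], taxa_union: list[str] | None = None
) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate gene alignments column-wise; absent taxa are gap-filled with N.

    Missing taxa receive 'N' (missing data for likelihood models) rather than
    '-' so that fill blocks never create spurious indel characters.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    if taxa_union is None:
        taxa_union = sorted({t for a in alignments for t in a.taxa})
    rows = {t: [] for t in taxa_union}
    partition = []
    col = 0
    for a in alignments:
        for t in taxa_union:
            rows[t].append(a.row(t) if t in a.taxa else "N" * a.n_cols)
        partition.append((a.gene, col, col + a.n_cols))
        col += a.n_cols
    combined = Alignment(taxa=list(taxa_union), rows=["".join(rows[t]) for t in taxa_union], gene="concat")
    return combined, partition


def write_binary_phylip(matrix: IndelCharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_characters}\n")
        for taxon, row in zip(matrix.taxa, matrix.states):
            fh.write(f"{taxon}  {row}\n")


def write_binary_nexus(matrix: IndelCharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_characters};\n")
        fh.write('FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\nMATRIX\n')
        for taxon, row in zip(matrix.taxa, matrix.states):
            fh.write(f"{taxon}  {row}\n")
        fh.write(";\nEND;\n")


def write_partition_file(partition: list[tuple[str, int, int]], path: str | Path, datatype: str = "DNA") -> None:
    """RAxML-style partition file (1-based inclusive column ranges)."""
    with open(path, "w") as fh:
        for gene, start, end in partition:
            fh.write(f"{datatype}, {gene} = {start + 1}-{end}\n")
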