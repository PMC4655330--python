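"""Circular-coordinate arithmetic for plastid genomes.

Plastomes are circular molecules; every interval in this package is 0-based,
half-open, and may wrap around the origin. A :class:`CircularInterval` stores
``start`` (normalized into ``[0, genome_length)``) and ``length``, which makes
the wrap case unambiguous: the interval wraps iff ``start + length >
genome_length``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CircularInterval", "merge_intervals", "union_length"]


@dataclass(frozen=True, order=True)
class CircularInterval:
    """A 0-based half-open interval on a circle of size ``genome_length``."""

    start: int
    length: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0 < self.length <= self.genome_length):
            raise ValueError(
                f"interval length {self.length} outside (0, {self.genome_length}]"
            )
        object.__setattr__(self, "start", self.start % self.genome_length)

    @classmethod
    def from_coords(cls, start: int, end: int, genome_length: int) -> "CircularInterval":
        """Build from ``[start, end)`` coordinates; ``end <= start`` wraps.

        ``end`` may exceed ``genome_length`` (unwrapped representation) or be
        smaller than ``start`` (already-wrapped representation); both denote
        the same arc.
        """
        length = (end - start) % genome_length
        if length == 0:
            if end == start:
                raise ValueError("zero-length interval")
            length = genome_length  # full circle expressed as end = start + L
        return cls(start % genome_length, length, genome_length)

    @property
    def end(self) -> int:
        """Exclusive end, normalized into ``[0, genome_length]``.

        For a wrapping interval this is smaller than ``start``.
        """
        e = (self.start + self.length) % self.genome_length
        return self.genome_length if e == 0 and not self.wraps else e

    @property
    def end_unwrapped(self) -> int:
        """Exclusive end without modular reduction (may exceed genome length)."""
        return self.start + self.length

    @property
    def wraps(self) -> bool:
        return self.start + self.length > self.genome_length

    @property
    def midpoint(self) -> int:
        return (self.start + self.length // 2) % self.genome_length

    def contains(self, pos: int) -> bool:
        return (pos - self.start) % self.genome_length < self.length

    def overlaps(self, other: "CircularInterval") -> bool:
        if self.genome_length != other.genome_length:
            raise ValueError("intervals on different circles")
        return any(
            self.contains(p % self.genome_length)
            for p in (other.start, other.end_unwrapped - 1)
        ) or any(
            other.contains(p % self.genome_length)
            for p in (self.start, self.end_unwrapped - 1)
        )

    def linear_pieces(self) -> list[tuple[int, int]]:
        """Decompose into 1 or 2 non-wrapping ``(start, end)`` pieces."""
        if not self.wraps:
            return [(self.start, self.start + self.length)]
        return [(self.start, self.genome_length), (0, self.end_unwrapped - self.genome_length)]


def merge_intervals(intervals: list[CircularInterval]) -> list[tuple[int, int]]:
    """Merge intervals into disjoint linear ``(start, end)`` pieces.

    Wrapping intervals are split at the origin first; the result is a sorted
    list of maximal disjoint pieces covering the same positions.
    """
    pieces: list[tuple[int, int]] = []
    for iv in intervals:
        pieces.extend(iv.linear_pieces())
    if not pieces:
        return []
    pieces.sort()
    merged = [pieces[0]]
    for s, e in pieces[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: list[CircularInterval]) -> int:
    """Total number of distinct positions covered by ``intervals``."""
    return sum(e - s for s, e in merge_intervals(intervals))
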