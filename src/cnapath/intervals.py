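"""Genomic interval primitives shared by BACs, genes and CNA segments.

All coordinates are 0-based, half-open ``[start, end)``; every reader
converts on ingest. Strand is ignored throughout: array-CGH copy number
is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an input value violates a documented contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open coordinate span.

    Parameters
    ----------
    chrom : str
        Chromosome identifier (e.g. ``"chr1"``).
    start : int
        0-based inclusive start; must be non-negative.
    end : int
        Exclusive end; must satisfy ``start < end`` for a mapped interval.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end < self.start:
            raise ValidationError(
                f"end {self.end} < start {self.start} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class BacClone:
    """A BAC clone with raw, expanded and extended genomic coordinates.

    ``left_anchored`` / ``right_anchored`` record whether the corresponding
    end sequence has been mapped: anchored ends are never moved by
    expansion or extension. ``left_frozen`` / ``right_frozen`` mark ends
    immobilised by a partial overlap with another BAC. A clone fully
    contained in a larger clone is marked via ``duplicate_of`` and adopts
    the container's final coordinates.
    """

    bac_id: str
    raw: GenomicInterval
    left_anchored: bool = False
    right_anchored: bool = False
    expanded: GenomicInterval | None = None
    extended: GenomicInterval | None = None
    left_frozen: bool = False
    right_frozen: bool = False
    duplicate_of: str | None = None

    @property
    def chrom(self) -> str:
        return self.raw.chrom

    @property
    def left_fixed(self) -> bool:
        """True when the left end may not move (anchored or overlap-frozen)."""
        return self.left_anchored or self.left_frozen

    @property
    def right_fixed(self) -> bool:
        return self.right_anchored or self.right_frozen


@dataclass(frozen=True)
class Gene:
    """A gene with a stable identifier and one mapped interval."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class SegmentCall:
    """A copy-number altered segment called in one sample.

    ``state`` is +1 for amplification, -1 for deletion.
    """

    sample_id: str
    interval: GenomicInterval
    state: int

    def __post_init__(self) -> None:
        if self.state not in (-1, 1):
            raise ValidationError(
                f"segment state must be -1 or +1, got {self.state}"
            )
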