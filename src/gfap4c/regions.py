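"""Genomic coordinate primitives shared by every stage of the screen.

Coordinates are 0-based, half-open (BED-compatible) throughout. A gene's
TSS/TES are strand-aware: on the ``-`` strand the TSS is the interval end.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome.

        0 when the intervals overlap or touch. Raises on different
        chromosomes (gap is undefined in linear coordinates).
        """
        if self.chrom != other.chrom:
            raise ValueError(
                f"gap undefined across chromosomes {self.chrom}/{other.chrom}"
            )
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start and end sites."""

    gene_id: str
    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id} needs a +/- strand")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end of the gene."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        """Strand-aware 3' end of the gene."""
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment bounded by two enzyme cut sites.

    ``left_site``/``right_site`` name the enzymes whose recognition-site
    5' coordinates bound the fragment on the forward strand; ``orientation``
    records which strand the enzyme-A-then-enzyme-B scan found it on.
    """

    interval: GenomicInterval
    left_site: str
    right_site: str
    orientation: str = "+"

    @property
    def length(self) -> int:
        return self.interval.length
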