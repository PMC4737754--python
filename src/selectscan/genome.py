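"""Genomic intervals and gene models.

All coordinates inside the package are 0-based, half-open. The I/O layer is
the only place where external conventions (1-based GFF3, 1-based methylation
TSV, 0-based BED) are converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """A gene as used by the pipeline.

    ``placed`` is False for genes annotated on unanchored scaffolds; such
    genes are excluded from sweep/non-sweep methylation comparisons because
    scaffolds are never scanned for sweeps.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    placed: bool = True
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad gene interval for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id} needs explicit strand")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end

    def __len__(self) -> int:
        return self.end - self.start
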