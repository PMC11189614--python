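"""Genomic intervals, transcript models, and aligned reads.

All internal coordinates are 0-based half-open (BED convention); the format
readers in :mod:`riboflux.io` convert 1-based inclusive GFF3/SAM coordinates
at the boundary.  Transcript-orientation helpers here are the single source
of 5'->3' base ordering used by the coverage and simulation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chrom or strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """One gene's 5'UTR / CDS / 3'UTR plus any upstream ORFs.

    The three features tile a contiguous genomic interval; ``uorfs`` lie
    within the 5'UTR and are ordered 5'->3' in transcript orientation.
    ``utr5_source`` records whether the 5'UTR was measured (annotated) or
    extended from the CDS by a default length.
    """

    gene_id: str
    utr5: GenomicInterval
    cds: GenomicInterval
    utr3: GenomicInterval
    uorfs: list[GenomicInterval] = field(default_factory=list)
    utr5_source: str = "measured"
    truncated_utr: bool = False
    introns: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        chroms = {self.utr5.chrom, self.cds.chrom, self.utr3.chrom}
        strands = {self.utr5.strand, self.cds.strand, self.utr3.strand}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.gene_id}: features on mixed chrom/strand")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {len(self.cds)} not a multiple of 3")
        if self.strand == "+":
            ok = self.utr5.end == self.cds.start and self.cds.end == self.utr3.start
        else:
            ok = self.utr3.end == self.cds.start and self.cds.end == self.utr5.start
        if not ok:
            raise ValueError(f"{self.gene_id}: utr5/cds/utr3 do not tile contiguously")
        for u in self.uorfs:
            if u.start < self.utr5.start or u.end > self.utr5.end:
                raise ValueError(f"{self.gene_id}: uORF {u} outside the 5'UTR")
        # order uORFs 5'->3' in transcript orientation
        self.uorfs = sorted(self.uorfs, key=lambda u: u.start, reverse=self.strand == "-")

    @property
    def chrom(self) -> str:
        return self.cds.chrom

    @property
    def strand(self) -> str:
        return self.cds.strand

    @property
    def span(self) -> GenomicInterval:
        """Full transcript interval (utr5 + cds + utr3)."""
        start = min(self.utr5.start, self.utr3.start)
        end = max(self.utr5.end, self.utr3.end)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def features(self) -> dict[str, GenomicInterval]:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}

    # -- transcript-orientation coordinate maps -------------------------------

    def to_transcript(self, genomic_pos: int) -> int:
        """Genomic position -> 0-based offset from the transcript 5' end."""
        s = self.span
        if not s.contains(genomic_pos):
            raise ValueError(f"{genomic_pos} outside transcript {self.gene_id}")
        if self.strand == "+":
            return genomic_pos - s.start
        return s.end - 1 - genomic_pos

    def to_genomic(self, transcript_pos: int) -> int:
        """0-based offset from the transcript 5' end -> genomic position."""
        s = self.span
        if not (0 <= transcript_pos < len(s)):
            raise ValueError(f"transcript offset {transcript_pos} out of range")
        if self.strand == "+":
            return s.start + transcript_pos
        return s.end - 1 - transcript_pos

    def cds_start_transcript(self) -> int:
        """Transcript-orientation offset of the first CDS base (the A of AUG)."""
        first = self.cds.start if self.strand == "+" else self.cds.end - 1
        return self.to_transcript(first)


@dataclass
class AlignedRead:
    """One mapped fragment: >=1 non-overlapping blocks on one chrom/strand.

    Multi-block reads encode splices; ``read_length`` is the summed block
    length, i.e. the aligned fragment length.
    """

    blocks: list[GenomicInterval]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("AlignedRead requires at least one block")
        chroms = {b.chrom for b in self.blocks}
        strands = {b.strand for b in self.blocks}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("read blocks on mixed chrom/strand")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError("read blocks overlap")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def read_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    def bases_5p_to_3p(self) -> list[int]:
        """All covered genomic positions ordered 5'->3' along the fragment."""
        fwd = [p for b in self.blocks for p in range(b.start, b.end)]
        return fwd if self.strand == "+" else fwd[::-1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3'-most aligned base."""
        return self.end - 1 if self.strand == "+" else self.start
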