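"""Domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GTF and
other 1-based formats are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import intervals as iv

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A stranded transcript: exons plus optional CDS / stop-codon structure.

    ``exons`` and ``cds`` are lists of (start, end) half-open intervals in
    ascending genomic order; ``cds`` excludes the stop codon, which is kept
    separately (GENCODE convention).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)
    stop_codon: Optional[Tuple[int, int]] = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e

    # --- transcript-coordinate arithmetic (5'->3') -------------------------

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Map a genomic position to the 5'->3' transcript coordinate.

        Returns None when ``pos`` falls outside the exons.
        """
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus = off + (pos - s)
                if self.strand == "+":
                    return plus
                return self.exonic_length - 1 - plus
            off += e - s
        return None

    def utr5(self) -> List[Tuple[int, int]]:
        """Exonic intervals 5' of the CDS (genomic coordinates)."""
        if not self.cds:
            return []
        if self.strand == "+":
            lim = self.cds[0][0]
            region = [(self.start, lim)] if lim > self.start else []
        else:
            lim = self.cds[-1][1]
            region = [(lim, self.end)] if lim < self.end else []
        return iv.intersect(self.exons, region)

    def utr3(self) -> List[Tuple[int, int]]:
        """Exonic intervals 3' of the stop codon (or CDS end if no stop)."""
        if not self.cds:
            return []
        stop = [self.stop_codon] if self.stop_codon else []
        coding = iv.merge(list(self.cds) + stop)
        if self.strand == "+":
            lim = coding[-1][1]
            region = [(lim, self.end)] if lim < self.end else []
        else:
            lim = coding[0][0]
            region = [(self.start, lim)] if lim > self.start else []
        return iv.intersect(self.exons, region)

    def spliced_sequence(self, genome: Dict[str, str]) -> str:
        """Sense-strand DNA of the concatenated exons."""
        chrom_seq = genome[self.chrom]
        s = "".join(chrom_seq[a:b] for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationBundle:
    genes: Dict[str, GeneModel]
    transcripts: List[TranscriptModel]
    chrom_sizes: Dict[str, int]
    sequence: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        self._by_gene: Dict[str, List[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._by_gene.setdefault(tx.gene_id, []).append(tx)

    def transcripts_of(self, gene_id: str) -> List[TranscriptModel]:
        return self._by_gene.get(gene_id, [])

    def validate(self) -> None:
        for tx in self.transcripts:
            tx.validate()
            if tx.gene_id not in self.genes:
                raise ValueError(f"{tx.transcript_id}: unknown gene {tx.gene_id}")
            size = self.chrom_sizes.get(tx.chrom)
            if size is None:
                raise ValueError(f"{tx.transcript_id}: unknown chromosome {tx.chrom}")
            if tx.start < 0 or tx.end > size:
                raise ValueError(
                    f"{tx.transcript_id}: interval [{tx.start}, {tx.end}) outside "
                    f"{tx.chrom} (size {size})"
                )

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class Peak:
    """A called m6A peak; ``summit`` is an absolute genomic position."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    name: str = "."
    replicate: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.name}: summit outside interval")


@dataclass
class RepeatLocus:
    """One retrotransposon copy after filtering."""

    locus_id: str
    subfamily: str
    repclass: str  # LINE | SINE | LTR | SVA
    chrom: str
    start: int
    end: int
    strand: str
    completeness: float
    architecture: str = "n/a"  # solo | full_length_ERV | n/a

    @property
    def length(self) -> int:
        return self.end - self.start
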