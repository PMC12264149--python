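"""Readers and writers for the standard formats the pipeline consumes.

Conventions normalized at this boundary:

* GTF is 1-based closed on disk, 0-based half-open in memory.
* BED / narrowPeak / bedGraph are 0-based half-open on both sides.
* TSV tables are tab-delimited with a header row and '.' for missing.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .core import AnnotationBundle, GeneModel, Peak, TranscriptModel
from .signal import BinnedTrack, n_bins

log = logging.getLogger("m6akit.io")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chrom sizes / FASTA
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{i}: expected 'chrom<TAB>length'")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None and line.strip():
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def read_gene_models(
    path,
    chrom_sizes: Optional[Dict[str, int]] = None,
    sequence: Optional[Dict[str, str]] = None,
) -> AnnotationBundle:
    """Parse a GTF file into an AnnotationBundle (0-based half-open).

    ``chrom_sizes`` defaults to the rightmost coordinate seen per chromosome.
    Transcripts without any exon record are rejected.
    """
    genes: Dict[str, GeneModel] = {}
    tx_meta: Dict[str, dict] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    stops: Dict[str, Tuple[int, int]] = {}

    n_lines = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        n_lines += 1
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{i}: expected 9 tab-separated fields")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
        try:
            start = int(start_s) - 1  # GTF is 1-based closed
            end = int(end_s)
        except ValueError:
            raise ParseError(f"{path}:{i}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{i}: bad interval {start_s}-{end_s}")
        attrs = dict(_ATTR_RE.findall(attrs_s))
        gid = attrs.get("gene_id")
        if gid is None:
            raise ParseError(f"{path}:{i}: missing gene_id attribute")
        if feature == "gene":
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype=attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
            )
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ParseError(f"{path}:{i}: missing transcript_id attribute")
        if feature == "transcript":
            tx_meta[tid] = {"gene_id": gid, "chrom": chrom, "strand": strand}
        elif feature == "exon":
            tx_meta.setdefault(tid, {"gene_id": gid, "chrom": chrom, "strand": strand})
            exons.setdefault(tid, []).append((start, end))
        elif feature == "CDS":
            cds.setdefault(tid, []).append((start, end))
        elif feature == "stop_codon":
            stops[tid] = (start, end)
        # other feature types (UTR, start_codon, ...) are derivable; skipped

    transcripts: List[TranscriptModel] = []
    for tid, meta in tx_meta.items():
        if tid not in exons:
            raise ParseError(f"{path}: transcript {tid} has no exon records")
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=meta["gene_id"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=sorted(exons[tid]),
            cds=sorted(cds.get(tid, [])),
            stop_codon=stops.get(tid),
        )
        tx.validate()
        transcripts.append(tx)

    # synthesize gene records missing an explicit 'gene' line
    for tx in transcripts:
        if tx.gene_id not in genes:
            genes[tx.gene_id] = GeneModel(
                gene_id=tx.gene_id, chrom=tx.chrom, strand=tx.strand,
                start=tx.start, end=tx.end,
            )

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes.values():
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)

    if n_lines == 0:
        log.warning("%s: empty annotation file", path)

    bundle = AnnotationBundle(
        genes=genes, transcripts=transcripts, chrom_sizes=chrom_sizes, sequence=sequence
    )
    bundle.validate()
    return bundle


def write_gene_models(bundle: AnnotationBundle, path) -> None:
    """Emit a GTF equivalent to what read_gene_models parses (round-trip safe)."""

    def row(chrom, feature, s, e, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\tm6akit\t{feature}\t{s + 1}\t{e}\t.\t{strand}\t.\t{a}\n"

    with open(path, "w") as fh:
        for gid, g in bundle.genes.items():
            fh.write(row(g.chrom, "gene", g.start, g.end, g.strand,
                         [("gene_id", gid), ("gene_biotype", g.biotype)]))
            for tx in bundle.transcripts_of(gid):
                base = [("gene_id", gid), ("transcript_id", tx.transcript_id)]
                fh.write(row(tx.chrom, "transcript", tx.start, tx.end, tx.strand, base))
                for s, e in tx.exons:
                    fh.write(row(tx.chrom, "exon", s, e, tx.strand, base))
                for s, e in tx.cds:
                    fh.write(row(tx.chrom, "CDS", s, e, tx.strand, base))
                if tx.stop_codon:
                    s, e = tx.stop_codon
                    fh.write(row(tx.chrom, "stop_codon", s, e, tx.strand, base))


# ---------------------------------------------------------------------------
# peaks (narrowPeak / BED)
# ---------------------------------------------------------------------------

def read_peaks(path, replicate: str = ".") -> List[Peak]:
    """Read narrowPeak (10 columns) or BED (>=3 columns) into Peak objects.

    narrowPeak column 10 is the summit offset from start; -1 (and any BED
    input) falls back to the interval midpoint (floor).
    """
    peaks: List[Peak] = []
    rejected = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: expected at least 3 BED columns")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if start >= end:
            rejected += 1
            continue
        name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{i}"
        score = float(f[6]) if len(f) >= 10 else (float(f[4]) if len(f) > 4 and f[4] != "." else 0.0)
        offset = int(f[9]) if len(f) >= 10 else -1
        summit = start + offset if offset >= 0 else (start + end) // 2
        peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                          score=score, name=name, replicate=replicate))
    if rejected:
        log.warning("%s: rejected %d records with start >= end", path, rejected)
    return peaks


def write_peaks(peaks: Iterable[Peak], path) -> None:
    """Write peaks in narrowPeak format (signalValue = score)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.score:.6g}\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def read_signal_track(
    path, chrom_sizes: Dict[str, int], bin_size: int, label: str = "."
) -> BinnedTrack:
    """Resample a bedGraph onto fixed bins by length-weighted mean.

    Uncovered bases contribute 0, so a partially covered bin averages the
    covered value against zero over the bin width.
    """
    track = BinnedTrack.zeros(chrom_sizes, bin_size, label=label)
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 4:
            raise ParseError(f"{path}:{i}: expected 4 bedGraph columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if chrom not in chrom_sizes:
            raise ParseError(f"{path}:{i}: unknown chromosome {chrom}")
        if start < 0 or end > chrom_sizes[chrom] or start >= end:
            raise ParseError(f"{path}:{i}: interval outside chromosome {chrom}")
        a = track.data[chrom]
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo, hi = max(start, b * bin_size), min(end, (b + 1) * bin_size)
            width = min(bin_size, chrom_sizes[chrom] - b * bin_size)
            a[b] += value * (hi - lo) / width
    return track


def write_signal_track(track: BinnedTrack, chrom_sizes: Dict[str, int], path) -> None:
    """Write a BinnedTrack as a bedGraph, merging equal-value runs, skipping 0."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            a = track.data[chrom]
            size = chrom_sizes[chrom]
            run_start = 0
            for b in range(1, len(a) + 1):
                if b == len(a) or a[b] != a[run_start]:
                    v = a[run_start]
                    if v != 0:
                        s = run_start * bs
                        e = min(b * bs, size)
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
                    run_start = b


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", na_rep=".", **kwargs)
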