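"""Peak-to-feature assignment, enrichment scores, metagene profiles,
gene-level m6A calls and RRACH motif counting.

Feature priority: stop_codon > 3UTR > 5UTR > CDS > exon > intron > intergenic.
The stop-codon feature is the annotated 3-nt stop codon extended 200 bp in
both directions in genomic space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import AnnotationBundle, Peak, TranscriptModel

log = logging.getLogger("m6akit.annotate")

FEATURE_ORDER = ["stop_codon", "3UTR", "5UTR", "CDS", "exon", "intron", "intergenic"]

RRACH_RE = re.compile(r"(?=([GA][GA]AC[ACT]))")


# ---------------------------------------------------------------------------
# feature projections
# ---------------------------------------------------------------------------

def build_feature_masks(
    bundle: AnnotationBundle, stop_codon_flank: int = 200
) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Merged genomic projections per feature, over all transcripts.

    Returns feature -> chrom -> merged interval list (unmasked; the priority
    hierarchy is applied at query/length time).
    """
    raw: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        f: {} for f in FEATURE_ORDER if f != "intergenic"
    }

    def add(feature: str, chrom: str, ivs_: Iterable[Tuple[int, int]]) -> None:
        raw[feature].setdefault(chrom, []).extend(ivs_)

    for tx in bundle.transcripts:
        size = bundle.chrom_sizes[tx.chrom]
        add("exon", tx.chrom, tx.exons)
        introns = iv.subtract([(tx.start, tx.end)], tx.exons)
        add("intron", tx.chrom, introns)
        if tx.is_coding:
            add("CDS", tx.chrom, tx.cds)
            add("5UTR", tx.chrom, tx.utr5())
            add("3UTR", tx.chrom, tx.utr3())
            if tx.stop_codon:
                s, e = tx.stop_codon
                add("stop_codon", tx.chrom,
                    [(max(0, s - stop_codon_flank), min(size, e + stop_codon_flank))])

    return {f: {c: iv.merge(ivs_) for c, ivs_ in by.items()} for f, by in raw.items()}


def assign_peak_feature(
    peak: Peak,
    masks: Mapping[str, Mapping[str, List[Tuple[int, int]]]],
) -> str:
    """First matching feature in priority order, testing the peak interval."""
    for feature in FEATURE_ORDER[:-1]:
        merged = masks.get(feature, {}).get(peak.chrom, [])
        if iv.overlaps_any(peak.start, peak.end, merged):
            return feature
    return "intergenic"


def annotate_peaks(
    peaks: Sequence[Peak], bundle: AnnotationBundle, stop_codon_flank: int = 200
) -> pd.DataFrame:
    masks = build_feature_masks(bundle, stop_codon_flank)
    rows = [
        {
            "peak": p.name,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "summit": p.summit,
            "feature": assign_peak_feature(p, masks),
        }
        for p in peaks
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hierarchy_masked_lengths(
    bundle: AnnotationBundle, stop_codon_flank: int = 200
) -> Dict[str, int]:
    """Genomic length of each feature after subtracting higher-priority
    projections; lengths partition the genome exactly."""
    masks = build_feature_masks(bundle, stop_codon_flank)
    genome = bundle.genome_length()
    lengths: Dict[str, int] = {}
    claimed: Dict[str, List[Tuple[int, int]]] = {}
    for feature in FEATURE_ORDER[:-1]:
        total = 0
        for chrom, ivs_ in masks.get(feature, {}).items():
            own = iv.subtract(ivs_, claimed.get(chrom, []))
            total += iv.total_length(own)
            claimed[chrom] = iv.merge(claimed.get(chrom, []) + ivs_)
        lengths[feature] = total
    lengths["intergenic"] = genome - sum(lengths.values())
    return lengths


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # index feature; observed, expected, enrichment

    def score(self, feature: str) -> float:
        return float(self.table.loc[feature, "enrichment"])


def feature_enrichment(
    peaks: Sequence[Peak], bundle: AnnotationBundle, stop_codon_flank: int = 200
) -> EnrichmentTable:
    """E_f = log2(observed_f / expected_f), expected proportional to the
    hierarchy-masked genomic length of each feature."""
    if not peaks:
        raise ValueError("feature_enrichment: empty peak list")
    masks = build_feature_masks(bundle, stop_codon_flank)
    observed = {f: 0 for f in FEATURE_ORDER}
    for p in peaks:
        observed[assign_peak_feature(p, masks)] += 1
    lengths = hierarchy_masked_lengths(bundle, stop_codon_flank)
    genome = bundle.genome_length()
    n = len(peaks)
    rows = []
    for f in FEATURE_ORDER:
        expected = n * lengths[f] / genome
        obs = observed[f]
        if obs > 0 and expected > 0:
            e = float(np.log2(obs / expected))
        else:
            e = np.nan
        rows.append({"feature": f, "length": lengths[f], "observed": obs,
                     "expected": expected, "enrichment": e})
    return EnrichmentTable(pd.DataFrame(rows).set_index("feature"))


# ---------------------------------------------------------------------------
# representative transcripts and metagene profile
# ---------------------------------------------------------------------------

def representative_transcript(
    bundle: AnnotationBundle,
    expression: Optional[pd.Series] = None,
) -> Dict[str, TranscriptModel]:
    """Highest-expression isoform per gene; ties broken by exonic length then
    lexicographic transcript id. Transcripts absent from ``expression`` count
    as zero."""
    reps: Dict[str, TranscriptModel] = {}
    for gid in bundle.genes:
        txs = bundle.transcripts_of(gid)
        if not txs:
            continue

        def key(tx: TranscriptModel):
            tpm = 0.0
            if expression is not None and tx.transcript_id in expression.index:
                tpm = float(expression[tx.transcript_id])
            return (-tpm, -tx.exonic_length, tx.transcript_id)

        reps[gid] = min(txs, key=key)
    return reps


@dataclass
class MetageneProfile:
    coords: np.ndarray          # per-summit metagene coordinate in [0, 3)
    density: np.ndarray         # sums to 1 (empty when no summits mapped)
    bin_edges: np.ndarray
    n_used: int
    n_skipped: int


def metagene_coordinate(summit: int, tx: TranscriptModel) -> Optional[float]:
    """Map a genomic summit onto [0,3): 5'UTR->[0,1), CDS->[1,2), 3'UTR->[2,3).

    The stop codon marks the CDS/3'UTR boundary (its first base maps to 2.0).
    Returns None for non-coding or UTR-less transcripts or summits off exons.
    """
    if not tx.is_coding or tx.stop_codon is None:
        return None
    pos = tx.genomic_to_tx(summit)
    if pos is None:
        return None
    utr5_len = sum(e - s for s, e in tx.utr5())
    stop_first_genomic = tx.stop_codon[0] if tx.strand == "+" else tx.stop_codon[1] - 1
    stop_tx = tx.genomic_to_tx(stop_first_genomic)
    if stop_tx is None:
        return None
    total = tx.exonic_length
    cds_len = stop_tx - utr5_len
    utr3_len = total - stop_tx
    if utr5_len == 0 or cds_len <= 0 or utr3_len <= 0:
        return None
    if pos < utr5_len:
        return pos / utr5_len
    if pos < stop_tx:
        return 1.0 + (pos - utr5_len) / cds_len
    return 2.0 + (pos - stop_tx) / utr3_len


def metagene_profile(
    summits: Sequence[Tuple[str, int]],
    bundle: AnnotationBundle,
    expression: Optional[pd.Series] = None,
    n_bins: int = 90,
) -> MetageneProfile:
    """Metagene coordinates of peak summits over representative transcripts.

    ``summits`` are (chrom, position) pairs. Each summit is mapped on the
    representative transcript of every gene whose exons contain it; summits
    on non-coding or UTR-less transcripts are skipped and counted.
    """
    reps = representative_transcript(bundle, expression)
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for tx in reps.values():
        by_chrom.setdefault(tx.chrom, []).append(tx)

    coords: List[float] = []
    skipped = 0
    for chrom, pos in summits:
        hit = None
        for tx in by_chrom.get(chrom, []):
            if tx.start <= pos < tx.end:
                c = metagene_coordinate(pos, tx)
                if c is not None:
                    hit = c
                    break
        if hit is None:
            skipped += 1
        else:
            coords.append(hit)
    if skipped:
        log.info("metagene: skipped %d summits (non-coding/UTR-less/off-exon)", skipped)
    arr = np.asarray(coords, dtype=float)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    if len(arr):
        hist, _ = np.histogram(arr, bins=edges)
        density = hist / hist.sum()
    else:
        density = np.zeros(n_bins)
    return MetageneProfile(coords=arr, density=density, bin_edges=edges,
                           n_used=len(arr), n_skipped=skipped)


# ---------------------------------------------------------------------------
# gene-level m6A calls
# ---------------------------------------------------------------------------

@dataclass
class GeneM6ACall:
    gene_id: str
    status: str  # m6A+ | m6A- | not_expressed
    supporting: Dict[str, List[str]] = field(default_factory=dict)  # replicate -> peak names


def call_m6a_genes(
    peaks_by_replicate: Mapping[str, Sequence[Peak]],
    bundle: AnnotationBundle,
    expression: Optional[pd.Series] = None,
    tpm_floor: float = 1.0,
    exon_level: bool = True,
) -> List[GeneM6ACall]:
    """A gene is m6A+ if any transcript intersects any peak by >= 1 bp in any
    replicate (union rule). ``exon_level`` intersects exonic intervals;
    otherwise the full transcript span is used. Genes below ``tpm_floor`` in
    ``expression`` are flagged not_expressed."""
    if not peaks_by_replicate:
        raise ValueError("call_m6a_genes: need at least one replicate")
    # merged exon (or span) projection per gene and chromosome
    gene_proj: Dict[str, Tuple[str, List[Tuple[int, int]]]] = {}
    for gid in bundle.genes:
        txs = bundle.transcripts_of(gid)
        if not txs:
            continue
        if exon_level:
            ivs_ = iv.merge([e for tx in txs for e in tx.exons])
        else:
            ivs_ = iv.merge([(tx.start, tx.end) for tx in txs])
        gene_proj[gid] = (txs[0].chrom, ivs_)

    calls: List[GeneM6ACall] = []
    for gid, (chrom, ivs_) in gene_proj.items():
        supporting: Dict[str, List[str]] = {}
        for rep, peaks in peaks_by_replicate.items():
            hits = [p.name for p in peaks
                    if p.chrom == chrom and iv.overlaps_any(p.start, p.end, ivs_)]
            if hits:
                supporting[rep] = hits
        if expression is not None:
            tpm = float(expression.get(gid, 0.0))
            if tpm < tpm_floor:
                calls.append(GeneM6ACall(gid, "not_expressed", supporting))
                continue
        status = "m6A+" if supporting else "m6A-"
        calls.append(GeneM6ACall(gid, status, supporting))
    n_pos = sum(1 for c in calls if c.status == "m6A+")
    log.info("call_m6a_genes: %d genes in, %d m6A+", len(calls), n_pos)
    return calls


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------

def count_rrach(
    bundle: AnnotationBundle,
    gene_id: str,
    expression: Optional[pd.Series] = None,
) -> Tuple[int, float]:
    """Count RRACH ([GA][GA]AC[ACT]) matches, overlaps allowed, on the
    sense-strand DNA of the representative transcript's concatenated exons.

    Returns (count, density per kb of exonic sequence).
    """
    if bundle.sequence is None:
        raise ValueError(f"count_rrach: no sequence available (gene {gene_id})")
    txs = bundle.transcripts_of(gene_id)
    if not txs:
        raise ValueError(f"count_rrach: unknown gene {gene_id}")
    reps = representative_transcript(
        AnnotationBundle(genes={gene_id: bundle.genes[gene_id]}, transcripts=txs,
                         chrom_sizes=bundle.chrom_sizes),
        expression,
    )
    tx = reps[gene_id]
    if tx.chrom not in bundle.sequence:
        raise ValueError(f"count_rrach: no sequence for chromosome of gene {gene_id}")
    seq = tx.spliced_sequence(bundle.sequence).upper()
    count = sum(1 for _ in RRACH_RE.finditer(seq))
    density = count / (len(seq) / 1000.0) if seq else 0.0
    return count, density


def peak_regions_by_gene(
    peaks: Sequence[Peak],
    bundle: AnnotationBundle,
    stop_codon_flank: int = 200,
) -> Dict[str, Set[str]]:
    """For each gene, the set of feature regions in which it has a peak summit.

    A summit is attributed to every gene whose merged exonic span contains it;
    the region label is the summit's own priority-hierarchy assignment. Used
    by the translation-by-region analysis (multi-membership convention).
    """
    masks = build_feature_masks(bundle, stop_codon_flank)
    out: Dict[str, Set[str]] = {}
    for p in peaks:
        point = Peak(chrom=p.chrom, start=p.summit, end=p.summit + 1,
                     summit=p.summit, name=p.name)
        label = assign_peak_feature(point, masks)
        if label not in {"stop_codon", "3UTR", "5UTR", "CDS"}:
            continue
        for gid in bundle.genes:
            txs = bundle.transcripts_of(gid)
            if not txs or txs[0].chrom != p.chrom:
                continue
            exons = iv.merge([e for tx in txs for e in tx.exons])
            lo = min(s for s, _ in exons) - stop_codon_flank
            hi = max(e for _, e in exons) + stop_codon_flank
            if lo <= p.summit < hi:
                out.setdefault(gid, set()).add(label)
    return out
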