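"""Synthetic-data generator: emits every input the pipeline reads (GTF,
FASTA, bedGraph tracks, narrowPeak, TSV tables) with a known ground truth.

Planted structure:

* genes with 5'UTR / CDS / stop codon / 3'UTR across multiple exons;
* per-gene expression classes (M-decay, Z-decay, ZGA, constant, background)
  whose stage-mean TPMs satisfy the printed classification inequalities with
  a configurable margin;
* m6A+ genes with IP enrichment concentrated in a Gaussian-shaped window
  around a summit placed near the stop codon;
* repeat loci with planted completeness, architecture (full-length ERV vs
  solo LTR), expression and modification status;
* miRNA counts and a conserved-family target map; Ribo/mRNA FPKM tables
  with a TE multiplier on m6A+ genes; Ctrl vs inhibitor condition pairs.

Tracks are expected-RPKM models with multiplicative log-normal replicate
noise (the pipeline consumes coverage tracks, not reads); an exact-depth
fragment sampler is provided separately for count-level tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .core import AnnotationBundle, GeneModel, Peak, TranscriptModel, revcomp
from .signal import BinnedTrack, call_peaks_naive, compute_m6a_signal, n_bins

log = logging.getLogger("m6akit.simulate")

STAGES = ["GV", "MII", "1C", "2C", "8C", "BLT"]
MOUSE_STAGES = ["GV", "MII", "1C", "2C", "BLT"]

SUBFAMILY_DEFS = {
    # subfamily -> (class, consensus length, part, family)
    "L1SIM": ("LINE", 3000, ".", "."),
    "ALUSIM": ("SINE", 300, ".", "."),
    "SVASIM": ("SVA", 1300, ".", "."),
    "THE1SIM": ("LTR", 400, "ltr", "THE1SIM"),
}
ERV_LTR = ("HERVSIM-LTR", 450)
ERV_INT = ("HERVSIM-int", 3000)


@dataclass
class SimConfig:
    # genome / annotation
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    n_exons_range: Tuple[int, int] = (2, 6)
    utr5_range: Tuple[int, int] = (60, 200)
    cds_range: Tuple[int, int] = (300, 900)
    utr3_range: Tuple[int, int] = (150, 450)
    intron_range: Tuple[int, int] = (100, 1200)
    gene_gap_range: Tuple[int, int] = (300, 1500)

    # stages and planted classes
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    replicates: int = 2
    n_mdecay: int = 8
    n_zdecay: int = 8
    n_zga: int = 8
    n_constant: int = 12
    margin: float = 1.5

    # peak / coverage model
    m6a_fraction: float = 0.5
    m6a_long_bias: bool = False
    summit_sd: float = 50.0
    peak_halfwidth: int = 80
    enrichment: float = 8.0
    unmodified_ip_factor: float = 0.5
    depth: int = 100_000
    replicate_noise: float = 0.05

    # repeat model
    loci_per_subfamily: int = 30
    n_erv_elements: int = 20
    incomplete_fraction: float = 0.3
    full_length_fraction: float = 0.6
    ltr_pair_fraction: float = 0.1
    exon_overlap_fraction: float = 0.05
    repeat_expressed_fraction: float = 0.9
    repeat_m6a_fraction: float = 0.5
    repeat_gap_range: Tuple[int, int] = (80, 300)

    # condition model
    inhibitor_reduction: float = 0.5

    # miRNA / translation model
    n_mirnas: int = 40
    conserved_fraction: float = 0.7
    target_density: float = 0.08
    mirna_m6a_bias: float = 2.0
    te_base: float = 1.0
    te_multiplier: float = 1.5

    seed: int = 0

    def validate(self) -> None:
        n_classes = self.n_mdecay + self.n_zdecay + self.n_zga + self.n_constant
        if n_classes > self.n_genes:
            raise ValueError("simulate: planted class counts exceed n_genes")
        if not 1.0 < self.margin < 2.0:
            raise ValueError("simulate: margin must lie in (1, 2) for unambiguous classes")
        if self.enrichment < 1.0:
            raise ValueError("simulate: enrichment factor must be >= 1")
        for name in ("m6a_fraction", "incomplete_fraction", "full_length_fraction",
                     "repeat_expressed_fraction", "repeat_m6a_fraction",
                     "conserved_fraction", "exon_overlap_fraction", "ltr_pair_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"simulate: {name} must be in [0, 1]")
        if not 0.0 <= self.inhibitor_reduction <= 1.0:
            raise ValueError("simulate: inhibitor_reduction must be in [0, 1]")


@dataclass
class TruthSet:
    gene_truth: pd.DataFrame    # index gene_id: class, m6a, span, exonic_length, te
    peak_truth: pd.DataFrame    # gene, chrom, strand, start, end, summit
    repeat_truth: pd.DataFrame  # locus_id, subfamily, planted flags
    target_truth: pd.DataFrame  # miRNA, gene


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def _plus_tx_to_genomic(exons: Sequence[Tuple[int, int]], a: int, b: int
                        ) -> List[Tuple[int, int]]:
    """Project a plus-orientation transcript range [a, b) onto the genome."""
    out = []
    off = 0
    for s, e in exons:
        n = e - s
        lo, hi = max(a, off), min(b, off + n)
        if lo < hi:
            out.append((s + (lo - off), s + (hi - off)))
        off += n
    return out


def _split_lengths(rng: np.random.Generator, total: int, k: int, minimum: int = 40
                   ) -> List[int]:
    if k == 1 or total < k * (minimum + 1):
        return [total]
    while True:
        cuts = np.sort(rng.integers(1, total, size=k - 1))
        parts = np.diff(np.concatenate([[0], cuts, [total]]))
        if (parts >= minimum).all():
            return [int(p) for p in parts]


def _make_transcript(rng: np.random.Generator, cfg: SimConfig, gid: str,
                     chrom: str, cursor: int, strand: str) -> TranscriptModel:
    u = int(rng.integers(*cfg.utr5_range))
    c = int(rng.integers(cfg.cds_range[0] // 3, cfg.cds_range[1] // 3)) * 3
    t = int(rng.integers(*cfg.utr3_range))
    total = u + c + 3 + t
    k = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
    exon_lens = _split_lengths(rng, total, k)
    exons = []
    pos = cursor
    for i, ln in enumerate(exon_lens):
        exons.append((pos, pos + ln))
        pos += ln
        if i < len(exon_lens) - 1:
            pos += int(rng.integers(*cfg.intron_range))
    if strand == "+":
        cds_rng, stop_rng = (u, u + c), (u + c, u + c + 3)
    else:
        cds_rng, stop_rng = (t + 3, t + 3 + c), (t, t + 3)
    cds = _plus_tx_to_genomic(exons, *cds_rng)
    stop = _plus_tx_to_genomic(exons, *stop_rng)
    return TranscriptModel(
        transcript_id=f"{gid}.t1", gene_id=gid, chrom=chrom, strand=strand,
        exons=exons, cds=cds, stop_codon=(stop[0][0], stop[-1][1]),
    )


def assign_gene_classes(cfg: SimConfig, gene_ids: Sequence[str],
                        rng: np.random.Generator) -> pd.Series:
    """Exact planted class counts; remaining genes are background."""
    labels = np.array(["background"] * len(gene_ids), dtype=object)
    order = rng.permutation(len(gene_ids))
    i = 0
    for klass, n in [("M-decay", cfg.n_mdecay), ("Z-decay", cfg.n_zdecay),
                     ("ZGA", cfg.n_zga), ("constant", cfg.n_constant)]:
        labels[order[i : i + n]] = klass
        i += n
    return pd.Series(labels, index=list(gene_ids), name="class")


def class_stage_template(cfg: SimConfig, klass: str, rng: np.random.Generator
                         ) -> Dict[str, float]:
    """Stage-mean TPM satisfying the class's defining inequalities with the
    configured margin (background avoids every rule)."""
    m = cfg.margin
    if klass == "M-decay":
        gv = 10.0 * m * m
        vals = {"GV": gv, "MII": gv / m, "1C": gv / (2 * m),
                "8C": gv / (2 * m * m), "2C": gv / (2 * m * 1.5), "BLT": gv / (4 * m * m)}
    elif klass == "Z-decay":
        gv = 10.0 * m * m
        vals = {"GV": gv, "MII": gv, "1C": gv, "8C": gv / (2 * m),
                "2C": gv / 1.2, "BLT": gv / (3 * m)}
    elif klass == "ZGA":
        lo = 1.0 / (2 * m)
        hi = 10.0 * m * m
        vals = {"GV": lo, "MII": lo, "1C": hi / 5, "2C": hi / 2, "8C": hi, "BLT": hi}
    elif klass == "constant":
        level = 10.0 * 2 * m
        vals = {st: level for st in STAGES}
    else:  # background: below every TPM gate
        base = float(rng.uniform(2.0, 8.0))
        vals = {st: base * float(rng.uniform(0.9, 1.1)) for st in STAGES}
    return {st: vals.get(st, vals.get("8C", 1.0)) for st in cfg.stages}


def simulate_annotation(cfg: SimConfig, seed: Optional[int] = None):
    """Build the genome, gene models, repeat annotation, homology table and
    the planted truth. Returns (bundle, repeats_df, consensus, homology_df,
    truth: TruthSet)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    gene_region_end = int(cfg.chrom_length * 0.5)

    genes: Dict[str, GeneModel] = {}
    transcripts: List[TranscriptModel] = []
    cursors = {c: 1000 for c in chroms}
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        cursor = cursors[chrom] + int(rng.integers(*cfg.gene_gap_range))
        tx = _make_transcript(rng, cfg, gid, chrom, cursor, strand)
        if tx.end > gene_region_end:
            need = tx.end - gene_region_end + cursors[chrom]
            raise ValueError(
                f"simulate: genome too small for {cfg.n_genes} genes; "
                f"chromosome length of at least ~{2 * (cfg.chrom_length + need)} bp required"
            )
        cursors[chrom] = tx.end
        genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                               start=tx.start, end=tx.end)
        transcripts.append(tx)

    # ---- planted gene truth ------------------------------------------------
    gene_ids = list(genes)
    classes = assign_gene_classes(cfg, gene_ids, rng)
    spans = pd.Series({g: genes[g].span_length for g in gene_ids})
    if cfg.m6a_long_bias:
        w = spans.to_numpy(float) ** 2
    else:
        w = np.ones(len(gene_ids))
    n_m6a = int(round(cfg.m6a_fraction * len(gene_ids)))
    chosen = rng.choice(len(gene_ids), size=n_m6a, replace=False, p=w / w.sum())
    m6a = pd.Series(False, index=gene_ids)
    m6a.iloc[chosen] = True

    # planted peak summit near the stop codon, in transcript coordinates
    peak_rows = []
    tx_by_gene = {tx.gene_id: tx for tx in transcripts}
    for gid in gene_ids:
        if not m6a[gid]:
            continue
        tx = tx_by_gene[gid]
        stop_first = tx.stop_codon[0] if tx.strand == "+" else tx.stop_codon[1] - 1
        stop_tx = tx.genomic_to_tx(stop_first)
        s_tx = stop_tx + rng.normal(0.0, cfg.summit_sd) if cfg.summit_sd > 0 else float(stop_tx)
        s_tx = int(np.clip(s_tx, cfg.peak_halfwidth, tx.exonic_length - cfg.peak_halfwidth - 1))
        # genomic summit position
        plus_pos = s_tx if tx.strand == "+" else tx.exonic_length - 1 - s_tx
        summit_iv = _plus_tx_to_genomic(tx.exons, plus_pos, plus_pos + 1)
        summit = summit_iv[0][0]
        peak_rows.append({"gene": gid, "chrom": tx.chrom, "strand": tx.strand,
                          "summit": summit, "summit_tx": s_tx,
                          "start": max(0, summit - cfg.peak_halfwidth),
                          "end": summit + cfg.peak_halfwidth})
    peak_truth = pd.DataFrame(peak_rows)

    gene_truth = pd.DataFrame({
        "class": classes,
        "m6a": m6a,
        "span": spans,
        "exonic_length": pd.Series({g: tx_by_gene[g].exonic_length for g in gene_ids}),
        "te": [cfg.te_base * (cfg.te_multiplier if m6a[g] else 1.0) for g in gene_ids],
    })

    # ---- sequence ----------------------------------------------------------
    sequence = {}
    for c in chroms:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.chrom_length)
        sequence[c] = arr
    for tx in transcripts:
        _write_sense(sequence[tx.chrom], tx.stop_codon[0], "TAA", tx.strand)
    for row in peak_rows:
        tx = tx_by_gene[row["gene"]]
        for _ in range(5):
            pos = int(rng.integers(row["start"], row["end"] - 5))
            _write_sense(sequence[tx.chrom], pos, "GGACT", tx.strand)
    sequence = {c: a.tobytes().decode() for c, a in sequence.items()}

    bundle = AnnotationBundle(genes=genes, transcripts=transcripts,
                              chrom_sizes=chrom_sizes, sequence=sequence)
    bundle.validate()

    repeats_df, consensus, repeat_truth = _simulate_repeats(cfg, rng, bundle)
    homology_df = _simulate_homology(cfg, rng, gene_ids)
    truth = TruthSet(gene_truth=gene_truth, peak_truth=peak_truth,
                     repeat_truth=repeat_truth, target_truth=pd.DataFrame())
    return bundle, repeats_df, consensus, homology_df, truth


def _write_sense(seq_arr: np.ndarray, pos: int, motif: str, strand: str) -> None:
    s = motif if strand == "+" else revcomp(motif)
    seq_arr[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype="S1")


def _simulate_repeats(cfg: SimConfig, rng: np.random.Generator,
                      bundle: AnnotationBundle):
    """Plant repeat loci in the repeat half of each chromosome; a configured
    fraction is fragmented (< 0.9 completeness), some overlap gene exons on
    purpose, and ERV elements come as full-length triplets, LTR pairs
    without internal sequence, or solo LTRs."""
    consensus = {sf: ln for sf, (_, ln, _, _) in SUBFAMILY_DEFS.items()}
    consensus[ERV_LTR[0]] = ERV_LTR[1]
    consensus[ERV_INT[0]] = ERV_INT[1]

    chroms = list(bundle.chrom_sizes)
    start_at = {c: int(cfg.chrom_length * 0.55) for c in chroms}
    rows: List[dict] = []
    truth_rows: List[dict] = []
    counter = 0

    def completeness_draw(incomplete: bool) -> float:
        if incomplete:
            return float(rng.uniform(0.3, 0.88))
        return float(rng.uniform(0.92, 1.0))

    def place(chrom: str, length: int) -> int:
        nonlocal start_at
        s = start_at[chrom] + int(rng.integers(*cfg.repeat_gap_range))
        if s + length > bundle.chrom_sizes[chrom]:
            raise ValueError(
                "simulate: genome too small for the requested repeat loci; "
                f"increase chrom_length above {s + length}"
            )
        start_at[chrom] = s + length
        return s

    exon_positions = [(tx.chrom, e) for tx in bundle.transcripts for e in tx.exons]

    for sf, (repclass, cons_len, part, family) in SUBFAMILY_DEFS.items():
        n = cfg.loci_per_subfamily
        n_incomplete = int(round(cfg.incomplete_fraction * n))
        n_exonic = int(round(cfg.exon_overlap_fraction * n))
        flags = (["incomplete"] * n_incomplete
                 + ["exonic"] * n_exonic
                 + ["clean"] * (n - n_incomplete - n_exonic))
        rng.shuffle(flags)
        for flag in flags:
            counter += 1
            lid = f"R{counter:05d}"
            c = completeness_draw(flag == "incomplete")
            length = max(30, int(round(c * cons_len)))
            chrom = chroms[counter % len(chroms)]
            strand = "+" if rng.random() < 0.5 else "-"
            if flag == "exonic" and exon_positions:
                echrom, (es, ee) = exon_positions[int(rng.integers(len(exon_positions)))]
                chrom, start = echrom, max(0, es - length // 2)
            else:
                start = place(chrom, length)
            rows.append({"locus_id": lid, "subfamily": sf, "repclass": repclass,
                         "chrom": chrom, "start": start, "end": start + length,
                         "strand": strand, "family": family, "part": part})
            truth_rows.append({"locus_id": lid, "subfamily": sf,
                               "completeness": c, "flag": flag,
                               "architecture": "solo" if part == "ltr" else "n/a",
                               "retained": flag == "clean" and c >= 0.9})

    # ERV elements
    n_full = int(round(cfg.full_length_fraction * cfg.n_erv_elements))
    n_pair = int(round(cfg.ltr_pair_fraction * cfg.n_erv_elements))
    kinds = (["full"] * n_full + ["pair"] * n_pair
             + ["solo"] * (cfg.n_erv_elements - n_full - n_pair))
    rng.shuffle(kinds)
    for kind in kinds:
        counter += 1
        chrom = chroms[counter % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "full":
            parts = [(ERV_LTR, "ltr"), (ERV_INT, "internal"), (ERV_LTR, "ltr")]
        elif kind == "pair":
            parts = [(ERV_LTR, "ltr"), (ERV_LTR, "ltr")]
        else:
            parts = [(ERV_LTR, "ltr")]
        ids = []
        seg_start = None
        seg_end = None
        for (sf, cons_len), part in parts:
            counter += 1
            lid = f"R{counter:05d}"
            ids.append(lid)
            c = float(rng.uniform(0.95, 1.0))
            length = int(round(c * cons_len))
            start = place(chrom, length)
            seg_start = start if seg_start is None else seg_start
            seg_end = start + length
            rows.append({"locus_id": lid, "subfamily": sf, "repclass": "LTR",
                         "chrom": chrom, "start": start, "end": start + length,
                         "strand": strand, "family": "HERVSIM", "part": part})
        start_at[chrom] += 600  # keep elements apart so runs never bridge them
        if kind == "full":
            truth_rows.append({"locus_id": "|".join(ids), "subfamily": ERV_INT[0],
                               "completeness": 1.0, "flag": kind,
                               "architecture": "full_length_ERV", "retained": True})
        else:
            # unassembled LTRs surface as individual solo loci
            for lid in ids:
                truth_rows.append({"locus_id": lid, "subfamily": ERV_LTR[0],
                                   "completeness": 1.0, "flag": kind,
                                   "architecture": "solo", "retained": True})

    return pd.DataFrame(rows), consensus, pd.DataFrame(truth_rows)


def _simulate_homology(cfg: SimConfig, rng: np.random.Generator,
                       gene_ids: Sequence[str]) -> pd.DataFrame:
    """One-to-one pairs for most genes, ~10% missing, plus deliberate
    many-to-one rows that the loader must drop."""
    rows = []
    for gid in gene_ids:
        r = rng.random()
        if r < 0.1:
            continue  # no homolog
        rows.append({"human_gene": gid, "mouse_gene": f"m{gid}"})
        if r > 0.95:  # many-to-one: second mouse counterpart
            rows.append({"human_gene": gid, "mouse_gene": f"m{gid}b"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage experiment
# ---------------------------------------------------------------------------

@dataclass
class StageData:
    tpm: pd.DataFrame                      # gene x sample
    transcript_tpm: pd.DataFrame           # transcript x sample
    sample_stage: Dict[str, str]
    input_tracks: Dict[str, List[BinnedTrack]]
    ip_tracks: Dict[str, List[BinnedTrack]]
    signal_tracks: Dict[str, List[BinnedTrack]]
    peaks: Dict[str, List[List[Peak]]]     # stage -> per-replicate peak lists
    mirna_counts: pd.DataFrame
    target_map: pd.DataFrame
    ribo_fpkm: pd.DataFrame
    mrna_fpkm: pd.DataFrame
    mouse_tpm: pd.DataFrame
    repeat_expression: pd.Series           # locus_id -> planted RPKM level
    repeat_modified: pd.Series             # locus_id -> planted modification


def simulate_expression_matrix(cfg: SimConfig, classes: pd.Series,
                               rng: np.random.Generator
                               ) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Per-gene, per-sample TPM with replicate noise; planted classes satisfy
    their defining inequalities with the configured margin."""
    samples = [f"{st}_rep{r + 1}" for st in cfg.stages for r in range(cfg.replicates)]
    sample_stage = {s: s.rsplit("_", 1)[0] for s in samples}
    data = np.zeros((len(classes), len(samples)))
    for i, gid in enumerate(classes.index):
        tpl = class_stage_template(cfg, classes[gid], rng)
        for j, s in enumerate(samples):
            noise = rng.lognormal(0.0, cfg.replicate_noise) if cfg.replicate_noise > 0 else 1.0
            data[i, j] = tpl[sample_stage[s]] * noise
    tpm = pd.DataFrame(data, index=list(classes.index), columns=samples)
    return tpm, sample_stage


def _bin_weights_for_peaks(cfg: SimConfig, bundle: AnnotationBundle,
                           peak_truth: pd.DataFrame, bin_size: int,
                           enrichment: float) -> Dict[str, np.ndarray]:
    """Per-bin IP weight: 1 outside peaks, a Gaussian profile reaching
    ``enrichment`` at the planted summit (width = peak_halfwidth / 2).

    Works for depleting factors too: enrichment < 1 carves a dip (0 erases
    IP coverage at the summit)."""
    w = {c: np.ones(n_bins(s, bin_size)) for c, s in bundle.chrom_sizes.items()}
    sigma = max(cfg.peak_halfwidth / 2.0, bin_size)
    amplify = enrichment >= 1.0
    for row in peak_truth.itertuples():
        a = w[row.chrom]
        b0 = max(0, (row.summit - 3 * cfg.peak_halfwidth) // bin_size)
        b1 = min(len(a) - 1, (row.summit + 3 * cfg.peak_halfwidth) // bin_size)
        centers = (np.arange(b0, b1 + 1) + 0.5) * bin_size
        profile = 1.0 + (enrichment - 1.0) * np.exp(
            -0.5 * ((centers - row.summit) / sigma) ** 2)
        if amplify:
            a[b0 : b1 + 1] = np.maximum(a[b0 : b1 + 1], profile)
        else:
            a[b0 : b1 + 1] = np.minimum(a[b0 : b1 + 1], profile)
    return w


def _apply_repeat_weights(w: Dict[str, np.ndarray], repeats_df: pd.DataFrame,
                          frag_expr: pd.Series, frag_mod: Mapping[str, bool],
                          e_eff: float, unmod_factor: float, bin_size: int) -> None:
    """Modified loci get a Gaussian IP bump reaching ``e_eff`` at the locus
    midpoint; unmodified expressed loci are flatly depleted."""
    for row in repeats_df.itertuples():
        if frag_expr[row.locus_id] <= 0:
            continue
        a = w[row.chrom]
        b0, b1 = row.start // bin_size, min((row.end - 1) // bin_size, len(a) - 1)
        if frag_mod.get(row.locus_id):
            mid = (row.start + row.end) / 2.0
            sigma = max(min((row.end - row.start) / 6.0, 200.0), bin_size)
            centers = (np.arange(b0, b1 + 1) + 0.5) * bin_size
            profile = 1.0 + (e_eff - 1.0) * np.exp(-0.5 * ((centers - mid) / sigma) ** 2)
            a[b0 : b1 + 1] = profile
        else:
            a[b0 : b1 + 1] = unmod_factor


def _base_coverage(bundle: AnnotationBundle, gene_tpm: pd.Series,
                   repeat_rows: pd.DataFrame, repeat_expr: pd.Series,
                   bin_size: int) -> Dict[str, np.ndarray]:
    """Expected Input RPKM per bin: TPM over gene exons, planted level over
    expressed repeat loci."""
    base = {c: np.zeros(n_bins(s, bin_size)) for c, s in bundle.chrom_sizes.items()}
    for tx in bundle.transcripts:
        v = float(gene_tpm.get(tx.gene_id, 0.0))
        if v <= 0:
            continue
        a = base[tx.chrom]
        for s, e in tx.exons:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                a[b] += v * (hi - lo) / bin_size
    for row in repeat_rows.itertuples():
        v = float(repeat_expr.get(row.locus_id, 0.0))
        if v <= 0:
            continue
        a = base[row.chrom]
        b0, b1 = row.start // bin_size, (row.end - 1) // bin_size
        a[b0 : b1 + 1] += v
    return base


def _noisy(rng: np.random.Generator, arr: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return arr.copy()
    return arr * rng.lognormal(0.0, sd, size=arr.shape)


def simulate_stage_experiment(cfg: SimConfig, bundle: AnnotationBundle,
                              truth: TruthSet, repeats_df: pd.DataFrame,
                              seed: Optional[int] = None,
                              bin_size: int = 10,
                              peak_threshold: float = 1.0,
                              peak_min_bins: int = 3) -> StageData:
    cfg.validate()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    classes = truth.gene_truth["class"]
    tpm, sample_stage = simulate_expression_matrix(cfg, classes, rng)
    transcript_tpm = tpm.copy()
    transcript_tpm.index = [f"{g}.t1" for g in tpm.index]

    # planted repeat status: exact counts over retained loci
    rep_truth = truth.repeat_truth.set_index("locus_id")
    retained = rep_truth[rep_truth["retained"]].index.to_list()
    n_expr = int(round(cfg.repeat_expressed_fraction * len(retained)))
    order = rng.permutation(len(retained))
    expressed_ids = [retained[i] for i in order[:n_expr]]
    n_mod = int(round(cfg.repeat_m6a_fraction * n_expr))
    modified_ids = set(expressed_ids[:n_mod])
    repeat_expr = pd.Series(0.0, index=rep_truth.index)
    for lid in expressed_ids:
        repeat_expr[lid] = float(rng.uniform(3.0, 12.0))
    repeat_modified = pd.Series(False, index=rep_truth.index)
    repeat_modified[list(modified_ids)] = True

    # expand composite (full-length ERV) truth ids onto their fragment rows
    frag_expr = pd.Series(0.0, index=repeats_df["locus_id"])
    frag_mod: Dict[str, bool] = {}
    for lid in rep_truth.index:
        for frag in str(lid).split("|"):
            frag_expr[frag] = repeat_expr[lid]
            frag_mod[frag] = bool(repeat_modified[lid])

    w_ip = _bin_weights_for_peaks(cfg, bundle, truth.peak_truth, bin_size,
                                  cfg.enrichment)
    _apply_repeat_weights(w_ip, repeats_df, frag_expr, frag_mod,
                          cfg.enrichment, cfg.unmodified_ip_factor, bin_size)

    input_tracks: Dict[str, List[BinnedTrack]] = {}
    ip_tracks: Dict[str, List[BinnedTrack]] = {}
    signal_tracks: Dict[str, List[BinnedTrack]] = {}
    peaks: Dict[str, List[List[Peak]]] = {}
    for st in cfg.stages:
        input_tracks[st], ip_tracks[st], signal_tracks[st], peaks[st] = [], [], [], []
        for r in range(cfg.replicates):
            sample = f"{st}_rep{r + 1}"
            base = _base_coverage(bundle, tpm[sample], repeats_df, frag_expr, bin_size)
            ip_exp = {c: base[c] * w_ip[c] for c in base}
            total_base = sum(a.sum() for a in base.values())
            total_ip = sum(a.sum() for a in ip_exp.values())
            scale = total_base / total_ip if total_ip > 0 else 1.0
            inp = BinnedTrack(bin_size, {c: _noisy(rng, base[c], cfg.replicate_noise)
                                         for c in base},
                              label=f"Input_{sample}", total_fragments=cfg.depth)
            ip = BinnedTrack(bin_size, {c: _noisy(rng, ip_exp[c] * scale, cfg.replicate_noise)
                                        for c in base},
                             label=f"IP_{sample}", total_fragments=cfg.depth)
            sig = compute_m6a_signal(ip, inp, label=f"signal_{sample}")
            called = call_peaks_naive(sig, threshold=peak_threshold,
                                      min_bins=peak_min_bins, replicate=f"rep{r + 1}")
            input_tracks[st].append(inp)
            ip_tracks[st].append(ip)
            signal_tracks[st].append(sig)
            peaks[st].append(called)

    mirna_counts, target_map = _simulate_mirna(cfg, rng, truth)
    ribo, mrna = _simulate_translation(cfg, rng, tpm, sample_stage, truth)
    mouse_tpm = _simulate_mouse(cfg, rng, tpm, sample_stage)

    return StageData(
        tpm=tpm, transcript_tpm=transcript_tpm, sample_stage=sample_stage,
        input_tracks=input_tracks, ip_tracks=ip_tracks,
        signal_tracks=signal_tracks, peaks=peaks,
        mirna_counts=mirna_counts, target_map=target_map,
        ribo_fpkm=ribo, mrna_fpkm=mrna, mouse_tpm=mouse_tpm,
        repeat_expression=repeat_expr, repeat_modified=repeat_modified,
    )


def _simulate_mirna(cfg: SimConfig, rng: np.random.Generator, truth: TruthSet):
    mirnas = [f"miR-{i + 1}" for i in range(cfg.n_mirnas)]
    n_cons = int(round(cfg.conserved_fraction * cfg.n_mirnas))
    conserved = {m: i < n_cons for i, m in enumerate(mirnas)}
    base = {m: float(rng.lognormal(3.0, 1.5)) for m in mirnas}
    rows = []
    mirna_stages = [st for st in cfg.stages if st in ("GV", "MII", "1C", "8C")]
    for st in mirna_stages:
        for r in range(cfg.replicates):
            for m in mirnas:
                lam = base[m] * float(rng.uniform(0.7, 1.3))
                rows.append({"miRNA": m, "stage": st, "replicate": f"rep{r + 1}",
                             "count": int(rng.poisson(lam)) + (1 if m == mirnas[0] else 0),
                             "conserved": conserved[m]})
    counts = pd.DataFrame(rows)

    genes = list(truth.gene_truth.index)
    m6a = truth.gene_truth["m6a"]
    trows = []
    for m in mirnas:
        if not conserved[m]:
            continue
        for g in genes:
            p = cfg.target_density * (cfg.mirna_m6a_bias if m6a[g] else 1.0)
            if rng.random() < min(p, 1.0):
                trows.append({"miRNA": m, "gene": g})
    target_map = pd.DataFrame(trows).drop_duplicates()
    truth.target_truth = target_map.copy()
    return counts, target_map


def _simulate_translation(cfg: SimConfig, rng: np.random.Generator,
                          tpm: pd.DataFrame, sample_stage: Mapping[str, str],
                          truth: TruthSet):
    """FPKM tables: mRNA mirrors TPM; Ribo = te * (mRNA + 1) - 1 with noise,
    te carrying the planted multiplier on m6A+ genes."""
    te = truth.gene_truth["te"]
    mrna = tpm.copy()
    ribo = pd.DataFrame(index=tpm.index, columns=tpm.columns, dtype=float)
    for col in tpm.columns:
        noise = (rng.lognormal(0.0, cfg.replicate_noise / 2, size=len(tpm))
                 if cfg.replicate_noise > 0 else np.ones(len(tpm)))
        ribo[col] = np.maximum(te.values * (mrna[col].values + 1.0) - 1.0, 0.0) * noise
    return ribo, mrna


def _simulate_mouse(cfg: SimConfig, rng: np.random.Generator,
                    tpm: pd.DataFrame, sample_stage: Mapping[str, str]) -> pd.DataFrame:
    """Mouse stage-mean TPM for homologs: mostly conserved scale, a fraction
    silenced to create species-specific categories."""
    stages = {}
    for s, st in sample_stage.items():
        stages.setdefault(st, []).append(s)
    human_stage = pd.DataFrame({st: tpm[cols].mean(axis=1) for st, cols in stages.items()})
    keep = [st for st in MOUSE_STAGES if st in human_stage.columns]
    scale = np.where(rng.random(len(tpm)) < 0.2, 0.02,
                     rng.uniform(0.8, 1.2, size=len(tpm)))
    mouse = human_stage[keep].mul(scale, axis=0)
    mouse.index = [f"m{g}" for g in tpm.index]
    return mouse


# ---------------------------------------------------------------------------
# condition experiment
# ---------------------------------------------------------------------------

@dataclass
class ConditionData:
    input_tracks: Dict[str, List[BinnedTrack]]   # condition -> replicates
    ip_tracks: Dict[str, List[BinnedTrack]]
    signal_tracks: Dict[str, List[BinnedTrack]]
    peaks: Dict[str, List[List[Peak]]]


def simulate_condition_experiment(cfg: SimConfig, bundle: AnnotationBundle,
                                  truth: TruthSet, repeats_df: pd.DataFrame,
                                  stage_data: StageData,
                                  seed: Optional[int] = None,
                                  bin_size: int = 10,
                                  peak_threshold: float = 1.0,
                                  peak_min_bins: int = 3) -> ConditionData:
    """Ctrl vs inhibitor: treated IP enrichment scaled by the reduction
    factor rho (peak weight e -> e*rho; rho=0 erases IP coverage at peaks)."""
    rho = cfg.inhibitor_reduction
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    frag_expr = pd.Series(0.0, index=repeats_df["locus_id"])
    frag_mod: Dict[str, bool] = {}
    rep_truth = truth.repeat_truth.set_index("locus_id")
    for lid in rep_truth.index:
        for frag in str(lid).split("|"):
            frag_expr[frag] = float(stage_data.repeat_expression.get(lid, 0.0))
            frag_mod[frag] = bool(stage_data.repeat_modified.get(lid, False))

    def weights(e_eff: float) -> Dict[str, np.ndarray]:
        w = _bin_weights_for_peaks(cfg, bundle, truth.peak_truth, bin_size, e_eff)
        _apply_repeat_weights(w, repeats_df, frag_expr, frag_mod, e_eff,
                              cfg.unmodified_ip_factor, bin_size)
        return w

    sample = f"{cfg.stages[0]}_rep1"
    gene_tpm = stage_data.tpm[sample]
    base = _base_coverage(bundle, gene_tpm, repeats_df, frag_expr, bin_size)
    out = ConditionData(input_tracks={}, ip_tracks={}, signal_tracks={}, peaks={})
    for cond, factor in [("ctrl", 1.0), ("treated", rho)]:
        w = weights(cfg.enrichment * factor)
        ip_exp = {c: base[c] * w[c] for c in base}
        total_base = sum(a.sum() for a in base.values())
        total_ip = sum(a.sum() for a in ip_exp.values())
        scale = total_base / total_ip if total_ip > 0 else 1.0
        out.input_tracks[cond] = []
        out.ip_tracks[cond] = []
        out.signal_tracks[cond] = []
        out.peaks[cond] = []
        for r in range(cfg.replicates):
            inp = BinnedTrack(bin_size, {c: _noisy(rng, base[c], cfg.replicate_noise)
                                         for c in base},
                              label=f"Input_{cond}_rep{r + 1}")
            ip = BinnedTrack(bin_size, {c: _noisy(rng, ip_exp[c] * scale, cfg.replicate_noise)
                                        for c in base},
                             label=f"IP_{cond}_rep{r + 1}")
            sig = compute_m6a_signal(ip, inp, label=f"signal_{cond}_rep{r + 1}")
            out.input_tracks[cond].append(inp)
            out.ip_tracks[cond].append(ip)
            out.signal_tracks[cond].append(sig)
            out.peaks[cond].append(call_peaks_naive(sig, threshold=peak_threshold,
                                                    min_bins=peak_min_bins,
                                                    replicate=f"{cond}_rep{r + 1}"))
    return out


# ---------------------------------------------------------------------------
# exact-depth fragment sampling (count-level tests)
# ---------------------------------------------------------------------------

def sample_fragments(base: Dict[str, np.ndarray], bin_size: int, depth: int,
                     rng: np.random.Generator, fragment_length: int = 100,
                     chrom_sizes: Optional[Dict[str, int]] = None
                     ) -> List[Tuple[str, int, int]]:
    """Draw exactly ``depth`` fragments, bins weighted by expected coverage
    (uniform when the expectation is everywhere zero)."""
    chroms = sorted(base)
    flat = np.concatenate([base[c] for c in chroms])
    if flat.sum() <= 0:
        flat = np.ones_like(flat)
    p = flat / flat.sum()
    picks = rng.choice(len(flat), size=depth, p=p)
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = (off, off + len(base[c]))
        off += len(base[c])
    frags = []
    for i in picks:
        for c in chroms:
            lo, hi = offsets[c]
            if lo <= i < hi:
                start = (i - lo) * bin_size
                size = chrom_sizes[c] if chrom_sizes else (hi - lo) * bin_size
                end = min(start + fragment_length, size)
                frags.append((c, start, end))
                break
    return frags


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(outdir, cfg: SimConfig, bundle: AnnotationBundle,
                     repeats_df: pd.DataFrame, consensus: Mapping[str, int],
                     homology_df: pd.DataFrame, truth: TruthSet,
                     data: StageData, cond: Optional[ConditionData] = None) -> None:
    out = Path(outdir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    mio.write_chrom_sizes(bundle.chrom_sizes, out / "chrom.sizes")
    mio.write_fasta(bundle.sequence, out / "genome.fa")
    mio.write_gene_models(bundle, out / "annotation.gtf")
    repeats_df.to_csv(out / "repeats.tsv", sep="\t", index=False)
    pd.DataFrame({"subfamily": list(consensus), "length": list(consensus.values())}
                 ).to_csv(out / "consensus_lengths.tsv", sep="\t", index=False)
    homology_df.to_csv(out / "homology.tsv", sep="\t", index=False)

    mio.write_tsv(data.tpm.rename_axis("gene"), out / "expression_tpm.tsv")
    mio.write_tsv(data.transcript_tpm.rename_axis("transcript"),
                  out / "transcript_tpm.tsv")
    mio.write_tsv(data.mouse_tpm.rename_axis("gene"), out / "mouse_tpm.tsv")
    data.mirna_counts.to_csv(out / "mirna_counts.tsv", sep="\t", index=False)
    data.target_map.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    mio.write_tsv(data.ribo_fpkm.rename_axis("gene"), out / "ribo_fpkm.tsv")
    mio.write_tsv(data.mrna_fpkm.rename_axis("gene"), out / "mrna_fpkm.tsv")
    pd.DataFrame([{"sample": s, "stage": st} for s, st in data.sample_stage.items()]
                 ).to_csv(out / "samples.tsv", sep="\t", index=False)

    for st in cfg.stages:
        for r in range(cfg.replicates):
            tag = f"{st}_rep{r + 1}"
            mio.write_signal_track(data.input_tracks[st][r], bundle.chrom_sizes,
                                   out / "tracks" / f"input_{tag}.bedgraph")
            mio.write_signal_track(data.ip_tracks[st][r], bundle.chrom_sizes,
                                   out / "tracks" / f"ip_{tag}.bedgraph")
            mio.write_peaks(data.peaks[st][r], out / "peaks" / f"{tag}.narrowPeak")

    if cond is not None:
        (out / "condition").mkdir(exist_ok=True)
        for c in cond.input_tracks:
            for r in range(len(cond.input_tracks[c])):
                tag = f"{c}_rep{r + 1}"
                mio.write_signal_track(cond.input_tracks[c][r], bundle.chrom_sizes,
                                       out / "condition" / f"input_{tag}.bedgraph")
                mio.write_signal_track(cond.ip_tracks[c][r], bundle.chrom_sizes,
                                       out / "condition" / f"ip_{tag}.bedgraph")
                mio.write_peaks(cond.peaks[c][r],
                                out / "condition" / f"peaks_{tag}.narrowPeak")

    truth.gene_truth.rename_axis("gene").to_csv(out / "truth" / "genes.tsv", sep="\t")
    truth.peak_truth.to_csv(out / "truth" / "peaks.tsv", sep="\t", index=False)
    rt = truth.repeat_truth.copy()
    rt["expression"] = rt["locus_id"].map(data.repeat_expression).fillna(0.0)
    rt["modified"] = rt["locus_id"].map(data.repeat_modified).fillna(False)
    rt.to_csv(out / "truth" / "repeats.tsv", sep="\t", index=False)
    truth.target_truth.to_csv(out / "truth" / "targets.tsv", sep="\t", index=False)
    pd.Series(dataclasses.asdict(cfg)).to_json(out / "sim_config.json")
    log.info("simulation written to %s", out)
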