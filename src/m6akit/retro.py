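"""Retrotransposon locus filtering, locus-level expression / m6A scoring,
subfamily summaries, element-scaled profiles and condition comparisons.

Filtering rules: LINE / SINE / SVA / solo-LTR loci are kept when annotated
length / consensus length >= 0.9 (closed boundary); full-length ERVs are
assembled from same-strand 5'LTR + internal + 3'LTR fragment runs of one
element family within a gap tolerance; loci overlapping any annotated exon
by >= 1 bp are removed. A locus is "expressed" when its max-over-bins Input
RPKM is > 0 and "modified" when its max-over-bins m6A signal is > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import AnnotationBundle, Peak, RepeatLocus
from .dynamics import GroupComparisonResult, compare_groups
from .signal import BinnedTrack

log = logging.getLogger("m6akit.retro")

REPEAT_COLUMNS = ["locus_id", "subfamily", "repclass", "chrom", "start", "end",
                  "strand", "family", "part"]


def read_repeats(path) -> pd.DataFrame:
    """RepeatMasker/HERVd-style TSV: locus_id, subfamily, repclass, chrom,
    start, end, strand, family, part (ltr | internal | '.')."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REPEAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read_repeats: missing columns {sorted(missing)}")
    return df


def read_consensus_lengths(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _exon_union(bundle: AnnotationBundle) -> Dict[str, List[Tuple[int, int]]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for tx in bundle.transcripts:
        by_chrom.setdefault(tx.chrom, []).extend(tx.exons)
    return {c: iv.merge(v) for c, v in by_chrom.items()}


def _assemble_full_length(
    fragments: pd.DataFrame, consensus: Mapping[str, int], gap: int
) -> Tuple[List[RepeatLocus], pd.DataFrame]:
    """Group LTR-class fragments into full-length ERVs (LTR, internal, LTR
    runs, same chrom / strand / family, gaps <= ``gap``). Returns assembled
    loci and the LTR fragments left unused (solo-LTR candidates)."""
    full: List[RepeatLocus] = []
    used_idx: set = set()
    for (chrom, strand, family), grp in fragments.groupby(["chrom", "strand", "family"]):
        grp = grp.sort_values("start")
        rows = list(grp.itertuples())
        i = 0
        while i + 2 < len(rows):
            a, b, c = rows[i], rows[i + 1], rows[i + 2]
            pattern_ok = (a.part == "ltr" and b.part == "internal" and c.part == "ltr")
            gaps_ok = (b.start - a.end <= gap) and (c.start - b.end <= gap)
            if pattern_ok and gaps_ok:
                ann_len = (a.end - a.start) + (b.end - b.start) + (c.end - c.start)
                cons = consensus.get(a.subfamily, 0) + consensus.get(b.subfamily, 0) + \
                    consensus.get(c.subfamily, 0)
                full.append(RepeatLocus(
                    locus_id=f"{a.locus_id}|{b.locus_id}|{c.locus_id}",
                    subfamily=str(b.subfamily),
                    repclass="LTR",
                    chrom=chrom,
                    start=int(a.start),
                    end=int(c.end),
                    strand=strand,
                    completeness=ann_len / cons if cons else 0.0,
                    architecture="full_length_ERV",
                ))
                used_idx.update({a.Index, b.Index, c.Index})
                i += 3
            else:
                i += 1
    leftover = fragments.loc[[i for i in fragments.index if i not in used_idx]]
    solo_candidates = leftover[leftover["part"] == "ltr"]
    return full, solo_candidates


def filter_repeat_loci(
    repeats: pd.DataFrame,
    consensus: Mapping[str, int],
    bundle: AnnotationBundle,
    min_completeness: float = 0.9,
    fl_gap: int = 500,
) -> List[RepeatLocus]:
    """Apply the completeness / architecture / exon-overlap filters."""
    for sf in repeats["subfamily"].unique():
        if sf not in consensus:
            raise ValueError(f"filter_repeat_loci: no consensus length for {sf}")

    simple = repeats[repeats["repclass"].isin(["LINE", "SINE", "SVA"])]
    ltr = repeats[repeats["repclass"] == "LTR"]

    loci: List[RepeatLocus] = []
    n_incomplete = 0
    for row in simple.itertuples():
        c = (row.end - row.start) / consensus[row.subfamily]
        if c >= min_completeness:
            loci.append(RepeatLocus(
                locus_id=str(row.locus_id), subfamily=str(row.subfamily),
                repclass=str(row.repclass), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), strand=str(row.strand),
                completeness=c, architecture="n/a",
            ))
        else:
            n_incomplete += 1

    full, solo_candidates = _assemble_full_length(ltr, consensus, fl_gap)
    loci.extend(full)
    for row in solo_candidates.itertuples():
        c = (row.end - row.start) / consensus[row.subfamily]
        if c >= min_completeness:
            loci.append(RepeatLocus(
                locus_id=str(row.locus_id), subfamily=str(row.subfamily),
                repclass="LTR", chrom=str(row.chrom), start=int(row.start),
                end=int(row.end), strand=str(row.strand), completeness=c,
                architecture="solo",
            ))
        else:
            n_incomplete += 1

    exons = _exon_union(bundle)
    kept = [l for l in loci
            if not iv.overlaps_any(l.start, l.end, exons.get(l.chrom, []))]
    n_exonic = len(loci) - len(kept)
    log.info(
        "filter_repeat_loci: %d rows in -> %d kept (%d below completeness, "
        "%d removed for exon overlap, %d full-length ERVs assembled)",
        len(repeats), len(kept), n_incomplete, n_exonic, len(full),
    )
    return kept


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _max_over_bins(track: BinnedTrack, locus: RepeatLocus) -> float:
    a = track.data.get(locus.chrom)
    if a is None:
        raise ValueError(f"score: chromosome {locus.chrom} missing from track")
    bs = track.bin_size
    b0, b1 = locus.start // bs, (locus.end - 1) // bs
    if b1 >= len(a):
        raise ValueError(f"score: locus {locus.locus_id} outside track bounds")
    return float(a[b0 : b1 + 1].max())


def score_repeat_loci(
    loci: Sequence[RepeatLocus],
    input_tracks: Mapping[str, Sequence[BinnedTrack]],
    signal_tracks: Mapping[str, Sequence[BinnedTrack]],
) -> pd.DataFrame:
    """Per locus and stage: expression = mean over replicates of the max
    Input RPKM over bins overlapping the locus; m6A analogous on the signal
    track. Long-form output with expressed / modified flags."""
    rows = []
    for locus in loci:
        for stage in input_tracks:
            expr = float(np.mean([_max_over_bins(t, locus) for t in input_tracks[stage]]))
            sig = float(np.mean([_max_over_bins(t, locus) for t in signal_tracks[stage]]))
            rows.append({
                "locus_id": locus.locus_id, "subfamily": locus.subfamily,
                "repclass": locus.repclass, "architecture": locus.architecture,
                "chrom": locus.chrom, "start": locus.start, "end": locus.end,
                "strand": locus.strand, "stage": stage,
                "expression": expr, "m6a_signal": sig,
                "expressed": expr > 0, "modified": sig > 0,
            })
    return pd.DataFrame(rows)


def subfamily_summary(scores: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Per subfamily at one stage: expressed loci, modified among expressed,
    percent modified (missing when nothing is expressed)."""
    sub = scores[scores["stage"] == stage]
    rows = []
    for sf, grp in sub.groupby("subfamily"):
        expressed = grp[grp["expressed"]]
        n_expr = len(expressed)
        n_mod = int(expressed["modified"].sum())
        pct = 100.0 * n_mod / n_expr if n_expr else np.nan
        rows.append({"subfamily": sf, "stage": stage, "n_loci": len(grp),
                     "n_expressed": n_expr, "n_modified": n_mod, "pct_modified": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# element-scaled profiles
# ---------------------------------------------------------------------------

@dataclass
class ElementProfile:
    subfamily: str
    mean: np.ndarray
    sd: np.ndarray
    n_loci: int


def element_profile(
    loci: Sequence[RepeatLocus],
    signal: BinnedTrack,
    n_bins: int = 100,
) -> ElementProfile:
    """Scale every locus to ``n_bins`` relative positions oriented 5'->3'
    (minus-strand loci reversed); each segment's value is the mean of the
    overlapping fixed-width signal bins; profile = per-segment mean and SD
    across loci."""
    if not loci:
        raise ValueError("element_profile: need >= 1 locus")
    bs = signal.bin_size
    mat = np.zeros((len(loci), n_bins))
    for i, locus in enumerate(loci):
        a = signal.data[locus.chrom]
        edges = np.linspace(locus.start, locus.end, n_bins + 1)
        for j in range(n_bins):
            s, e = edges[j], edges[j + 1]
            b0, b1 = int(s // bs), int(np.ceil(e / bs)) - 1
            b1 = min(b1, len(a) - 1)
            mat[i, j] = a[b0 : b1 + 1].mean()
        if locus.strand == "-":
            mat[i] = mat[i][::-1]
    return ElementProfile(
        subfamily=loci[0].subfamily,
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0),
        n_loci=len(loci),
    )


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    n_associated_ctrl: int
    n_associated_treated: int
    pct_reduction: Optional[float]  # None when ctrl count is 0
    per_subfamily: pd.DataFrame     # subfamily, p_value, medians


def _count_associated(peaks: Sequence[Peak], loci: Sequence[RepeatLocus]) -> int:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
    by_chrom = {c: iv.merge(v) for c, v in by_chrom.items()}
    return sum(1 for p in peaks
               if iv.overlaps_any(p.start, p.end, by_chrom.get(p.chrom, [])))


def condition_peak_comparison(
    peaks_ctrl: Sequence[Peak],
    peaks_treated: Sequence[Peak],
    loci: Sequence[RepeatLocus],
    scores_ctrl: Optional[pd.DataFrame] = None,
    scores_treated: Optional[pd.DataFrame] = None,
) -> ConditionComparison:
    """Retrotransposon-associated peak counts per condition (overlap >= 1 bp
    with any retained locus) and per-subfamily two-sided Wilcoxon on locus
    m6A signal between conditions."""
    n_ctrl = _count_associated(peaks_ctrl, loci)
    n_trt = _count_associated(peaks_treated, loci)
    reduction = 100.0 * (n_ctrl - n_trt) / n_ctrl if n_ctrl else None

    rows = []
    if scores_ctrl is not None and scores_treated is not None:
        for sf in sorted(scores_ctrl["subfamily"].unique()):
            a = scores_ctrl.loc[scores_ctrl["subfamily"] == sf, "m6a_signal"]
            b = scores_treated.loc[scores_treated["subfamily"] == sf, "m6a_signal"]
            if len(a) < 2 or len(b) < 2:
                continue
            res = compare_groups(a, b)
            rows.append({"subfamily": sf, "p_value": res.p_value,
                         "median_ctrl": float(a.median()),
                         "median_treated": float(b.median()),
                         "n_loci": len(a)})
    per_subfamily = pd.DataFrame(rows)
    return ConditionComparison(
        n_associated_ctrl=n_ctrl,
        n_associated_treated=n_trt,
        pct_reduction=reduction,
        per_subfamily=per_subfamily,
    )
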