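"""miRNA expression normalization and m6A-targeting association, plus
translation-efficiency computation and its m6A association.

miRNA expression is normalized to reads per million within each replicate
and averaged across replicates of a stage. A gene counts as targeted at a
stage when >= 1 conserved, highly expressed (RPM >= 10) miRNA targets it;
the weighted count is the sum of log10(RPM) over those miRNAs. Translation
efficiency is (mean Ribo FPKM + 1) / (mean mRNA FPKM + 1) for genes with
mean mRNA FPKM >= 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dynamics import GroupComparisonResult, compare_groups, five_number_summary

log = logging.getLogger("m6akit.translation")


# ---------------------------------------------------------------------------
# miRNA expression
# ---------------------------------------------------------------------------

def mirna_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize miRNA read counts to RPM and average over replicates.

    ``counts`` is long-form with columns miRNA, stage, replicate, count (a
    ``conserved`` column is carried through when present). Returns per-stage
    mean RPM, long-form: miRNA, stage, rpm[, conserved].
    """
    required = {"miRNA", "stage", "replicate", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"mirna_rpm: need columns {sorted(required)}")
    df = counts.copy()
    totals = df.groupby(["stage", "replicate"])["count"].transform("sum")
    if (totals == 0).any():
        bad = df.loc[totals == 0, ["stage", "replicate"]].drop_duplicates()
        raise ValueError(f"mirna_rpm: zero-total replicate(s): {bad.values.tolist()}")
    df["rpm"] = df["count"] / totals * 1e6
    keys = ["miRNA", "stage"]
    agg = {"rpm": "mean"}
    if "conserved" in df.columns:
        agg["conserved"] = "first"
    out = df.groupby(keys, as_index=False).agg(agg)
    return out


# ---------------------------------------------------------------------------
# targeting association
# ---------------------------------------------------------------------------

@dataclass
class TargetingResult:
    per_gene: pd.DataFrame  # gene, m6a, targeted, n_mirnas, weighted
    fisher: GroupComparisonResult
    wilcoxon_counts: Optional[GroupComparisonResult]
    wilcoxon_weighted: Optional[GroupComparisonResult]


def mirna_targeting(
    m6a_status: Mapping[str, bool],
    target_map: pd.DataFrame,
    expression: pd.DataFrame,
    stage: str,
    rpm_min: float = 10.0,
) -> TargetingResult:
    """Associate m6A status with miRNA targeting at one stage.

    ``m6a_status`` maps protein-coding gene id -> m6A+ flag; ``target_map``
    has columns (miRNA, gene), already restricted to conserved targets;
    ``expression`` is the mirna_rpm output. Only conserved miRNAs with stage
    RPM >= rpm_min count.
    """
    if target_map.empty:
        raise ValueError("mirna_targeting: empty target map")
    expr = expression[expression["stage"] == stage]
    if "conserved" in expr.columns:
        expr = expr[expr["conserved"].astype(bool)]
    rpm = expr.set_index("miRNA")["rpm"]
    active = rpm[rpm >= rpm_min]

    tmap = target_map[target_map["miRNA"].isin(active.index)]
    per_mirna_weight = np.log10(active)

    rows = []
    grouped = tmap.groupby("gene")["miRNA"].apply(list)
    for gene, flag in m6a_status.items():
        mirnas = grouped.get(gene, [])
        weighted = float(sum(per_mirna_weight[m] for m in mirnas))
        rows.append({"gene": gene, "m6a": bool(flag), "targeted": len(mirnas) > 0,
                     "n_mirnas": len(mirnas), "weighted": weighted})
    per_gene = pd.DataFrame(rows)

    pos = per_gene[per_gene["m6a"]]
    neg = per_gene[~per_gene["m6a"]]
    table = [
        [int(pos["targeted"].sum()), int((~pos["targeted"]).sum())],
        [int(neg["targeted"].sum()), int((~neg["targeted"]).sum())],
    ]
    fisher = compare_groups(table, test="fisher_one_sided")
    wc = ww = None
    if len(pos) >= 2 and len(neg) >= 2:
        wc = compare_groups(pos["n_mirnas"], neg["n_mirnas"])
        ww = compare_groups(pos["weighted"], neg["weighted"])
    return TargetingResult(per_gene=per_gene, fisher=fisher,
                           wilcoxon_counts=wc, wilcoxon_weighted=ww)


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def translation_efficiency(
    ribo: pd.DataFrame,
    mrna: pd.DataFrame,
    sample_stage_ribo: Mapping[str, str],
    sample_stage_mrna: Mapping[str, str],
    fpkm_min: float = 10.0,
) -> pd.DataFrame:
    """Per gene and stage: TE = (mean Ribo FPKM + 1) / (mean mRNA FPKM + 1),
    restricted to genes with mean mRNA FPKM >= ``fpkm_min`` at that stage.

    Returns long-form: gene, stage, ribo_fpkm, mrna_fpkm, te, included.
    """
    ribo_stages: Dict[str, list] = {}
    for s, st in sample_stage_ribo.items():
        ribo_stages.setdefault(st, []).append(s)
    mrna_stages: Dict[str, list] = {}
    for s, st in sample_stage_mrna.items():
        mrna_stages.setdefault(st, []).append(s)
    common = sorted(set(ribo_stages) & set(mrna_stages))
    missing = set(ribo_stages) ^ set(mrna_stages)
    if not common:
        raise ValueError("translation_efficiency: no stage present in both assays")
    if missing:
        log.info("translation_efficiency: stages without pairing skipped: %s",
                 sorted(missing))
    rows = []
    genes = ribo.index.intersection(mrna.index)
    for st in common:
        r = ribo.loc[genes, ribo_stages[st]].mean(axis=1)
        m = mrna.loc[genes, mrna_stages[st]].mean(axis=1)
        te = (r + 1.0) / (m + 1.0)
        inc = m >= fpkm_min
        for g in genes:
            rows.append({"gene": g, "stage": st, "ribo_fpkm": float(r[g]),
                         "mrna_fpkm": float(m[g]), "te": float(te[g]),
                         "included": bool(inc[g])})
    return pd.DataFrame(rows)


def te_association(
    te_table: pd.DataFrame,
    m6a_status: Mapping[str, bool],
    stage: str,
) -> Tuple[GroupComparisonResult, pd.DataFrame]:
    """Two-sided Wilcoxon of TE between m6A+ and m6A- genes at one stage."""
    sub = te_table[(te_table["stage"] == stage) & te_table["included"]]
    sub = sub[sub["gene"].isin(m6a_status)]
    flags = sub["gene"].map(lambda g: bool(m6a_status[g]))
    pos = sub.loc[flags.values, "te"]
    neg = sub.loc[(~flags).values, "te"]
    res = compare_groups(pos, neg)
    return res, sub.assign(m6a=flags.values)


def te_by_peak_region(
    te_table: pd.DataFrame,
    gene_regions: Mapping[str, Set[str]],
    constant_m6a_genes: Iterable[str],
    stage: str,
) -> pd.DataFrame:
    """Grouped TE summaries per modification region for constant m6A+ genes.

    A gene contributes to every region ({5UTR, CDS, stop_codon, 3UTR}) in
    which it has a peak summit.
    """
    regions = ["5UTR", "CDS", "stop_codon", "3UTR"]
    sub = te_table[(te_table["stage"] == stage) & te_table["included"]]
    te = sub.set_index("gene")["te"]
    keep = [g for g in constant_m6a_genes if g in te.index and g in gene_regions]
    rows = []
    for region in regions:
        vals = [float(te[g]) for g in keep if region in gene_regions[g]]
        if not vals:
            continue
        summary = five_number_summary(vals)
        summary.update({"region": region, "n": len(vals)})
        rows.append(summary)
    if not rows:
        log.warning("te_by_peak_region: no constant m6A+ genes with region data")
        return pd.DataFrame(columns=["region", "n", "p5", "p25", "p50", "p75", "p95", "mean"])
    return pd.DataFrame(rows)[["region", "n", "p5", "p25", "p50", "p75", "p95", "mean"]]
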