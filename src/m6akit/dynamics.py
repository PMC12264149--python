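"""Expression normalization, maternal-decay/ZGA classification, cross-species
homolog expression categories and grouped statistical comparisons.

Classification rules are evaluated literally on stage-averaged TPM:

M-decay: TPM_GV > 10; TPM_GV > TPM_MII; GV/8C > 2; GV/1C > 2; GV/MII < 2.
Z-decay: TPM_GV > 10; 1C/GV < 1.5; GV/8C > 2; GV/1C < 2; 1C/8C > 2.
ZGA:     TPM < 1 in GV and MII; TPM > 10 at 8C; 8C > 1C.
Constant: entropy specificity < 0.5 and TPM >= 10 in every sample.

Fold change A versus B is TPM_A / TPM_B; x/0 with x > 0 is +inf and 0/0
makes the condition false. M-decay is evaluated before Z-decay; a gene
meeting both keeps the M-decay label and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("m6akit.dynamics")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_expression(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors (the DESeq method).

    Reference is the per-gene geometric mean across samples over genes
    positive in every sample; each sample is divided by the median ratio to
    that reference. Returns (normalized matrix, factors).
    """
    if matrix.shape[1] == 0:
        raise ValueError("normalize_expression: no samples")
    if matrix.shape[1] == 1:
        return matrix.copy(), pd.Series([1.0], index=matrix.columns)
    positive = (matrix > 0).all(axis=1)
    if not positive.any():
        raise ValueError("normalize_expression: no gene positive in all samples")
    sub = matrix.loc[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_ref, axis=0).median(axis=0))
    return matrix.div(factors, axis=1), factors


def stage_means(matrix: pd.DataFrame, sample_stage: Dict[str, str]) -> pd.DataFrame:
    """Average replicate columns into one column per stage."""
    stages = {}
    for sample in matrix.columns:
        stages.setdefault(sample_stage[sample], []).append(sample)
    return pd.DataFrame({st: matrix[cols].mean(axis=1) for st, cols in stages.items()})


# ---------------------------------------------------------------------------
# maternal / zygotic classification
# ---------------------------------------------------------------------------

def _fc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fold change a/b with x/0 -> inf (x>0) and 0/0 -> NaN (condition false)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.divide(a, b)
    out[(a == 0) & (b == 0)] = np.nan
    return out


def entropy_specificity(values: Sequence[float]) -> float:
    """KL divergence (base 2) of the cross-sample distribution from uniform:
    sum p_i log2(N p_i) with 0*log 0 := 0."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("entropy_specificity: need >= 2 values")
    if (x < 0).any():
        raise ValueError("entropy_specificity: negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("entropy_specificity: all-zero vector")
    p = x / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(len(x) * p[nz])))


@dataclass
class StageClassification:
    labels: pd.Series       # gene -> M-decay | Z-decay | ZGA | constant | none
    entropy: pd.Series      # per-gene entropy specificity over all samples
    decay_overlap: pd.Series  # genes meeting both M- and Z-decay rules

    def genes(self, label: str) -> List[str]:
        return list(self.labels.index[self.labels == label])


def classify_maternal_zga(
    stage_tpm: pd.DataFrame,
    sample_tpm: Optional[pd.DataFrame] = None,
    gv_tpm_min: float = 10.0,
    zga_oocyte_max: float = 1.0,
    zga_8c_min: float = 10.0,
    constant_tpm_min: float = 10.0,
    entropy_max: float = 0.5,
) -> StageClassification:
    """Classify genes from stage-averaged TPM (columns GV, MII, 1C, 8C
    required). ``sample_tpm`` (all Input samples) drives the entropy score
    and the constant-gene rule; it defaults to ``stage_tpm``."""
    for st in ("GV", "MII", "1C", "8C"):
        if st not in stage_tpm.columns:
            raise ValueError(f"classify_maternal_zga: missing stage {st}")
    if sample_tpm is None:
        sample_tpm = stage_tpm
    gv = stage_tpm["GV"].to_numpy(float)
    mii = stage_tpm["MII"].to_numpy(float)
    c1 = stage_tpm["1C"].to_numpy(float)
    c8 = stage_tpm["8C"].to_numpy(float)

    m_decay = (
        (gv > gv_tpm_min)
        & (gv > mii)
        & (_fc(gv, c8) > 2)
        & (_fc(gv, c1) > 2)
        & (_fc(gv, mii) < 2)
    )
    z_decay = (
        (gv > gv_tpm_min)
        & (_fc(c1, gv) < 1.5)
        & (_fc(gv, c8) > 2)
        & (_fc(gv, c1) < 2)
        & (_fc(c1, c8) > 2)
    )
    zga = (
        (gv < zga_oocyte_max)
        & (mii < zga_oocyte_max)
        & (c8 > zga_8c_min)
        & (c8 > c1)
    )

    ent = sample_tpm.apply(
        lambda row: entropy_specificity(row.to_numpy(float)) if row.sum() > 0 else np.inf,
        axis=1,
    )
    constant = (ent < entropy_max) & (sample_tpm >= constant_tpm_min).all(axis=1)

    labels = pd.Series("none", index=stage_tpm.index, dtype=object)
    labels[constant.reindex(stage_tpm.index, fill_value=False)] = "constant"
    labels[zga] = "ZGA"
    labels[z_decay] = "Z-decay"
    labels[m_decay] = "M-decay"

    overlap = pd.Series(m_decay & z_decay, index=stage_tpm.index)
    if overlap.any():
        log.info("classify: %d genes satisfy both M- and Z-decay; labeled M-decay",
                 int(overlap.sum()))
    counts = labels.value_counts().to_dict()
    log.info("classify: %s", counts)
    return StageClassification(labels=labels, entropy=ent.reindex(stage_tpm.index),
                               decay_overlap=overlap)


# ---------------------------------------------------------------------------
# human-mouse homolog expression categories
# ---------------------------------------------------------------------------

def load_homology(path) -> pd.DataFrame:
    """Two-column TSV (human_gene, mouse_gene); any gene appearing in more
    than one row is omitted entirely (no >1 homologous counterpart)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={df.columns[0]: "human_gene", df.columns[1]: "mouse_gene"})
    before = len(df)
    multi_h = df["human_gene"].duplicated(keep=False)
    multi_m = df["mouse_gene"].duplicated(keep=False)
    df = df[~(multi_h | multi_m)].reset_index(drop=True)
    log.info("homology: %d pairs in, %d one-to-one retained", before, len(df))
    return df


def classify_homolog_expression(
    human: pd.DataFrame,
    mouse: pd.DataFrame,
    homology: pd.DataFrame,
    stage_pairs: Sequence[Tuple[str, str]],
    coexpressed_min: float = 50.0,
    specific_max: float = 10.0,
) -> pd.DataFrame:
    """Per homolog pair and stage pair: co-expressed (TPM >= 50 both),
    human-specific (>= 50 human, <= 10 mouse), mouse-specific (mirror),
    else ambiguous."""
    rows = []
    for h_stage, m_stage in stage_pairs:
        if h_stage not in human.columns:
            raise ValueError(f"classify_homolog_expression: human stage {h_stage} missing")
        if m_stage not in mouse.columns:
            raise ValueError(f"classify_homolog_expression: mouse stage {m_stage} missing")
        for _, pair in homology.iterrows():
            hg, mg = pair["human_gene"], pair["mouse_gene"]
            if hg not in human.index or mg not in mouse.index:
                continue
            h = float(human.at[hg, h_stage])
            m = float(mouse.at[mg, m_stage])
            if h >= coexpressed_min and m >= coexpressed_min:
                cat = "co-expressed"
            elif h >= coexpressed_min and m <= specific_max:
                cat = "human-specific"
            elif m >= coexpressed_min and h <= specific_max:
                cat = "mouse-specific"
            else:
                cat = "ambiguous"
            rows.append({"human_gene": hg, "mouse_gene": mg, "human_stage": h_stage,
                         "mouse_stage": m_stage, "human_tpm": h, "mouse_tpm": m,
                         "category": cat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grouped comparisons
# ---------------------------------------------------------------------------

PERCENTILES = (5, 25, 50, 75, 95)


def five_number_summary(values: Sequence[float]) -> Dict[str, float]:
    """5th/25th/50th/75th/95th percentiles (linear interpolation) plus mean."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty group")
    out = {f"p{p}": float(np.percentile(x, p)) for p in PERCENTILES}
    out["mean"] = float(x.mean())
    return out


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: Tuple[int, ...]
    summaries: Tuple[Dict[str, float], ...] = ()


def compare_groups(a, b=None, test: str = "wilcoxon_two_sided") -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum on two value groups, or one-sided Fisher
    (alternative: greater proportion in the first row) on a 2x2 table.

    Wilcoxon is exact when both groups have n <= 25 and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    """
    if test == "wilcoxon_two_sided":
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("compare_groups: each group needs >= 2 values")
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (no_ties and len(x) <= 25 and len(y) <= 25) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                               use_continuity=True)
        return GroupComparisonResult(
            test=test,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_sizes=(len(x), len(y)),
            summaries=(five_number_summary(x), five_number_summary(y)),
        )
    if test == "fisher_one_sided":
        table = np.asarray(a, dtype=int)
        if table.shape != (2, 2) or (table < 0).any():
            raise ValueError("compare_groups: Fisher needs a non-negative 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="greater")
        return GroupComparisonResult(
            test=test,
            statistic=float(odds),
            p_value=float(p),
            group_sizes=(int(table[0].sum()), int(table[1].sum())),
        )
    raise ValueError(f"compare_groups: unknown test {test!r}")
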