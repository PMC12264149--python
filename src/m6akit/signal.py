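"""Binned coverage tracks, the m6A signal statistic, sample similarity and a
naive run-length peak caller for synthetic end-to-end runs.

A fragment is a (chrom, start, end) genomic interval; a fragment spanning
several bins contributes one count to each bin it overlaps by >= 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import Peak

log = logging.getLogger("m6akit.signal")


def n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome value arrays (RPKM or log2 signal)."""

    bin_size: int
    data: Dict[str, np.ndarray]
    label: str = "."
    total_fragments: Optional[int] = None

    @classmethod
    def zeros(cls, chrom_sizes: Dict[str, int], bin_size: int, label: str = ".") -> "BinnedTrack":
        return cls(
            bin_size=bin_size,
            data={c: np.zeros(n_bins(s, bin_size)) for c, s in chrom_sizes.items()},
            label=label,
        )

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and {
            c: a.shape for c, a in self.data.items()
        } == {c: a.shape for c, a in other.data.items()}

    def flat(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])


def compute_binned_rpkm(
    fragments: Iterable[Tuple[str, int, int]],
    chrom_sizes: Dict[str, int],
    bin_size: int,
    total: int,
    label: str = ".",
) -> BinnedTrack:
    """RPKM per bin: n_b / ((bin_size/1000) * (total/1e6)).

    n_b counts fragments overlapping bin b by at least one base.
    """
    if total <= 0:
        raise ValueError("total mapped fragments must be > 0")
    counts = {c: np.zeros(n_bins(s, bin_size)) for c, s in chrom_sizes.items()}
    for chrom, start, end in fragments:
        if chrom not in chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome {chrom}")
        if start < 0 or end > chrom_sizes[chrom] or start >= end:
            raise ValueError(f"fragment [{start}, {end}) outside {chrom}")
        counts[chrom][start // bin_size : (end - 1) // bin_size + 1] += 1
    scale = (bin_size / 1000.0) * (total / 1e6)
    track = BinnedTrack(
        bin_size=bin_size,
        data={c: a / scale for c, a in counts.items()},
        label=label,
        total_fragments=total,
    )
    return track


def compute_m6a_signal(ip: BinnedTrack, inp: BinnedTrack, label: str = ".") -> BinnedTrack:
    """Per-bin log2((RPKM_IP + 1) / (RPKM_Input + 1))."""
    if not ip.same_grid(inp):
        raise ValueError("IP and Input tracks are on different bin grids")
    data = {c: np.log2((ip.data[c] + 1.0) / (inp.data[c] + 1.0)) for c in ip.data}
    return BinnedTrack(bin_size=ip.bin_size, data=data, label=label)


@dataclass
class SimilarityResult:
    labels: List[str]
    r: np.ndarray  # Pearson matrix, NaN rows for zero-variance tracks
    distance: np.ndarray  # 1 - r
    pca_coords: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    linkage_matrix: Optional[np.ndarray]  # scipy format, over non-degenerate tracks
    clustered_labels: List[str] = field(default_factory=list)


def _window_matrix(tracks: Sequence[BinnedTrack], window: int) -> np.ndarray:
    """Aggregate each track to window-sized bins (mean) -> windows x samples."""
    bs = tracks[0].bin_size
    if window % bs:
        raise ValueError("window must be a multiple of bin_size")
    k = window // bs
    cols = []
    for t in tracks:
        if not t.same_grid(tracks[0]):
            raise ValueError("tracks are on different bin grids")
        parts = []
        for c in sorted(t.data):
            a = t.data[c]
            pad = (-len(a)) % k
            if pad:
                a = np.concatenate([a, np.full(pad, np.nan)])
            parts.append(np.nanmean(a.reshape(-1, k), axis=1))
        cols.append(np.concatenate(parts))
    return np.column_stack(cols)


def sample_similarity(tracks: Sequence[BinnedTrack], window: int) -> SimilarityResult:
    """Pearson r over windowed values, PCA and average-linkage clustering on 1 - r."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    labels = [t.label for t in tracks]
    X = _window_matrix(tracks, window)
    n = X.shape[1]
    sd = X.std(axis=0)
    degenerate = sd == 0
    r = np.full((n, n), np.nan)
    ok = ~degenerate
    if ok.sum() >= 2:
        r_ok = np.corrcoef(X[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = r_ok
    np.fill_diagonal(r, 1.0)
    if degenerate.any():
        bad = [labels[i] for i in np.where(degenerate)[0]]
        log.warning("zero-variance tracks excluded from clustering: %s", ", ".join(bad))

    dist = 1.0 - r

    # PCA on the feature-centered windows x samples matrix.
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = (Vt.T * S)  # samples x components
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)

    link = None
    kept = [labels[i] for i in np.where(ok)[0]]
    if ok.sum() >= 2:
        d_ok = dist[np.ix_(ok, ok)].copy()
        np.fill_diagonal(d_ok, 0.0)
        # guard tiny negative values from float round-off
        d_ok = np.clip(d_ok, 0.0, None)
        link = linkage(squareform(d_ok, checks=False), method="average")
    return SimilarityResult(
        labels=labels,
        r=r,
        distance=dist,
        pca_coords=coords,
        explained_variance_ratio=evr,
        linkage_matrix=link,
        clustered_labels=kept,
    )


def call_peaks_naive(
    signal: BinnedTrack,
    threshold: float,
    min_bins: int = 3,
    merge_gap: int = 1,
    replicate: str = ".",
) -> List[Peak]:
    """Maximal runs of bins with value >= threshold; gaps <= merge_gap bridged.

    Summit is the centre of the leftmost maximal-signal bin; score is the
    maximal signal in the run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    bs = signal.bin_size
    peaks: List[Peak] = []
    for chrom in sorted(signal.data):
        a = signal.data[chrom]
        above = np.where(a >= threshold)[0]
        if len(above) == 0:
            continue
        runs: List[List[int]] = [[above[0], above[0]]]
        for i in above[1:]:
            if i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for first, last in runs:
            if last - first + 1 < min_bins:
                continue
            seg = a[first : last + 1]
            imax = first + int(np.argmax(seg))
            start, end = first * bs, (last + 1) * bs
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=imax * bs + bs // 2,
                    score=float(seg.max()),
                    name=f"{chrom}:{start}-{end}",
                    replicate=replicate,
                )
            )
    return peaks
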