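"""Normalization, GC correction and QC of binned single-cell counts.

The input is a cells × bins matrix of unique-molecule counts over fixed
500-kb genomic bins, with per-bin metadata (chrom, start, end, GC fraction,
unique restriction cut-site count).  Processing follows the standard
single-cell WGS recipe for restriction-site libraries: drop poorly mappable
bins (too few cut sites), median-normalize each cell to a baseline copy
number of 2, remove the GC-dependent amplification bias with a per-cell
LOESS fit, clip to a maximum copy number, and discard cells whose profiles
are too noisy to segment using a cluster-derived random-forest classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "BinnedCountMatrix",
    "CopyNumberProfile",
    "filter_bins",
    "normalize_profiles",
    "correct_gc_bias",
    "qc_filter_cells",
]


@dataclass
class BinnedCountMatrix:
    """Integer molecule counts (cells × bins) with bin metadata.

    ``counts`` is a DataFrame indexed by cell id with one column per bin;
    ``bins`` has columns chrom, start, end (0-based half-open), gc,
    cutsites, aligned positionally with the count columns.
    """

    counts: pd.DataFrame
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] != len(self.bins):
            raise ValueError(
                f"count matrix has {self.counts.shape[1]} bins but metadata "
                f"describes {len(self.bins)}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("molecule counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class CopyNumberProfile:
    """Real-valued copy numbers (cells × bins) plus per-cell totals."""

    values: pd.DataFrame
    bins: pd.DataFrame
    total_molecules: pd.Series

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def filter_bins(matrix: BinnedCountMatrix,
                min_cutsites: int = 3000) -> BinnedCountMatrix:
    """Drop bins with fewer than ``min_cutsites`` unique cut sites.

    Bins below the threshold have poor mappability; the boundary is
    inclusive (exactly ``min_cutsites`` cut sites is retained).
    """
    keep = matrix.bins.cutsites.to_numpy() >= min_cutsites
    if not keep.any():
        raise ValueError(
            f"no bins have >= {min_cutsites} cut sites; nothing to analyze")
    return BinnedCountMatrix(
        counts=matrix.counts.loc[:, keep].copy(),
        bins=matrix.bins.loc[keep].reset_index(drop=True),
    )


def normalize_profiles(matrix: BinnedCountMatrix,
                       clip_max: float = 4.0) -> CopyNumberProfile:
    """Median-normalize each cell to a baseline of copy number 2.

    Each cell's counts are divided by the cell's median bin count and
    multiplied by 2, so the median copy number of every cell is exactly 2.
    Clipping to ``clip_max`` is NOT applied here: it belongs after GC
    correction (see :func:`correct_gc_bias`), which re-clips to
    [0, clip_max].
    """
    counts = matrix.counts.to_numpy(dtype=float)
    med = np.median(counts, axis=1)
    bad = np.flatnonzero(med <= 0)
    if bad.size:
        names = list(matrix.counts.index[bad[:5]])
        raise ValueError(f"cells with zero median count: {names}")
    values = 2.0 * counts / med[:, None]
    return CopyNumberProfile(
        values=pd.DataFrame(values, index=matrix.counts.index,
                            columns=matrix.counts.columns),
        bins=matrix.bins,
        total_molecules=matrix.counts.sum(axis=1),
    )


def correct_gc_bias(profile: CopyNumberProfile, span: float = 0.3,
                    clip_max: float | None = 4.0) -> CopyNumberProfile:
    """Remove per-cell GC amplification bias by LOESS regression.

    For each cell a locally weighted linear regression (tricube weights,
    window fraction ``span``) of copy number on bin GC fraction is fitted;
    the corrected value is ``raw − fit(GC) + mean(fit)``, which preserves
    the per-cell mean.  Output is clipped to [0, clip_max] unless
    ``clip_max`` is None.
    """
    gc = profile.bins.gc.to_numpy(dtype=float)
    if not np.all(np.isfinite(gc)) or gc.min() < 0 or gc.max() > 1:
        raise ValueError("GC fractions must be finite and within [0, 1]")
    values = profile.values.to_numpy(dtype=float)
    n_bins = values.shape[1]
    if n_bins * span < 2:
        raise ValueError(
            f"{n_bins} bins at span {span} leaves fewer than 2 points per "
            "local window; increase span or provide more bins")
    if np.ptp(gc) < 1e-12:
        corrected = values.copy()  # flat fit: correction is a no-op
    else:
        corrected = np.empty_like(values)
        for i in range(values.shape[0]):
            fit = lowess(values[i], gc, frac=span, return_sorted=False)
            corrected[i] = values[i] - fit + fit.mean()
    if clip_max is not None:
        corrected = np.clip(corrected, 0.0, clip_max)
    return CopyNumberProfile(
        values=pd.DataFrame(corrected, index=profile.values.index,
                            columns=profile.values.columns),
        bins=profile.bins,
        total_molecules=profile.total_molecules,
    )


def _spikiness(values: np.ndarray) -> np.ndarray:
    """Median absolute lag-1 difference per cell (noise statistic)."""
    return np.median(np.abs(np.diff(values, axis=1)), axis=1)


def qc_filter_cells(profiles: CopyNumberProfile, k: int = 12,
                    posterior_cut: float = 0.99, seed: int = 0,
                    spikiness_factor: float = 2.0,
                    n_trees: int = 300):
    """Discard cells with unreliable (noisy) copy-number profiles.

    Cells are embedded in 2-D by PCA and k-means clustered (k clusters);
    clusters whose median profile spikiness (median absolute lag-1 bin
    difference) exceeds ``spikiness_factor`` × the overall median spikiness
    are labeled noisy.  A random forest trained on the bin values with
    these labels assigns each cell a noisy-class posterior; cells above
    ``posterior_cut`` are discarded.

    Returns
    -------
    (kept, report) : (pandas.Index, pandas.DataFrame)
        Kept cell ids and a per-cell audit table with columns
        ``posterior_noisy`` and ``kept``.
    """
    values = profiles.values.to_numpy(dtype=float)
    cells = profiles.values.index
    n = values.shape[0]
    if n < k:
        raise ValueError(
            f"need at least k={k} cells for k-means, got {n}; use a smaller k")

    emb = PCA(n_components=2, random_state=seed).fit_transform(values)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(emb)
    spik = _spikiness(values)
    overall = np.median(spik)
    cluster_med = np.array([np.median(spik[km.labels_ == c]) for c in range(k)])
    noisy_clusters = np.flatnonzero(
        cluster_med > spikiness_factor * max(overall, 1e-12))
    labels = np.isin(km.labels_, noisy_clusters).astype(int)

    if labels.sum() == 0 or labels.sum() == n:
        # single training class: no separable noisy population
        posterior = np.full(n, float(labels[0] if n else 0.0))
    else:
        # features: bin values plus per-cell dispersion summaries, so the
        # forest can overrule cluster-label errors for cells whose profile
        # noise is unambiguous
        feats = np.column_stack([values, spik,
                                 np.std(np.diff(values, axis=1), axis=1)])
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    class_weight="balanced")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(feats, labels)
        posterior = rf.predict_proba(feats)[:, list(rf.classes_).index(1)]

    kept_mask = posterior <= posterior_cut
    report = pd.DataFrame({"posterior_noisy": posterior, "kept": kept_mask},
                          index=cells)
    return cells[kept_mask], report
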