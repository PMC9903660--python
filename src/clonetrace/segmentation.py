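"""Copy-number segmentation and CNV-state definition.

Cells are first grouped by Ward hierarchical clustering (cluster count by
maximum silhouette).  Each cluster's mean profile is segmented per
chromosome by circular binary segmentation (CBS): the best circular split
is found by a maximal two-sample t statistic over all arcs and tested
against a permutation null (bins shuffled within the chromosome); splits
whose resulting adjacent segment means differ by less than a minimum step
are rejected.  Per-cell integer copy numbers are the rounded per-segment
medians; high-variance segments are discarded; allele-specific copies on
diplotyped chromosomes come from per-cell B-allele frequencies; and cells
with identical integer vectors (hamming distance 0) form the CNV states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "Segment",
    "Diplotype",
    "CNVState",
    "cluster_cells",
    "segment_cluster",
    "call_integer_segments",
    "allele_specific_calls",
    "define_cnv_states",
    "max_circular_t",
]


# ---------------------------------------------------------------------------
# CBS core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _max_circ_t(x):  # pragma: no cover - exercised via wrappers
    """Maximal |t| over all circular arcs of x (global-variance t).

    Arcs wrapping the origin are the complements of non-wrapping arcs and
    give identical |t|, so only contiguous arcs [i, j) with 0 < j-i < n are
    scanned.  The global variance factor is omitted: it is constant under
    permutation and cancels from the test.
    """
    n = x.size
    c = np.empty(n + 1)
    c[0] = 0.0
    for i in range(n):
        c[i + 1] = c[i] + x[i]
    s = c[n]
    best = -1.0
    bi = 0
    bj = 0
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            d = c[j] - c[i]
            u = 1.0 / k + 1.0 / (n - k)
            t = abs(d / k - (s - d) / (n - k)) / np.sqrt(u)
            if t > best:
                best = t
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _perm_exceed(x, t_obs, n_perm, limit, seed):  # pragma: no cover
    """Count permutations with max |t| >= t_obs, stopping once > limit.

    Early stopping is decision-preserving: once the exceedance count
    guarantees p > alpha, the remaining shuffles cannot change the split
    decision.  Returns (exceedances, permutations actually run).
    """
    np.random.seed(seed)
    exceed = 0
    done = 0
    for i in range(n_perm):
        xp = np.random.permutation(x)
        t, _, _ = _max_circ_t(xp)
        done = i + 1
        if t >= t_obs - 1e-12:
            exceed += 1
            if exceed > limit:
                break
    return exceed, done


def max_circular_t(x) -> tuple[float, int, int]:
    """Public wrapper: maximal circular-split t statistic and arc (i, j)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 bins")
    t, i, j = _max_circ_t(x)
    return float(t), int(i), int(j)


@dataclass
class Segment:
    """A contiguous run of bins with a shared copy number.

    ``start_bin``/``end_bin`` are half-open indices into the retained-bin
    axis; ``mean`` is the cluster mean copy number over the run.
    """

    chrom: str
    start_bin: int
    end_bin: int
    mean: float
    cluster: int = 0
    accepted: bool = True

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def _segment_one_chrom(x: np.ndarray, offset: int, alpha: float, n_perm: int,
                       rng: np.random.Generator) -> list[int]:
    """Recursive CBS on one chromosome; returns interior breakpoints
    (indices relative to ``offset``)."""
    limit = int(np.floor(alpha * (n_perm + 1))) - 1  # exceed > limit => p > alpha
    breakpoints: list[int] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        if seg.size < 2 or np.ptp(seg) < 1e-12:
            continue
        t_obs, i, j = _max_circ_t(np.ascontiguousarray(seg))
        seed = int(rng.integers(2**31 - 1))
        exceed, done = _perm_exceed(np.ascontiguousarray(seg), t_obs,
                                    n_perm, limit, seed)
        p = (exceed + 1) / (done + 1)
        if p > alpha:
            continue
        cuts = [c for c in (i, j) if 0 < c < seg.size]
        for c in cuts:
            breakpoints.append(lo + c)
        pieces = sorted({lo, hi, *[lo + c for c in cuts]})
        for a, b in zip(pieces[:-1], pieces[1:]):
            if (a, b) != (lo, hi):
                stack.append((a, b))
    return sorted(set(breakpoints))


def _merge_small_steps(x: np.ndarray, breakpoints: list[int],
                       min_mean_diff: float) -> list[int]:
    """Drop breakpoints whose adjacent segment means differ < min_mean_diff,
    smallest step first (rejected split calls)."""
    bps = sorted(breakpoints)
    while bps:
        bounds = [0, *bps, x.size]
        means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(bps))]
        kmin = int(np.argmin(diffs))
        if diffs[kmin] >= min_mean_diff:
            break
        bps.pop(kmin)
    return bps


def segment_cluster(mean_profile, chrom, alpha: float = 0.05,
                    n_perm: int = 10000, min_mean_diff: float = 0.6,
                    seed: int = 0, cluster: int = 0) -> list[Segment]:
    """Circular binary segmentation of a cluster-mean copy-number profile.

    Parameters
    ----------
    mean_profile : array-like
        Mean copy number per retained bin (all chromosomes concatenated).
    chrom : array-like of str
        Chromosome label per bin; segmentation runs within chromosomes.
    alpha : float
        Permutation significance threshold for accepting a split.
    n_perm : int
        Number of bin-order shuffles for the permutation null (>= 100).
    min_mean_diff : float
        Splits whose adjacent segment means differ by less than this are
        rejected (merged back).
    """
    x = np.asarray(mean_profile, dtype=float)
    chrom = np.asarray(chrom)
    if x.size != chrom.size:
        raise ValueError("profile and chromosome labels differ in length")
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} gives too coarse p-value resolution"
                         " (need >= 100)")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    offset = 0
    # preserve input chromosome order
    seen: list[str] = []
    for c in chrom:
        if c not in seen:
            seen.append(c)
    for c in seen:
        mask = chrom == c
        xc = x[mask]
        if xc.size < 2:
            bps: list[int] = []
        else:
            bps = _segment_one_chrom(xc, offset, alpha, n_perm, rng)
            bps = _merge_small_steps(xc, bps, min_mean_diff)
        bounds = [0, *bps, xc.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(chrom=str(c), start_bin=offset + a,
                                    end_bin=offset + b,
                                    mean=float(xc[a:b].mean()),
                                    cluster=cluster))
        offset += xc.size
    return segments


def segments_to_frame(segments: list[Segment],
                      bins: pd.DataFrame | None = None) -> pd.DataFrame:
    """BED-like table of segments; adds bp coordinates if bins are given."""
    rows = []
    for s in segments:
        row = {"chrom": s.chrom, "start_bin": s.start_bin,
               "end_bin": s.end_bin, "cluster": s.cluster,
               "mean": s.mean, "accepted": s.accepted}
        if bins is not None:
            row["start_bp"] = int(bins.iloc[s.start_bin].start)
            row["end_bp"] = int(bins.iloc[s.end_bin - 1].end)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_cells(profiles, k_range=None, forced_splits=()):
    """Ward hierarchical clustering with silhouette-selected cluster count.

    Parameters
    ----------
    profiles : DataFrame or array (cells × bins)
    k_range : iterable of int, optional
        Candidate cluster counts; the maximum mean silhouette (Euclidean,
        raw bins) wins.  Defaults to 2 .. min(10, n_cells - 1).
    forced_splits : iterable of int
        Cluster labels (from the silhouette-optimal cut) to re-cut one
        linkage level deeper — the manual "overclustering" hook for large
        heterogeneous clusters.

    Returns
    -------
    numpy.ndarray of int cluster labels (0-based, relabeled contiguously).
    """
    values = np.asarray(profiles, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k_range is None:
        k_range = range(2, min(11, n))
    ks = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if np.ptp(values) < 1e-12:
        warnings.warn("all cells identical; returning a single cluster")
        return np.zeros(n, dtype=int)
    link = linkage(values, method="ward")
    best_k, best_score = None, -np.inf
    for k in ks:
        labels = fcluster(link, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(values, labels, metric="euclidean")
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        warnings.warn("silhouette undefined for all k; single cluster")
        return np.zeros(n, dtype=int)
    labels = fcluster(link, best_k, criterion="maxclust") - 1
    for target in forced_splits:
        members = np.flatnonzero(labels == target)
        if members.size < 2:
            continue
        sub = linkage(values[members], method="ward")
        sub_labels = fcluster(sub, 2, criterion="maxclust")
        new_label = labels.max() + 1
        labels = labels.copy()
        labels[members[sub_labels == 2]] = new_label
    # relabel contiguously in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


# ---------------------------------------------------------------------------
# Integer and allele-specific calls
# ---------------------------------------------------------------------------

def call_integer_segments(profiles, segments: list[Segment],
                          var_max: float = 0.025):
    """Per-cell integer copy number per segment, with a variance filter.

    Each cell's call is the rounded (half-to-even) median of its bin values
    within the segment.  Segments where the rounding residuals (pre-rounding
    median minus integer call) have variance (population, ddof=0) above
    ``var_max`` across cells are rejected from the accepted set — in
    practice small segments with hard to resolve copy numbers, whose
    medians sit between integers (e.g. cells alternating 1.4/1.6).  True
    CNV segments resolve near integers in every cell and pass.

    Returns
    -------
    (integer_calls, medians, accepted) :
        DataFrames (cells × accepted segments) of integer calls and raw
        medians over ALL segments, plus the accepted Segment list (the
        rejected ones are returned too, flagged ``accepted=False``).
    """
    if hasattr(profiles, "bins"):  # CopyNumberProfile
        profiles = profiles.values
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        values = profiles.to_numpy(dtype=float)
    else:
        values = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    covered = sorted({b for s in segments for b in range(s.start_bin, s.end_bin)})
    if covered != list(range(values.shape[1])):
        raise ValueError("segments must cover all retained bins exactly")
    med = np.column_stack([
        np.median(values[:, s.start_bin:s.end_bin], axis=1) for s in segments])
    residuals = med - np.rint(med)
    for k, s in enumerate(segments):
        s.accepted = bool(np.var(residuals[:, k]) <= var_max)
    accepted_idx = [k for k, s in enumerate(segments) if s.accepted]
    if not accepted_idx:
        raise ValueError("variance filter rejected every segment")
    calls = np.rint(med[:, accepted_idx]).astype(int)
    medians = pd.DataFrame(med, index=index,
                           columns=[f"seg{k}" for k in range(len(segments))])
    integer_calls = pd.DataFrame(
        calls, index=index, columns=[f"seg{k}" for k in accepted_idx])
    return integer_calls, medians, segments


@dataclass(frozen=True)
class Diplotype:
    """Haplotype assignment of heterozygous germline SNVs on one chromosome.

    ``alleles[locus] = (base_A, base_B)``; the allele with bulk BAF 1 in the
    clonally-deleted reference line is B, the one with BAF 0 is A.
    """

    chrom: str
    alleles: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for locus, (a, b) in self.alleles.items():
            if a == b:
                raise ValueError(f"locus {locus}: alleles A and B must differ")


def allele_specific_calls(total_cn: pd.DataFrame,
                          allele_counts: pd.DataFrame) -> pd.DataFrame:
    """Split total integer copy numbers into A and B allele copies.

    Parameters
    ----------
    total_cn : DataFrame (cells × segments) of total integer calls.
    allele_counts : long DataFrame with columns cell, segment, a_count,
        b_count — informative gSNV molecule counts summed per cell per
        segment (oriented by the diplotype).

    Returns
    -------
    DataFrame with columns cell, segment, baf, cn_a, cn_b; cells without
    informative gSNV observations in a segment get missing (NaN) calls.
    ``cn_a = round(total × freq_A)``, ``cn_b = total − cn_a``.
    """
    rows = []
    grouped = allele_counts.groupby(["cell", "segment"])[["a_count", "b_count"]].sum()
    for cell in total_cn.index:
        for seg in total_cn.columns:
            total = total_cn.at[cell, seg]
            try:
                a, b = grouped.loc[(cell, seg)]
            except KeyError:
                a = b = 0
            if a + b == 0:
                rows.append((cell, seg, np.nan, np.nan, np.nan))
                continue
            freq_a = a / (a + b)
            cn_a = int(np.rint(total * freq_a))
            rows.append((cell, seg, 1.0 - freq_a, cn_a, int(total) - cn_a))
    return pd.DataFrame(rows, columns=["cell", "segment", "baf", "cn_a", "cn_b"])


# ---------------------------------------------------------------------------
# CNV states
# ---------------------------------------------------------------------------

@dataclass
class CNVState:
    """A group of cells sharing an identical integer CNV vector."""

    state_id: int
    vector: tuple
    cells: list
    abundance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def define_cnv_states(matrix: pd.DataFrame, min_cells: int = 2):
    """Group cells with hamming distance 0 into CNV states.

    Cells with any undefined (NaN) entry are excluded and reported; states
    with fewer than ``min_cells`` members are discarded and reported.
    States are ranked by descending size (ids 1, 2, ...).

    Returns
    -------
    (states, discarded_cells, excluded_cells)
    """
    values = matrix.to_numpy()
    has_nan = pd.isna(matrix).any(axis=1).to_numpy()
    excluded = list(matrix.index[has_nan])
    groups: dict[tuple, list] = {}
    for cell, row, bad in zip(matrix.index, values, has_nan):
        if bad:
            continue
        groups.setdefault(tuple(row.tolist()), []).append(cell)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    states: list[CNVState] = []
    discarded: list = []
    sid = 0
    for vec, cells in ordered:
        if len(cells) < min_cells:
            discarded.extend(cells)
            continue
        sid += 1
        states.append(CNVState(state_id=sid, vector=vec, cells=cells))
    return states, discarded, excluded


def state_abundance(states: list[CNVState],
                    cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(state, timepoint[, replicate]) member-cell counts.

    ``cell_meta`` is indexed by cell id with a ``timepoint`` column and an
    optional ``replicate`` column.
    """
    keys = ["timepoint"] + (["replicate"] if "replicate" in cell_meta else [])
    rows = []
    for st in states:
        sub = cell_meta.loc[[c for c in st.cells if c in cell_meta.index]]
        for key, grp in sub.groupby(keys):
            key = key if isinstance(key, tuple) else (key,)
            rows.append({"state": st.state_id,
                         **dict(zip(keys, key)),
                         "n_cells": len(grp)})
    return pd.DataFrame(rows)
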