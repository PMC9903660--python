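"""Readers and writers for the package's on-disk formats.

Counts travel as MatrixMarket (.mtx) with sidecar cells.tsv and a BED-like
bins table (0-based half-open, extra columns gc and cutsites); everything
else is plain TSV/CSV/JSON.  A synthetic experiment round-trips as a
directory bundle (counts.mtx or profiles.tsv, cells.tsv, bins.bed,
barcodes.tsv, variants.tsv, bulk_barcodes.tsv, truth.json).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .cnv_pipeline import BinnedCountMatrix
from .evolution_sim import CloneSizeSeries

BED_COLUMNS = ["chrom", "start", "end", "gc", "cutsites"]


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    bins[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                       dtype={"chrom": str})


def write_counts(counts: pd.DataFrame, bins: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx",
                     scipy.sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="cell_id").to_csv(
        outdir / "cells.tsv", sep="\t", index=False)
    write_bins_bed(bins, outdir / "bins.bed")


def read_counts(outdir) -> BinnedCountMatrix:
    outdir = Path(outdir)
    mat = scipy.io.mmread(outdir / "counts.mtx").toarray()
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t").cell_id
    bins = read_bins_bed(outdir / "bins.bed")
    counts = pd.DataFrame(mat.astype(int), index=cells,
                          columns=np.arange(bins.shape[0]))
    return BinnedCountMatrix(counts=counts, bins=bins)


def write_clone_sizes(series: CloneSizeSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def read_clone_sizes(path) -> CloneSizeSeries:
    df = pd.read_csv(path, sep="\t")
    counts: dict[int, dict[int, int]] = {}
    for _, row in df.iterrows():
        counts.setdefault(int(row.week), {})[int(row.clone_id)] = int(row["count"])
    return CloneSizeSeries(counts)


def save_experiment(exp, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bins_bed(exp.bins, outdir / "bins.bed")
    exp.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    exp.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    exp.profiles.to_csv(outdir / "profiles.tsv", sep="\t")
    if exp.counts is not None:
        scipy.io.mmwrite(outdir / "counts.mtx",
                         scipy.sparse.csr_matrix(exp.counts.to_numpy()))
    exp.variant_obs.to_csv(outdir / "variants.tsv", sep="\t")
    exp.bulk_barcodes.to_csv(outdir / "bulk_barcodes.tsv", sep="\t",
                             index=False)
    write_clone_sizes(exp.clone_sizes, outdir / "clone_sizes.tsv")
    truth = json.loads(json.dumps(exp.truth, default=_jsonable))
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))
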