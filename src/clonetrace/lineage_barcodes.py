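"""Viral lineage-barcode canonicalization and tree projection.

Raw barcode sequences from the viral library carry sequencing errors:
sequences within hamming distance 2 of a more abundant sequence are merged
into it (quality breaking count ties), yielding canonical barcodes that are
mutually more than 2 apart.  Canonical barcodes are projected onto the
clonal tree as per-state compositions, from which each CNV state's origin
is classified (arose during the experiment vs pre-existing) and
lower bounds on independent occurrences of each copy-number change are
derived: k distinct barcodes shared across a tree edge imply the edge's CNV
change happened at least k times independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree_inference import ROOT, LineageTree

__all__ = [
    "BarcodeTable",
    "OriginCall",
    "merge_barcodes",
    "state_barcode_composition",
    "classify_state_origin",
    "detect_parallel_by_barcode",
]

MISSING = "__missing__"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeTable:
    """Canonical barcode map and merged counts.

    ``canonical`` maps every raw sequence to its canonical representative;
    ``counts``/``quality`` are the merged per-canonical totals and the
    representative's mean base quality.
    """

    canonical: dict[str, str]
    counts: dict[str, int]
    quality: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [(raw, canon, self.counts[canon], self.quality[canon])
                for raw, canon in sorted(self.canonical.items())]
        return pd.DataFrame(rows, columns=["sequence", "canonical_id",
                                           "count", "quality"])


def merge_barcodes(raw: dict, max_dist: int = 2) -> BarcodeTable:
    """Merge sequencing-error satellites into their true barcodes.

    Parameters
    ----------
    raw : dict sequence -> count, or sequence -> (count, mean_quality)
    max_dist : int
        Hamming radius for absorption (default 2).

    Notes
    -----
    Sequences are processed in ascending count order (quality breaks ties);
    each is absorbed into the most abundant more-abundant sequence within
    ``max_dist``, transitively following later absorptions, and counts are
    summed into the final representative.  Surviving canonical barcodes are
    therefore mutually more than ``max_dist`` apart, and the operation is
    idempotent and count-conserving.
    """
    items = []
    for seq, v in raw.items():
        count, qual = (v if isinstance(v, (tuple, list)) else (v, 0.0))
        items.append((str(seq), int(count), float(qual)))
    lengths = {len(s) for s, _, _ in items}
    if len(lengths) > 1:
        raise ValueError(f"mixed barcode lengths: {sorted(lengths)}")
    # ascending (count, quality, seq) for the absorption scan; the key also
    # defines "more abundant" (later in this order wins ties)
    items.sort(key=lambda it: (it[1], it[2], it[0]))
    seqs = [it[0] for it in items]
    absorbed_into: dict[str, str] = {}
    for i, (s, c, q) in enumerate(items):
        best = None
        for j in range(len(items) - 1, i, -1):  # most abundant first
            t = items[j][0]
            if _hamming(s, t) <= max_dist:
                best = t
                break
        if best is not None:
            absorbed_into[s] = best

    def resolve(s: str) -> str:
        while s in absorbed_into:
            s = absorbed_into[s]
        return s

    canonical = {s: resolve(s) for s, _, _ in items}
    counts: dict[str, int] = {}
    quality: dict[str, float] = {}
    for s, c, q in items:
        canon = canonical[s]
        counts[canon] = counts.get(canon, 0) + c
        if canon == s:
            quality[canon] = q
    return BarcodeTable(canonical=canonical, counts=counts, quality=quality)


def state_barcode_composition(tree: LineageTree,
                              cell_barcodes: pd.DataFrame,
                              cell_states: pd.DataFrame) -> dict:
    """Per-(state, timepoint) barcode fractions over the state's cells.

    Parameters
    ----------
    tree : LineageTree
    cell_barcodes : DataFrame indexed by cell id with a ``barcode`` column
        (NaN / ``-1`` / missing row = no barcode detected).
    cell_states : DataFrame indexed by cell id with ``state`` and
        ``timepoint`` columns.

    Returns
    -------
    dict (state, timepoint) -> {barcode: fraction, ..., MISSING: fraction};
    fractions sum to 1 over barcodes plus the explicit missing mass.
    """
    comp: dict = {}
    for (s, t), grp in cell_states.groupby(["state", "timepoint"]):
        n = len(grp)
        fracs: dict = {}
        n_missing = 0
        for cell in grp.index:
            bc = None
            if cell in cell_barcodes.index:
                val = cell_barcodes.at[cell, "barcode"]
                if not (pd.isna(val) or val == -1):
                    bc = val
            if bc is None:
                n_missing += 1
            else:
                fracs[bc] = fracs.get(bc, 0) + 1
        comp[(s, t)] = {b: c / n for b, c in fracs.items()}
        comp[(s, t)][MISSING] = n_missing / n
    return comp


def _state_barcode_sets(composition: dict) -> dict:
    out: dict = {}
    for (s, _t), fracs in composition.items():
        out.setdefault(s, set()).update(
            b for b, f in fracs.items() if b != MISSING and f > 0)
    return out


@dataclass
class OriginCall:
    """Origin classification of one CNV state.

    ``label`` is "arose-during-experiment" (a barcode is shared with the
    inferred parent lineage — directly or through an ancestor),
    "pre-existing" (multiple distinct barcodes and none shared with the
    parental lineage: the state predates barcode introduction), or
    "undetermined" (no barcode data).
    """

    state: int
    label: str
    supporting_barcodes: list = field(default_factory=list)
    parallel_events: int = 1


def classify_state_origin(tree: LineageTree, composition: dict) -> dict:
    """Classify each state's origin from its barcodes and its ancestry.

    Shared-barcode evidence is accepted transitively: a barcode seen in the
    state and in any ancestor state counts, covering the case where the
    barcode was missed by sampling in the direct parent.
    """
    spm = tree.state_parent_map()
    sets = _state_barcode_sets(composition)

    def ancestors(s):
        out = []
        p = spm.get(s, ROOT)
        while p != ROOT:
            out.append(p)
            p = spm.get(p, ROOT)
        return out

    calls: dict[int, OriginCall] = {}
    for s in spm:
        own = sets.get(s, set())
        if not own:
            calls[s] = OriginCall(state=s, label="undetermined")
            continue
        shared = set()
        for a in ancestors(s):
            shared |= own & sets.get(a, set())
        if shared:
            calls[s] = OriginCall(state=s, label="arose-during-experiment",
                                  supporting_barcodes=sorted(shared, key=str),
                                  parallel_events=max(1, len(shared)))
        elif len(own) >= 2:
            calls[s] = OriginCall(state=s, label="pre-existing",
                                  supporting_barcodes=sorted(own, key=str))
        else:
            calls[s] = OriginCall(state=s, label="undetermined",
                                  supporting_barcodes=sorted(own, key=str))
    return calls


def detect_parallel_by_barcode(tree: LineageTree, composition: dict,
                               min_bound: int = 2) -> pd.DataFrame:
    """Lower-bound independent occurrences of each tree edge's CNV change.

    For each state-level edge parent -> child, every distinct barcode
    present on both sides marks an independent cell lineage in which the
    same copy-number change must have occurred; the number of shared
    barcodes is therefore a lower bound on independent occurrences.

    Returns a DataFrame of edges with bound >= ``min_bound`` (columns:
    parent, child, barcodes, min_independent_occurrences).
    """
    spm = tree.state_parent_map()
    sets = _state_barcode_sets(composition)
    rows = []
    for child, parent in spm.items():
        if parent == ROOT:
            continue
        shared = sets.get(child, set()) & sets.get(parent, set())
        bound = len(shared)
        if bound >= min_bound:
            rows.append({"parent": parent, "child": child,
                         "barcodes": sorted(shared, key=str),
                         "min_independent_occurrences": bound})
    return pd.DataFrame(rows, columns=["parent", "child", "barcodes",
                                       "min_independent_occurrences"])
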