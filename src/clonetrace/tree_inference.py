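"""Clonal tree inference from CNV states over time.

Every CNV state becomes one node per timepoint at which it is present
(observed, or linearly interpolated between observations).  Directed edges
carry the copy-number edit distance between state vectors; edges are pruned
when they run backward in time or would raise a segment from zero copies.
Zero-weight edges chain consecutive timepoints of the same state, and an
artificial all-diploid root feeds each state's first appearance.  The
minimum spanning arborescence of this graph (Edmonds' algorithm) is the
clonal evolution tree; a stream-plot layout assigns each state a band whose
width tracks its abundance, with children nested inside their parent's span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "edit_distance",
    "interpolate_abundance",
    "build_state_graph",
    "infer_arborescence",
    "LineageTree",
    "layout_tree",
    "tree_to_newick",
]

ROOT = "root"


def edit_distance(a, b, metric: str = "l1") -> int:
    """Number of single-copy edits between two integer CNV vectors.

    ``l1`` (default) sums |a_s − b_s| over segments — each unit is one
    single-copy gain or loss; ``changed-segments`` counts differing
    segments instead.  Allele-specific entries are compared allele-wise
    (they are just extra vector entries).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(
            f"state vectors have mismatched segment support: {a.shape} vs {b.shape}")
    if metric == "l1":
        return int(np.abs(a - b).sum())
    if metric == "changed-segments":
        return int((a != b).sum())
    raise ValueError(f"unknown edit metric {metric!r}")


def interpolate_abundance(observed: pd.DataFrame, timepoints) -> pd.DataFrame:
    """Linear interpolation of per-state abundance across timepoints.

    Parameters
    ----------
    observed : DataFrame with columns state, timepoint, n_cells
        Observed member-cell counts per state per timepoint.
    timepoints : sequence
        Full ordered timepoint axis.

    Returns
    -------
    DataFrame (states × timepoints): linear between flanking observations,
    0 outside each state's observed range (no extrapolation).
    """
    timepoints = list(timepoints)
    states = sorted(observed.state.unique())
    out = pd.DataFrame(0.0, index=states, columns=timepoints)
    for s in states:
        sub = observed[observed.state == s].sort_values("timepoint")
        tp = sub.timepoint.to_numpy(dtype=float)
        n = sub.n_cells.to_numpy(dtype=float)
        for t in timepoints:
            if tp.min() <= t <= tp.max():
                out.at[s, t] = float(np.interp(t, tp, n))
    return out


def _pruned(vp: np.ndarray, vc: np.ndarray) -> bool:
    """True if the edge parent->child is biologically implausible
    (a segment at zero copies rising to a higher copy number)."""
    return bool(np.any((vp == 0) & (vc > vp)))


def build_state_graph(vectors: dict, abundance: pd.DataFrame,
                      root_vector=None, edge_mode: str = "first-appearance",
                      metric: str = "l1") -> nx.DiGraph:
    """Build the time-layered directed edit-distance graph over CNV states.

    Parameters
    ----------
    vectors : dict state_id -> integer vector
    abundance : DataFrame (states × timepoints)
        Interpolated abundance (see :func:`interpolate_abundance`); a state
        is present at the timepoints where its abundance is > 0.
    root_vector : array-like, optional
        The artificial diploid root state; defaults to all-2 (use 1s for
        allele-resolved entries by passing it explicitly).
    edge_mode : "first-appearance" or "all-pairs"
        Cross-state edges run from every timepoint of P to the first
        timepoint of C at or after it (default), or to every later
        timepoint of C.

    Notes
    -----
    Pruning: no backward-in-time edges, and no edges raising a segment
    from zero copies.  Consecutive timepoints of one state are linked by
    zero-weight edges; the root feeds each state's first appearance.
    """
    if not vectors:
        raise ValueError("no states given")
    if edge_mode not in ("first-appearance", "all-pairs"):
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    n_entries = len(np.asarray(next(iter(vectors.values()))))
    root_vec = (np.full(n_entries, 2, dtype=int) if root_vector is None
                else np.asarray(root_vector))
    timepoints = list(abundance.columns)
    present: dict[int, list] = {}
    for s in vectors:
        present[s] = [t for t in timepoints if abundance.at[s, t] > 0]

    g = nx.DiGraph()
    g.add_node(ROOT, abundance=0.0, vector=tuple(root_vec.tolist()))
    for s, ts in present.items():
        for t in ts:
            g.add_node((s, t), abundance=float(abundance.at[s, t]),
                       vector=tuple(np.asarray(vectors[s]).tolist()))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            g.add_edge((s, t0), (s, t1), weight=0)
    order = {t: i for i, t in enumerate(timepoints)}
    for c, tc in present.items():
        if not tc:
            continue
        vc = np.asarray(vectors[c])
        if not _pruned(root_vec, vc):
            g.add_edge(ROOT, (c, tc[0]),
                       weight=edit_distance(root_vec, vc, metric))
        for p, tp in present.items():
            if p == c or not tp:
                continue
            vp = np.asarray(vectors[p])
            if _pruned(vp, vc):
                continue
            w = edit_distance(vp, vc, metric)
            for t in tp:
                if edge_mode == "first-appearance":
                    targets = [tc[0]] if order[tc[0]] >= order[t] else []
                else:
                    targets = [u for u in tc if order[u] >= order[t]]
                for u in targets:
                    g.add_edge((p, t), (c, u), weight=w)
    return g


@dataclass
class LineageTree:
    """A rooted arborescence over (state, timepoint) nodes.

    ``parent`` maps each non-root node to its tree parent; ``weight`` holds
    the edit cost of each tree edge; ``abundance`` the per-node abundance.
    """

    parent: dict
    weight: dict
    abundance: dict
    vectors: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return [ROOT] + list(self.parent)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weight.values()))

    def children(self, node) -> list:
        return [n for n, p in self.parent.items() if p == node]

    def state_parent_map(self) -> dict:
        """Derived state-level parent: for each state, the state owning the
        tree parent of its earliest node (root maps to ``ROOT``)."""
        first: dict = {}
        for node in self.parent:
            s, t = node
            if s not in first or self._order(t) < self._order(first[s][1]):
                first[s] = node
        out = {}
        for s, node in first.items():
            p = self.parent[node]
            # climb through same-state chain nodes (shouldn't occur for the
            # earliest node, but be safe)
            while p != ROOT and p[0] == s:
                p = self.parent[p]
            out[s] = ROOT if p == ROOT else p[0]
        return out

    @staticmethod
    def _order(t):
        return t


def _tiebreak_weights(g: nx.DiGraph) -> nx.DiGraph:
    """Perturb weights so Edmonds breaks ties deterministically:
    prefer the parent with larger abundance at the child's timepoint,
    then the lower parent state id; perturbations are too small to alter
    the optimal total of the integer weights."""
    edges = list(g.edges(data=True))
    if not edges:
        return g

    def key(e):
        u, v, _ = e
        abund = g.nodes[u].get("abundance", 0.0)
        sid = "" if u == ROOT else str(u[0] if isinstance(u, tuple) else u)
        return (-abund, sid)

    ranked = sorted(edges, key=key)
    unit = 0.5 / (len(edges) + 1) / (len(g) + 1)
    h = g.copy()
    for r, (u, v, d) in enumerate(ranked):
        h[u][v]["weight"] = d["weight"] + unit * r / len(edges)
    return h


def infer_arborescence(graph: nx.DiGraph) -> LineageTree:
    """Minimum spanning arborescence of the state-time graph (Edmonds).

    Raises if any node is unreachable from the root (a sign of
    over-pruning), naming the unreachable nodes.
    """
    reachable = set(nx.descendants(graph, ROOT)) | {ROOT}
    missing = set(graph.nodes) - reachable
    if missing:
        raise ValueError(
            f"nodes unreachable from the root (over-pruned graph): "
            f"{sorted(missing, key=str)}")
    h = _tiebreak_weights(graph)
    arb = nx.minimum_spanning_arborescence(h, attr="weight",
                                           preserve_attrs=False)
    parent, weight = {}, {}
    for u, v in arb.edges:
        parent[v] = u
        weight[v] = graph[u][v]["weight"]  # original integer weight
    abundance = {n: graph.nodes[n]["abundance"] for n in graph.nodes}
    vectors = {n: graph.nodes[n].get("vector") for n in graph.nodes}
    return LineageTree(parent=parent, weight=weight, abundance=abundance,
                       vectors=vectors)


def tree_to_newick(tree: LineageTree) -> str:
    """Newick export of the state-level tree (branch lengths = edit cost)."""
    spm = tree.state_parent_map()
    # edge length: weight of the state's first-node in-edge
    first_w: dict = {}
    for node, p in tree.parent.items():
        s = node[0]
        if p == ROOT or p[0] != s:
            first_w[s] = tree.weight[node]
    children: dict = {}
    for s, p in spm.items():
        children.setdefault(p, []).append(s)

    def rec(node):
        kids = sorted(children.get(node, []))
        label = "root" if node == ROOT else f"state{node}"
        length = "" if node == ROOT else f":{first_w.get(node, 0)}"
        if not kids:
            return f"{label}{length}"
        inner = ",".join(rec(k) for k in kids)
        return f"({inner}){label}{length}"

    return rec(ROOT) + ";"


def layout_tree(tree: LineageTree, composition: dict | None = None):
    """Stream-plot layout: per-(state, timepoint) vertical bands.

    Each state's band width at a timepoint equals its abundance; children
    are nested within the parent's span starting at the branch timepoint.
    Returns (bands, sublanes, smoother): ``bands`` has columns state, time,
    y0, y1; ``sublanes`` splits each band by the composition fractions
    (barcodes or sSNV backgrounds); ``smoother(state)`` returns a cubic
    interpolant (t -> (y0, y1)) through the band anchors.

    ``composition`` maps (state, time) -> {label: fraction}.
    """
    for n, a in tree.abundance.items():
        if a < 0:
            raise ValueError(f"negative abundance at node {n}")
    spm = tree.state_parent_map()
    states = list(spm)
    times = sorted({t for (s, t) in tree.parent if s in states} |
                   {t for n in tree.abundance if n != ROOT for t in [n[1]]})
    abund = {(s, t): tree.abundance.get((s, t), 0.0)
             for s in states for t in times}
    children: dict = {}
    for s, p in spm.items():
        children.setdefault(p, []).append(s)

    def span(s, t):
        return abund[(s, t)] + sum(span(c, t) for c in children.get(s, []))

    rows = []

    def place(s, t, y0):
        a = abund[(s, t)]
        rows.append({"state": s, "time": t, "y0": y0, "y1": y0 + a})
        y = y0 + a
        for c in sorted(children.get(s, [])):
            place(c, t, y)
            y += span(c, t)

    for t in times:
        y = 0.0
        for s in sorted(children.get(ROOT, [])):
            place(s, t, y)
            y += span(s, t)
    bands = pd.DataFrame(rows)

    sub_rows = []
    if composition:
        for (s, t), fracs in composition.items():
            band = bands[(bands.state == s) & (bands.time == t)]
            if band.empty:
                continue
            y0, y1 = float(band.y0.iloc[0]), float(band.y1.iloc[0])
            total = sum(fracs.values())
            y = y0
            for label, f in sorted(fracs.items()):
                h = (y1 - y0) * (f / total if total > 0 else 0.0)
                sub_rows.append({"state": s, "time": t, "label": label,
                                 "fraction": f, "y0": y, "y1": y + h})
                y += h
    sublanes = pd.DataFrame(sub_rows)

    def smoother(s):
        sub = bands[bands.state == s].sort_values("time")
        t = sub.time.to_numpy(dtype=float)
        if t.size == 1:
            y0v, y1v = float(sub.y0.iloc[0]), float(sub.y1.iloc[0])
            return lambda x: (np.full_like(np.asarray(x, float), y0v),
                              np.full_like(np.asarray(x, float), y1v))
        c0 = CubicSpline(t, sub.y0.to_numpy(dtype=float))
        c1 = CubicSpline(t, sub.y1.to_numpy(dtype=float))
        return lambda x: (c0(x), c1(x))

    return bands, sublanes, smoother
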