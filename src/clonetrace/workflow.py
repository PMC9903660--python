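"""End-to-end reconstruction: profiles -> segments -> states -> tree.

Glue over the module pipeline: cluster the cells, run circular binary
segmentation per cluster, union the breakpoints into a shared segment set,
call per-cell integer copy numbers, group hamming-0 CNV states, and infer
the clonal tree from the time-layered state graph.  Also provides scoring
helpers that compare a reconstruction against the ground truth of a
:class:`~clonetrace.evolution_sim.SyntheticExperiment`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import segmentation, tree_inference
from .evolution_sim import SyntheticExperiment
from .segmentation import Segment
from .tree_inference import ROOT, LineageTree


@dataclass
class Reconstruction:
    segments: list
    integer_calls: pd.DataFrame
    states: list
    cell_states: pd.DataFrame      # index cell, columns state, timepoint
    abundance: pd.DataFrame
    graph: object
    tree: LineageTree

    def state_vector_bins(self, state) -> np.ndarray:
        """Expand a state's per-segment vector back to bin space."""
        accepted = [s for s in self.segments if s.accepted]
        n_bins = max(s.end_bin for s in self.segments)
        out = np.full(n_bins, np.nan)
        for seg, v in zip(accepted, state.vector):
            out[seg.start_bin:seg.end_bin] = v
        return out


def reconstruct(profiles: pd.DataFrame, chrom, cell_timepoints: pd.Series,
                alpha: float = 0.05, n_perm: int = 2000,
                min_mean_diff: float = 0.6, var_max: float = 0.025,
                min_cells: int = 2, k_range=None, seed: int = 0,
                edit_metric: str = "l1") -> Reconstruction:
    """Run the full state/tree reconstruction on per-cell bin profiles.

    Parameters
    ----------
    profiles : DataFrame (cells × bins) of copy-number values.
    chrom : per-bin chromosome labels.
    cell_timepoints : Series mapping cell id -> timepoint.
    n_perm : CBS permutation count (desk-scale default 2000; the full-scale
        analysis uses 10000).
    """
    chrom = np.asarray(chrom)
    values = profiles.to_numpy(dtype=float)
    n = values.shape[0]
    if k_range is None:
        k_range = range(2, min(13, n))
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        labels = segmentation.cluster_cells(profiles.to_numpy(),
                                            k_range=k_range)
    # per-cluster CBS; union of breakpoints -> shared segment set
    cut_of_chrom: dict = {}
    for lab in np.unique(labels):
        mean_profile = values[labels == lab].mean(axis=0)
        segs = segmentation.segment_cluster(
            mean_profile, chrom, alpha=alpha, n_perm=n_perm,
            min_mean_diff=min_mean_diff, seed=seed + int(lab),
            cluster=int(lab))
        for s in segs:
            cut_of_chrom.setdefault(s.chrom, set()).update(
                (s.start_bin, s.end_bin))
    segments: list[Segment] = []
    for c in pd.unique(chrom):
        cuts = sorted(cut_of_chrom.get(str(c), set()))
        for a, b in zip(cuts[:-1], cuts[1:]):
            segments.append(Segment(
                chrom=str(c), start_bin=a, end_bin=b,
                mean=float(values[:, a:b].mean())))
    calls, _medians, segments = segmentation.call_integer_segments(
        profiles, segments, var_max=var_max)
    states, _disc, _excl = segmentation.define_cnv_states(
        calls, min_cells=min_cells)

    meta = pd.DataFrame({"timepoint": cell_timepoints})
    abundance_long = segmentation.state_abundance(states, meta)
    timepoints = sorted(meta.timepoint.unique())
    abundance = tree_inference.interpolate_abundance(
        abundance_long.rename(columns={"state": "state"}), timepoints)

    vectors = {s.state_id: np.asarray(s.vector) for s in states}
    graph = tree_inference.build_state_graph(vectors, abundance,
                                             metric=edit_metric)
    tree = tree_inference.infer_arborescence(graph)

    rows = []
    for s in states:
        for cell in s.cells:
            rows.append({"cell": cell, "state": s.state_id,
                         "timepoint": meta.timepoint.get(cell)})
    cell_states = pd.DataFrame(rows).set_index("cell")
    return Reconstruction(segments=segments, integer_calls=calls,
                          states=states, cell_states=cell_states,
                          abundance=abundance, graph=graph, tree=tree)


# ---------------------------------------------------------------------------
# Scoring against simulator ground truth
# ---------------------------------------------------------------------------

def _true_bin_vectors(exp: SyntheticExperiment) -> dict[int, tuple]:
    """Total-CN bin vector per genealogy clone."""
    seg_of_bin = np.empty(len(exp.bins), dtype=int)
    for si, seg in exp.segments.iterrows():
        seg_of_bin[seg.start_bin:seg.end_bin] = si
    out = {}
    for cid in range(len(exp.truth["clones"])):
        total = np.asarray(exp.truth["clone_cn"][cid]).sum(axis=1)
        out[cid] = tuple(total[seg_of_bin].tolist())
    return out


def score_genealogy(exp: SyntheticExperiment, rec: Reconstruction):
    """Fraction of inferred state-parent assignments matching the truth.

    Each inferred state is matched to genealogy clones by its bin-space
    total-CN vector; a parent assignment is correct when the inferred
    parent state's vector equals the true parent clone's vector (the
    diploid root maps to founder clones / the artificial root).

    Returns (n_correct, n_scored, detail DataFrame).
    """
    true_vecs = _true_bin_vectors(exp)
    parent_of = {c["id"]: c["parent"] for c in exp.truth["clones"]}
    # valid (child vector, parent vector) pairs in the truth
    valid_pairs = set()
    root_vec = None
    for cid, vec in true_vecs.items():
        p = parent_of[cid]
        if p == -1:
            root_vec = vec  # founders are diploid
            valid_pairs.add((vec, "ROOT"))
        else:
            valid_pairs.add((vec, true_vecs[p]))

    spm = rec.tree.state_parent_map()
    state_vec = {}
    for s in rec.states:
        bins_vec = rec.state_vector_bins(s)
        state_vec[s.state_id] = tuple(
            None if np.isnan(v) else int(v) for v in bins_vec)
    n_correct = 0
    rows = []
    for sid, pid in spm.items():
        child_vec = state_vec[sid]
        parent_vec = "ROOT" if pid == ROOT else state_vec[pid]
        ok = (child_vec, parent_vec) in valid_pairs
        # a state whose vector equals the diploid founders' counts as
        # correctly rooted if attached to the artificial root
        if not ok and parent_vec == "ROOT" and child_vec == root_vec:
            ok = True
        n_correct += ok
        rows.append({"state": sid, "parent": pid, "correct": ok})
    return n_correct, len(spm), pd.DataFrame(rows)


def experiment_profiles(exp: SyntheticExperiment):
    """(profiles, chrom labels, cell->timepoint) triple for reconstruct()."""
    return (exp.profiles, exp.bins.chrom.to_numpy(),
            exp.cells.set_index("cell_id").week)


# ---------------------------------------------------------------------------
# Canned recovery experiments
# ---------------------------------------------------------------------------

def genealogy_study_config(noise_sd: float = 0.0,
                           n_branch_events: int = 5):
    """Study conditions for the genealogy-recovery experiment.

    A diploid founder population under weekly passaging accrues
    ``n_branch_events`` planted single-copy losses (each on a distinct
    segment, mild fitness gain) forming chains and branches of depth <= 2;
    cells are sampled at three timepoints with per-bin Gaussian observation
    noise ``noise_sd``.
    """
    from .evolution_sim import CNVEvent, ExperimentConfig
    sp = 30
    # events: ids sp+i in order; chains via target_clone
    events = [
        CNVEvent(week=2, segment=0, allele=0, delta=-1, fitness=1.15,
                 target_founder=-1, n_cells=60, name="e1"),
        CNVEvent(week=2, segment=4, allele=0, delta=-1, fitness=1.15,
                 target_founder=-1, n_cells=60, name="e2"),
        CNVEvent(week=3, segment=5, allele=0, delta=-1, fitness=1.15,
                 target_founder=-1, n_cells=60, name="e3"),
        # chained events: ids follow creation order (week, config order)
        CNVEvent(week=4, segment=2, allele=0, delta=-1, fitness=1.15,
                 target_clone=sp + 0, n_cells=40, name="e4"),
        CNVEvent(week=4, segment=1, allele=0, delta=-1, fitness=1.15,
                 target_clone=sp + 1, n_cells=40, name="e5"),
    ][:n_branch_events]
    return ExperimentConfig(
        chromosomes=(("1", 40), ("2", 40), ("3", 40)),
        n_segments_per_chrom=2, sp=sp, bns=1000, weeks=7,
        sampling={3: 200, 5: 200, 7: 200},
        cnv_events=tuple(events), profile_noise_sd=noise_sd)


def run_genealogy_recovery(noise_sd: float, seed: int,
                           n_perm: int = 1000):
    """One genealogy-recovery replicate; returns (n_correct, n_scored)."""
    from .evolution_sim import simulate_selective_evolution
    exp = simulate_selective_evolution(genealogy_study_config(noise_sd),
                                       seed=seed)
    prof, chrom, tp = experiment_profiles(exp)
    rec = reconstruct(prof, chrom, tp, n_perm=n_perm, seed=seed)
    n_correct, n_scored, _ = score_genealogy(exp, rec)
    return n_correct, n_scored


def parallel_study_config(parallel: bool = True,
                          barcode_detection_rate: float = 0.5,
                          ssnv_fn: float = 0.001):
    """Study conditions for the parallel-evolution detection experiment.

    A somatic SNV splits the diploid founder population into mutant and
    wild-type backgrounds at week 2; at week 3 the same single-copy loss is
    planted either once (on the mutant background; ``parallel=False``) or
    twice independently (once per background; ``parallel=True``).  The two
    event clones are hamming-identical, so they collapse into one CNV
    state; only the sSNV backgrounds and the lineage barcodes can reveal
    the double origin.
    """
    from .evolution_sim import CNVEvent, ExperimentConfig, SNVEvent
    sp = 30
    # the sSNV expands on founder 0's lineage (barcode BC0); the loss is
    # planted on the mutant clone and, in the parallel design, a second
    # time on founder 1's wild-type lineage (BC1)
    cnv_events = [CNVEvent(week=4, segment=0, allele=0, delta=-1,
                           fitness=1.15, target_clone=sp + 0, n_cells=50,
                           name="loss_on_mutant")]
    if parallel:
        cnv_events.append(CNVEvent(week=4, segment=0, allele=0, delta=-1,
                                   fitness=1.35, target_founder=-1,
                                   n_cells=15, name="loss_on_wildtype"))
    return ExperimentConfig(
        chromosomes=(("1", 40), ("2", 40), ("3", 40)),
        n_segments_per_chrom=2, sp=sp, bns=1000, weeks=7,
        sampling={3: 200, 5: 200, 7: 200},
        snv_events=(SNVEvent(week=2, variant="v1", target_founder=-1,
                             n_cells=500, fitness=1.2),),
        cnv_events=tuple(cnv_events),
        barcode_detection_rate=barcode_detection_rate,
        ssnv_fn=ssnv_fn, ssnv_coverage=0.9)


def run_parallel_detection(parallel: bool, seed: int, min_support: int = 2,
                           n_perm: int = 1000):
    """One parallel-detection replicate.

    Returns a dict with ``class3`` (any class-3 call on the loss branch),
    ``class3_pairs``/``pairs`` (for false-positive rates), and
    ``barcode_bound`` (max shared-barcode lower bound across tree edges).
    """
    from . import lineage_barcodes, ssnv
    from .evolution_sim import simulate_selective_evolution
    exp = simulate_selective_evolution(parallel_study_config(parallel),
                                       seed=seed)
    prof, chrom, tp = experiment_profiles(exp)
    rec = reconstruct(prof, chrom, tp, n_perm=n_perm, seed=seed)

    cls = ssnv.classify_branch_variants(
        rec.tree, exp.variant_obs, rec.cell_states.state,
        min_support=min_support)
    n_class3 = int((cls["class"] == 3).sum()) if len(cls) else 0

    cell_barcodes = exp.cells.set_index("cell_id")[["barcode_id"]].rename(
        columns={"barcode_id": "barcode"})
    comp = lineage_barcodes.state_barcode_composition(
        rec.tree, cell_barcodes, rec.cell_states)
    events = lineage_barcodes.detect_parallel_by_barcode(rec.tree, comp)
    bound = (int(events.min_independent_occurrences.max())
             if len(events) else 1)
    return {"class3": n_class3 > 0, "class3_pairs": n_class3,
            "pairs": int(len(cls)), "barcode_bound": bound}


def hazard_recovery_config(n_samples: int = 2000, true_hr: float = 2.0):
    """Cohort design for the conditional-hazard recovery experiment.

    Two focal contigs (chr18, chr4) have loss prevalences 0.35 so that the
    doubly-aberrant group is large enough for a stable Cox fit at
    ``n_samples``; the remaining contigs keep a low background prevalence
    (their pairs fall below the 30-sample filter, keeping the scan
    focussed); carrying both focal losses multiplies the hazard by
    ``true_hr``.
    """
    from .cohort import CohortConfig
    return CohortConfig(
        n_samples=n_samples,
        prevalences={"chr18": 0.35, "chr4": 0.35},
        default_prevalence=0.02,
        hazard_effects=((frozenset({"chr18", "chr4"}), true_hr),),
    )


def run_hazard_recovery(seed: int, n_samples: int = 2000,
                        true_hr: float = 2.0):
    """One conditional-hazard recovery replicate.

    Returns the scan row for the planted (chr18 -> chr4) pair as a dict,
    or None if the pair did not pass the filters.
    """
    from .cohort import conditional_hazard_scan, simulate_cohort
    table = simulate_cohort(hazard_recovery_config(n_samples, true_hr),
                            seed=seed)
    scan = conditional_hazard_scan(table)
    row = scan[(scan.priming == "chr18") & (scan.conditional == "chr4")]
    return row.iloc[0].to_dict() if len(row) else None
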