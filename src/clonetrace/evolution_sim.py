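"""Clonal dynamics simulators for barcoded organoid cultures.

Two generators live here.  :func:`simulate_neutral_drift` is the neutral null:
every founder cell is a unique clone, every cell divides each hour with a
fixed probability, and once a week the culture is bottlenecked to a fixed
number of cells chosen at random.  Shannon entropy of the clone-size
distribution summarises how fast clonal diversity collapses under drift
alone, and :func:`entropy_neutrality_check` turns an observed entropy series
into per-week empirical p-values against that null.

:func:`simulate_selective_evolution` is the full ground-truthed generator: a
clone genealogy accrues copy-number events (per segment, per allele) and
somatic SNVs — planted deterministically or at random — under the same
weekly growth/bottleneck cycle, with optional fitness effects.  Sampled
cells come with noisy binned molecule counts (negative binomial with a
smooth GC bias), barcode observations with dropout, and ternary sSNV
observations with false-negative/false-positive rates, together with full
ground-truth labels so every downstream inference stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DriftParams",
    "CloneSizeSeries",
    "simulate_neutral_drift",
    "shannon_entropy",
    "entropy_neutrality_check",
    "CNVEvent",
    "SNVEvent",
    "ExperimentConfig",
    "SyntheticExperiment",
    "simulate_selective_evolution",
]


# ---------------------------------------------------------------------------
# Neutral drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftParams:
    """Parameters of the neutral weekly-passaging drift model.

    Attributes
    ----------
    rr : float
        Probability that a cell divides in one hour (replication rate).
    sp : int
        Starting population size; every starting cell is a unique clone.
    bns : int
        Bottleneck size: number of cells retained at each weekly passage.
    weeks : int
        Number of weekly passages to simulate.
    hours_per_week : int
        Growth hours between passages (168 h = 1 week).
    seed : int
        RNG seed; identical seeds give identical trajectories.
    """

    rr: float = 0.03
    sp: int = 1000
    bns: int = 1000
    weeks: int = 25
    hours_per_week: int = 168
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rr <= 1.0:
            raise ValueError(f"rr must be in [0, 1], got {self.rr}")
        if self.sp < 1:
            raise ValueError(f"sp must be >= 1, got {self.sp}")
        if self.bns < 1:
            raise ValueError(f"bns must be >= 1, got {self.bns}")
        if self.weeks < 0:
            raise ValueError(f"weeks must be >= 0, got {self.weeks}")


@dataclass
class CloneSizeSeries:
    """Per-week clone sizes: ``counts[w]`` maps clone id -> cell count."""

    counts: dict[int, dict[int, int]]

    @property
    def weeks(self) -> list[int]:
        return sorted(self.counts)

    def entropy_series(self) -> pd.Series:
        """Shannon entropy (bits) of the clone-size distribution per week."""
        return pd.Series(
            {w: shannon_entropy(self.counts[w]) for w in self.weeks},
            name="entropy_bits",
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (week, clone_id, count)."""
        rows = [
            (w, cid, n)
            for w in self.weeks
            for cid, n in sorted(self.counts[w].items())
        ]
        return pd.DataFrame(rows, columns=["week", "clone_id", "count"])


def _grow_one_week(rng: np.random.Generator, counts: np.ndarray,
                   p_divide: np.ndarray | float, hours: int) -> np.ndarray:
    # Clone-wise binomial draws per hour: distributionally identical to
    # per-cell Bernoulli divisions, but O(#clones) instead of O(#cells).
    counts = counts.copy()
    for _ in range(hours):
        counts = counts + rng.binomial(counts, p_divide)
    return counts


def _bottleneck(rng: np.random.Generator, counts: np.ndarray, bns: int,
                week: int, with_replacement: bool = False) -> np.ndarray:
    total = int(counts.sum())
    if with_replacement:
        return rng.multinomial(bns, counts / total)
    if total < bns:
        raise ValueError(
            f"bottleneck size {bns} exceeds the week-{week} pre-bottleneck "
            f"population of {total} cells"
        )
    return rng.multivariate_hypergeometric(counts, bns)


def simulate_neutral_drift(params: DriftParams,
                           with_replacement: bool = False) -> CloneSizeSeries:
    """Simulate neutral clonal drift under weekly bottleneck passaging.

    Every founder is a unique clone; each hour every cell divides with
    probability ``params.rr``; after ``hours_per_week`` hours, ``bns`` cells
    are sampled uniformly without replacement to restart the week.

    Parameters
    ----------
    params : DriftParams
    with_replacement : bool
        If True, the bottleneck is a multinomial (with-replacement) sample
        instead of the default uniform without-replacement draw.

    Returns
    -------
    CloneSizeSeries
        Clone sizes at week 0 (founders) and after each weekly bottleneck.
    """
    rng = np.random.default_rng(params.seed)
    ids = np.arange(1, params.sp + 1)
    counts = np.ones(params.sp, dtype=np.int64)
    series = {0: {int(i): 1 for i in ids}}
    for week in range(1, params.weeks + 1):
        counts = _grow_one_week(rng, counts, params.rr, params.hours_per_week)
        counts = _bottleneck(rng, counts, params.bns, week, with_replacement)
        alive = counts > 0
        ids, counts = ids[alive], counts[alive]
        series[week] = {int(i): int(n) for i, n in zip(ids, counts)}
    return CloneSizeSeries(series)


def shannon_entropy(counts) -> float:
    """Shannon entropy in bits of a clone-size distribution.

    Parameters
    ----------
    counts : mapping or array-like
        Clone sizes (non-negative); zero-size clones are ignored.
    """
    values = np.asarray(
        list(counts.values()) if hasattr(counts, "values") else counts,
        dtype=float,
    )
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("entropy requires at least one positive count")
    if np.any(values < 0):
        raise ValueError("clone counts must be non-negative")
    p = values[values > 0]
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_neutrality_check(observed, params: DriftParams, n_sims: int = 1000,
                             seed: int = 0) -> pd.DataFrame:
    """Lower-tail empirical p-values of an observed entropy series vs drift.

    For each week ``w`` in the observed series, the p-value is the fraction
    of neutral simulations whose entropy at that week is <= the observed
    entropy, with the +1/(n+1) finite-sample correction: faster-than-neutral
    entropy collapse gives small p.

    Parameters
    ----------
    observed : sequence of float
        Observed entropy (bits) at weeks 0, 1, ... len-1.
    params : DriftParams
        Null-model parameters; ``params.weeks`` must cover the series.
    n_sims : int
        Number of neutral replicates (>= 100).
    seed : int
        Seed for the replicate ensemble (independent of ``params.seed``).

    Returns
    -------
    pandas.DataFrame with columns week, observed_entropy, p_value.
    """
    observed = np.asarray(observed, dtype=float)
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for meaningful p-values")
    if observed.size > params.weeks + 1:
        raise ValueError(
            f"observed series has {observed.size} weeks but the simulator "
            f"only covers weeks 0..{params.weeks}"
        )
    child_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    sims = np.empty((n_sims, observed.size))
    for i, ss in enumerate(child_seeds):
        p = DriftParams(rr=params.rr, sp=params.sp, bns=params.bns,
                        weeks=observed.size - 1,
                        hours_per_week=params.hours_per_week,
                        seed=ss.generate_state(1)[0] % (2**31))
        ent = simulate_neutral_drift(p).entropy_series()
        sims[i] = ent.to_numpy()
    n_le = (sims <= observed[None, :]).sum(axis=0)
    pvals = (n_le + 1) / (n_sims + 1)
    return pd.DataFrame({
        "week": np.arange(observed.size),
        "observed_entropy": observed,
        "p_value": pvals,
    })


# ---------------------------------------------------------------------------
# Selective generator with ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNVEvent:
    """A planted copy-number event.

    ``segment`` indexes the config's segment map; ``allele`` is 0 (A) or
    1 (B); ``delta`` is the copy change (-1 loss, +1 gain).  The event is
    applied to one cell of the lineage founded by ``target_founder`` (or of
    clone ``target_clone`` if given) at the start of week ``week``, founding
    a new clone whose fitness is multiplied by ``fitness``.
    """

    week: int
    segment: int
    allele: int = 0
    delta: int = -1
    fitness: float = 1.0
    target_founder: int | None = None
    target_clone: int | None = None
    n_cells: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.fitness <= 0:
            raise ValueError(f"fitness multiplier must be > 0, got {self.fitness}")
        if self.allele not in (0, 1):
            raise ValueError("allele must be 0 (A) or 1 (B)")


@dataclass(frozen=True)
class SNVEvent:
    """A planted somatic SNV acquisition (same targeting semantics)."""

    week: int
    variant: str
    fitness: float = 1.0
    target_founder: int | None = None
    target_clone: int | None = None
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.fitness <= 0:
            raise ValueError(f"fitness multiplier must be > 0, got {self.fitness}")


@dataclass
class ExperimentConfig:
    """Study conditions for the selective generator.

    The genome is a list of (chromosome, number of 500-kb bins) pairs carved
    into ``n_segments_per_chrom`` equal segments per chromosome; copy numbers
    are tracked per segment per allele (diploid root: one copy of A and one
    of B everywhere).
    """

    chromosomes: tuple[tuple[str, int], ...] = (("1", 40), ("2", 40), ("3", 40))
    n_segments_per_chrom: int = 2
    rr: float = 0.03
    sp: int = 50
    bns: int = 50
    weeks: int = 8
    hours_per_week: int = 168
    # stochastic event rates, per cell per week
    cnv_rate: float = 0.0
    ssnv_rate: float = 0.0
    # planted events
    cnv_events: tuple[CNVEvent, ...] = ()
    snv_events: tuple[SNVEvent, ...] = ()
    # barcoding
    barcode_library_size: int = 10000
    barcode_length: int = 20
    barcode_detection_rate: float = 1.0
    allow_barcode_collisions: bool = False
    # sampling schedule: week -> number of cells sampled
    sampling: dict[int, int] = field(default_factory=lambda: {2: 40, 5: 40, 8: 40})
    # observation noise
    mean_molecules_per_bin: float = 50.0
    nb_dispersion: float = 20.0
    gc_bias_amplitude: float = 0.0
    profile_noise_sd: float = 0.0
    count_noise: bool = False
    ssnv_fn: float = 0.0
    ssnv_fp: float = 0.0
    ssnv_coverage: float = 1.0
    bin_width: int = 500_000


@dataclass
class SyntheticExperiment:
    """A fully labeled synthetic organoid evolution experiment.

    ``cells`` has one row per sampled cell (cell_id, week, clone_id,
    founder_id, barcode_id — -1 when the barcode was not detected);
    ``profiles`` are per-cell per-bin copy-number observations (noise-free
    integer totals unless noise was configured); ``counts`` are NB molecule
    counts when ``count_noise`` is on, else None; ``variant_obs`` is the
    ternary sSNV observation matrix (cells × variants, values "A"/"R"/".");
    ``truth`` records the genealogy and per-clone state vectors.
    """

    config: ExperimentConfig
    bins: pd.DataFrame
    segments: pd.DataFrame
    cells: pd.DataFrame
    profiles: pd.DataFrame
    counts: pd.DataFrame | None
    variant_obs: pd.DataFrame
    bulk_barcodes: pd.DataFrame
    clone_sizes: CloneSizeSeries
    truth: dict

    # -- convenience accessors -------------------------------------------
    def clone_state_vector(self, clone_id: int) -> np.ndarray:
        """Allele-resolved CN vector (n_segments, 2) of a genealogy clone."""
        return np.asarray(self.truth["clone_cn"][clone_id])

    def true_parent_map(self) -> dict[int, int]:
        """clone id -> parent clone id (founders map to -1)."""
        return {c["id"]: c["parent"] for c in self.truth["clones"]}

    def save(self, outdir) -> None:
        from . import io as _io
        _io.save_experiment(self, outdir)


def _gc_bias_curve(gc: np.ndarray, amplitude: float) -> np.ndarray:
    # Smooth multiplicative bias peaking at mid GC, as seen in PCR-amplified
    # single-cell libraries.
    return 1.0 + amplitude * np.sin(2.0 * np.pi * (gc - 0.25))


def _make_bins(config: ExperimentConfig, rng: np.random.Generator):
    rows = []
    for chrom, n in config.chromosomes:
        gc = np.clip(0.42 + 0.08 * rng.standard_normal(n), 0.25, 0.65)
        cut = rng.integers(3500, 9000, size=n)
        for i in range(n):
            rows.append((chrom, i * config.bin_width, (i + 1) * config.bin_width,
                         float(gc[i]), int(cut[i])))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "cutsites"])
    seg_rows = []
    offset = 0
    for chrom, n in config.chromosomes:
        bounds = np.linspace(0, n, config.n_segments_per_chrom + 1).astype(int)
        for s in range(config.n_segments_per_chrom):
            seg_rows.append((chrom, offset + bounds[s], offset + bounds[s + 1]))
        offset += n
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start_bin", "end_bin"])
    return bins, segments


class _Genealogy:
    """Mutable clone genealogy during the forward simulation."""

    def __init__(self, sp: int):
        self.cn: list[np.ndarray] = []
        self.ssnvs: list[frozenset] = []
        self.fitness: list[float] = []
        self.parent: list[int] = []
        self.founder: list[int] = []
        self.birth_week: list[int] = []
        self.events: list[dict] = []

    def add(self, cn, ssnvs, fitness, parent, founder, week, event=None) -> int:
        cid = len(self.cn)
        self.cn.append(cn)
        self.ssnvs.append(frozenset(ssnvs))
        self.fitness.append(float(fitness))
        self.parent.append(parent)
        self.founder.append(founder)
        self.birth_week.append(week)
        if event is not None:
            self.events.append({"clone": cid, "parent": parent, "week": week,
                                **event})
        return cid


def simulate_selective_evolution(config: ExperimentConfig,
                                 seed: int = 0) -> SyntheticExperiment:
    """Run the forward clone-genealogy simulation and sample observations.

    Growth and bottleneck dynamics are those of the neutral model, except
    each clone's hourly division probability is ``rr × fitness`` (clamped to
    1).  Planted events are applied at the start of their week to one cell
    of the targeted lineage; stochastic events (rates per cell per week)
    spawn new clones with random segment/allele losses or gains / new sSNVs.

    With all rates zero and no planted events, every sampled cell carries
    the diploid root state, no sSNVs, and one barcode per founder.
    """
    rng = np.random.default_rng(seed)
    if (not config.allow_barcode_collisions
            and config.barcode_library_size < config.sp):
        raise ValueError(
            f"barcode library size {config.barcode_library_size} is smaller "
            f"than the founder count {config.sp}; enable "
            "allow_barcode_collisions to permit collisions"
        )

    bins, segments = _make_bins(config, rng)
    n_seg = len(segments)
    root_cn = np.ones((n_seg, 2), dtype=np.int64)

    gen = _Genealogy(config.sp)
    for f in range(config.sp):
        gen.add(root_cn.copy(), frozenset(), 1.0, -1, f, 0)

    # barcodes: unique draw per founder from the library (t0 introduction)
    lib = rng.choice(config.barcode_library_size, size=config.sp,
                     replace=config.allow_barcode_collisions)
    alphabet = np.array(list("ACGT"))
    bc_seq = {
        int(b): "".join(rng.choice(alphabet, size=config.barcode_length))
        for b in np.unique(lib)
    }

    clone_ids = np.arange(config.sp)
    counts = np.ones(config.sp, dtype=np.int64)

    variant_registry: list[str] = []
    for ev in config.snv_events:
        if ev.variant not in variant_registry:
            variant_registry.append(ev.variant)

    def _pick_target(week: int, founder: int | None, clone: int | None) -> int:
        """Index into clone_ids of one cell's clone matching the target."""
        if clone is not None:
            idx = np.flatnonzero(clone_ids == clone)
            if idx.size == 0 or counts[idx[0]] == 0:
                raise ValueError(f"target clone {clone} extinct at week {week}")
            return int(idx[0])
        mask = np.ones(clone_ids.size, dtype=bool)
        if founder == -1:
            # largest pristine clone (diploid CN, no sSNVs): a deterministic
            # robust target for planting events on an unmutated background
            mask = np.array([
                bool(np.all(gen.cn[int(c)] == 1) and not gen.ssnvs[int(c)])
                for c in clone_ids])
            if not (mask & (counts > 0)).any():
                raise ValueError(f"no live pristine lineage at week {week}")
            w = np.where(mask, counts, -1)
            return int(np.argmax(w))
        elif founder is not None:
            fo = np.array([gen.founder[c] for c in clone_ids])
            mask = fo == founder
        mask &= counts > 0
        if not mask.any():
            raise ValueError(f"no live target lineage at week {week}")
        w = counts * mask
        return int(rng.choice(clone_ids.size, p=w / w.sum()))

    series = {0: {int(i): 1 for i in clone_ids}}
    sampled_rows = []
    sampled_clone_of_cell: list[int] = []
    cell_counter = 0
    bulk_rows = []

    def _sample_cells(week: int) -> None:
        nonlocal cell_counter
        n = config.sampling.get(week, 0)
        if n <= 0:
            return
        total = int(counts.sum())
        take = rng.multivariate_hypergeometric(counts, min(n, total))
        for slot, k in zip(range(clone_ids.size), take):
            for _ in range(k):
                cid = int(clone_ids[slot])
                fo = gen.founder[cid]
                bc = int(lib[fo])
                detected = rng.random() < config.barcode_detection_rate
                sampled_rows.append({
                    "cell_id": f"cell{cell_counter:05d}",
                    "week": week,
                    "clone_id": cid,
                    "founder_id": fo,
                    "barcode_id": bc if detected else -1,
                })
                sampled_clone_of_cell.append(cid)
                cell_counter += 1

    def _record_bulk(week: int) -> None:
        agg: dict[int, int] = {}
        for cid, n in zip(clone_ids, counts):
            if n > 0:
                b = int(lib[gen.founder[int(cid)]])
                agg[b] = agg.get(b, 0) + int(n)
        for b, n in sorted(agg.items()):
            bulk_rows.append({"week": week, "barcode_id": b, "count": n})

    _record_bulk(0)
    _sample_cells(0)

    for week in range(1, config.weeks + 1):
        # planted events at the start of the week
        for ev in config.cnv_events:
            if ev.week != week:
                continue
            slot = _pick_target(week, ev.target_founder, ev.target_clone)
            src = int(clone_ids[slot])
            cn = gen.cn[src].copy()
            cn[ev.segment, ev.allele] = max(0, cn[ev.segment, ev.allele] + ev.delta)
            new = gen.add(cn, gen.ssnvs[src], gen.fitness[src] * ev.fitness,
                          src, gen.founder[src], week,
                          {"kind": "cnv", "segment": ev.segment,
                           "allele": ev.allele, "delta": ev.delta,
                           "name": ev.name})
            n_take = min(ev.n_cells, int(counts[slot]))
            counts[slot] -= n_take
            clone_ids = np.append(clone_ids, new)
            counts = np.append(counts, n_take)
        for ev in config.snv_events:
            if ev.week != week:
                continue
            slot = _pick_target(week, ev.target_founder, ev.target_clone)
            src = int(clone_ids[slot])
            new = gen.add(gen.cn[src], gen.ssnvs[src] | {ev.variant},
                          gen.fitness[src] * ev.fitness, src,
                          gen.founder[src], week,
                          {"kind": "ssnv", "variant": ev.variant})
            n_take = min(ev.n_cells, int(counts[slot]))
            counts[slot] -= n_take
            clone_ids = np.append(clone_ids, new)
            counts = np.append(counts, n_take)
        # stochastic events
        if config.cnv_rate > 0 or config.ssnv_rate > 0:
            for slot in range(clone_ids.size):
                if counts[slot] == 0:
                    continue
                src = int(clone_ids[slot])
                n_cnv = rng.binomial(counts[slot], config.cnv_rate)
                for _ in range(n_cnv):
                    seg = int(rng.integers(n_seg))
                    allele = int(rng.integers(2))
                    delta = -1 if rng.random() < 0.8 else 1
                    cn = gen.cn[src].copy()
                    cn[seg, allele] = max(0, cn[seg, allele] + delta)
                    new = gen.add(cn, gen.ssnvs[src], gen.fitness[src], src,
                                  gen.founder[src], week,
                                  {"kind": "cnv", "segment": seg,
                                   "allele": allele, "delta": delta,
                                   "name": ""})
                    counts[slot] -= 1
                    clone_ids = np.append(clone_ids, new)
                    counts = np.append(counts, 1)
                n_snv = rng.binomial(max(counts[slot], 0), config.ssnv_rate)
                for _ in range(n_snv):
                    var = f"rv{len(variant_registry)}"
                    variant_registry.append(var)
                    new = gen.add(gen.cn[src], gen.ssnvs[src] | {var},
                                  gen.fitness[src], src, gen.founder[src],
                                  week, {"kind": "ssnv", "variant": var})
                    counts[slot] -= 1
                    clone_ids = np.append(clone_ids, new)
                    counts = np.append(counts, 1)

        p_div = np.minimum(
            1.0, config.rr * np.array([gen.fitness[int(c)] for c in clone_ids]))
        counts = _grow_one_week(rng, counts, p_div, config.hours_per_week)
        counts = _bottleneck(rng, counts, config.bns, week)
        alive = counts > 0
        clone_ids, counts = clone_ids[alive], counts[alive]
        series[week] = {int(c): int(n) for c, n in zip(clone_ids, counts)}
        _record_bulk(week)
        _sample_cells(week)

    # ------------------------------------------------------------------
    # observations
    # ------------------------------------------------------------------
    cells = pd.DataFrame(sampled_rows)
    if cells.empty:
        cells = pd.DataFrame(
            columns=["cell_id", "week", "clone_id", "founder_id", "barcode_id"])
    n_cells = len(cells)

    seg_of_bin = np.empty(len(bins), dtype=int)
    for si, seg in segments.iterrows():
        seg_of_bin[seg.start_bin:seg.end_bin] = si

    prof = np.empty((n_cells, len(bins)))
    for i, cid in enumerate(sampled_clone_of_cell):
        total_cn = gen.cn[cid].sum(axis=1).astype(float)
        prof[i] = total_cn[seg_of_bin]
    if config.profile_noise_sd > 0:
        prof = prof + rng.normal(0.0, config.profile_noise_sd, size=prof.shape)

    counts_df = None
    if config.count_noise:
        gc_mult = _gc_bias_curve(bins.gc.to_numpy(), config.gc_bias_amplitude)
        mu = (config.mean_molecules_per_bin * (prof / 2.0) * gc_mult[None, :])
        mu = np.maximum(mu, 1e-9)
        r = config.nb_dispersion
        nb = rng.negative_binomial(r, r / (r + mu))
        counts_df = pd.DataFrame(nb, index=cells.cell_id.to_numpy(),
                                 columns=np.arange(len(bins)))

    profiles = pd.DataFrame(prof, index=cells.cell_id.to_numpy(),
                            columns=np.arange(len(bins)))

    obs = np.full((n_cells, len(variant_registry)), ".", dtype=object)
    for i, cid in enumerate(sampled_clone_of_cell):
        carried = gen.ssnvs[cid]
        for j, var in enumerate(variant_registry):
            if rng.random() >= config.ssnv_coverage:
                continue  # locus not covered in this cell
            if var in carried:
                obs[i, j] = "A" if rng.random() >= config.ssnv_fn else "."
            else:
                obs[i, j] = "A" if rng.random() < config.ssnv_fp else "R"
    variant_obs = pd.DataFrame(obs, index=cells.cell_id.to_numpy(),
                               columns=variant_registry)

    bulk = pd.DataFrame(bulk_rows, columns=["week", "barcode_id", "count"])

    truth = {
        "clones": [
            {"id": c, "parent": gen.parent[c], "founder": gen.founder[c],
             "birth_week": gen.birth_week[c], "fitness": gen.fitness[c],
             "ssnvs": sorted(gen.ssnvs[c])}
            for c in range(len(gen.cn))
        ],
        "clone_cn": {c: gen.cn[c].tolist() for c in range(len(gen.cn))},
        "events": gen.events,
        "barcode_sequences": bc_seq,
        "founder_barcode": {f: int(lib[f]) for f in range(config.sp)},
        "variants": variant_registry,
    }

    return SyntheticExperiment(
        config=config, bins=bins, segments=segments, cells=cells,
        profiles=profiles, counts=counts_df, variant_obs=variant_obs,
        bulk_barcodes=bulk, clone_sizes=CloneSizeSeries(series), truth=truth,
    )


def barcode_collision_probability(n_cells: int, library_size: int,
                                  n_sims: int = 10000, seed: int = 0) -> float:
    """Monte-Carlo probability that any two cells draw the same barcode.

    Exposed for library-complexity what-if analyses; the pairing definition
    is "at least one collision among the starting cells".
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        draw = rng.integers(library_size, size=n_cells)
        if np.unique(draw).size < n_cells:
            hits += 1
    return hits / n_sims
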