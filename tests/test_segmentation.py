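"""Clustering, circular binary segmentation, integer calls, CNV states."""

import numpy as np
import pandas as pd
import pytest

from clonetrace.segmentation import (
    Diplotype,
    Segment,
    allele_specific_calls,
    call_integer_segments,
    cluster_cells,
    define_cnv_states,
    max_circular_t,
    segment_cluster,
)


def brute_force_max_t(x):
    """Exhaustive circular-split scan (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best, arc = -np.inf, None
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            m_arc = x[i:j].mean()
            m_comp = np.concatenate([x[:i], x[j:]]).mean()
            t = abs(m_arc - m_comp) / np.sqrt(1 / k + 1 / (n - k))
            if t > best:
                best, arc = t, (i, j)
    return best, arc


class TestClusterCells:
    def test_two_planted_clones_recovered(self, rng):
        base = np.full(100, 2.0)
        shifted = base.copy()
        shifted[:20] -= 1.0  # one-copy loss over 20% of bins
        cells = np.vstack([base + rng.normal(0, 0.1, 100) for _ in range(25)]
                          + [shifted + rng.normal(0, 0.1, 100)
                             for _ in range(25)])
        labels = cluster_cells(cells, k_range=range(2, 8))
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
        assert labels[0] != labels[25]

    def test_identical_cells_single_cluster_with_warning(self):
        cells = np.full((10, 30), 2.0)
        with pytest.warns(UserWarning):
            labels = cluster_cells(cells)
        assert len(np.unique(labels)) == 1

    def test_forced_split_adds_exactly_one_cluster(self, rng):
        cells = np.vstack([
            2 + rng.normal(0, 0.05, (20, 50)),
            3 + rng.normal(0, 0.05, (20, 50)),
        ])
        base = cluster_cells(cells, k_range=range(2, 6))
        forced = cluster_cells(cells, k_range=range(2, 6),
                               forced_splits=[0])
        assert len(np.unique(forced)) == len(np.unique(base)) + 1

    def test_k_range_out_of_bounds_errors(self, rng):
        cells = rng.normal(2, 0.1, (5, 20))
        with pytest.raises(ValueError):
            cluster_cells(cells, k_range=range(2, 10))


class TestCBS:
    def test_long_noiseless_step_found_exactly(self):
        x = np.concatenate([np.full(30, 2.0), np.full(30, 1.0)])
        segs = segment_cluster(x, np.array(["1"] * 60), n_perm=500, seed=0)
        assert [(s.start_bin, s.end_bin) for s in segs] == [(0, 30), (30, 60)]
        assert segs[0].mean == pytest.approx(2.0)
        assert segs[1].mean == pytest.approx(1.0)

    def test_step_below_rejection_threshold_merged(self):
        x = np.concatenate([np.full(30, 2.0), np.full(30, 1.5)])
        segs = segment_cluster(x, np.array(["1"] * 60), n_perm=500, seed=0)
        assert len(segs) == 1  # |step| = 0.5 < 0.6

    def test_segments_partition_each_chromosome(self, rng):
        x = rng.normal(2, 0.2, 80)
        chrom = np.array(["1"] * 50 + ["2"] * 30)
        segs = segment_cluster(x, chrom, n_perm=300, seed=1)
        for c, lo, hi in (("1", 0, 50), ("2", 50, 80)):
            csegs = sorted((s for s in segs if s.chrom == c),
                           key=lambda s: s.start_bin)
            assert csegs[0].start_bin == lo and csegs[-1].end_bin == hi
            for a, b in zip(csegs[:-1], csegs[1:]):
                assert a.end_bin == b.start_bin

    def test_first_split_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(2, 0.3, size=rng.integers(4, 13))
            n = x.size
            t, i, j = max_circular_t(x)
            t_ref, arc = brute_force_max_t(x)
            assert t == pytest.approx(t_ref)
            # an arc and its complement give the same |t|; compare the
            # induced interior cut points instead of the raw pair
            cuts = {c for c in (i, j) if 0 < c < n}
            ref_cuts = {c for c in arc if 0 < c < n}
            assert cuts == ref_cuts

    def test_type_i_control_on_exchangeable_profiles(self):
        single = 0
        n_runs = 50
        for seed in range(n_runs):
            x = np.random.default_rng(seed).normal(2, 0.15, 60)
            segs = segment_cluster(x, np.array(["1"] * 60), n_perm=400,
                                   seed=seed, min_mean_diff=0.0)
            single += len(segs) == 1
        assert single / n_runs >= 0.94 - 0.05  # alpha=0.05 + MC margin

    def test_too_few_permutations_error(self):
        with pytest.raises(ValueError):
            segment_cluster(np.ones(10), np.array(["1"] * 10), n_perm=50)


class TestIntegerCalls:
    def test_rounding_of_near_integer_medians(self):
        profiles = pd.DataFrame([[1.9, 2.1, 2.0]])
        segs = [Segment("1", 0, 3, mean=2.0)]
        calls, _, _ = call_integer_segments(profiles, segs, var_max=1.0)
        assert calls.iloc[0, 0] == 2

    def test_half_integer_rounds_to_even(self):
        profiles = pd.DataFrame([[1.5, 1.5], [2.5, 2.5]])
        segs = [Segment("1", 0, 2, mean=2.0)]
        calls, _, _ = call_integer_segments(profiles, segs, var_max=1.0)
        assert list(calls.iloc[:, 0]) == [2, 2]  # 1.5 -> 2, 2.5 -> 2

    def test_unresolvable_segment_rejected(self):
        # medians alternate 1.4/1.6: rounding residuals +-0.4 across cells
        bad = np.where((np.arange(10) % 2 == 0)[:, None],
                       np.full((10, 3), 1.4), np.full((10, 3), 1.6))
        profiles = pd.DataFrame(np.column_stack([bad, np.full((10, 3), 2.0)]))
        segs = [Segment("1", 0, 3, mean=1.5), Segment("1", 3, 6, mean=2.0)]
        calls, _, segs = call_integer_segments(profiles, segs)
        assert not segs[0].accepted
        assert segs[1].accepted
        assert list(calls.columns) == ["seg1"]

    def test_clean_polymorphic_segment_kept(self):
        values = np.vstack([np.full((5, 4), 1.0), np.full((5, 4), 2.0)])
        profiles = pd.DataFrame(values)
        segs = [Segment("1", 0, 4, mean=1.5)]
        calls, _, segs = call_integer_segments(profiles, segs)
        assert segs[0].accepted
        assert sorted(calls.iloc[:, 0].unique()) == [1, 2]

    def test_incomplete_coverage_errors(self):
        profiles = pd.DataFrame([[2.0, 2.0, 2.0]])
        with pytest.raises(ValueError):
            call_integer_segments(profiles, [Segment("1", 0, 2, mean=2.0)])


class TestAlleleSpecific:
    @pytest.mark.parametrize("total,a,b,exp_a,exp_b", [
        (2, 5, 5, 1, 1),
        (1, 0, 8, 0, 1),
        (2, 10, 0, 2, 0),
    ])
    def test_forced_arithmetic(self, total, a, b, exp_a, exp_b):
        total_cn = pd.DataFrame({"seg0": [total]}, index=["c0"])
        counts = pd.DataFrame([{"cell": "c0", "segment": "seg0",
                                "a_count": a, "b_count": b}])
        out = allele_specific_calls(total_cn, counts)
        assert out.cn_a.iloc[0] == exp_a
        assert out.cn_b.iloc[0] == exp_b

    def test_a_plus_b_equals_total(self, rng):
        total_cn = pd.DataFrame({"seg0": rng.integers(1, 4, size=10)},
                                index=[f"c{i}" for i in range(10)])
        counts = pd.DataFrame([
            {"cell": f"c{i}", "segment": "seg0",
             "a_count": int(rng.integers(0, 10)),
             "b_count": int(rng.integers(1, 10))}
            for i in range(10)])
        out = allele_specific_calls(total_cn, counts)
        assert (out.cn_a + out.cn_b == total_cn.seg0.to_numpy()).all()

    def test_no_informative_gsnv_gives_missing(self):
        total_cn = pd.DataFrame({"seg0": [2]}, index=["c0"])
        counts = pd.DataFrame(columns=["cell", "segment", "a_count",
                                       "b_count"])
        out = allele_specific_calls(total_cn, counts)
        assert np.isnan(out.cn_a.iloc[0])

    def test_diplotype_requires_distinct_alleles(self):
        with pytest.raises(ValueError):
            Diplotype(chrom="4", alleles={"snv1": ("A", "A")})


class TestCNVStates:
    def test_grouping_and_ranking(self):
        m = pd.DataFrame([[2, 1], [2, 1], [2, 1], [2, 2], [2, 2]],
                         index=list("abcde"))
        states, discarded, excluded = define_cnv_states(m)
        assert [(s.state_id, s.n_cells) for s in states] == [(1, 3), (2, 2)]
        assert discarded == [] and excluded == []

    def test_singletons_discarded(self):
        m = pd.DataFrame([[1, 1], [1, 2], [2, 2]], index=list("abc"))
        states, discarded, _ = define_cnv_states(m)
        assert states == []
        assert sorted(discarded) == ["a", "b", "c"]

    def test_cells_with_missing_entries_excluded(self):
        m = pd.DataFrame([[2.0, 1.0], [2.0, np.nan], [2.0, 1.0]],
                         index=list("abc"))
        states, _, excluded = define_cnv_states(m)
        assert excluded == ["b"]
        assert states[0].cells == ["a", "c"]

    def test_52_planted_vectors_recovered(self, rng):
        vectors = rng.integers(0, 4, size=(52, 12))
        while len(np.unique(vectors, axis=0)) < 52:  # ensure distinct
            vectors = rng.integers(0, 4, size=(52, 12))
        counts = rng.integers(2, 80, size=52)
        counts = (counts / counts.sum() * (1641 - 2 * 52)).astype(int) + 2
        rows = np.repeat(vectors, counts, axis=0)
        m = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
        states, discarded, _ = define_cnv_states(m)
        assert len(states) == 52
        assert discarded == []
        # partition: every cell in exactly one state
        assert sum(s.n_cells for s in states) == len(rows)
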