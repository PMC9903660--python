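"""Neutral-drift simulator, entropy, and the selective generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.evolution_sim import (
    CNVEvent,
    DriftParams,
    ExperimentConfig,
    SNVEvent,
    entropy_neutrality_check,
    shannon_entropy,
    simulate_neutral_drift,
    simulate_selective_evolution,
)


def brute_force_drift(rr, sp, bns, weeks, hours, seed):
    """Cell-wise Bernoulli reference implementation (independent oracle)."""
    rng = np.random.default_rng(seed)
    cells = np.arange(1, sp + 1)  # clone id per cell
    out = {0: {int(c): 1 for c in cells}}
    for w in range(1, weeks + 1):
        for _ in range(hours):
            divides = rng.random(cells.size) < rr
            cells = np.concatenate([cells, cells[divides]])
        keep = rng.choice(cells.size, size=bns, replace=False)
        cells = cells[keep]
        ids, counts = np.unique(cells, return_counts=True)
        out[w] = dict(zip(ids.tolist(), counts.tolist()))
    return out


class TestNeutralDrift:
    def test_no_growth_forces_uniform_subsample(self):
        series = simulate_neutral_drift(
            DriftParams(rr=0.0, sp=10, bns=5, weeks=1, seed=3))
        week1 = series.counts[1]
        assert sum(week1.values()) == 5
        assert all(v == 1 for v in week1.values())
        assert set(week1) <= set(range(1, 11))

    def test_single_founder_stays_single_clone(self):
        series = simulate_neutral_drift(
            DriftParams(rr=0.05, sp=1, bns=1, weeks=25, seed=0))
        for w in series.weeks:
            assert len(series.counts[w]) == 1
        assert np.allclose(series.entropy_series(), 0.0)

    def test_population_conserved_at_bottleneck(self):
        series = simulate_neutral_drift(
            DriftParams(rr=0.02, sp=50, bns=80, weeks=4, seed=1))
        for w in range(1, 5):
            assert sum(series.counts[w].values()) == 80

    def test_bottleneck_larger_than_population_errors(self):
        with pytest.raises(ValueError, match="week-1"):
            simulate_neutral_drift(
                DriftParams(rr=0.0, sp=10, bns=11, weeks=1, seed=0))

    def test_deterministic_given_seed(self):
        p = DriftParams(rr=0.02, sp=40, bns=40, weeks=3, seed=9)
        a = simulate_neutral_drift(p)
        b = simulate_neutral_drift(p)
        assert a.counts == b.counts

    def test_week0_entropy_is_log2_sp(self):
        series = simulate_neutral_drift(
            DriftParams(rr=0.02, sp=128, bns=128, weeks=1, seed=2))
        assert series.entropy_series()[0] == pytest.approx(np.log2(128))

    def test_matches_cellwise_oracle(self):
        """Clone-wise binomial growth is distributionally identical to the
        cell-wise Bernoulli process: mean final entropy within 2 SE."""
        rr, sp, bns, weeks, hours = 0.02, 60, 60, 3, 168
        n_rep = 120
        fast = [simulate_neutral_drift(
            DriftParams(rr=rr, sp=sp, bns=bns, weeks=weeks, seed=s)
        ).entropy_series().iloc[-1] for s in range(n_rep)]
        slow = [shannon_entropy(
            brute_force_drift(rr, sp, bns, weeks, hours, 10_000 + s)[weeks])
            for s in range(n_rep)]
        fast, slow = np.asarray(fast), np.asarray(slow)
        se = np.sqrt(fast.var() / n_rep + slow.var() / n_rep)
        assert abs(fast.mean() - slow.mean()) < 2 * se


class TestShannonEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ({1: 5, 2: 5, 3: 5, 4: 5}, 2.0),
        ({1: 7}, 0.0),
        ({1: 2, 2: 1, 3: 1}, 1.5),
        ([8, 8], 1.0),
    ])
    def test_closed_forms(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy({1: 0, 2: 0})

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                    max_size=30).filter(lambda c: sum(c) > 0))
    @settings(deadline=None, max_examples=50)
    def test_bounds(self, counts):
        h = shannon_entropy(counts)
        k = sum(1 for c in counts if c > 0)
        assert -1e-9 <= h <= np.log2(max(k, 1)) + 1e-9


class TestNeutralityCheck:
    def test_entropy_collapse_gives_minimal_p(self):
        params = DriftParams(rr=0.03, sp=200, bns=200, weeks=2)
        observed = [np.log2(200), 0.0]  # collapse to one clone in a week
        res = entropy_neutrality_check(observed, params, n_sims=100, seed=1)
        assert res.p_value.iloc[1] <= 1 / 101 + 1e-12

    def test_observed_at_simulation_maximum_gives_p_1(self):
        params = DriftParams(rr=0.02, sp=50, bns=50, weeks=1)
        observed = [np.log2(50), np.log2(50)]  # cannot exceed log2(sp)
        res = entropy_neutrality_check(observed, params, n_sims=100, seed=2)
        assert res.p_value.iloc[1] == 1.0

    def test_series_longer_than_weeks_errors(self):
        with pytest.raises(ValueError):
            entropy_neutrality_check(
                [1.0] * 5, DriftParams(weeks=2), n_sims=100)

    def test_null_calibration(self):
        """Held-out neutral series give roughly uniform p-values."""
        params = DriftParams(rr=0.02, sp=60, bns=60, weeks=3)
        n_trials = 60
        below = 0
        for t in range(n_trials):
            obs = simulate_neutral_drift(
                DriftParams(rr=0.02, sp=60, bns=60, weeks=3,
                            seed=90_000 + t)).entropy_series()
            res = entropy_neutrality_check(obs.to_numpy(), params,
                                           n_sims=100, seed=t)
            below += res.p_value.iloc[-1] <= 0.05
        assert below / n_trials < 0.2  # not anti-conservative


class TestSelectiveGenerator:
    def test_no_events_no_noise_gives_diploid_root_everywhere(self):
        cfg = ExperimentConfig(sp=20, bns=50, weeks=3, sampling={2: 20})
        exp = simulate_selective_evolution(cfg, seed=0)
        assert (exp.profiles.to_numpy() == 2.0).all()
        assert exp.variant_obs.shape[1] == 0
        # one barcode per founder lineage
        per_founder = exp.cells.groupby("founder_id").barcode_id.nunique()
        assert (per_founder == 1).all()

    def test_fitness_multiplier_must_be_positive(self):
        with pytest.raises(ValueError):
            CNVEvent(week=1, segment=0, fitness=0.0)
        with pytest.raises(ValueError):
            SNVEvent(week=1, variant="v", fitness=-1.0)

    def test_barcode_library_smaller_than_founders_errors(self):
        cfg = ExperimentConfig(sp=50, bns=50, barcode_library_size=10)
        with pytest.raises(ValueError, match="library"):
            simulate_selective_evolution(cfg, seed=0)

    def test_deterministic_given_seed(self):
        cfg = ExperimentConfig(
            sp=15, bns=40, weeks=3, sampling={2: 20, 3: 20},
            cnv_events=(CNVEvent(week=2, segment=1, fitness=1.2,
                                 target_founder=-1, n_cells=5),))
        a = simulate_selective_evolution(cfg, seed=7)
        b = simulate_selective_evolution(cfg, seed=7)
        assert a.cells.equals(b.cells)
        assert a.profiles.equals(b.profiles)
        assert a.truth["events"] == b.truth["events"]

    def test_selected_clone_frequency_increases(self):
        cfg = ExperimentConfig(
            sp=20, bns=300, weeks=5, sampling={},
            cnv_events=(CNVEvent(week=2, segment=0, fitness=1.5,
                                 target_founder=-1, n_cells=10),))
        freqs = np.zeros((40, 3))
        for i in range(40):
            exp = simulate_selective_evolution(cfg, seed=i)
            sizes = exp.clone_sizes.counts
            sel = {c["id"] for c in exp.truth["clones"]
                   if c["parent"] != -1}
            for j, w in enumerate([3, 4, 5]):
                tot = sum(sizes[w].values())
                freqs[i, j] = sum(sizes[w].get(c, 0) for c in sel) / tot
        mean = freqs.mean(axis=0)
        assert mean[0] < mean[1] < mean[2]

    def test_two_independent_losses_share_state_vector(self):
        cfg = ExperimentConfig(
            sp=20, bns=200, weeks=4, sampling={},
            cnv_events=(
                CNVEvent(week=2, segment=1, allele=0, delta=-1,
                         target_founder=-1, n_cells=5, name="a"),
                CNVEvent(week=3, segment=1, allele=0, delta=-1,
                         target_founder=-1, n_cells=5, name="b"),
            ))
        exp = simulate_selective_evolution(cfg, seed=4)
        events = [e for e in exp.truth["events"] if e["kind"] == "cnv"]
        assert len(events) == 2
        c1, c2 = (e["clone"] for e in events)
        assert c1 != c2
        assert np.array_equal(exp.clone_state_vector(c1),
                              exp.clone_state_vector(c2))

    def test_event_timestamps_non_decreasing_along_lineages(self):
        cfg = ExperimentConfig(
            sp=15, bns=200, weeks=5, sampling={},
            cnv_events=(CNVEvent(week=2, segment=0, target_founder=-1,
                                 n_cells=8, fitness=1.3),
                        CNVEvent(week=4, segment=1, target_clone=15,
                                 n_cells=4, fitness=1.1)))
        exp = simulate_selective_evolution(cfg, seed=2)
        birth = {c["id"]: c["birth_week"] for c in exp.truth["clones"]}
        for c in exp.truth["clones"]:
            if c["parent"] != -1:
                assert birth[c["parent"]] <= c["birth_week"]
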