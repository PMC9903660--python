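"""Phasing, ternary genotypes, RF filter, imputation, branch classes."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from clonetrace.ssnv import (
    ALT,
    MISS,
    REF,
    build_genotype_matrix,
    classify_branch_variants,
    cooccurrence_log10,
    cooccurrence_test,
    filter_genotype_matrix,
    filter_variants_rf,
    impute_genotypes,
    phase_variants,
    sequence_complexity_features,
)
from clonetrace.tree_inference import ROOT, LineageTree


def molecules(rows):
    return pd.DataFrame(rows, columns=["cell", "variant", "gsnv",
                                       "variant_allele", "gsnv_allele"])


class TestPhasing:
    def test_fully_concordant_variant_retained(self):
        rows = [(f"c{i}", "v1", "g1", "alt", "C") for i in range(20)]
        phased, discarded = phase_variants(molecules(rows))
        assert len(phased) == 1 and discarded.empty
        assert phased[0].concordance == 1.0
        assert phased[0].phase_allele == "C"

    def test_ninety_percent_concordance_discarded(self):
        rows = [(f"c{i}", "v1", "g1", "alt", "C" if i < 18 else "T")
                for i in range(20)]
        phased, discarded = phase_variants(molecules(rows))
        assert phased == []
        assert discarded.reason.iloc[0] == "low_concordance"
        assert discarded.concordance.iloc[0] == pytest.approx(0.9)

    def test_unphaseable_candidate_reported_not_raised(self):
        rows = [("c0", "v1", "g1", "ref", "C")]
        phased, discarded = phase_variants(molecules(rows))
        assert phased == []
        assert discarded.reason.iloc[0] == "unphaseable"

    def test_row_order_invariance(self, rng):
        rows = [(f"c{i}", "v1", "g1", "alt", "C") for i in range(10)]
        rows += [(f"c{i}", "v1", "g2", "alt", "A") for i in range(4)]
        df = molecules(rows)
        shuffled = df.sample(frac=1.0, random_state=1)
        a, _ = phase_variants(df)
        b, _ = phase_variants(shuffled)
        assert a == b

    def test_matches_brute_force_concordance(self, rng):
        # planted phase with per-molecule error: recompute concordance
        # over all (variant, gSNV) pairs independently
        rows = []
        for i in range(30):
            err = rng.random() < 0.01
            rows.append((f"c{i}", "v1", "g1", "alt",
                         "T" if err else "C"))
        df = molecules(rows)
        phased, _ = phase_variants(df)
        per_cell = df.groupby("cell").gsnv_allele.first()
        expected = (per_cell == per_cell.mode().iloc[0]).mean()
        assert phased[0].concordance == pytest.approx(expected)


class TestGenotypeMatrix:
    def test_alt_precedence_and_phase_requirement(self):
        rows = [
            # c0: alt molecule and ref-in-phase molecule -> ALT wins
            ("c0", "v1", "g1", "alt", "C"),
            ("c0", "v1", "g1", "ref", "C"),
            # c1: ref molecule on the phased haplotype -> REF
            ("c1", "v1", "g1", "ref", "C"),
            # c2: coverage only on the other haplotype -> MISSING
            ("c2", "v1", "g1", "ref", "T"),
            # second cell with alt so the variant passes the 2-cell filter
            ("c3", "v1", "g1", "alt", "C"),
        ]
        phased, _ = phase_variants(molecules(rows))
        mat, _, _ = build_genotype_matrix(phased, molecules(rows),
                                          min_cells=2, min_calls=0)
        assert mat.at["c0", "v1"] == ALT
        assert mat.at["c1", "v1"] == REF
        assert mat.at["c2", "v1"] == MISS

    def test_variant_below_two_cells_removed(self):
        mat = pd.DataFrame({"v1": [ALT, REF, REF], "v2": [ALT, ALT, MISS]},
                           index=list("abc"))
        out, dropped_vars, _ = filter_genotype_matrix(mat, min_calls=0)
        assert dropped_vars == ["v1"]
        assert list(out.columns) == ["v2"]

    def test_cells_below_four_calls_removed(self):
        mat = pd.DataFrame(
            {f"v{j}": [ALT, ALT, MISS] for j in range(4)},
            index=list("abc"))
        out, _, dropped_cells = filter_genotype_matrix(mat)
        assert dropped_cells == ["c"]


class TestRFFilter:
    def test_separable_labels_high_cv_accuracy(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.r_[np.ones(30, int), np.zeros(30, int)]
            complexity = np.where(y == 1, rng.normal(100, 10, n),
                                  rng.normal(30, 10, n))
            qual = np.where(y == 1, rng.normal(35, 3, n),
                            rng.normal(15, 3, n))
            feats = pd.DataFrame({"complexity": complexity, "qual": qual})
            _, _, acc = filter_variants_rf(feats, y, seed=seed)
            accs.append(acc)
        assert np.mean(accs) >= 0.9

    def test_constant_features_retain_nothing_confidently(self, rng):
        y = rng.integers(0, 2, 40)
        feats = pd.DataFrame({"a": np.ones(40), "b": np.zeros(40)})
        _, scores, _ = filter_variants_rf(feats, y, threshold=0.9, seed=0)
        assert (scores < 0.9).mean() > 0.8  # scores hover near class prior

    def test_single_class_errors(self):
        feats = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            filter_variants_rf(feats, [1, 1])

    def test_poly_a_window_has_one_unique_5mer(self):
        feats = sequence_complexity_features("A" * 151, windows=(75,),
                                             ks=(5,))
        assert feats["unique_5mers_75bp"] == 1


class TestImputation:
    @staticmethod
    def planted(rng, n_cells=30, missing=0.05):
        g1 = np.array([1] * 5 + [0] * 5)
        g2 = np.array([0] * 5 + [1] * 5)
        rows = []
        for i in range(n_cells):
            g = g1 if i < n_cells // 2 else g2
            obs = np.where(g == 1, ALT, REF).astype(object)
            obs[rng.random(10) < missing] = MISS
            rows.append(obs)
        return pd.DataFrame(rows, index=[f"c{i}" for i in range(n_cells)],
                            columns=[f"v{j}" for j in range(10)])

    def test_two_planted_clones_recovered(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mat = self.planted(rng)
            res = impute_genotypes(mat, n_clones_range=range(1, 5),
                                   seed=seed)
            assert res.n_clones == 2
            first = res.assignments.iloc[:15]
            second = res.assignments.iloc[15:]
            assert first.nunique() == 1 and second.nunique() == 1
            assert first.iloc[0] != second.iloc[0]
            accs.append(res.cv_accuracy)
        assert np.mean(accs) >= 0.95

    def test_no_missing_entries_imputed_equals_input(self, rng):
        mat = self.planted(rng, missing=0.0)
        res = impute_genotypes(mat, n_clones_range=range(1, 4), seed=0,
                               compute_cv=False)
        assert res.imputed.equals(mat)

    def test_impossible_observation_flagged_at_zero_rates(self):
        mat = pd.DataFrame([[ALT] * 6, [ALT] * 6, [ALT] * 5 + [REF]],
                           index=list("abc"),
                           columns=[f"v{j}" for j in range(6)])
        res = impute_genotypes(mat, fn=0.0, fp=0.0,
                               n_clones_range=[1], seed=0,
                               compute_cv=False)
        assert (res.clone_genotypes.to_numpy() == 1).all()
        assert "c" in res.flagged_cells

    def test_empty_matrix_errors(self):
        mat = pd.DataFrame([[MISS, MISS]], index=["a"], columns=["v", "w"])
        with pytest.raises(ValueError):
            impute_genotypes(mat)

    def test_likelihood_reported_finite_on_clean_data(self, rng):
        mat = self.planted(rng, missing=0.1)
        res = impute_genotypes(mat, n_clones_range=[2], seed=0,
                               compute_cv=False)
        assert np.isfinite(res.log_likelihood)


def two_state_tree():
    parent = {(1, 1): ROOT, (2, 1): (1, 1)}
    return LineageTree(parent=parent, weight={(1, 1): 0, (2, 1): 1},
                       abundance={ROOT: 0, (1, 1): 4, (2, 1): 4})


class TestBranchClasses:
    def classify(self, p_calls, c_calls, min_support=1):
        cells = [f"p{i}" for i in range(len(p_calls))] + \
                [f"c{i}" for i in range(len(c_calls))]
        mat = pd.DataFrame({"v1": list(p_calls) + list(c_calls)},
                           index=cells)
        states = pd.Series([1] * len(p_calls) + [2] * len(c_calls),
                           index=cells)
        out = classify_branch_variants(two_state_tree(), mat, states,
                                       min_support=min_support)
        return int(out["class"].iloc[0])

    def test_class1_cnv_after_ssnv(self):
        assert self.classify([ALT, ALT, MISS], [ALT, ALT]) == 1

    def test_class2_ssnv_after_cnv(self):
        assert self.classify([REF, REF], [ALT, ALT]) == 2

    def test_class3_parallel_evolution(self):
        assert self.classify([ALT, REF, ALT, REF], [ALT, REF]) == 3

    def test_min_support_two_demotes_weak_class3(self):
        assert self.classify([ALT, REF, ALT, REF], [ALT, REF],
                             min_support=2) == 0

    def test_ref_only_in_child_is_unclassifiable(self):
        # ALT everywhere in the parent: a lone REF in the child cannot be
        # attributed to a second origin (no wild-type background upstream)
        assert self.classify([ALT, ALT], [ALT, REF, ALT]) == 0


class TestCooccurrence:
    def test_small_case_matches_exact_enumeration(self):
        # P(both of 2 draws are among the 5 A-carriers of 10)
        p = cooccurrence_test(10, 5, 2, 2)
        exact = Fraction(comb(5, 2), comb(10, 2))
        assert p == pytest.approx(float(exact))
        # full brute-force tail over all 2-subsets
        brute = sum(1 for i in range(10) for j in range(i + 1, 10)
                    if i < 5 and j < 5) / comb(10, 2)
        assert p == pytest.approx(brute)

    def test_zero_overlap_tail_is_one(self):
        assert cooccurrence_test(20, 6, 4, 0) == pytest.approx(1.0)

    def test_log_space_matches_exact_rational(self):
        # moderately sized case computed with exact rational arithmetic
        n_total, n_a, n_b, n_ab = 200, 80, 50, 40
        exact = sum(
            Fraction(comb(n_a, k) * comb(n_total - n_a, n_b - k),
                     comb(n_total, n_b))
            for k in range(n_ab, min(n_a, n_b) + 1))
        assert cooccurrence_log10(n_total, n_a, n_b, n_ab) == pytest.approx(
            float(np.log10(float(exact))), abs=1e-9)

    def test_stable_for_large_populations(self):
        log10p = cooccurrence_log10(100_000, 40_000, 20_000, 12_000)
        assert np.isfinite(log10p) and log10p < -100

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            cooccurrence_test(10, 5, 2, 3)
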