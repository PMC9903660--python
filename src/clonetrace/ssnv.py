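"""Somatic-SNV phasing, ternary genotypes, imputation and branch classes.

Somatic SNVs (sSNVs) in single cells suffer allele dropout: absence of an
alt read does not mean absence of the mutation.  Phasing each candidate
sSNV to a nearby heterozygous germline SNV (gSNV) fixes this — a molecule
carrying the phased gSNV allele together with the reference base at the
sSNV locus is positive evidence of absence.  Each cell/variant is then
ALT ("A"), REF-in-phase ("R") or MISSING ("."), the ternary genotype
matrix.  Candidate artifacts are filtered with a random forest on caller
annotations plus sequence-complexity features; missing genotypes are
imputed with a maximum-likelihood clone model honoring fixed
false-negative/false-positive rates; and at each branch point of the
clonal tree, variants are classified into three classes, where class 3
(ALT and REF on both sides of the branch) implies the branch's copy-number
change occurred at least twice — parallel evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .tree_inference import ROOT, LineageTree

__all__ = [
    "PhasedVariant",
    "phase_variants",
    "build_genotype_matrix",
    "filter_genotype_matrix",
    "sequence_complexity_features",
    "filter_variants_rf",
    "impute_genotypes",
    "ImputationResult",
    "classify_branch_variants",
    "cooccurrence_test",
    "cooccurrence_log10",
]

ALT, REF, MISS = "A", "R", "."


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedVariant:
    """A candidate sSNV linked to a heterozygous gSNV.

    ``phase_allele`` is the gSNV allele the sSNV alt rides on;
    ``concordance`` the fraction of alt-informative cells consistent with
    that phase.
    """

    variant: str
    gsnv: str
    phase_allele: str
    concordance: float
    n_informative: int


def phase_variants(molecules: pd.DataFrame,
                   min_concordance: float = 0.95):
    """Phase candidate sSNVs to germline heterozygous SNVs.

    Parameters
    ----------
    molecules : DataFrame with columns cell, variant, gsnv, variant_allele
        ("alt"/"ref"), gsnv_allele — one row per molecule spanning an
        (sSNV, gSNV) pair.
    min_concordance : float
        Minimum fraction of alt-informative cells whose alt molecules carry
        the modal gSNV allele; candidates below are discarded.

    Returns
    -------
    (phased, discarded) : (list[PhasedVariant], DataFrame)
        Discarded candidates carry reason codes "unphaseable" (no spanning
        molecule with an alt read) or "low_concordance".
    """
    phased: list[PhasedVariant] = []
    discarded = []
    molecules = molecules.sort_values(["variant", "gsnv", "cell"],
                                      kind="stable")
    for variant, vgrp in molecules.groupby("variant", sort=True):
        # best-linked gSNV: maximum number of cells with spanning molecules
        n_cells = vgrp.groupby("gsnv")["cell"].nunique()
        best_gsnv = n_cells.sort_values(ascending=False,
                                        kind="stable").index[0]
        sub = vgrp[vgrp.gsnv == best_gsnv]
        alt = sub[sub.variant_allele == "alt"]
        if alt.empty:
            discarded.append({"variant": variant, "reason": "unphaseable"})
            continue
        # modal gSNV allele on alt molecules defines the phase
        phase = alt.gsnv_allele.mode().iloc[0]
        per_cell = alt.groupby("cell").gsnv_allele.agg(
            lambda s: s.mode().iloc[0])
        concordance = float((per_cell == phase).mean())
        if concordance < min_concordance:
            discarded.append({"variant": variant,
                              "reason": "low_concordance",
                              "concordance": concordance})
            continue
        phased.append(PhasedVariant(variant=variant, gsnv=str(best_gsnv),
                                    phase_allele=str(phase),
                                    concordance=concordance,
                                    n_informative=int(per_cell.size)))
    return phased, pd.DataFrame(discarded,
                                columns=["variant", "reason", "concordance"])


def build_genotype_matrix(phased: list[PhasedVariant],
                          molecules: pd.DataFrame,
                          min_cells: int = 2, min_calls: int = 4):
    """Ternary genotype matrix (cells × phased sSNVs).

    A cell is ALT if any of its molecules carries the variant's alt allele
    (alt precedence), REF if a molecule carries the reference base together
    with the phased gSNV allele, else MISSING.  Columns with ALT in fewer
    than ``min_cells`` cells and rows with fewer than ``min_calls``
    non-missing calls are then removed (reported).

    Returns (matrix, dropped_variants, dropped_cells).
    """
    cells = sorted(molecules.cell.unique())
    mat = pd.DataFrame(MISS, index=cells,
                       columns=[p.variant for p in phased], dtype=object)
    for p in phased:
        sub = molecules[(molecules.variant == p.variant)
                        & (molecules.gsnv == p.gsnv)]
        for cell, grp in sub.groupby("cell"):
            if (grp.variant_allele == "alt").any():
                mat.at[cell, p.variant] = ALT
            elif ((grp.variant_allele == "ref")
                  & (grp.gsnv_allele == p.phase_allele)).any():
                mat.at[cell, p.variant] = REF
    return filter_genotype_matrix(mat, min_cells=min_cells,
                                  min_calls=min_calls)


def filter_genotype_matrix(matrix: pd.DataFrame, min_cells: int = 2,
                           min_calls: int = 4):
    """Apply the >=min_cells-ALT column and >=min_calls-row filters."""
    alt_cells = (matrix == ALT).sum(axis=0)
    keep_vars = alt_cells[alt_cells >= min_cells].index
    dropped_vars = [v for v in matrix.columns if v not in set(keep_vars)]
    mat = matrix[keep_vars]
    n_calls = (mat != MISS).sum(axis=1)
    keep_cells = n_calls[n_calls >= min_calls].index
    dropped_cells = [c for c in mat.index if c not in set(keep_cells)]
    return mat.loc[keep_cells], dropped_vars, dropped_cells


# ---------------------------------------------------------------------------
# Random-forest artifact filter
# ---------------------------------------------------------------------------

def sequence_complexity_features(context: str,
                                 windows=(75, 150, 300, 500, 1000),
                                 ks=(5, 7)) -> dict:
    """Unique k-mer counts in centered windows of the reference context.

    ``context`` is the reference sequence centered on the variant position;
    windows larger than the context use the full context.
    """
    mid = len(context) // 2
    feats = {}
    for w in windows:
        half = w // 2
        sub = context[max(0, mid - half):mid + half]
        for k in ks:
            kmers = {sub[i:i + k] for i in range(max(0, len(sub) - k + 1))}
            feats[f"unique_{k}mers_{w}bp"] = len(kmers)
    return feats


def filter_variants_rf(features: pd.DataFrame, labels, n_trees: int = 100,
                       threshold: float = 0.5, seed: int = 0):
    """Random-forest artifact filter with cross-validated scores.

    Leave-one-out cross-validation for <= 500 candidates, stratified
    10-fold beyond; class-balanced forest.  Returns (retained_index,
    scores, cv_accuracy).
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = features.to_numpy(dtype=float)
    n = len(y)
    scores = np.zeros(n)
    splitter = (LeaveOneOut() if n <= 500
                else StratifiedKFold(n_splits=10, shuffle=True,
                                     random_state=seed))
    for train, test in splitter.split(x, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    class_weight="balanced")
        rf.fit(x[train], y[train])
        if len(rf.classes_) == 1:
            scores[test] = float(rf.classes_[0])
        else:
            col = list(rf.classes_).index(1)
            scores[test] = rf.predict_proba(x[test])[:, col]
    scores = pd.Series(scores, index=features.index, name="rf_score")
    retained = scores[scores >= threshold].index
    cv_accuracy = float(((scores >= 0.5).astype(int) == y).mean())
    return retained, scores, cv_accuracy


# ---------------------------------------------------------------------------
# Imputation (maximum-likelihood clone model)
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    assignments: pd.Series          # cell -> clone index
    clone_genotypes: pd.DataFrame   # clones × variants, 0/1
    imputed: pd.DataFrame           # observed values kept, MISSING imputed
    log_likelihood: float
    n_clones: int
    cv_accuracy: float | None = None
    flagged_cells: list = None      # cells with impossible observations


def _encode(matrix: pd.DataFrame) -> np.ndarray:
    enc = np.full(matrix.shape, -1, dtype=np.int8)
    enc[(matrix == ALT).to_numpy()] = 1
    enc[(matrix == REF).to_numpy()] = 0
    return enc


_LOG_ZERO = -1e9  # finite stand-in for log(0): keeps arithmetic NaN-free
                  # while making impossible observations dominate


def _log_or_zero(p: float) -> float:
    return np.log(p) if p > 0 else _LOG_ZERO


def _fit_clones(obs: np.ndarray, n_clones: int, fn: float, fp: float,
                seed: int, max_iter: int = 50):
    """Hard-EM clone model: alternating genotype re-estimation and
    maximum-likelihood cell assignment.  Log-likelihood never decreases."""
    l_alt_g1, l_alt_g0 = _log_or_zero(1 - fn), _log_or_zero(fp)
    l_ref_g1, l_ref_g0 = _log_or_zero(fn), _log_or_zero(1 - fp)
    n_cells, n_vars = obs.shape
    isalt = (obs == 1).astype(float)
    isref = (obs == 0).astype(float)
    # initialise with k-means on a numeric encoding (missing -> 0.5)
    num = np.where(obs == 1, 1.0, np.where(obs == 0, 0.0, 0.5))
    km = KMeans(n_clusters=min(n_clones, n_cells), random_state=seed,
                n_init=10).fit(num)
    assign = km.labels_.astype(int)
    prev_ll = -np.inf
    genotypes = np.zeros((n_clones, n_vars), dtype=np.int8)
    for _ in range(max_iter):
        # genotype per clone per variant: pick g maximizing member likelihood
        for c in range(n_clones):
            members = assign == c
            if not members.any():
                genotypes[c] = 0
                continue
            n_alt = isalt[members].sum(axis=0)
            n_ref = isref[members].sum(axis=0)
            ll1 = n_alt * l_alt_g1 + n_ref * l_ref_g1
            ll0 = n_alt * l_alt_g0 + n_ref * l_ref_g0
            genotypes[c] = (ll1 >= ll0).astype(np.int8)
        # cell assignment: clone maximizing the cell's likelihood
        ll_cell = np.zeros((n_cells, n_clones))
        for c in range(n_clones):
            g = genotypes[c]
            l_alt = np.where(g == 1, l_alt_g1, l_alt_g0)
            l_ref = np.where(g == 1, l_ref_g1, l_ref_g0)
            ll_cell[:, c] = isalt @ l_alt + isref @ l_ref
        new_assign = np.argmax(ll_cell, axis=1)
        ll = float(ll_cell[np.arange(n_cells), new_assign].sum())
        if np.array_equal(new_assign, assign) and ll <= prev_ll + 1e-9:
            prev_ll = ll
            break
        assign = new_assign
        prev_ll = ll
    return assign, genotypes, prev_ll


def impute_genotypes(matrix: pd.DataFrame, fn: float = 0.001,
                     fp: float = 0.0001, n_clones_range=range(1, 9),
                     seed: int = 0, cv_folds: int = 10,
                     compute_cv: bool = True) -> ImputationResult:
    """Cluster cells into clones and impute missing ternary genotypes.

    A stand-in for Gibbs-sampling clone inference: cells are assigned to
    clones by maximum likelihood under a per-entry error model with fixed
    false-negative (``fn``, ALT missed) and false-positive (``fp``,
    spurious ALT) rates; clone genotypes are re-estimated until
    convergence (hard EM, monotone log-likelihood).  The clone count is
    chosen from ``n_clones_range`` by BIC.  MISSING entries are imputed
    from the assigned clone's genotype; ``cv_accuracy`` masks 10% of
    non-missing entries per fold and scores their recovery.
    """
    obs = _encode(matrix)
    n_obs = int((obs >= 0).sum())
    if n_obs == 0:
        raise ValueError("genotype matrix has no non-missing entries")
    best = None
    for k in n_clones_range:
        if k > len(matrix):
            continue
        assign, genotypes, ll = _fit_clones(obs, k, fn, fp, seed)
        bic = -2 * ll + k * matrix.shape[1] * np.log(max(n_obs, 2))
        if best is None or bic < best[0]:
            best = (bic, k, assign, genotypes, ll)
    _, k, assign, genotypes, ll = best

    flagged = [matrix.index[i] for i in range(len(matrix))
               if not np.isfinite(_cell_ll(obs[i], genotypes[assign[i]],
                                           fn, fp))]
    imputed = matrix.copy()
    for i, cell in enumerate(matrix.index):
        g = genotypes[assign[i]]
        miss = obs[i] == -1
        imputed.loc[cell, matrix.columns[miss]] = np.where(
            g[miss] == 1, ALT, REF)

    cv_acc = None
    if compute_cv:
        cv_acc = _cv_accuracy(matrix, obs, k, fn, fp, seed, cv_folds)
    return ImputationResult(
        assignments=pd.Series(assign, index=matrix.index, name="clone"),
        clone_genotypes=pd.DataFrame(genotypes, columns=matrix.columns),
        imputed=imputed, log_likelihood=ll, n_clones=k,
        cv_accuracy=cv_acc, flagged_cells=flagged)


def _cell_ll(row: np.ndarray, g: np.ndarray, fn: float, fp: float) -> float:
    """True log-likelihood of one cell (−inf if an observation is
    impossible under the error model, e.g. a REF call at fp = 0)."""
    with np.errstate(divide="ignore"):
        l_alt = np.where(g == 1, np.log(1 - fn), np.log(fp))
        l_ref = np.where(g == 1, np.log(fn), np.log(1 - fp))
    return float(l_alt[row == 1].sum() + l_ref[row == 0].sum())


def _cv_accuracy(matrix, obs, n_clones, fn, fp, seed, folds) -> float:
    rng = np.random.default_rng(seed)
    observed = np.argwhere(obs >= 0)
    rng.shuffle(observed)
    fold_id = np.arange(len(observed)) % folds
    hits = total = 0
    for f in range(folds):
        mask = observed[fold_id == f]
        obs_masked = obs.copy()
        obs_masked[mask[:, 0], mask[:, 1]] = -1
        assign, genotypes, _ = _fit_clones(obs_masked, n_clones, fn, fp, seed)
        pred = genotypes[assign[mask[:, 0]], mask[:, 1]]
        truth = obs[mask[:, 0], mask[:, 1]]
        hits += int((pred == truth).sum())
        total += len(mask)
    return hits / total if total else float("nan")


# ---------------------------------------------------------------------------
# Branch-point classification
# ---------------------------------------------------------------------------

def classify_branch_variants(tree: LineageTree, matrix: pd.DataFrame,
                             cell_states: pd.Series,
                             min_support: int = 1) -> pd.DataFrame:
    """Classify sSNVs at each branch point of the clonal tree.

    For a branch parent P -> child C, with ALT/REF counts among P-member
    and C-member cells:

    * class 1 — CNV after sSNV: ALT on both sides and REF never seen in C;
    * class 2 — sSNV after CNV: ALT only in C, REF seen in P;
    * class 3 — parallel evolution: ALT and REF both present (each with at
      least ``min_support`` cells) on BOTH sides, implying the CNV occurred
      at least twice;
    * otherwise unclassifiable.

    ``cell_states`` maps cell id -> state id.  Returns a long DataFrame
    (variant, parent, child, class, support counts).
    """
    spm = tree.state_parent_map()
    members: dict = {}
    for cell, s in cell_states.items():
        members.setdefault(s, []).append(cell)
    rows = []
    for child, parent in spm.items():
        if parent == ROOT:
            continue
        p_cells = [c for c in members.get(parent, []) if c in matrix.index]
        c_cells = [c for c in members.get(child, []) if c in matrix.index]
        if not p_cells or not c_cells:
            continue
        pm = matrix.loc[p_cells]
        cm = matrix.loc[c_cells]
        for var in matrix.columns:
            ap = int((pm[var] == ALT).sum())
            rp = int((pm[var] == REF).sum())
            ac = int((cm[var] == ALT).sum())
            rc = int((cm[var] == REF).sum())
            ms = min_support
            if ap >= ms and ac >= ms and rc == 0:
                cls = 1
            elif ap == 0 and ac >= ms and rp >= ms:
                cls = 2
            elif ap >= ms and rp >= ms and ac >= ms and rc >= ms:
                cls = 3
            else:
                cls = 0  # unclassifiable
            rows.append({"variant": var, "parent": parent, "child": child,
                         "class": cls, "alt_parent": ap, "ref_parent": rp,
                         "alt_child": ac, "ref_child": rc})
    return pd.DataFrame(rows, columns=["variant", "parent", "child", "class",
                                       "alt_parent", "ref_parent",
                                       "alt_child", "ref_child"])


# ---------------------------------------------------------------------------
# Hypergeometric co-occurrence
# ---------------------------------------------------------------------------

def _check_cooc(n_total, n_a, n_b, n_ab):
    if not (0 <= n_ab <= min(n_a, n_b) <= max(n_a, n_b) <= n_total):
        raise ValueError(
            f"inconsistent counts: n_total={n_total}, n_A={n_a}, "
            f"n_B={n_b}, n_AB={n_ab}")


def cooccurrence_log10(n_total: int, n_a: int, n_b: int, n_ab: int) -> float:
    """log10 of the upper-tail hypergeometric co-occurrence probability.

    Computed in log space (sum of log-pmfs over the tail), stable for
    populations up to 1e5 where the probability itself underflows.
    """
    _check_cooc(n_total, n_a, n_b, n_ab)
    ks = np.arange(n_ab, min(n_a, n_b) + 1)
    if ks.size == 0:
        return 0.0
    logs = hypergeom.logpmf(ks, n_total, n_a, n_b)
    return float(logsumexp(logs) / np.log(10))


def cooccurrence_test(n_total: int, n_a: int, n_b: int, n_ab: int) -> float:
    """Upper-tail hypergeometric probability of >= n_AB doubly aberrant
    samples when n_B are drawn from n_total of which n_A carry A."""
    return float(10.0 ** cooccurrence_log10(n_total, n_a, n_b, n_ab))
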