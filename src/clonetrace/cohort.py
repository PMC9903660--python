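"""Cohort-level ordered-loss and conditional-hazard analyses.

Works on tables of per-contig log copy ratios (chromosomes 1..22 with 8
split into 8p/8q) plus recurrence-free survival.  Provides: a correlated
synthetic cohort generator with proportional-hazards survival, loss calls
at a fixed log-ratio threshold, a permutation test for the ordering of two
chromosome losses (is chr18 below chr4 more often than chance?), the
log-rank comparison of two event strata, and a systematic priming /
conditional aberration Cox scan with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortConfig",
    "simulate_cohort",
    "call_losses",
    "ordering_permutation_test",
    "conditional_hazard_scan",
    "logrank_compare",
    "DEFAULT_CONTIGS",
]

DEFAULT_CONTIGS = tuple(
    [f"chr{i}" for i in range(1, 8)] + ["chr8p", "chr8q"]
    + [f"chr{i}" for i in range(9, 23)]
)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Log ratios come from a Gaussian-copula mixture: per contig, a sample is
    in the loss component with probability ``prevalence`` (correlated
    across contigs via ``correlation``), drawn near ``loss_mean``; else
    near 0.  Survival is exponential with per-sample hazard
    ``base_hazard`` multiplied by the effect of every event combination in
    ``hazard_effects`` that the sample carries, administratively censored
    at ``followup_months``.
    """

    n_samples: int = 1000
    contigs: tuple = DEFAULT_CONTIGS
    prevalences: dict = field(default_factory=dict)   # contig -> P(loss)
    default_prevalence: float = 0.15
    correlation: np.ndarray | None = None             # contig × contig
    loss_mean: float = -0.6
    loss_sd: float = 0.1
    neutral_sd: float = 0.1
    base_hazard: float = 0.01                          # events per month
    hazard_effects: tuple = ()   # ((frozenset of contigs lost, multiplier), ...)
    followup_months: float = 120.0
    loss_threshold: float = -0.4


def simulate_cohort(config: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns a DataFrame indexed by sample id with one log-ratio column per
    contig plus ``rfs_months``, ``rfs_event`` and ``mss_flag``.
    """
    rng = np.random.default_rng(seed)
    contigs = list(config.contigs)
    m = len(contigs)
    corr = (np.eye(m) if config.correlation is None
            else np.asarray(config.correlation, dtype=float))
    if corr.shape != (m, m):
        raise ValueError(f"correlation matrix must be {m}x{m}")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g})")
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    z = rng.standard_normal((config.n_samples, m)) @ chol.T
    u = norm.cdf(z)
    prev = np.array([config.prevalences.get(c, config.default_prevalence)
                     for c in contigs])
    is_loss = u < prev[None, :]
    ratios = np.where(
        is_loss,
        rng.normal(config.loss_mean, config.loss_sd, size=z.shape),
        rng.normal(0.0, config.neutral_sd, size=z.shape),
    )
    table = pd.DataFrame(ratios, columns=contigs,
                         index=[f"s{i:05d}" for i in range(config.n_samples)])

    losses = call_losses(table, threshold=config.loss_threshold)
    hazard = np.full(config.n_samples, config.base_hazard)
    for combo, mult in config.hazard_effects:
        carries = losses[list(combo)].all(axis=1).to_numpy()
        hazard = np.where(carries, hazard * mult, hazard)
    t_event = rng.exponential(1.0 / hazard)
    observed = t_event <= config.followup_months
    table["rfs_months"] = np.where(observed, t_event, config.followup_months)
    table["rfs_event"] = observed.astype(int)
    table["mss_flag"] = 1
    return table


def _ratio_columns(table: pd.DataFrame) -> list:
    meta = {"rfs_months", "rfs_event", "mss_flag"}
    return [c for c in table.columns if c not in meta]


def call_losses(table: pd.DataFrame, threshold: float = -0.4) -> pd.DataFrame:
    """Boolean loss calls: log copy ratio strictly below ``threshold``."""
    cols = _ratio_columns(table)
    return table[cols] < threshold


def ordering_permutation_test(r18, r4, n_perm: int = 100_000,
                              seed: int = 0) -> dict:
    """Permutation test for enrichment of samples with r18 below r4.

    The observed statistic is the fraction of samples where the chr18 log
    ratio is strictly below the chr4 log ratio; the null shuffles the chr4
    ratios across samples.  The enrichment p-value is
    (1 + #{permutation statistic >= observed}) / (n_perm + 1).

    Returns a dict with observed_fraction, reverse_fraction (r4 < r18,
    reported for symmetry), p_enrichment, n_perm and seed.
    """
    r18 = np.asarray(r18, dtype=float)
    r4 = np.asarray(r4, dtype=float)
    if r18.shape != r4.shape or r18.ndim != 1 or r18.size < 2:
        raise ValueError("r18 and r4 must be equal-length vectors (n >= 2)")
    if n_perm < 1000:
        import warnings
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    n = r18.size
    observed = float(np.mean(r18 < r4))
    n_ge = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        stats = (r18[None, :] < r4[idx]).mean(axis=1)
        n_ge += int((stats >= observed - 1e-12).sum())
        done += b
    p = (1 + n_ge) / (n_perm + 1)
    return {"observed_fraction": observed,
            "reverse_fraction": float(np.mean(r4 < r18)),
            "p_enrichment": float(p), "n_perm": n_perm, "seed": seed}


def logrank_compare(table: pd.DataFrame, group_a, group_b) -> dict:
    """Log-rank test between two sample strata of the cohort table.

    ``group_a`` / ``group_b`` are boolean masks or index lists selecting
    samples; returns the test statistic and p-value.
    """
    a = table.loc[group_a]
    b = table.loc[group_b]
    if a.empty or b.empty:
        raise ValueError("both strata must be non-empty")
    if a.rfs_event.sum() + b.rfs_event.sum() == 0:
        raise ValueError("no events in either stratum; log-rank undefined")
    res = logrank_test(a.rfs_months, b.rfs_months,
                       event_observed_A=a.rfs_event,
                       event_observed_B=b.rfs_event)
    return {"statistic": float(res.test_statistic),
            "p_value": float(res.p_value),
            "n_a": len(a), "n_b": len(b)}


def conditional_hazard_scan(table: pd.DataFrame, contig_filter: float = 0.4,
                            min_samples: int = 30, alpha: float = 0.05,
                            aberration_threshold: float = 0.4,
                            filter_scope: str = "aberrant") -> pd.DataFrame:
    """Priming/conditional aberration Cox scan with BH correction.

    Contigs pass the magnitude filter when the mean |log ratio| — over
    aberrant samples (|ratio| > ``aberration_threshold``) by default, over
    all samples with ``filter_scope="all"`` — exceeds ``contig_filter``.
    Each contig's aberration direction (loss or gain) is the sign of its
    mean aberrant log ratio.  For every ordered (priming, conditional)
    pair with at least ``min_samples`` samples carrying both events, a Cox
    proportional-hazards model on the priming-event carriers compares
    samples with both events against priming-only samples.

    Returns a DataFrame with one row per retained pair: priming,
    conditional, direction labels, |correlation| of the log ratios,
    n_both, n_priming_only, hazard_ratio, p, p_bh, significant.
    """
    cols = _ratio_columns(table)
    ratios = table[cols]
    aberrant = ratios.abs() > aberration_threshold
    passed = []
    directions = {}
    for c in cols:
        sub = ratios[c][aberrant[c]]
        if sub.empty:
            continue
        scope = sub.abs().mean() if filter_scope == "aberrant" \
            else ratios[c].abs().mean()
        if scope > contig_filter:
            passed.append(c)
            directions[c] = "loss" if sub.mean() < 0 else "gain"

    def event_mask(c):
        if directions[c] == "loss":
            return ratios[c] < -aberration_threshold
        return ratios[c] > aberration_threshold

    rows = []
    for prim in passed:
        for cond in passed:
            if prim == cond:
                continue
            ep, ec = event_mask(prim), event_mask(cond)
            both = ep & ec
            prim_only = ep & ~ec
            if int(both.sum()) < min_samples or int(prim_only.sum()) == 0:
                continue
            sub = table.loc[ep, ["rfs_months", "rfs_event"]].copy()
            sub["conditional"] = ec[ep].astype(int).to_numpy()
            if sub.rfs_event.sum() == 0:
                continue
            cph = CoxPHFitter()
            try:
                cph.fit(sub, duration_col="rfs_months",
                        event_col="rfs_event")
            except Exception:
                continue
            hr = float(np.exp(cph.params_["conditional"]))
            p = float(cph.summary.loc["conditional", "p"])
            corr = float(abs(np.corrcoef(ratios[prim], ratios[cond])[0, 1]))
            rows.append({"priming": prim, "conditional": cond,
                         "priming_direction": directions[prim],
                         "conditional_direction": directions[cond],
                         "abs_correlation": corr,
                         "n_both": int(both.sum()),
                         "n_priming_only": int(prim_only.sum()),
                         "hazard_ratio": hr, "p": p})
    out = pd.DataFrame(rows, columns=["priming", "conditional",
                                      "priming_direction",
                                      "conditional_direction",
                                      "abs_correlation", "n_both",
                                      "n_priming_only", "hazard_ratio", "p"])
    if out.empty:
        out["p_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out.attrs["diagnostics"] = {"contigs_passed": passed,
                                    "n_pairs_tested": 0}
        return out
    reject, p_bh, _, _ = multipletests(out.p, alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_bh
    out["significant"] = reject
    out.attrs["diagnostics"] = {"contigs_passed": passed,
                                "n_pairs_tested": len(out)}
    return out
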