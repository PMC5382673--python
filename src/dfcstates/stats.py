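"""Occupancy/transition metrics and the group-level statistics.

Per subject we summarize the state-assignment vector by its reoccurrence
times (windows per state) and its transition frequency per unordered state
pair.  Group differences on the pooled count tables are tested by Pearson
chi-square with Benjamini-Hochberg corrected post-hoc 2x2 partitions, and
brain-behaviour associations use covariate-adjusted (partial) Pearson
correlation.  A summary-statistics two-sample t-test covers demographic
tables reported as mean/sd/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cluster import StateModel


def state_pairs(K: int) -> list[tuple[int, int]]:
    """Unordered state pairs (1-based), in (1,2), (1,3), ... order."""
    return [(a, b) for a in range(1, K + 1) for b in range(a + 1, K + 1)]


def occupancy(assignment_vector, K: int) -> np.ndarray:
    """Reoccurrence times: windows assigned to each state (length-K counts)."""
    a = np.asarray(assignment_vector, dtype=int)
    if a.size and (a.min() < 1 or a.max() > K):
        raise ValueError("state labels must lie in 1..K")
    return np.bincount(a, minlength=K + 1)[1:]


def transition_counts(assignment_vector, K: int):
    """Transition frequency per unordered state pair.

    Returns ``(pair_counts, total)`` where ``pair_counts`` follows the
    :func:`state_pairs` order; a transition from state a to b and from b to
    a increment the same pair.
    """
    a = np.asarray(assignment_vector, dtype=int)
    if a.size and (a.min() < 1 or a.max() > K):
        raise ValueError("state labels must lie in 1..K")
    pairs = state_pairs(K)
    index = {p: i for i, p in enumerate(pairs)}
    counts = np.zeros(len(pairs), dtype=int)
    for prev, cur in zip(a[:-1], a[1:]):
        if prev != cur:
            counts[index[(min(prev, cur), max(prev, cur))]] += 1
    return counts, int(counts.sum())


@dataclass
class StateTransitionProfile:
    subject_id: str
    occupancy: np.ndarray
    pair_transitions: np.ndarray
    total_transitions: int


def profile_subject(subject_id: str, assignment_vector,
                    K: int) -> StateTransitionProfile:
    occ = occupancy(assignment_vector, K)
    pc, total = transition_counts(assignment_vector, K)
    return StateTransitionProfile(subject_id=subject_id, occupancy=occ,
                                  pair_transitions=pc,
                                  total_transitions=total)


def profiles_from_model(model: StateModel) -> pd.DataFrame:
    """One row per subject: occupancy_1..K, pair transition counts, total."""
    rows = []
    pairs = state_pairs(model.K)
    for sid in sorted(model.assignments):
        p = profile_subject(sid, model.assignments[sid], model.K)
        row = {"subject_id": sid}
        row.update({f"occupancy_{k}": int(c)
                    for k, c in enumerate(p.occupancy, start=1)})
        row.update({f"trans_{a}_{b}": int(c)
                    for (a, b), c in zip(pairs, p.pair_transitions)})
        row["total_transitions"] = p.total_transitions
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    df: int
    p: float
    posthoc: pd.DataFrame | None = None


def chi_square_table(table) -> GroupTestResult:
    """Pearson chi-square on a 2 x M count table (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("need a 2-D count table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("row and column sums must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected <= 0).any():
        raise ValueError("expected cell count of zero")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return GroupTestResult(test="chi-square", statistic=float(stat),
                           df=int(df), p=float(p))


def posthoc_categories(table, alpha: float = 0.05,
                       categories=None) -> pd.DataFrame:
    """Per-category 2x2 chi-square follow-up with BH-FDR across categories.

    Each category is tested against the pool of the remaining categories
    (2 groups x {category, rest}).  Returns a table with raw p, BH q, and
    both FDR-corrected and uncorrected significance flags at ``alpha``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("need a 2 x M count table")
    M = t.shape[1]
    if categories is None:
        categories = list(range(1, M + 1))
    ps = []
    stats_ = []
    for m in range(M):
        sub = np.array([[t[0, m], t[0].sum() - t[0, m]],
                        [t[1, m], t[1].sum() - t[1, m]]])
        res = chi_square_table(sub)
        ps.append(res.p)
        stats_.append(res.statistic)
    reject, q, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({
        "category": categories,
        "statistic": stats_,
        "p": ps,
        "q": q,
        "significant_fdr": reject,
        "significant_uncorrected": np.asarray(ps) < alpha,
    })


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags."""
    reject, _, _, _ = multipletests(np.asarray(pvalues, float), alpha=alpha,
                                    method="fdr_bh")
    return reject


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of x and y after residualizing on covariates.

    Covariates with zero variance are dropped (an intercept is always
    included).  Returns ``(r, p, df)`` with df = n - 2 - q for q retained
    covariates; p is two-sided via the t transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        keep = Z.std(axis=0) > 0
        Z = Z[:, keep]
    q = Z.shape[1]
    if n <= q + 3:
        raise ValueError(f"need n > q + 3 (n={n}, q={q})")
    design = np.column_stack([np.ones(n), Z])
    proj = design @ np.linalg.pinv(design)
    rx = x - proj @ x
    ry = y - proj @ y
    if rx.var() < 1e-12 or ry.var() < 1e-12:
        raise ValueError("a covariate is collinear with x or y "
                         "(zero residual variance)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p), int(df)


def t_from_summary(m1: float, sd1: float, n1: int,
                   m2: float, sd2: float, n2: int):
    """Pooled-variance two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2; p is two-sided.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def group_count_tables(profiles: pd.DataFrame, sample_sheet: pd.DataFrame,
                       K: int):
    """Pooled 2 x K occupancy and 2 x K(K-1)/2 transition tables by group.

    Groups are taken in sorted label order; rows of the returned tables
    follow that order.
    """
    merged = profiles.merge(sample_sheet[["subject_id", "group"]],
                            on="subject_id")
    groups = sorted(merged["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly 2 groups are required")
    occ_cols = [f"occupancy_{k}" for k in range(1, K + 1)]
    pair_cols = [f"trans_{a}_{b}" for a, b in state_pairs(K)]
    occ = np.vstack([merged.loc[merged["group"] == g, occ_cols].sum()
                     for g in groups])
    trans = np.vstack([merged.loc[merged["group"] == g, pair_cols].sum()
                       for g in groups])
    return occ, trans, groups


def transition_rate_table(profiles: pd.DataFrame,
                          sample_sheet: pd.DataFrame) -> np.ndarray:
    """2 x 2 table of transition frequency: switches vs non-switch steps.

    Each subject contributes W - 1 consecutive-window steps (W = total
    windows, recovered from the occupancy columns); the table pools, per
    group, how many of those steps changed state.  Unlike the pair-
    distribution table this is sensitive to an overall switching-rate
    difference between groups.
    """
    merged = profiles.merge(sample_sheet[["subject_id", "group"]],
                            on="subject_id")
    groups = sorted(merged["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly 2 groups are required")
    occ_cols = [c for c in merged.columns if c.startswith("occupancy_")]
    rows = []
    for g in groups:
        sub = merged[merged["group"] == g]
        switches = int(sub["total_transitions"].sum())
        opportunities = int((sub[occ_cols].sum(axis=1) - 1).sum())
        rows.append([switches, opportunities - switches])
    return np.asarray(rows)


def per_subject_group_means(profiles: pd.DataFrame,
                            sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Subject-level means of every metric column by group (companion view
    to the pooled-count chi-square, which ignores within-subject
    dependence)."""
    merged = profiles.merge(sample_sheet[["subject_id", "group"]],
                            on="subject_id")
    return merged.drop(columns="subject_id").groupby("group").mean()


def permutation_group_test(values, groups, n_permutations: int = 5000,
                           seed: int | None = None) -> float:
    """Subject-level permutation test of a group difference in means.

    Alternative to the pooled-count chi-square that respects the subject as
    the sampling unit. Returns the two-sided p-value for the observed
    difference of group means under random relabeling.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly 2 groups are required")
    mask = g == labels[0]
    obs = abs(v[mask].mean() - v[~mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(mask)
        diff = abs(v[perm].mean() - v[~perm].mean())
        if diff >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)
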