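"""Biomarker evaluation: rank tests, ROC/AUC and stratified-bootstrap CIs.

The Mann-Whitney statistic and the AUC are deliberately implemented from the
same midrank machinery so that the identity ``AUC = U / (n1 * n2)`` holds
exactly; small tie-free problems are tested by full enumeration rather than
the normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

EXACT_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney U statistic and p-value for x versus y."""

    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= self.n_x * self.n_y:
            raise ValueError("U must lie in [0, n1*n2]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class RocResult:
    """AUC with a stratified-bootstrap percentile confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the point AUC")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected (midrank) U for x versus y."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_p(u_obs: float, n1: int, n2: int, alternative: str) -> float:
    """Exact p by enumerating every assignment of ranks to x (no ties)."""
    n = n1 + n2
    offset = n1 * (n1 + 1) // 2
    total = comb(n, n1)
    ge = le = 0
    for ranks in combinations(range(1, n + 1), n1):
        u = sum(ranks) - offset
        if u >= u_obs - 1e-9:
            ge += 1
        if u <= u_obs + 1e-9:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> TestResult:
    """Unpaired two-sample Mann-Whitney test (midrank ties).

    Uses exact enumeration when ``n1 + n2 <= 12`` and no ties are present,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        p = _exact_p(u, n1, n2, alternative)
        return TestResult(u, p, alternative, n1, n2)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # all observations identical
        p = 1.0 if alternative == "two_sided" else 0.5
        return TestResult(u, p, alternative, n1, n2)
    sd = np.sqrt(var_u)
    if alternative == "greater":
        p = float(norm.sf((u - mean_u - 0.5) / sd))
    elif alternative == "less":
        p = float(norm.cdf((u - mean_u + 0.5) / sd))
    else:
        z = (abs(u - mean_u) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return TestResult(u, p, alternative, n1, n2)


def auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Empirical AUC: ``(#{pos > neg} + 0.5 * #{pos = neg}) / (n_pos * n_neg)``."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    return _u_statistic(pos, neg) / (len(pos) * len(neg))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matching 2-D arrays of resampled scores."""
    n1 = pos.shape[1]
    pooled = np.concatenate([pos, neg], axis=1)
    ranks = rankdata(pooled, axis=1, method="average")
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * neg.shape[1])


def stratified_bootstrap_ci(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """Percentile bootstrap CI for the AUC, resampling within each class.

    Each replicate resamples positives and negatives independently with
    replacement (stratified), recomputes the AUC, and the CI is the central
    ``level`` percentile interval.  Deterministic given ``seed``.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if len(pos) < 2 or len(neg) < 2:
        warnings.warn("a class has < 2 members; bootstrap resampling is degenerate")
    point = auc(pos, neg)
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    aucs = _auc_rows(bp, bn)
    lo, hi = np.percentile(aucs, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    # percentile interval can narrowly miss the point estimate; widen to keep
    # the bracket invariant
    lo, hi = min(float(lo), point), max(float(hi), point)
    return RocResult(
        auc=point,
        ci_low=lo,
        ci_high=hi,
        n_pos=len(pos),
        n_neg=len(neg),
        n_boot=n_boot,
        seed=seed,
    )


def evaluate_biomarkers(
    table: pd.DataFrame,
    biomarkers: Sequence[str],
    group_col: str = "group",
    positive_group: str = "R",
    alternative: str = "greater",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate per-subject biomarkers for NR/R discrimination.

    For each named biomarker column: AUC (positive group as cases) with a
    stratified-bootstrap CI plus a Mann-Whitney p-value.  Missing columns are
    listed as failed rows.  The result is sorted by AUC, best first.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = table[group_col]
    rows = []
    for i, b in enumerate(biomarkers):
        if b not in table.columns:
            rows.append({"biomarker": b, "status": "failed: column missing"})
            continue
        vals = pd.to_numeric(table[b], errors="coerce")
        pos = vals[groups == positive_group].dropna().to_numpy()
        neg = vals[groups != positive_group].dropna().to_numpy()
        if len(pos) < 3 or len(neg) < 3:
            rows.append({"biomarker": b, "status": "failed: < 3 subjects per group"})
            continue
        roc = stratified_bootstrap_ci(pos, neg, n_boot=n_boot, level=level, seed=seed + i)
        test = mann_whitney(pos, neg, alternative=alternative)
        rows.append(
            {
                "biomarker": b,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "p": test.p_value,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "status": "ok",
            }
        )
    df = pd.DataFrame(rows)
    if "auc" in df.columns:
        df = df.sort_values("auc", ascending=False, na_position="last").reset_index(drop=True)
    return df
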