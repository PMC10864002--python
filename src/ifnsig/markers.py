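"""Cross-species functional signature construction and marker derivation.

The chain implemented here mirrors the single-cell half of the analysis:
union three response-pathway gene sets into one functional signature, locate
the cluster of cells most enriched for it, derive that cluster's marker
genes by rank-test differential expression, and reduce the markers to a
compact signature of genes with near-exclusive expression in the target
state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .biomarkers import mann_whitney
from .core_io import ExpressionMatrix, GeneSet
from .scoring import SignatureScores

logger = logging.getLogger(__name__)

FUNCTIONAL_SIGNATURE_NAME = "functional_ifn_tnfa"


@dataclass(frozen=True)
class MarkerResult:
    """One differentially expressed gene of a target cluster."""

    gene: str
    log2_fc: float
    p_value: float
    p_adj: float
    frac_in: float
    frac_out: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError("p_adj must lie in [0, 1]")
        for f in (self.frac_in, self.frac_out):
            if not 0.0 <= f <= 1.0:
                raise ValueError("expressing fractions must lie in [0, 1]")


def markers_to_frame(markers: Sequence[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "log2_fc": r.log2_fc,
                "p": r.p_value,
                "p_adj": r.p_adj,
                "frac_in": r.frac_in,
                "frac_out": r.frac_out,
            }
            for r in markers
        ]
    )


def build_functional_signature(sets: Sequence[GeneSet]) -> GeneSet:
    """Union exactly three gene sets into one functional signature.

    De-duplication is case-insensitive, preserving first occurrence order.
    """
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 gene sets, got {len(sets)}")
    genes: list[str] = []
    seen: set[str] = set()
    for s in sets:
        for g in s.genes:
            if g.upper() not in seen:
                seen.add(g.upper())
                genes.append(g)
    return GeneSet(name=FUNCTIONAL_SIGNATURE_NAME, genes=tuple(genes))


def find_enriched_cluster(
    scores: SignatureScores,
    clusters: Mapping[str, str],
    min_cluster_size: int = 3,
) -> tuple[str, pd.DataFrame]:
    """Return the cluster with the highest median score plus a per-cluster summary.

    Clusters smaller than ``min_cluster_size`` are excluded with a warning.
    The summary lists, per eligible cluster, its size, median score and the
    one-sided rank-test p-value of that cluster's scores versus all other
    units.
    """
    missing = [u for u in scores.unit_ids if u not in clusters]
    if missing:
        raise ValueError(f"units without cluster assignment: {missing[:5]}")
    s = scores.series()
    labels = pd.Series([clusters[u] for u in scores.unit_ids], index=scores.unit_ids)
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("need >= 2 clusters")
    eligible = [c for c in sizes.index if sizes[c] >= min_cluster_size]
    for c in sizes.index:
        if c not in eligible:
            warnings.warn(f"cluster {c!r} has < {min_cluster_size} units; excluded")
    if not eligible:
        raise ValueError("all clusters excluded (too small)")

    rows = []
    for c in eligible:
        inside = s[labels == c].to_numpy()
        outside = s[labels != c].to_numpy()
        res = mann_whitney(inside, outside, alternative="greater")
        rows.append(
            {
                "cluster": c,
                "n": int(sizes[c]),
                "median_score": float(np.median(inside)),
                "p_greater": res.p_value,
            }
        )
    summary = pd.DataFrame(rows).sort_values("median_score", ascending=False).reset_index(drop=True)
    return str(summary.loc[0, "cluster"]), summary


def _mw_pvalues_vectorized(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation rank-test p per gene (rows), tie-corrected."""
    n1, n2 = x_in.shape[1], x_out.shape[1]
    n = n1 + n2
    pooled = np.concatenate([x_in, x_out], axis=1)
    ranks = rankdata(pooled, axis=1, method="average")
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var_u = np.maximum(var_u, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var_u > 0, (np.abs(u1 - mean_u) - 0.5) / np.sqrt(var_u), 0.0)
    z = np.maximum(z, 0.0)
    return np.minimum(1.0, 2.0 * norm.sf(z))


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        ranked = p[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        return np.minimum(1.0, adj)
    raise ValueError(f"unknown adjustment {method!r}")


def derive_markers(
    m: ExpressionMatrix,
    target: Sequence[str],
    fc_min: float = 1.5,
    alpha: float = 0.001,
    adjust: str = "bh",
    expr_threshold: float = 0.0,
) -> list[MarkerResult]:
    """Rank-test differential expression of a target unit subset versus the rest.

    Per gene: log2 fold-change of mean *linear* expression (pseudocount 1)
    between target and remaining units, and a two-sided rank-test p-value,
    multiplicity-adjusted (Benjamini-Hochberg by default, ``bonferroni``
    optional).  Genes passing ``p_adj < alpha`` and ``log2_fc > fc_min`` are
    returned sorted by adjusted p then descending fold-change.  A unit
    "expresses" a gene when its linear expression exceeds ``expr_threshold``.
    """
    target = list(target)
    if not target:
        raise ValueError("target subset is empty")
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    unknown = [t for t in target if t not in pos]
    if unknown:
        raise ValueError(f"target units not in matrix: {unknown[:5]}")
    mask = np.zeros(m.n_samples, dtype=bool)
    mask[[pos[t] for t in target]] = True
    if mask.all():
        raise ValueError("target must be a proper subset of units")

    if m.layer == "logcpm":
        linear = 2.0**m.values - 1.0
    else:
        linear = m.values
    x_in, x_out = m.values[:, mask], m.values[:, ~mask]
    lin_in, lin_out = linear[:, mask], linear[:, ~mask]

    log2_fc = np.log2(lin_in.mean(axis=1) + 1.0) - np.log2(lin_out.mean(axis=1) + 1.0)
    p = _mw_pvalues_vectorized(x_in, x_out)
    p_adj = _adjust(p, adjust)
    frac_in = (lin_in > expr_threshold).mean(axis=1)
    frac_out = (lin_out > expr_threshold).mean(axis=1)

    passing = np.flatnonzero((p_adj < alpha) & (log2_fc > fc_min))
    results = [
        MarkerResult(
            gene=m.gene_ids[i],
            log2_fc=float(log2_fc[i]),
            p_value=float(p[i]),
            p_adj=float(p_adj[i]),
            frac_in=float(frac_in[i]),
            frac_out=float(frac_out[i]),
        )
        for i in passing
    ]
    results.sort(key=lambda r: (r.p_adj, -r.log2_fc, r.gene.upper()))
    return results


def derive_exclusive_signature(
    markers: Sequence[MarkerResult],
    k: int = 15,
    frac_in_min: float = 0.5,
    frac_out_max: float = 0.1,
    name: str = "neut_ifn_derived",
) -> GeneSet:
    """Reduce markers to the top-k genes with near-exclusive target expression.

    Markers are filtered to ``frac_in >= frac_in_min`` and
    ``frac_out <= frac_out_max``; the best ``k`` by adjusted p then
    fold-change form the returned set.  Fewer than ``k`` survivors (including
    zero) yields a smaller (possibly empty) set with a warning, not an error.
    """
    if not markers:
        raise ValueError("markers list is empty")
    survivors = [
        r for r in markers if r.frac_in >= frac_in_min and r.frac_out <= frac_out_max
    ]
    survivors.sort(key=lambda r: (r.p_adj, -r.log2_fc, r.gene.upper()))
    if len(survivors) < k:
        warnings.warn(
            f"only {len(survivors)} markers survive exclusivity filtering (requested {k})"
        )
    return GeneSet(name=name, genes=tuple(r.gene for r in survivors[:k]))
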