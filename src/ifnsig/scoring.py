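"""Gene-set scoring: per-cell module scores and per-sample rank-ECDF enrichment.

Two schemes are provided.  ``module_score`` is the binned-control scheme used
on single cells: the mean expression of the set's genes minus the mean of
expression-bin-matched control genes.  ``gsva_score`` is a per-sample,
rank-based enrichment score from a weighted Kolmogorov-like random walk over
genes ordered by a cross-sample empirical-CDF statistic; it depends on the
input only through per-gene cross-sample ranks, so it is exactly invariant
under per-gene monotone transforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class SignatureScores:
    """Per-unit scores for one or more signatures.

    ``scores`` is ``(n_units, n_signatures)``; ``method`` records the scheme.
    """

    unit_ids: list[str]
    signature_names: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.unit_ids), len(self.signature_names)):
            raise ValueError("scores shape does not match unit/signature ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def series(self, signature: str | None = None) -> pd.Series:
        if signature is None:
            if len(self.signature_names) != 1:
                raise ValueError("multiple signatures present; name one")
            signature = self.signature_names[0]
        j = self.signature_names.index(signature)
        return pd.Series(self.scores[:, j], index=self.unit_ids, name=signature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.unit_ids, columns=self.signature_names)

    def to_tidy(self, grouping: Mapping[str, str] | None = None) -> pd.DataFrame:
        df = self.to_frame().reset_index(names="unit_id").melt(
            id_vars="unit_id", var_name="signature", value_name="score"
        )
        df["method"] = self.method
        if grouping is not None:
            df["dataset"] = df["unit_id"].map(dict(grouping))
        return df


def module_score(
    m: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureScores:
    """Binned-control module score per unit (cell).

    Genes are cut into ``n_bins`` equal-size bins by average expression across
    units.  For each set gene, ``n_ctrl`` control genes are drawn with
    replacement from the gene's bin (set genes excluded) and de-duplicated;
    bins no larger than ``n_ctrl`` contribute their whole pool.  The score of
    a unit is the mean over set genes minus the mean over pooled controls.
    """
    present = gene_set.present_in(m)
    if len(present) < 2:
        missing = [g for g in gene_set.genes if g.upper() not in m.gene_index()]
        raise ValueError(
            f"need >= 2 set genes in matrix; set {gene_set.name!r} has {len(present)} "
            f"(missing: {missing})"
        )
    n_genes = m.n_genes
    n_bins = min(n_bins, n_genes)
    avg = m.values.mean(axis=1)
    # equal-count bins by rank of average expression; ties broken by row order
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    set_rows = np.array(present, dtype=int)
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_rows] = True

    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    for g in set_rows:
        pool = np.flatnonzero((bin_of == bin_of[g]) & ~in_set)
        if len(pool) == 0:
            continue
        if len(pool) <= n_ctrl:
            chosen = pool
        else:
            chosen = np.unique(rng.choice(pool, size=n_ctrl, replace=True))
        ctrl_rows.append(chosen)
    if not ctrl_rows:
        raise ValueError("no control genes available outside the set")
    ctrl = np.concatenate(ctrl_rows)
    scores = m.values[set_rows, :].mean(axis=0) - m.values[ctrl, :].mean(axis=0)
    return SignatureScores(
        unit_ids=list(m.sample_ids),
        signature_names=[gene_set.name],
        scores=scores[:, None],
        method="module_score",
    )


def _walk_es(stat_col: np.ndarray, order: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Signed magnitude-difference enrichment score for one sample."""
    hit = in_set[order]
    w = np.abs(stat_col[order]) ** tau * hit
    wsum = w.sum()
    if wsum == 0:  # degenerate: all set-gene stats zero; uniform hit steps
        w = hit.astype(float)
        wsum = w.sum()
    steps = w / wsum - (~hit) / float((~hit).sum())
    walk = np.cumsum(steps)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def gsva_score(
    m: ExpressionMatrix,
    sets: Sequence[GeneSet],
    tau: float = 1.0,
) -> SignatureScores:
    """Per-sample rank-ECDF enrichment scores for each gene set.

    Per gene, a cross-sample empirical-CDF statistic (average ranks divided by
    the sample count) is computed.  Per sample, genes are ordered by
    decreasing statistic — ties broken by upper-cased gene id — and a random
    walk with set-gene weight ``|stat|**tau`` against a uniform complement
    penalty accumulates; the score is the maximum positive deviation plus the
    maximum negative deviation, a value in ``[-1, 1]``.
    """
    if m.n_samples < 2:
        raise ValueError("gsva_score needs >= 2 samples")
    n_genes = m.n_genes
    # cross-sample ECDF via midranks: invariant under per-gene monotone transforms
    stat = rankdata(m.values, axis=1, method="average") / m.n_samples

    gene_upper = np.array([g.upper() for g in m.gene_ids])
    lex = np.argsort(gene_upper, kind="stable")
    lex_rank = np.empty(n_genes, dtype=int)
    lex_rank[lex] = np.arange(n_genes)

    masks = []
    for s in sets:
        rows = s.present_in(m)
        if len(rows) < 1:
            raise ValueError(f"set {s.name!r} has no genes in the matrix")
        if len(rows) == n_genes:
            raise ValueError(f"set {s.name!r} covers every matrix gene; complement walk undefined")
        mask = np.zeros(n_genes, dtype=bool)
        mask[rows] = True
        masks.append(mask)

    scores = np.empty((m.n_samples, len(sets)))
    for j in range(m.n_samples):
        col = stat[:, j]
        # decreasing statistic, deterministic tie-break by gene id
        order = np.lexsort((lex_rank, -col))
        for k, mask in enumerate(masks):
            scores[j, k] = _walk_es(col, order, mask, tau)
    return SignatureScores(
        unit_ids=list(m.sample_ids),
        signature_names=[s.name for s in sets],
        scores=scores,
        method="gsva",
    )


def normalize_scores(
    s: SignatureScores,
    grouping: Mapping[str, str],
    method: str = "mad",
) -> SignatureScores:
    """Normalize scores within each dataset, per signature.

    ``method="mad"`` (default) centers to zero median and scales by the raw
    median absolute deviation (robust; idempotent).  ``method="zscore"``
    uses mean/standard deviation.  Datasets with fewer than 2 units are an
    error; a zero spread leaves the centered values unscaled.
    """
    datasets = [grouping.get(u) for u in s.unit_ids]
    if any(d is None for d in datasets):
        missing = [u for u, d in zip(s.unit_ids, datasets) if d is None]
        raise ValueError(f"units without dataset assignment: {missing[:5]}")
    datasets = np.array(datasets)
    out = s.scores.copy()
    for d in np.unique(datasets):
        idx = np.flatnonzero(datasets == d)
        if len(idx) < 2:
            raise ValueError(f"dataset {d!r} has < 2 units")
        block = out[idx, :]
        if method == "mad":
            center = np.median(block, axis=0)
            spread = np.median(np.abs(block - center), axis=0)
        elif method == "zscore":
            center = block.mean(axis=0)
            spread = block.std(axis=0, ddof=1)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        spread = np.where(spread > 0, spread, 1.0)
        out[idx, :] = (block - center) / spread
    return SignatureScores(
        unit_ids=list(s.unit_ids),
        signature_names=list(s.signature_names),
        scores=out,
        method=s.method,
    )
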