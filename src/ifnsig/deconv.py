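"""Bulk deconvolution and per-group cell-type profile imputation.

Cell-type fractions are estimated by non-negative least squares against a
reference signature matrix, rescaled to sum to one — a deliberately minimal
fraction estimator with a clean parameter-recovery contract.  Group-mode
imputation inverts the mixing per group and gene: each sample's bulk value
is expressed as the fraction-weighted sum of cell-type means, solved by NNLS
over samples, and per-gene variability (CV) is estimated from the residual
attribution to the target cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class SignatureMatrixRef:
    """Reference cell-type profiles (genes x cell types)."""

    gene_ids: list[str]
    cell_type_ids: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValueError("profiles shape does not match id lists")
        if np.any(self.profiles < 0):
            raise ValueError("reference profiles must be non-negative")
        if len(set(g.upper() for g in self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in reference")
        zero_cols = np.flatnonzero(self.profiles.sum(axis=0) == 0)
        if len(zero_cols):
            raise ValueError(
                f"all-zero reference column(s): {[self.cell_type_ids[i] for i in zero_cols]}"
            )

    @classmethod
    def from_expression(cls, m: ExpressionMatrix) -> "SignatureMatrixRef":
        return cls(list(m.gene_ids), list(m.sample_ids), m.values.copy())

    @classmethod
    def read_csv(cls, path: str | Path) -> "SignatureMatrixRef":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
        )

    def gene_index(self) -> dict[str, int]:
        return {g.upper(): i for i, g in enumerate(self.gene_ids)}


@dataclass
class FractionMatrix:
    """Sample x cell-type mixture proportions; rows sum to 1."""

    sample_ids: list[str]
    cell_type_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.sample_ids), len(self.cell_type_ids)):
            raise ValueError("fractions shape does not match id lists")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_type_ids)


@dataclass
class GroupProfile:
    """Imputed cell-type expression for one response group.

    Per gene: mean ``mu >= 0`` and coefficient of variation ``cv >= 0``
    (defined as 0 wherever ``mu == 0``).
    """

    group: str
    cell_type: str
    gene_ids: list[str]
    mu: np.ndarray
    cv: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if self.mu.shape != (len(self.gene_ids),) or self.cv.shape != self.mu.shape:
            raise ValueError("mu/cv shape mismatch")
        if np.any(self.mu < 0) or np.any(self.cv < 0):
            raise ValueError("mu and cv must be >= 0")
        if np.any(~np.isfinite(self.cv[self.mu > 0])):
            raise ValueError("cv must be finite where mu > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "cell_type": self.cell_type,
                "gene": self.gene_ids,
                "mu": self.mu,
                "cv": self.cv,
            }
        )


def estimate_fractions(bulk: ExpressionMatrix, ref: SignatureMatrixRef) -> FractionMatrix:
    """Per-sample NNLS fit of bulk expression to reference profiles.

    Each bulk column is total-normalized before fitting, making the result
    scale-invariant; coefficients are rescaled to sum to one.  An all-zero
    coefficient vector maps to uniform fractions with a warning.
    """
    bulk_gi = bulk.gene_index()
    ref_gi = ref.gene_index()
    shared_upper = [g for g in ref_gi if g in bulk_gi]
    if not shared_upper:
        raise ValueError("no shared genes between bulk matrix and reference")
    n_types = len(ref.cell_type_ids)
    if len(shared_upper) < n_types:
        warnings.warn(
            f"only {len(shared_upper)} shared genes for {n_types} cell types; "
            "fractions may be unidentifiable"
        )
    a = ref.profiles[[ref_gi[g] for g in shared_upper], :]
    b_all = bulk.values[[bulk_gi[g] for g in shared_upper], :]

    fractions = np.empty((bulk.n_samples, n_types))
    for j in range(bulk.n_samples):
        b = b_all[:, j]
        total = b.sum()
        if total > 0:
            b = b / total
        coef, _ = nnls(a, b)
        s = coef.sum()
        if s == 0:
            warnings.warn(f"sample {bulk.sample_ids[j]!r}: all-zero NNLS fit; uniform fractions")
            fractions[j] = 1.0 / n_types
        else:
            fractions[j] = coef / s
    return FractionMatrix(list(bulk.sample_ids), list(ref.cell_type_ids), fractions)


def _check_design_rank(f: np.ndarray, cell_type_ids: list[str]) -> None:
    n_types = f.shape[1]
    rank = np.linalg.matrix_rank(f)
    if rank >= n_types:
        return
    # name a type whose removal does not lower the rank (it is collinear)
    for t in range(n_types):
        reduced = np.delete(f, t, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(
                f"fraction design is rank-deficient: cell type "
                f"{cell_type_ids[t]!r} is collinear across samples"
            )
    raise ValueError("fraction design is rank-deficient")


def impute_group_profiles(
    bulk: ExpressionMatrix,
    fractions: FractionMatrix,
    meta: SampleMetadata,
    cell_type: str,
) -> dict[str, GroupProfile]:
    """Impute per-group expression profiles for one cell type.

    Per group and gene, NNLS solves ``bulk[g, s] ~= sum_t fractions[s, t] *
    mu[t, g]`` over the group's samples, giving cell-type means.  The CV is
    taken over per-sample attributed values ``mu[target, g] + residual``,
    where each sample's residual share is assigned to the target type in
    proportion to its fraction; attributed values are floored at 0.
    """
    if cell_type not in fractions.cell_type_ids:
        raise ValueError(f"cell type {cell_type!r} not in fraction matrix")
    t_idx = fractions.cell_type_ids.index(cell_type)
    frac_df = fractions.to_frame()
    out: dict[str, GroupProfile] = {}
    for group in ("NR", "R"):
        samples = [s for s in meta.samples_in_group(group) if s in bulk.sample_ids]
        if len(samples) < 3:
            raise ValueError(f"group {group!r} has < 3 samples with expression data")
        sub = bulk.subset_samples(samples)
        f = frac_df.loc[samples].to_numpy()  # n_samples x n_types
        _check_design_rank(f, fractions.cell_type_ids)

        n_genes = sub.n_genes
        mu_all = np.empty((f.shape[1], n_genes))
        for g in range(n_genes):
            coef, _ = nnls(f, sub.values[g, :])
            mu_all[:, g] = coef
        mu_t = mu_all[t_idx, :]

        resid = sub.values - (f @ mu_all).T  # genes x samples
        attributed = mu_t[:, None] + resid  # per-sample view of the target type
        attributed = np.maximum(attributed, 0.0)
        mean_att = attributed.mean(axis=1)
        sd_att = attributed.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean_att > 0, sd_att / mean_att, 0.0)
        cv = np.maximum(np.nan_to_num(cv, nan=0.0), 0.0)
        n_zero = int((mu_t == 0).sum())
        if n_zero:
            logger.info("group %s: %d genes with mu=0 excluded from dispersion use", group, n_zero)
        out[group] = GroupProfile(
            group=group,
            cell_type=cell_type,
            gene_ids=list(sub.gene_ids),
            mu=mu_t,
            cv=cv,
        )
    return out
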