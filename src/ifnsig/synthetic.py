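"""Synthetic data generators with planted ground truth.

Every downstream stage (scoring, marker derivation, deconvolution, the NB
bootstrap and biomarker evaluation) is exercised against matrices produced
here, so each generator returns a :class:`SyntheticTruth` record sufficient
to recompute any planted quantity.

Counts are negative-binomial with the ``Var = mu + alpha * mu**2``
parameterization (size = 1/alpha); mixture fractions are Dirichlet and
flow-style frequencies are Beta — the minimal distributions with the right
supports.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSet, SampleMetadata

NEUTROPHIL_TYPE = "neutrophil"
IFNHI_LABEL = "neutrophil_ifnhi"


@dataclass
class SyntheticTruth:
    """Record of everything planted by a generator.

    Attributes
    ----------
    fractions
        Per-sample generating cell-type fractions (bulk cohorts) or the
        requested cell-type proportions (single-cell), rows summing to 1.
    ifnhi_fraction
        Per-sample (or per-cohort) fraction of the IFN-high neutrophil
        component.
    planted_genes
        Signature genes carrying the group/state shift.
    shift_log2
        log2 mean shift applied to planted genes (and only those).
    gene_mu
        Generating per-gene means; one column per cell type / group.
    gene_alpha
        Generating per-gene NB dispersions (>= 0).
    seed
        Root seed the generator was called with.
    """

    fractions: pd.DataFrame
    ifnhi_fraction: pd.Series
    planted_genes: tuple[str, ...]
    shift_log2: float
    gene_mu: pd.DataFrame
    gene_alpha: pd.Series
    seed: int

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("truth fractions must sum to 1 per sample")
        if np.any(self.gene_alpha.to_numpy() < 0):
            raise ValueError("gene_alpha must be >= 0")


@dataclass
class FlowTable:
    """Per-subject IFN-high neutrophil frequencies with response labels."""

    table: pd.DataFrame  # subject_id, group, ly6e_hi_freq

    def __post_init__(self) -> None:
        freq = self.table["ly6e_hi_freq"].to_numpy()
        if np.any((freq < 0) | (freq > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    def values_by_group(self) -> dict[str, np.ndarray]:
        return {
            g: self.table.loc[self.table["group"] == g, "ly6e_hi_freq"].to_numpy()
            for g in ("NR", "R")
        }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with Var = mu + alpha mu^2; alpha == 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    pois = pos & (alpha <= 0)
    over = pos & (alpha > 0)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if over.any():
        size = 1.0 / alpha[over]
        p = size / (size + mu[over])
        out[over] = rng.negative_binomial(size, p)
    return out


def simulate_single_cell(
    n_cells: int,
    cell_type_props: Mapping[str, float],
    ifnhi_share_of_neutrophils: float,
    signature: GeneSet,
    shift_log2: float,
    n_genes: int,
    seed: int,
    *,
    signature_base_mean: float | None = None,
    alpha_range: tuple[float, float] = (0.1, 0.5),
    lognorm_sigma: float = 1.0,
) -> tuple[ExpressionMatrix, list[str], SyntheticTruth]:
    """Simulate a single-cell count matrix with an IFN-high neutrophil subpopulation.

    Gene means are drawn log-normally per cell type; per-gene dispersion is
    uniform on ``alpha_range``.  Cells of the ``neutrophil`` type become
    ``neutrophil_ifnhi`` with probability ``ifnhi_share_of_neutrophils`` and
    have their signature-gene means multiplied by ``2**shift_log2``.

    ``signature_base_mean``, when given, pins the signature genes' baseline
    mean in *every* non-ifnhi cell type, so the planted state is the only
    source of differential expression for those genes (near-exclusive mode).
    """
    if shift_log2 < 0:
        raise ValueError("shift_log2 must be >= 0")
    props = dict(cell_type_props)
    if NEUTROPHIL_TYPE not in props:
        raise ValueError(f"cell_type_props must include {NEUTROPHIL_TYPE!r}")
    if not np.isclose(sum(props.values()), 1.0, atol=1e-8):
        raise ValueError("cell type proportions must sum to 1")
    if not 0.0 <= ifnhi_share_of_neutrophils <= 1.0:
        raise ValueError("ifnhi_share_of_neutrophils must lie in [0, 1]")

    gene_ids = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    gene_upper = {g.upper(): i for i, g in enumerate(gene_ids)}
    sig_idx = []
    for g in signature.genes:
        if g.upper() not in gene_upper:
            raise ValueError(f"signature gene {g!r} not in the simulated universe of {n_genes}")
        sig_idx.append(gene_upper[g.upper()])
    sig_idx = np.array(sig_idx, dtype=int)

    rng = np.random.default_rng(seed)
    types = sorted(props)
    mu = {
        t: rng.lognormal(mean=0.0, sigma=lognorm_sigma, size=n_genes) for t in types
    }
    if signature_base_mean is not None:
        for t in types:
            mu[t][sig_idx] = signature_base_mean
    mu_ifnhi = mu[NEUTROPHIL_TYPE].copy()
    mu_ifnhi[sig_idx] = mu_ifnhi[sig_idx] * 2.0**shift_log2
    mu[IFNHI_LABEL] = mu_ifnhi
    alpha = rng.uniform(alpha_range[0], alpha_range[1], size=n_genes)

    labels = list(rng.choice(types, size=n_cells, p=[props[t] for t in types]))
    is_neut = np.array([lab == NEUTROPHIL_TYPE for lab in labels])
    to_ifnhi = is_neut & (rng.random(n_cells) < ifnhi_share_of_neutrophils)
    labels = [IFNHI_LABEL if hi else lab for lab, hi in zip(labels, to_ifnhi)]

    values = np.empty((n_genes, n_cells), dtype=float)
    for j, lab in enumerate(labels):
        values[:, j] = _nb_draw(rng, mu[lab], alpha)

    cell_ids = [f"CELL{j:05d}" for j in range(1, n_cells + 1)]
    m = ExpressionMatrix(gene_ids, cell_ids, values, layer="counts")

    frac_row = {t: props[t] for t in types}
    frac_row[NEUTROPHIL_TYPE] = props[NEUTROPHIL_TYPE] * (1 - ifnhi_share_of_neutrophils)
    frac_row[IFNHI_LABEL] = props[NEUTROPHIL_TYPE] * ifnhi_share_of_neutrophils
    truth = SyntheticTruth(
        fractions=pd.DataFrame([frac_row], index=["cohort"]),
        ifnhi_fraction=pd.Series({"cohort": frac_row[IFNHI_LABEL]}),
        planted_genes=tuple(signature.genes),
        shift_log2=float(shift_log2),
        gene_mu=pd.DataFrame(mu, index=gene_ids),
        gene_alpha=pd.Series(alpha, index=gene_ids),
        seed=seed,
    )
    return m, labels, truth


@dataclass(frozen=True)
class BulkEffect:
    """Group-wise planted effect for bulk cohorts.

    The responder group gets its IFN-high neutrophil Dirichlet mean raised to
    ``ifnhi_fraction_r`` and the signature-gene means of the IFN-high profile
    multiplied by ``2**shift_log2``.
    """

    signature_genes: tuple[str, ...] = ()
    shift_log2: float = 0.0
    ifnhi_fraction_nr: float = 0.05
    ifnhi_fraction_r: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.ifnhi_fraction_nr, self.ifnhi_fraction_r):
            if not 0.0 <= f <= 1.0:
                raise ValueError("effect fractions must lie in [0, 1]")


def simulate_bulk_cohort(
    n_per_group: tuple[int, int],
    sigmatrix: ExpressionMatrix,
    effect: BulkEffect,
    noise_alpha: float,
    seed: int,
    *,
    ifnhi_type: str = "Neut_IFN",
    dataset: str = "synthetic",
    concentration: float = 200.0,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Simulate a bulk NR/R cohort as NB noise around signature-matrix mixtures.

    Per-sample fractions are Dirichlet around group-specific means; the bulk
    expectation is ``profiles @ fractions``.  With ``noise_alpha == 0`` the
    observed matrix *is* the expectation (expectation mode, no sampling);
    otherwise integer NB counts with dispersion ``noise_alpha`` are drawn.
    """
    n_nr, n_r = n_per_group
    if min(n_nr, n_r) < 3:
        raise ValueError("need >= 3 samples per group for downstream rank tests")
    if noise_alpha < 0:
        raise ValueError("noise_alpha must be >= 0")
    types = list(sigmatrix.sample_ids)  # columns of the reference are cell types
    if ifnhi_type not in types:
        raise ValueError(f"signature matrix lacks cell type {ifnhi_type!r}")

    gi = sigmatrix.gene_index()
    sig_rows = []
    for g in effect.signature_genes:
        if g.upper() not in gi:
            raise ValueError(f"planted signature gene {g!r} absent from signature matrix")
        sig_rows.append(gi[g.upper()])
    sig_rows = np.array(sig_rows, dtype=int)

    rng = np.random.default_rng(seed)
    hi_col = types.index(ifnhi_type)
    profiles = {"NR": sigmatrix.values.copy(), "R": sigmatrix.values.copy()}
    if len(sig_rows):
        profiles["R"][sig_rows, hi_col] *= 2.0**effect.shift_log2

    n_types = len(types)
    rows, sample_ids, groups, frac_rows = [], [], [], []
    for group, n, hi_mean in (
        ("NR", n_nr, effect.ifnhi_fraction_nr),
        ("R", n_r, effect.ifnhi_fraction_r),
    ):
        base = np.full(n_types, (1.0 - hi_mean) / (n_types - 1))
        base[hi_col] = hi_mean
        fr = rng.dirichlet(base * concentration, size=n)
        mean_bulk = profiles[group] @ fr.T  # genes x n
        if noise_alpha == 0:
            obs = mean_bulk
        else:
            obs = _nb_draw(rng, mean_bulk, noise_alpha)
        rows.append(np.asarray(obs, dtype=float))
        sample_ids += [f"{dataset}_{group}_{i:02d}" for i in range(1, n + 1)]
        groups += [group] * n
        frac_rows.append(fr)

    values = np.concatenate(rows, axis=1)
    layer = "counts" if noise_alpha > 0 else "cpm"
    bulk = ExpressionMatrix(sigmatrix.gene_ids, sample_ids, values, layer=layer)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "dataset": dataset,
                "timing": "PRE",
            }
        )
    )
    fractions = pd.DataFrame(np.concatenate(frac_rows), index=sample_ids, columns=types)
    truth = SyntheticTruth(
        fractions=fractions,
        ifnhi_fraction=fractions[ifnhi_type],
        planted_genes=tuple(effect.signature_genes),
        shift_log2=float(effect.shift_log2),
        gene_mu=pd.DataFrame(
            {
                f"{ifnhi_type}:NR": profiles["NR"][:, hi_col],
                f"{ifnhi_type}:R": profiles["R"][:, hi_col],
            },
            index=sigmatrix.gene_ids,
        ),
        gene_alpha=pd.Series(noise_alpha, index=sigmatrix.gene_ids),
        seed=seed,
    )
    return bulk, meta, truth


def simulate_flow_table(
    n_per_group: tuple[int, int],
    mean_freqs: tuple[float, float],
    concentration: float,
    seed: int,
) -> FlowTable:
    """Beta-distributed per-subject IFN-high neutrophil frequencies by group."""
    n_nr, n_r = n_per_group
    if min(n_nr, n_r) < 1:
        raise ValueError("need >= 1 subject per group")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    for m in mean_freqs:
        if not 0.0 < m < 1.0:
            raise ValueError("mean frequencies must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for group, n, mean in (("NR", n_nr, mean_freqs[0]), ("R", n_r, mean_freqs[1])):
        a, b = mean * concentration, (1.0 - mean) * concentration
        freqs = rng.beta(a, b, size=n)
        for i, f in enumerate(freqs, start=1):
            records.append({"subject_id": f"{group}_{i:02d}", "group": group, "ly6e_hi_freq": f})
    return FlowTable(pd.DataFrame(records))


def load_signature_matrix() -> ExpressionMatrix:
    """Packaged 10-cell-type reference profile matrix (genes x cell types)."""
    with resources.as_file(resources.files("ifnsig.data") / "lm10_like.csv") as p:
        from .core_io import read_expression

        return read_expression(p, format="csv")


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent stage seeds from a root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]
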