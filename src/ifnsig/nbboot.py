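"""Negative-binomial model-based bootstrap of group expression profiles.

Per-gene NB dispersion is derived from the imputed mean and coefficient of
variation as ``alpha = CV**2 - 1/mu`` (clamped at the Poisson floor 0),
which is the method-of-moments dispersion under ``Var = mu + alpha * mu**2``
since ``CV**2 = 1/mu + alpha``.  Replicate samples are simulated per group
from these per-gene laws, scored by the rank-ECDF enrichment scheme,
normalized within dataset, and compared NR versus R with a one-sided rank
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarkers import TestResult, mann_whitney
from .core_io import ExpressionMatrix, GeneSet, SampleMetadata
from .deconv import GroupProfile, SignatureMatrixRef, estimate_fractions, impute_group_profiles
from .scoring import gsva_score, normalize_scores
from .synthetic import _nb_draw, spawn_seeds

logger = logging.getLogger(__name__)

STAR_BINS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def stars(p: float) -> str:
    """Significance stars at the 0.01 / 0.001 / 0.0001 thresholds."""
    for cut, label in STAR_BINS:
        if p < cut:
            return label
    return "NS"


@dataclass
class DispersionTable:
    """Per-gene (mu, cv, alpha) for one group; alpha = max(0, cv^2 - 1/mu)."""

    group: str
    gene_ids: list[str]
    mu: np.ndarray
    cv: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "group": self.group,
                "mu": self.mu,
                "cv": self.cv,
                "alpha": self.alpha,
            }
        )


@dataclass
class BootstrapResult:
    """NR-vs-R comparison of one signature in one dataset."""

    dataset: str
    signature: str
    scores_nr: np.ndarray
    scores_r: np.ndarray
    median_nr: float
    median_r: float
    u_statistic: float
    p_value: float
    direction: str

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def alpha_from_moments(mu: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """``alpha = cv**2 - 1/mu`` clamped at 0; genes with ``mu == 0`` get 0."""
    mu = np.asarray(mu, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if np.any(mu < 0) or np.any(cv < 0):
        raise ValueError("mu and cv must be >= 0")
    with np.errstate(divide="ignore"):
        raw = cv**2 - np.where(mu > 0, 1.0 / mu, np.inf)
    return np.where(mu > 0, np.maximum(raw, 0.0), 0.0)


def estimate_dispersion(profile: GroupProfile) -> DispersionTable:
    """Derive the per-gene NB dispersion table from an imputed group profile."""
    alpha = alpha_from_moments(profile.mu, profile.cv)
    n_zero = int((profile.mu == 0).sum())
    if n_zero:
        logger.info(
            "group %s: %d genes with mu=0 flagged (alpha fixed at 0)", profile.group, n_zero
        )
    return DispersionTable(
        group=profile.group,
        gene_ids=list(profile.gene_ids),
        mu=profile.mu.copy(),
        cv=profile.cv.copy(),
        alpha=alpha,
    )


def simulate_replicates(
    disp: Mapping[str, DispersionTable],
    n_reps: int,
    seed: int,
) -> dict[str, ExpressionMatrix]:
    """Simulate ``n_reps`` NB replicate samples per group from dispersion tables.

    Genes with ``alpha == 0`` are drawn Poisson; genes with ``mu == 0`` stay
    zero.  Simulated values are integer counts.
    """
    if n_reps < 3:
        raise ValueError("n_reps must be >= 3")
    rng = np.random.default_rng(seed)
    out: dict[str, ExpressionMatrix] = {}
    for group in sorted(disp):
        table = disp[group]
        n_genes = len(table.gene_ids)
        mu = np.broadcast_to(table.mu[:, None], (n_genes, n_reps))
        alpha = np.broadcast_to(table.alpha[:, None], (n_genes, n_reps))
        values = _nb_draw(rng, mu, alpha).astype(float)
        out[group] = ExpressionMatrix(
            gene_ids=list(table.gene_ids),
            sample_ids=[f"{group}_rep{i:03d}" for i in range(1, n_reps + 1)],
            values=values,
            layer="counts",
        )
    return out


def score_and_compare(
    reps_by_group: Mapping[str, ExpressionMatrix],
    sets: Sequence[GeneSet],
    dataset: str,
    tau: float = 1.0,
    alternative: str = "greater",
    norm_method: str = "mad",
) -> list[BootstrapResult]:
    """Score pooled replicates per signature and rank-test R versus NR.

    The replicate matrices of both groups are pooled, scored with the
    rank-ECDF scheme, normalized within the dataset, and per signature a
    one-sided (default ``R > NR``) rank test is run on the replicate scores.
    """
    for group in ("NR", "R"):
        if group not in reps_by_group:
            raise ValueError(f"missing group {group!r}")
    nr, r = reps_by_group["NR"], reps_by_group["R"]
    if [g.upper() for g in nr.gene_ids] != [g.upper() for g in r.gene_ids]:
        raise ValueError("groups must share an identical gene universe")
    pooled = ExpressionMatrix(
        gene_ids=list(nr.gene_ids),
        sample_ids=list(nr.sample_ids) + list(r.sample_ids),
        values=np.concatenate([nr.values, r.values], axis=1),
        layer=nr.layer,
    )
    raw = gsva_score(pooled, sets, tau=tau)
    normed = normalize_scores(raw, {u: dataset for u in raw.unit_ids}, method=norm_method)

    results = []
    n_nr = nr.n_samples
    for k, s in enumerate(sets):
        scores_nr = normed.scores[:n_nr, k]
        scores_r = normed.scores[n_nr:, k]
        test = mann_whitney(scores_r, scores_nr, alternative=alternative)
        results.append(
            BootstrapResult(
                dataset=dataset,
                signature=s.name,
                scores_nr=scores_nr,
                scores_r=scores_r,
                median_nr=float(np.median(scores_nr)),
                median_r=float(np.median(scores_r)),
                u_statistic=test.statistic,
                p_value=test.p_value,
                direction="R>NR" if np.median(scores_r) > np.median(scores_nr) else "NR>=R",
            )
        )
    return results


@dataclass
class PanelConfig:
    """Stage parameters for a multi-dataset bootstrap panel."""

    cell_type: str = "Neut_IFN"
    n_reps: int = 50
    tau: float = 1.0
    alternative: str = "greater"
    norm_method: str = "mad"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 3:
            raise ValueError("n_reps must be >= 3")


@dataclass
class PanelResult:
    """Per-dataset bootstrap results plus isolated per-dataset failures."""

    results: list[BootstrapResult]
    failures: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Heatmap-ready table: one row per dataset x signature x group."""
        rows = []
        for res in self.results:
            for group, med in (("NR", res.median_nr), ("R", res.median_r)):
                rows.append(
                    {
                        "dataset": res.dataset,
                        "signature": res.signature,
                        "group": group,
                        "median_norm_ES": med,
                        "U": res.u_statistic,
                        "p": res.p_value,
                        "stars": res.stars,
                    }
                )
        return pd.DataFrame(rows)


def run_dataset_panel(
    cohorts: Sequence[tuple[ExpressionMatrix, SampleMetadata, str]],
    ref: SignatureMatrixRef,
    sets: Sequence[GeneSet],
    config: PanelConfig | None = None,
) -> PanelResult:
    """Run the full bootstrap chain over a panel of bulk cohorts.

    Per dataset: estimate fractions, impute group profiles for the target
    cell type, derive dispersions, simulate replicate samples, score and
    compare.  Errors in one dataset are recorded without aborting the panel.
    """
    config = config or PanelConfig()
    seeds = spawn_seeds(config.seed, len(cohorts))
    results: list[BootstrapResult] = []
    failures: dict[str, str] = {}
    for (bulk, meta, dataset), ds_seed in zip(cohorts, seeds):
        try:
            fractions = estimate_fractions(bulk, ref)
            profiles = impute_group_profiles(bulk, fractions, meta, config.cell_type)
            disp = {g: estimate_dispersion(p) for g, p in profiles.items()}
            reps = simulate_replicates(disp, config.n_reps, ds_seed)
            results.extend(
                score_and_compare(
                    reps,
                    sets,
                    dataset,
                    tau=config.tau,
                    alternative=config.alternative,
                    norm_method=config.norm_method,
                )
            )
        except Exception as exc:  # noqa: BLE001 - panel isolates dataset failures
            logger.warning("dataset %s failed: %s", dataset, exc)
            failures[dataset] = str(exc)
    return PanelResult(results=results, failures=failures)
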