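"""Validated in-memory containers and readers/writers for expression data.

All downstream modules operate on the domain types defined here:
:class:`ExpressionMatrix`, :class:`GeneSet` and :class:`SampleMetadata`.
Supported external formats are dense CSV/TSV matrices, Matrix Market
coordinate triplets with plain-text id sidecars, GMT gene-set files and
CSV metadata tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

Layer = Literal["counts", "cpm", "logcpm"]

VALID_GROUPS = ("NR", "R")
VALID_TIMINGS = ("PRE", "POST")


class FormatError(ValueError):
    """Raised when an external file or in-memory container violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if not isinstance(x, str) or not x:
            raise FormatError(f"empty or non-string {what}: {x!r}")
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Gene x sample (or gene x cell) non-negative expression matrix.

    Parameters
    ----------
    gene_ids
        Unique, non-empty gene identifiers (rows).
    sample_ids
        Unique sample/cell identifiers (columns).
    values
        ``(n_genes, n_samples)`` array of non-negative values.  With
        ``layer="counts"`` all entries must additionally be integral.
    layer
        One of ``counts``, ``cpm`` or ``logcpm``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: Layer = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression values")
        if np.any(self.values < 0):
            raise FormatError("negative expression values")
        if self.layer not in ("counts", "cpm", "logcpm"):
            raise FormatError(f"unknown layer {self.layer!r}")
        if self.layer == "counts" and not np.allclose(self.values, np.round(self.values)):
            raise FormatError("layer=counts requires integral values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        """Upper-cased gene id -> row index (first occurrence wins)."""
        out: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            out.setdefault(g.upper(), i)
        return out

    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            layer=self.layer,
        )

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        gi = self.gene_index()
        idx = [gi[g.upper()] for g in keep if g.upper() in gi]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=self.sample_ids,
            values=self.values[idx, :],
            layer=self.layer,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of gene identifiers.

    Duplicate identifiers (after upper-casing) are rejected; matching against
    matrices is always case-insensitive.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.name:
            raise FormatError("gene set name must be non-empty")
        upper = [g.upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            raise FormatError(f"duplicate genes in set {self.name!r} after case-normalization")

    def __len__(self) -> int:
        return len(self.genes)

    def genes_upper(self) -> tuple[str, ...]:
        return tuple(g.upper() for g in self.genes)

    def present_in(self, m: ExpressionMatrix) -> list[int]:
        """Row indices of the set's genes found in ``m`` (case-insensitive)."""
        gi = m.gene_index()
        hit, missing = [], []
        for g in self.genes:
            if g.upper() in gi:
                hit.append(gi[g.upper()])
            else:
                missing.append(g)
        if missing:
            logger.warning(
                "gene set %s: %d/%d genes absent from matrix: %s",
                self.name, len(missing), len(self.genes), ",".join(missing[:10]),
            )
        return hit


@dataclass
class SampleMetadata:
    """Per-sample annotations: response group, dataset id and sampling timing."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "dataset", "timing")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        _check_unique(list(t["sample_id"]), "sample id")
        bad_group = set(t["group"]) - set(VALID_GROUPS)
        if bad_group:
            raise FormatError(f"invalid group labels: {sorted(bad_group)} (expected NR/R)")
        bad_timing = set(t["timing"]) - set(VALID_TIMINGS)
        if bad_timing:
            raise FormatError(f"invalid timing labels: {sorted(bad_timing)} (expected PRE/POST)")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])


# ---------------------------------------------------------------------------
# readers / writers


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(str(stem) + ".genes.txt"), Path(str(stem) + ".samples.txt")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample matrix from dense CSV/TSV or Matrix Market triplet.

    The layer is inferred: all-integral values are tagged ``counts``,
    anything else ``cpm``.  For MTX input, ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` sidecars must accompany the triplet file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".txt": "csv"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FormatError(f"missing MTX sidecar: {p}")
        mat = spio.mmread(str(path))
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        gene_ids = genes_path.read_text().split()
        sample_ids = samples_path.read_text().split()
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id: {dup[0]!r}")
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise FormatError(f"unknown expression format {format!r}")

    if np.any(values < 0):
        raise FormatError("negative entries in expression file")
    layer: Layer = "counts" if np.allclose(values, np.round(values)) else "cpm"
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values, layer=layer)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        spio.mmwrite(str(path), sparse.coo_matrix(m.values))
        genes_path.write_text("\n".join(m.gene_ids) + "\n", encoding="utf-8")
        samples_path.write_text("\n".join(m.sample_ids) + "\n", encoding="utf-8")
    elif format == "csv":
        m.to_frame().to_csv(path)
    else:
        raise FormatError(f"unknown expression format {format!r}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Genes are de-duplicated (case-insensitively) preserving first occurrence.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 tab-separated fields")
        name = fields[0]
        genes: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            g = g.strip()
            if not g or g.upper() in seen:
                continue
            seen.add(g.upper())
            genes.append(g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: GMT line has no genes")
        sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join([s.name, "na", *s.genes]) for s in sets]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms


def normalize(m: ExpressionMatrix, target: Layer = "logcpm") -> ExpressionMatrix:
    """Library-size normalize counts to ``cpm`` or ``logcpm`` (log2(cpm + 1))."""
    if m.layer != "counts":
        raise ValueError(f"layer must be counts, got {m.layer!r}")
    if target not in ("cpm", "logcpm"):
        raise ValueError(f"normalize target must be cpm or logcpm, got {target!r}")
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"all-zero column(s): {[m.sample_ids[i] for i in zero]}")
    cpm = m.values / totals * 1e6
    values = np.log2(cpm + 1.0) if target == "logcpm" else cpm
    return ExpressionMatrix(m.gene_ids, m.sample_ids, values, layer=target)


def filter_cells(
    m: ExpressionMatrix,
    min_genes: int = 500,
    max_genes: int = 5000,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "mt-",
) -> ExpressionMatrix:
    """Drop cells outside the detected-gene range or above the mitochondrial fraction.

    A cell is kept when its number of detected genes (non-zero rows) lies in
    ``[min_genes, max_genes]`` and the fraction of its counts on genes whose
    id starts with ``mito_prefix`` (case-insensitive) is ``<= max_mito_frac``.
    """
    if m.layer != "counts":
        raise ValueError(f"layer must be counts, got {m.layer!r}")
    detected = (m.values > 0).sum(axis=0)
    mito_rows = np.array(
        [g.upper().startswith(mito_prefix.upper()) for g in m.gene_ids], dtype=bool
    )
    totals = m.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.values[mito_rows, :].sum(axis=0) / totals, 0.0)
    keep = (detected >= min_genes) & (detected <= max_genes) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise ValueError("cell filtering removed every cell")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_cells removed %d/%d cells", n_removed, m.n_samples)
    return m.subset_samples(keep)
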