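"""Pipeline configuration with YAML round-trip and CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class ScConfig:
    """Single-cell signature-derivation pipeline parameters."""

    synthetic: bool = True
    matrix_path: str | None = None
    clusters_path: str | None = None
    gmt_path: str | None = None
    n_cells: int = 2000
    n_genes: int = 300
    neutrophil_prop: float = 0.45
    ifnhi_share: float = 0.35
    shift_log2: float = 2.0
    signature_base_mean: float = 0.25
    n_planted: int = 15
    n_bins: int = 24
    n_ctrl: int = 100
    fc_min: float = 1.5
    alpha: float = 0.001
    adjust: str = "bh"
    frac_in_min: float = 0.3
    frac_out_max: float = 0.3
    k: int = 15


@dataclass
class BulkConfig:
    """Bulk panel pipeline parameters."""

    n_datasets: int = 3
    n_planted_datasets: int = 2
    n_per_group: int = 10
    shift_log2: float = 1.0
    ifnhi_fraction_nr: float = 0.05
    ifnhi_fraction_r: float = 0.20
    noise_alpha: float = 0.0
    concentration: float = 5.0
    cell_type: str = "Neut_IFN"
    n_reps: int = 50
    tau: float = 1.0
    norm_method: str = "mad"
    n_boot: int = 1000
    flow_mean_nr: float = 0.05
    flow_mean_r: float = 0.30
    flow_concentration: float = 50.0
    flow_n_per_group: int = 25


@dataclass
class PipelineConfig:
    """Root configuration: stage parameters, root seed and output directory."""

    seed: int = 0
    out_dir: str = "ifnsig_out"
    sc: ScConfig = field(default_factory=ScConfig)
    bulk: BulkConfig = field(default_factory=BulkConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = ScConfig(**d.pop("sc", {}))
        bulk = BulkConfig(**d.pop("bulk", {}))
        allowed = {f.name for f in fields(cls)} - {"sc", "bulk"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sc=sc, bulk=bulk, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with top-level, sc.* or bulk.* keys replaced.

        CLI flags take precedence over file values; keys use dotted paths
        (``sc.shift_log2``) or plain names for root fields.
        """
        d = self.to_dict()
        for key, value in kwargs.items():
            if value is None:
                continue
            if "." in key:
                section, name = key.split(".", 1)
                if section not in ("sc", "bulk") or name not in d[section]:
                    raise ValueError(f"unknown config key {key!r}")
                d[section][name] = value
            else:
                if key not in d or key in ("sc", "bulk"):
                    raise ValueError(f"unknown config key {key!r}")
                d[key] = value
        return PipelineConfig.from_dict(d)
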