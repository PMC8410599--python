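"""Pipeline configuration: protocol defaults, validation, provenance hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, defaulting to the assay protocol.

    Numeric defaults mirror the bench protocol: 30 s baseline and 10 s
    response tail, a 7-point 3-fold dilution series topping at 0.5 mM,
    four technical replicates, censoring placeholder log10 EC50 = −2.
    Everything is overridable; the resolved config is serialized next to
    every stage output for provenance.
    """

    out_dir: str = "odortune_out"
    traces_path: str | None = None
    platemap_path: str | None = None
    ligand_table_path: str | None = None

    baseline_s: float = 30.0
    response_tail_s: float = 10.0
    read_s: float = 120.0
    sample_hz: float = 1.0

    top_concentration: float = 5e-4
    fold: float = 3.0
    n_points: int = 7
    n_technical: int = 4

    censor_value: float = -2.0
    censor_on_top_exceed: bool = True
    fit_mode: str = "per_replicate"

    agonist_require_uncensored: bool = True
    agonist_min_activity: float = 0.0
    alpha_bartlett: float = 0.05
    label_map: list = field(
        default_factory=lambda: [[1e-4, "****"], [1e-3, "***"], [1e-2, "*"]]
    )

    # simulation stage
    receptor_id: str = "MhOR5"
    mutant_ids: list = field(default_factory=list)
    n_ligands: int = 8
    n_plates: int = 3
    noise_sd: float = 0.5
    kinetic_tau: float = 10.0
    panel_n_ligands: int = 54
    panel_n_missing: int = 6
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.fold <= 1:
            raise ConfigError(f"fold must exceed 1, got {self.fold} (field: fold)")
        if self.top_concentration <= 0:
            raise ConfigError(
                f"top_concentration must be positive, got {self.top_concentration}"
            )
        if self.n_points < 1:
            raise ConfigError(f"n_points must be >= 1, got {self.n_points}")
        for name in ("baseline_s", "response_tail_s", "read_s", "sample_hz",
                     "kinetic_tau"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.fit_mode not in ("pooled", "per_replicate"):
            raise ConfigError(f"fit_mode must be pooled|per_replicate, got {self.fit_mode}")
        return self

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data).validate()

    def digest(self) -> str:
        """Short SHA-256 of the canonical serialized config.

        Filesystem paths are excluded: the digest identifies the analysis
        parameters, not where the outputs happen to live.
        """
        data = asdict(self)
        for key in ("out_dir", "traces_path", "platemap_path", "ligand_table_path"):
            data.pop(key, None)
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
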