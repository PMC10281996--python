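"""Pipeline configuration: a single strict YAML document.

Unknown keys are rejected (typos fail loudly); omitted optional blocks
materialize the method's default parameters (1000 pseudo-absences, 500 km
buffer, VIF 8, |r| 0.7, fourfold CV, n > 60 minimum sample, richness
hotspot threshold 25).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    occurrences: str
    env_dir: str
    landcover_dir: str | None = None
    output_dir: str = "output"


class QCConfig(_Strict):
    baseline_year: int = 1969
    tail_fraction: float = 0.10
    min_n: int = 60
    source_blacklist: list[str] = Field(default_factory=lambda: ["fossil", "unknown"])


class PseudoAbsenceConfig(_Strict):
    n: int = 1000
    buffer_km: float = 500.0


class SelectionConfig(_Strict):
    vif_threshold: float = 8.0
    r_max: float = 0.7
    priority: list[str] | None = None  # most-preferred first


class ModelConfig(_Strict):
    algorithms: list[str] = Field(default_factory=lambda: ["GLM", "GAM", "GBM", "RF"])
    k: int = 4
    weight_mode: str = "skill"
    n_permutations: int = 5
    hyperparams: dict[str, dict] = Field(default_factory=dict)


class ScenarioConfig(_Strict):
    ssp: str
    period: str
    gcm: str
    env_dir: str

    @property
    def label(self) -> str:
        return f"{self.ssp}_{self.period}_{self.gcm}"


class ProjectionConfig(_Strict):
    allowed_classes: list[str] = Field(
        default_factory=lambda: ["shrubs", "grassland", "cropland", "sparse_vegetation"])
    area_mode: str = "geodesic"


class CommunityConfig(_Strict):
    min_richness: int = 25
    focal_species: str | None = None
    overlap_layer: str | None = None  # default: highest pooled-median importance


class PipelineConfig(_Strict):
    paths: PathsConfig
    qc: QCConfig = Field(default_factory=QCConfig)
    pseudoabsence: PseudoAbsenceConfig = Field(default_factory=PseudoAbsenceConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    scenarios: list[ScenarioConfig] = Field(default_factory=list)
    projection: ProjectionConfig = Field(default_factory=ProjectionConfig)
    community: CommunityConfig = Field(default_factory=CommunityConfig)
    seed: int = 0


def validate_config(raw: dict | str | Path, base_dir: Path | None = None,
                    check_paths: bool = True) -> PipelineConfig:
    """Parse and validate a config mapping or YAML file.

    Relative paths resolve against the config file's directory (or
    ``base_dir``). Scenario labels must be unique; referenced input paths
    must exist when ``check_paths`` is set.
    """
    if isinstance(raw, (str, Path)):
        path = Path(raw)
        base_dir = base_dir or path.parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    cfg = PipelineConfig.model_validate(raw)
    base = Path(base_dir) if base_dir else Path(".")

    def resolve(p: str | None) -> str | None:
        return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

    cfg.paths.occurrences = resolve(cfg.paths.occurrences)
    cfg.paths.env_dir = resolve(cfg.paths.env_dir)
    cfg.paths.landcover_dir = resolve(cfg.paths.landcover_dir)
    cfg.paths.output_dir = resolve(cfg.paths.output_dir)
    for sc in cfg.scenarios:
        sc.env_dir = resolve(sc.env_dir)
    labels = [sc.label for sc in cfg.scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels (ssp_period_gcm) must be unique")
    if check_paths:
        missing = [p for p in (
            [cfg.paths.occurrences, cfg.paths.env_dir, cfg.paths.landcover_dir]
            + [sc.env_dir for sc in cfg.scenarios]) if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
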