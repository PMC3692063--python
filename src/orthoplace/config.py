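"""Pipeline configuration and the four parameter presets.

The presets trade recall against precision: *high recall* (the default) is
robust to small gene-model errors; *high precision* demands near-global,
high-identity alignments plus orthology support for the placement clade;
*remote homolog* relaxes E-value, overlap and identity constraints; *partial
sequence* drops query-coverage requirements for incomplete inputs. Numeric
values are this package's own defaults and every one can be overridden.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

PRESET_NAMES = (
    "high_recall",
    "high_precision",
    "remote_homolog",
    "partial_sequence",
    "custom",
)


@dataclass
class PresetConfig:
    preset_name: str = "high_recall"
    # stage 1: family-root profile scan
    stage1_evalue_max: float = 1e-3
    stage1_query_coverage_min: float = 0.5
    # stage 2: subtree placement criteria
    stage2_evalue_max: float = 1e-3
    stage2_query_coverage_min: float = 0.5
    stage2_model_coverage_min: float = 0.0
    require_orthology_support: bool = False
    # stage 3: candidate-ortholog alignment thresholds
    stage3_identity_min: float = 0.30
    stage3_query_coverage_min: float = 0.5
    stage3_subject_coverage_min: float = 0.5
    align_mode: str = "glocal_query"  # global | glocal_query | local
    # general
    max_query_length: int = 2000
    kerf_threshold: float = 0.70
    intra_identity_min: float = 0.97  # same-genome isoform clustering
    occupancy_min: float = 0.5
    pseudocount_alpha: float = 0.5
    calib_n_random: int = 150
    # fast bypass
    fastcat: bool = False
    fastcat_k: int = 4
    fastcat_top_n: int = 10
    fastcat_subtree_min: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = [
            ("stage1_query_coverage_min", self.stage1_query_coverage_min),
            ("stage2_query_coverage_min", self.stage2_query_coverage_min),
            ("stage2_model_coverage_min", self.stage2_model_coverage_min),
            ("stage3_identity_min", self.stage3_identity_min),
            ("stage3_query_coverage_min", self.stage3_query_coverage_min),
            ("stage3_subject_coverage_min", self.stage3_subject_coverage_min),
            ("kerf_threshold", self.kerf_threshold),
            ("intra_identity_min", self.intra_identity_min),
            ("occupancy_min", self.occupancy_min),
        ]
        for name, value in fracs:
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name}={value} is not a fraction in [0, 1]")
        for name, value in (
            ("stage1_evalue_max", self.stage1_evalue_max),
            ("stage2_evalue_max", self.stage2_evalue_max),
        ):
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_query_length < 1:
            raise ConfigurationError("max_query_length must be positive")
        if self.align_mode not in ("global", "glocal_query", "local"):
            raise ConfigurationError(f"unknown align_mode {self.align_mode!r}")
        if self.fastcat_k < 2:
            raise ConfigurationError("fastcat_k must be at least 2")
        if self.fastcat_top_n < 1:
            raise ConfigurationError("fastcat_top_n must be at least 1")

    def replace(self, **overrides) -> "PresetConfig":
        d = asdict(self)
        d.update(overrides)
        return PresetConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)


_PRESETS: dict[str, dict] = {
    "high_recall": {},
    "high_precision": dict(
        stage1_evalue_max=1e-5,
        stage1_query_coverage_min=0.8,
        stage2_evalue_max=1e-5,
        stage2_query_coverage_min=0.8,
        stage2_model_coverage_min=0.8,
        require_orthology_support=True,
        stage3_identity_min=0.60,
        stage3_query_coverage_min=0.8,
        stage3_subject_coverage_min=0.8,
        align_mode="global",
    ),
    "remote_homolog": dict(
        stage1_evalue_max=1.0,
        stage1_query_coverage_min=0.3,
        stage2_evalue_max=1.0,
        stage2_query_coverage_min=0.3,
        stage2_model_coverage_min=0.0,
        stage3_identity_min=0.15,
        stage3_query_coverage_min=0.3,
        stage3_subject_coverage_min=0.3,
        align_mode="local",
    ),
    "partial_sequence": dict(
        stage1_query_coverage_min=0.0,
        stage2_query_coverage_min=0.0,
        stage3_query_coverage_min=0.0,
        stage3_subject_coverage_min=0.5,
        align_mode="glocal_query",
    ),
    "custom": {},
}


def preset(name: str, **overrides) -> PresetConfig:
    """A preset configuration, optionally with per-parameter overrides."""
    if name not in _PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return PresetConfig(preset_name=name, **params)


def load_config(path: str | Path) -> PresetConfig:
    """Read a YAML or JSON config; a ``preset`` key seeds the defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} does not hold a mapping")
    name = data.pop("preset", data.pop("preset_name", "custom"))
    known = {f.name for f in fields(PresetConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return preset(name, **data)
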