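"""Pipeline configuration: defaults, validation and YAML loading.

Defaults equal the study conditions the pipeline was designed around:
annotation cutoffs E-value 1e-5 / identity 25 %, differential thresholds
|log2FC| >= 2 / FDR <= 0.001, enrichment alpha 0.01, probe radius 0.8 Å,
clustering threshold 4.5 Å and shell depth/radius 4/3 Å.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .transportome import DEFAULT_TC_CLASSES


@dataclass
class TransportomeParams:
    max_e_value: float = 1e-5
    min_identity_pct: float = 25.0
    tc_classes: tuple[str, ...] = tuple(sorted(DEFAULT_TC_CLASSES))
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_segment_length: int = 15
    min_segments: int = 1


@dataclass
class ExpressionParams:
    lfc_min: float = 2.0
    fdr_max: float = 0.001
    alpha: float = 0.01
    n_perm: int = 9999
    pseudocount: float = 0.0


@dataclass
class RinParams:
    contact_slack: float = 0.5
    hbond_dist_max: float = 3.5
    min_seq_separation: int = 2


@dataclass
class TunnelParams:
    probe_radius: float = 0.8
    clustering_threshold: float = 4.5
    shell_depth: float = 4.0
    shell_radius: float = 3.0
    grid_spacing: float = 0.8
    bottleneck_cutoff: float = 3.0


@dataclass
class IntegrationParams:
    peak_quantile: float = 0.95
    energy_tolerance: float = 0.005


@dataclass
class PipelineConfig:
    seed: int = 7
    out_dir: str = "sugarport_run"
    stages: tuple[str, ...] = (
        "simulate",
        "transportome",
        "expression",
        "structure",
        "integrate",
    )
    transportome: TransportomeParams = field(default_factory=TransportomeParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    rin: RinParams = field(default_factory=RinParams)
    tunnels: TunnelParams = field(default_factory=TunnelParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)

    def stage_seed(self, stage: str) -> int:
        """Fixed per-stage seed offsets, so stages reproduce independently."""
        offsets = {
            "simulate": 0,
            "transportome": 101,
            "expression": 211,
            "structure": 307,
            "integrate": 401,
        }
        return (self.seed + offsets[stage]) % (2**31)


_VALID_STAGES = ("simulate", "transportome", "expression", "structure", "integrate")


def _build_section(cls, data: dict, errors: list[str], prefix: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"unknown key {prefix}{key!r}")
    kwargs = {k: v for k, v in data.items() if k in known}
    if "tc_classes" in kwargs:
        kwargs["tc_classes"] = tuple(kwargs["tc_classes"])
    return cls(**kwargs)


def validate_config(data: dict | None) -> PipelineConfig:
    """Build a normalized PipelineConfig from a (possibly partial) mapping.

    Unknown keys are rejected; all violations are reported together.
    """
    data = dict(data or {})
    errors: list[str] = []
    sections = {
        "transportome": TransportomeParams,
        "expression": ExpressionParams,
        "rin": RinParams,
        "tunnels": TunnelParams,
        "integration": IntegrationParams,
    }
    top_known = {"seed", "out_dir", "stages"} | set(sections)
    for key in sorted(set(data) - top_known):
        errors.append(f"unknown key {key!r}")
    kwargs: dict = {}
    for name, cls in sections.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            errors.append(f"section {name!r} must be a mapping")
            sub = {}
        kwargs[name] = _build_section(cls, sub, errors, prefix=f"{name}.")
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    if "stages" in data:
        stages = tuple(data["stages"])
        for s in stages:
            if s not in _VALID_STAGES:
                errors.append(f"unknown stage {s!r}")
        kwargs["stages"] = stages
    config = PipelineConfig(**{k: v for k, v in kwargs.items()})

    # bound checks, collected together
    t = config.tunnels
    for name, value in (
        ("tunnels.probe_radius", t.probe_radius),
        ("tunnels.clustering_threshold", t.clustering_threshold),
        ("tunnels.shell_depth", t.shell_depth),
        ("tunnels.shell_radius", t.shell_radius),
        ("tunnels.grid_spacing", t.grid_spacing),
        ("tunnels.bottleneck_cutoff", t.bottleneck_cutoff),
        ("rin.contact_slack", config.rin.contact_slack),
        ("rin.hbond_dist_max", config.rin.hbond_dist_max),
        ("transportome.max_e_value", config.transportome.max_e_value),
        ("expression.lfc_min", config.expression.lfc_min),
        ("expression.fdr_max", config.expression.fdr_max),
    ):
        if value <= 0:
            errors.append(f"{name} must be positive (got {value})")
    if not 0 < config.expression.alpha < 1:
        errors.append(
            f"expression.alpha must be in (0, 1) (got {config.expression.alpha})"
        )
    if not 0 < config.integration.peak_quantile < 1:
        errors.append(
            "integration.peak_quantile must be in (0, 1) "
            f"(got {config.integration.peak_quantile})"
        )
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return config


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file (missing path -> defaults)."""
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    return validate_config(yaml.safe_load(text) or {})


def config_to_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    d["transportome"]["tc_classes"] = list(config.transportome.tc_classes)
    return d
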