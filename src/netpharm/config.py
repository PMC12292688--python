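"""Run configuration: YAML schema, validation, defaults."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from netpharm.core import DEFAULT_METRICS
from netpharm.errors import ConfigError

#: allowed keys per config section (None marks a scalar top-level key)
_SCHEMA = {
    "inputs": {"genecards", "drugbank", "pharmgkb", "pubchem", "edges", "gmt"},
    "network": {"confidence", "keep_isolates", "lcc_only"},
    "core": {"metrics", "rounds", "comparison", "combine"},
    "hubs": {"k", "consensus"},
    "enrichment": {"background", "min_overlap"},
    "output_dir": None,
    "seed": None,
    "log_level": None,
}

_REQUIRED_INPUTS = ("genecards", "edges", "gmt")


@dataclass(frozen=True)
class RunConfig:
    genecards: Path
    edges: Path
    gmt: Path
    output_dir: Path
    drugbank: Path | None = None
    pharmgkb: Path | None = None
    pubchem: Path | None = None
    confidence: float = 0.400
    keep_isolates: bool = False
    lcc_only: bool = False
    core_metrics: tuple[str, ...] = DEFAULT_METRICS
    core_rounds: int = 2
    core_comparison: str = "strict"
    core_combine: str = "all"
    hub_k: int = 10
    hub_consensus: str = "intersection"
    background: Path | None = None
    min_overlap: int = 2
    seed: int = 0
    log_level: str = "INFO"


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a YAML mapping")
    _reject_unknown("config", raw, set(_SCHEMA))
    for section, allowed in _SCHEMA.items():
        if allowed is not None and section in raw:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"{path}: section {section!r} must be a mapping")
            _reject_unknown(section, raw[section], allowed)

    inputs = raw.get("inputs", {})
    for key in _REQUIRED_INPUTS:
        if key not in inputs:
            raise ConfigError(f"{path}: inputs.{key} is required")

    def _path(section: dict, key: str, required: bool = False) -> Path | None:
        if key not in section or section[key] is None:
            if required:
                raise ConfigError(f"{path}: missing required path {key!r}")
            return None
        p = Path(section[key])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise ConfigError(f"{path}: {key} path does not exist: {p}")
        return p

    network = raw.get("network", {})
    confidence = float(network.get("confidence", 0.400))
    if not 0.0 <= confidence <= 1.0:
        raise ConfigError(f"network.confidence {confidence} outside [0, 1]")

    core = raw.get("core", {})
    rounds = int(core.get("rounds", 2))
    if rounds < 1:
        raise ConfigError(f"core.rounds must be >= 1, got {rounds}")
    comparison = str(core.get("comparison", "strict"))
    if comparison not in ("strict", "inclusive"):
        raise ConfigError(f"core.comparison must be strict|inclusive, got {comparison!r}")
    combine = str(core.get("combine", "all"))
    if combine not in ("all", "any"):
        raise ConfigError(f"core.combine must be all|any, got {combine!r}")
    metrics = tuple(core.get("metrics", DEFAULT_METRICS))

    hubs_cfg = raw.get("hubs", {})
    k = int(hubs_cfg.get("k", 10))
    if k < 1:
        raise ConfigError(f"hubs.k must be >= 1, got {k}")
    consensus = str(hubs_cfg.get("consensus", "intersection"))
    if consensus not in ("intersection", "union"):
        raise ConfigError(f"hubs.consensus must be intersection|union, got {consensus!r}")

    enrich = raw.get("enrichment", {})
    min_overlap = int(enrich.get("min_overlap", 2))
    if min_overlap < 0:
        raise ConfigError(f"enrichment.min_overlap must be >= 0, got {min_overlap}")

    if "output_dir" not in raw:
        raise ConfigError(f"{path}: output_dir is required")
    output_dir = Path(raw["output_dir"])
    if not output_dir.is_absolute():
        output_dir = path.parent / output_dir

    return RunConfig(
        genecards=_path(inputs, "genecards", required=True),
        drugbank=_path(inputs, "drugbank"),
        pharmgkb=_path(inputs, "pharmgkb"),
        pubchem=_path(inputs, "pubchem"),
        edges=_path(inputs, "edges", required=True),
        gmt=_path(inputs, "gmt", required=True),
        confidence=confidence,
        keep_isolates=bool(network.get("keep_isolates", False)),
        lcc_only=bool(network.get("lcc_only", False)),
        core_metrics=metrics,
        core_rounds=rounds,
        core_comparison=comparison,
        core_combine=combine,
        hub_k=k,
        hub_consensus=consensus,
        background=_path(enrich, "background"),
        min_overlap=min_overlap,
        output_dir=output_dir,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
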