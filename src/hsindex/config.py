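"""Indicator dictionary and run configuration.

The configuration file is a single YAML document with two sections::

    indicators:
      - name: poverty
        direction: insecurity_aligned   # or security_aligned
        fabric: economic                # economic | environmental | social
        subfabric: null                 # education | health | crime | social_stress
                                        # (required iff fabric == social)
        log_transform: none             # none | natural_log | log_shift (true == natural_log)
        selection_override: auto        # auto | force_include | force_exclude
    run:
      min_population: 2000
      loading_threshold: 0.5
      threshold_mode: strict            # strict (>) | inclusive (>=)
      use_absolute_loading: true
      aggregation: sum                  # sum | mean
      align_by_loading_sign: false
      max_missing_fraction: 0.25
      seed: 0

One file versions the whole variable dictionary: which raw column feeds which
fabric, which way it points, and any post-hoc inclusion/exclusion override.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "Direction",
    "Fabric",
    "Subfabric",
    "LogPolicy",
    "Override",
    "IndicatorSpec",
    "RunConfig",
    "read_config",
    "write_config",
    "validate_specs",
]


class Direction(str, enum.Enum):
    """Which way a raw indicator points before recoding."""

    INSECURITY = "insecurity_aligned"
    SECURITY = "security_aligned"


class Fabric(str, enum.Enum):
    ECONOMIC = "economic"
    ENVIRONMENTAL = "environmental"
    SOCIAL = "social"


class Subfabric(str, enum.Enum):
    EDUCATION = "education"
    HEALTH = "health"
    CRIME = "crime"
    SOCIAL_STRESS = "social_stress"


class LogPolicy(str, enum.Enum):
    NONE = "none"
    NATURAL_LOG = "natural_log"
    LOG_SHIFT = "log_shift"


class Override(str, enum.Enum):
    AUTO = "auto"
    FORCE_INCLUDE = "force_include"
    FORCE_EXCLUDE = "force_exclude"


@dataclass(frozen=True)
class IndicatorSpec:
    """Per-variable metadata: orientation, transform, and group membership.

    ``subfabric`` is required when ``fabric`` is social (the Social Fabric is
    the only hierarchical one) and forbidden otherwise.  ``selection_override``
    lets a variable bypass the loading-threshold rule, which is how post-hoc
    editorial decisions (e.g. dropping a variable with too little data) are
    expressed without touching the algorithm.
    """

    name: str
    direction: Direction
    fabric: Fabric
    subfabric: Subfabric | None = None
    log_transform: LogPolicy = LogPolicy.NONE
    selection_override: Override = Override.AUTO

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "fabric", Fabric(self.fabric))
        if self.subfabric is not None:
            object.__setattr__(self, "subfabric", Subfabric(self.subfabric))
        log = self.log_transform
        if log is True:
            log = LogPolicy.NATURAL_LOG
        elif log is False or log is None:
            log = LogPolicy.NONE
        object.__setattr__(self, "log_transform", LogPolicy(log))
        object.__setattr__(self, "selection_override", Override(self.selection_override))
        if self.fabric is Fabric.SOCIAL and self.subfabric is None:
            raise ValueError(f"indicator {self.name!r}: social fabric requires a subfabric")
        if self.fabric is not Fabric.SOCIAL and self.subfabric is not None:
            raise ValueError(
                f"indicator {self.name!r}: subfabric {self.subfabric.value!r} given "
                f"for non-social fabric {self.fabric.value!r}"
            )

    @property
    def group(self) -> str:
        """Factor-analysis group this indicator belongs to.

        Economic and environmental indicators factor at the fabric level;
        social indicators factor within their subfabric.
        """
        return self.subfabric.value if self.subfabric is not None else self.fabric.value


@dataclass(frozen=True)
class RunConfig:
    """Tunable pipeline parameters, all with stated defaults."""

    min_population: int = 2000
    loading_threshold: float = 0.5
    threshold_mode: str = "strict"  # strict: |loading| > t ; inclusive: >= t
    use_absolute_loading: bool = True
    aggregation: str = "sum"  # sum | mean
    align_by_loading_sign: bool = False
    max_missing_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("strict", "inclusive"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not (0.0 < self.loading_threshold < 1.0):
            raise ValueError("loading_threshold must lie in (0, 1)")
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        if self.min_population < 0:
            raise ValueError("min_population must be nonnegative")


def validate_specs(specs: list[IndicatorSpec]) -> None:
    """Cross-spec invariants: unique names."""
    seen: set[str] = set()
    for s in specs:
        if s.name in seen:
            raise ValueError(f"duplicate indicator name {s.name!r}")
        seen.add(s.name)


def _spec_to_dict(spec: IndicatorSpec) -> dict:
    d = asdict(spec)
    for key in ("direction", "fabric", "log_transform", "selection_override"):
        d[key] = d[key].value
    d["subfabric"] = spec.subfabric.value if spec.subfabric is not None else None
    return d


def read_config(path: str | Path) -> tuple[list[IndicatorSpec], RunConfig]:
    """Parse a YAML configuration; defaults fill any omitted ``run`` field."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "indicators" not in doc:
        raise ValueError(f"{path}: expected a mapping with an 'indicators' section")
    raw_specs = doc["indicators"]
    if not isinstance(raw_specs, list) or not raw_specs:
        raise ValueError(f"{path}: 'indicators' must be a non-empty list")
    specs = [IndicatorSpec(**entry) for entry in raw_specs]
    validate_specs(specs)
    run = doc.get("run") or {}
    if not isinstance(run, dict):
        raise ValueError(f"{path}: 'run' must be a mapping")
    unknown = set(run) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown run option(s): {sorted(unknown)}")
    cfg = RunConfig(**run)
    return specs, cfg


def write_config(specs: list[IndicatorSpec], cfg: RunConfig, path: str | Path) -> None:
    """Serialize configuration; ``read_config`` of the result round-trips."""
    doc = {
        "indicators": [_spec_to_dict(s) for s in specs],
        "run": asdict(cfg),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
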