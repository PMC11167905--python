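"""Run configuration: a strictly parsed YAML-compatible key-value schema.

Unknown keys are rejected, every threshold is validated against its
documented domain, and the full effective configuration (defaults
included) can be serialized back to YAML so a run is reproducible from
its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .coloc import ColocPriors


@dataclass
class Paths:
    """Input file locations. ``outcome`` is one path used for every
    tissue, or a per-tissue mapping."""

    exposure: dict[str, str] = field(default_factory=dict)
    outcome: str | dict[str, str] = ""
    annotations: str = ""
    druggable: list[str] = field(default_factory=list)
    ld_dir: str = ""
    exclusions: str | None = None
    gene_sets: str | None = None

    def outcome_for(self, tissue: str) -> str:
        if isinstance(self.outcome, str):
            return self.outcome
        return self.outcome[tissue]


@dataclass
class Thresholds:
    window_bp: int = 100_000
    eqtl_fdr: float = 0.05
    clump_r2: float = 0.001
    mr_fdr: float = 0.05
    pph4_min: float = 0.75

    def validate(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        for name in ("eqtl_fdr", "clump_r2", "mr_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.pph4_min < 0:
            raise ValueError("pph4_min must be non-negative")


@dataclass
class Options:
    palindrome_eaf_limit: float = 0.42
    re_flavor: str = "multiplicative"  # multiplicative | additive
    fdr_family: str = "per_tissue"  # per_tissue | global
    wald_se: str = "first_order"  # first_order | second_order
    coloc_all_genes: bool = False
    use_fdr_column: bool | None = None  # None = auto-detect
    missing_ld: str = "strict"  # strict | drop
    min_set_size: int = 3
    comparators: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not (0 <= self.palindrome_eaf_limit <= 0.5):
            raise ValueError("palindrome_eaf_limit must be in [0, 0.5]")
        if self.re_flavor not in ("multiplicative", "additive"):
            raise ValueError(f"unknown re_flavor {self.re_flavor!r}")
        if self.fdr_family not in ("per_tissue", "global"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")
        if self.wald_se not in ("first_order", "second_order"):
            raise ValueError(f"unknown wald_se {self.wald_se!r}")
        if self.missing_ld not in ("strict", "drop"):
            raise ValueError(f"unknown missing_ld {self.missing_ld!r}")


@dataclass
class RunConfig:
    paths: Paths = field(default_factory=Paths)
    thresholds: Thresholds = field(default_factory=Thresholds)
    priors: ColocPriors = field(default_factory=ColocPriors)
    options: Options = field(default_factory=Options)
    seed: int = 0
    out_dir: str = "targetmr_results"

    def validate(self) -> None:
        self.thresholds.validate()
        self.options.validate()

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["priors"] = {
            "p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12,
            "w_quant": self.priors.w_quant, "w_cc": self.priors.w_cc,
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build a validated RunConfig from a nested mapping (strict keys)."""
    top_known = {"paths", "thresholds", "priors", "options", "seed", "out_dir"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(
        paths=_build(Paths, data.get("paths", {}) or {}, "paths"),
        thresholds=_build(Thresholds, data.get("thresholds", {}) or {}, "thresholds"),
        priors=_build(ColocPriors, data.get("priors", {}) or {}, "priors"),
        options=_build(Options, data.get("options", {}) or {}, "options"),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "targetmr_results")),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def default_config_yaml() -> str:
    return RunConfig().to_yaml()
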