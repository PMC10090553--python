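"""Run configuration: YAML document -> validated RunConfig.

The analysis is parameter-laden (SCN cutoff, network cutoff, screen alpha,
top-K, GSEA weighting/permutations) and silent defaults would be untraceable,
so the schema is strict: unknown keys are rejected with a closest-match
suggestion, thresholds are range-checked, and every constant is echoed into
the run manifest.
"""
from __future__ import annotations

import dataclasses
import difflib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ValidationError


@dataclass
class ScenarioConfig:
    """Synthetic study conditions for the default end-to-end run.

    Group sizes mirror a 46/445 HI/LO cell-line split and 33/14 two-cohort
    tumour design so power behaviour is realistic at desk scale.
    """

    n_genes: int = 500
    n_hi: int = 46
    n_lo: int = 445
    hi_center: float = 2.0
    lo_center: float = 0.0
    spread: float = 0.2
    missing_rate: float = 0.02
    n_tfs: int = 6
    n_tf_excluded: int = 3
    rho_tf_hi: float = 0.7
    rho_tf_lo_excluded: float = 0.4
    rho_tf_lo_retained: float = -0.1
    n_expr_genes: int = 300
    n_cohort_a: int = 33
    n_cohort_b: int = 14
    block_rho_a: float = 0.85
    block_size_a: int = 10
    block_rho_b: float = 0.8
    block_size_b: int = 40
    n_sets: int = 237
    set_size: int = 25
    n_enriched: int = 10

    def validate(self) -> None:
        for name in ("n_genes", "n_hi", "n_lo", "n_tfs", "n_expr_genes",
                     "n_cohort_a", "n_cohort_b", "n_sets", "set_size",
                     "block_size_a", "block_size_b"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"scenario.{name} must be positive")
        if not 0 <= self.n_tf_excluded <= self.n_tfs:
            raise ValidationError("scenario.n_tf_excluded must be in [0, n_tfs]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("scenario.missing_rate must be in [0, 1)")
        for name in ("rho_tf_hi", "rho_tf_lo_excluded", "rho_tf_lo_retained",
                     "block_rho_a", "block_rho_b"):
            if not -1 < getattr(self, name) < 1:
                raise ValidationError(f"scenario.{name} must lie in (-1, 1)")
        if self.n_tfs + 1 > self.n_genes:
            raise ValidationError("scenario.n_genes too small for the TF panel")
        if self.block_size_a + self.block_size_b + 1 > self.n_expr_genes:
            raise ValidationError("scenario.n_expr_genes too small for the blocks")
        if self.set_size >= self.n_expr_genes:
            raise ValidationError("scenario.set_size must be below n_expr_genes")
        if self.n_cohort_b < 3 or self.n_cohort_a < 3:
            raise ValidationError("cohort sizes must be >= 3")


@dataclass
class InputPaths:
    """External inputs; when all are set, simulation is skipped."""

    dependency: str | None = None
    annotation: str | None = None
    expr_a: str | None = None
    expr_b: str | None = None
    gmt: str | None = None
    tf_list: str | None = None

    @property
    def provided(self) -> bool:
        return any(dataclasses.asdict(self).values())

    def validate(self, gsea_enabled: bool = True) -> None:
        if not self.provided:
            return
        required = ["dependency", "annotation", "expr_a", "expr_b", "tf_list"]
        if gsea_enabled:
            required.append("gmt")
        for name in required:
            val = getattr(self, name)
            if val is None:
                raise ValidationError(f"inputs.{name} is required when inputs are given")
            if not Path(val).exists():
                raise ValidationError(f"inputs.{name}: file not found: {val}")


@dataclass
class RunConfig:
    """Validated pipeline configuration (all constants in one place)."""

    outdir: str = "runs/default"
    seed: int = 0
    anchor: str = "ANCHOR"
    cutoff: float = 1.1           # SCN HI/LO boundary (score >= cutoff -> HI)
    network_cutoff: float = 0.7   # signature membership: coefficient > cutoff
    alpha: float = 0.05           # screen significance gate (raw p)
    top_k: int = 100              # positive-rank gate of the funnel
    min_n: int = 10               # minimum pairwise-complete lines per gene
    method: str = "pearson"       # network correlation method
    weight_p: float = 1.0         # GSEA hit weighting exponent
    n_perm: int = 1000
    min_hits: int = 5
    max_hits: int = 500
    top_n_extremes: int = 30      # extreme-annotation window of the profile
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    inputs: InputPaths = field(default_factory=InputPaths)

    def validate(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")
        if not -1 < self.network_cutoff < 1:
            raise ValidationError(
                f"network_cutoff must lie in (-1, 1), got {self.network_cutoff}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.min_n < 3:
            raise ValidationError("min_n must be >= 3")
        if self.method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.weight_p < 0:
            raise ValidationError("weight_p must be >= 0")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if not 1 <= self.min_hits <= self.max_hits:
            raise ValidationError("need 1 <= min_hits <= max_hits")
        if self.top_n_extremes < 1:
            raise ValidationError("top_n_extremes must be >= 1")
        if not 0 <= self.seed < 2**31:
            raise ValidationError("seed must be a non-negative 31-bit integer")
        self.scenario.validate()
        self.inputs.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _apply(obj: Any, raw: Mapping[str, Any], context: str) -> None:
    known = {f.name for f in dataclasses.fields(obj)}
    for key, val in raw.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key '{context}{key}'{suggestion}")
        setattr(obj, key, val)


def validate_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Build a RunConfig from a parsed key-value document.

    Missing keys take defaults; unknown keys are rejected with a suggestion;
    all thresholds are range-checked.
    """
    cfg = RunConfig()
    raw = dict(raw or {})
    scenario_raw = raw.pop("scenario", None) or {}
    inputs_raw = raw.pop("inputs", None) or {}
    if not isinstance(scenario_raw, Mapping):
        raise ValidationError("config key 'scenario' must be a mapping")
    if not isinstance(inputs_raw, Mapping):
        raise ValidationError("config key 'inputs' must be a mapping")
    _apply(cfg, raw, "")
    _apply(cfg.scenario, scenario_raw, "scenario.")
    _apply(cfg.inputs, inputs_raw, "inputs.")
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: top level must be a mapping")
    return validate_config(raw)
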