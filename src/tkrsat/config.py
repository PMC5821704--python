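"""Run configuration: every knob and every stage seed in one round-trippable file."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synth import CohortSpec, coast_spec, gar_spec
from . import published

#: Stages that consume randomness; each needs an explicit seed.
SEED_STAGES = (
    "generate_development", "generate_external",
    "missingness_development", "missingness_external",
    "impute_development", "impute_external",
    "select", "validate",
)


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    Cohorts come either from generative specs (with optional raw-registry
    cascades, so the exclusion filter is exercised) or from cohort CSVs.
    """

    development: CohortSpec | str
    external: CohortSpec | str
    seeds: dict
    outdir: str = "results/run"
    development_cascade: dict | None = None
    external_cascade: dict | None = None
    missingness_mechanism: str = "MCAR"
    m: int = 50
    n_cycles: int = 10
    B_select: int = 200
    alpha: float = 0.157
    threshold: float = 0.60
    forced: tuple = ("man", "age")
    B_validate: int = 200
    bins: int = 10
    reselect_in_validation: bool = True

    def __post_init__(self):
        missing = [s for s in SEED_STAGES if s not in self.seeds]
        if missing:
            raise ConfigError(f"config lacks seeds for stages: {missing}")
        for s, v in self.seeds.items():
            if not isinstance(v, int):
                raise ConfigError(f"seed for stage {s!r} must be an integer")
        if self.m < 1 or self.B_select < 1 or self.B_validate < 1:
            raise ConfigError("m, B_select and B_validate must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("development", "external"):
            spec = d[key]
            if isinstance(spec, dict):
                spec["age_range"] = list(spec["age_range"])
                spec["score_range"] = list(spec["score_range"])
        d["forced"] = list(self.forced)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("development", "external"):
            spec = d[key]
            if isinstance(spec, dict):
                spec = dict(spec)
                spec["age_range"] = tuple(spec["age_range"])
                spec["score_range"] = tuple(spec["score_range"])
                spec["copula_corr"] = spec.get("copula_corr")
                d[key] = CohortSpec(**spec)
        d["forced"] = tuple(d.get("forced", ("man", "age")))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(outdir: str = "results/coast-gar-replica", seed: int = 20180221,
                   **overrides) -> RunConfig:
    """The bundled COASt-to-GAR replica configuration.

    Cohort sizes, case mix, outcome equations, missingness, m=50 and
    B=200 follow the published study; one master seed deterministically
    derives the per-stage seeds.
    """
    import numpy as np
    stage_seeds = {s: int(v) for s, v in zip(
        SEED_STAGES, np.random.default_rng(seed).integers(2**31, size=len(SEED_STAGES)))}
    kw = dict(
        development=coast_spec(),
        external=gar_spec(),
        development_cascade=dict(published.COAST_CASCADE),
        external_cascade=dict(published.GAR_CASCADE),
        seeds=stage_seeds,
        outdir=str(outdir),
    )
    kw.update(overrides)
    return RunConfig(**kw)
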