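"""Run configuration shared by the scoring pipeline, CLI and writers."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for out-of-bounds or inconsistent configuration values."""


@dataclass
class RunConfig:
    """All tunable knobs of a scoring / analysis run.

    Attributes
    ----------
    min_pathway_genes:
        Minimum number of pathway genes surviving intersection with the
        expression matrix; smaller pathways are skipped.
    min_normals:
        Minimum size of the normal reference cohort.
    shrinkage:
        ``"lw"`` (analytic Ledoit–Wolf-style intensity, estimated once per
        pathway from the normal cohort), ``"fixed"`` (use
        ``shrinkage_intensity``), or ``"none"``.
    shrinkage_intensity:
        Intensity in [0, 1] for ``shrinkage="fixed"``.
    k:
        Dysregulation threshold multiplier: a tumor sample is called
        dysregulated on a pathway when its score exceeds
        mean + k * sd of the normal samples' scores.
    alpha:
        Raw log-rank p-value threshold of the prognostic screen.
    normal_mode:
        ``"jackknife"`` (score each normal against the other normals) or
        ``"duplicate"`` (append a copy of the normal to the reference).
    benchmark_repeats / benchmark_n_tumor / benchmark_n_normal /
    benchmark_top_k:
        Clustering-benchmark harness: number of seeded repeats, subsample
        sizes, and how many top differential pathways feed the clustering.
    seed:
        Seed for every stochastic step (subsampling; scoring itself is
        deterministic).
    log2_transform:
        Apply log2(x + 1) at load time (inputs are otherwise assumed
        already log2-transformed).
    """

    min_pathway_genes: int = 5
    min_normals: int = 10
    shrinkage: str = "lw"
    shrinkage_intensity: float | None = None
    k: float = 2.0
    alpha: float = 0.05
    normal_mode: str = "jackknife"
    benchmark_repeats: int = 50
    benchmark_n_tumor: int = 50
    benchmark_n_normal: int = 50
    benchmark_top_k: int = 10
    seed: int = 0
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if self.min_pathway_genes < 2:
            raise ConfigError("min_pathway_genes must be >= 2")
        if self.min_normals < 2:
            raise ConfigError("min_normals must be >= 2")
        if self.shrinkage not in ("lw", "fixed", "none"):
            raise ConfigError(f"unknown shrinkage mode {self.shrinkage!r}")
        if self.shrinkage == "fixed":
            if self.shrinkage_intensity is None or not 0.0 <= self.shrinkage_intensity <= 1.0:
                raise ConfigError("fixed shrinkage requires shrinkage_intensity in [0, 1]")
        if self.normal_mode not in ("jackknife", "duplicate"):
            raise ConfigError(f"unknown normal_mode {self.normal_mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.k < 0:
            raise ConfigError("k must be nonnegative")
        for name in ("benchmark_repeats", "benchmark_n_tumor", "benchmark_n_normal", "benchmark_top_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
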