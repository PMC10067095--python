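"""Pipeline configuration.

Collects every analysis constant in one validated object: the SRM signal
quantification limit (default 1500 intensity units), the screening
significance level (0.05), the random-forest top-N rule (50), the
consensus-clustering resampling scheme, the PAC interval (0.1, 0.9), the
volcano thresholds (fold change 2, p 0.05) and the correlation-network FDR
cutoff (1e-4).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    quantification_limit: float = 1500.0
    screen_alpha: float = 0.05
    rf_top_n: int = 50
    rf_n_trees: int = 1000
    imputation_method: str = "half_min"  # half_min | min | knn
    k_range: tuple[int, int] = (2, 8)
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    inner_clusterer: str = "kmeans"  # kmeans | ward
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    volcano_fc_threshold: float = 2.0
    volcano_alpha: float = 0.05
    correlation_method: str = "pearson_log2"  # pearson_log2 | spearman
    network_fdr_threshold: float = 1e-4
    positive_only: bool = True
    stage_iv_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        self.pac_bounds = tuple(float(x) for x in self.pac_bounds)
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be an interval with minimum >= 2")
        x1, x2 = self.pac_bounds
        if not (0 <= x1 < x2 <= 1):
            raise ValueError("pac_bounds must satisfy 0 <= x1 < x2 <= 1")
        if self.quantification_limit < 0:
            raise ValueError("quantification_limit must be >= 0")
        for name in (
            "screen_alpha",
            "volcano_alpha",
            "volcano_fc_threshold",
            "network_fdr_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rf_top_n < 1:
            raise ValueError("rf_top_n must be >= 1")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.imputation_method not in ("half_min", "min", "knn"):
            raise ValueError(f"unknown imputation_method {self.imputation_method!r}")
        if self.inner_clusterer not in ("kmeans", "ward"):
            raise ValueError(f"unknown inner_clusterer {self.inner_clusterer!r}")
        if self.correlation_method not in ("pearson_log2", "spearman"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["pac_bounds"] = list(self.pac_bounds)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML key-value config.

    Every field has a documented default except ``seed``, which pins all
    randomized stages and must be stated explicitly; omitting it raises an
    error naming the key.  Unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "seed" not in raw:
        raise KeyError("missing required config key: 'seed'")
    return PipelineConfig(**raw)
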