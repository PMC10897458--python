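"""Pipeline configuration and named parameter profiles.

Profiles bundle the hyperparameters of the clustering pipeline.  The
``default`` profile holds broadly well-performing values for dense
aggregation movies; the others are the published per-treatment presets
(``isotropic``, ``random``, ``fibril``, ``sparse-4`` … ``sparse-25``).
Every field can be overridden per call or via the CLI.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = ["PipelineConfig", "load_profile", "available_profiles"]


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the clustering pipeline.

    Parameters follow the published vocabulary: ``investigate_min_sample``
    is the DBSCAN ``min_samples`` used to detect new aggregation seeds
    during temporal refinement (default 50); ``radius_ratio`` multiplies
    the SEM in the search-range formula r_search = sqrt(radius_ratio * SEM)
    (default 1.96, i.e. the 95% CI factor); ``rough_min_points`` /
    ``final_min_points`` are size filters applied before / after temporal
    refinement; ``filter_mode`` controls whether a candidate must pass the
    density filter and the size filter (``strict``), either (``lose``), or
    neither (``none``).
    """

    # initial clustering; initial_model "auto" applies the density rule,
    # dbscan_eps None derives eps from the observed density
    initial_model: str = "auto"  # auto | dbscan | hdbscan
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 10
    hdbscan_min_cluster_size: int = 200
    hdbscan_min_samples: int | None = None
    cluster_selection_epsilon: float = 0.03
    initial_dims: str = "spatial"  # spatial | spatiotemporal
    # temporal refinement
    investigate_min_sample: int = 50
    radius_ratio: float = 1.96
    refine_margin: float = 0.3
    # filtering
    rough_min_points: int = 50
    final_min_points: int = 20
    filter_mode: str = "strict"
    density_k: int = 10
    # numerics
    pdist_max_points: int = 2000
    failsafe_bins: int = 128
    failsafe_sigma: float = 2.0
    failsafe_percentile: float = 90.0
    seed: int = 0

    def __post_init__(self):
        if self.filter_mode not in ("strict", "lose", "none"):
            raise ValueError(f"filter_mode must be strict/lose/none, got {self.filter_mode!r}")
        if self.initial_model not in ("auto", "dbscan", "hdbscan"):
            raise ValueError(
                f"initial_model must be auto/dbscan/hdbscan, got {self.initial_model!r}"
            )
        if self.initial_dims not in ("spatial", "spatiotemporal"):
            raise ValueError(
                f"initial_dims must be spatial/spatiotemporal, got {self.initial_dims!r}"
            )

    def replace(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)


def _registry() -> dict:
    text = (
        importlib.resources.files("smorph").joinpath("profiles/default.yaml").read_text()
    )
    return yaml.safe_load(text)


def available_profiles() -> list[str]:
    return sorted(_registry()["profiles"])


def load_profile(name: str = "default", **overrides) -> PipelineConfig:
    """Load a named profile, applying the ``default`` base then overrides."""
    reg = _registry()["profiles"]
    if name not in reg:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(reg)}")
    params = dict(reg["default"])
    if name != "default":
        params.update(reg[name] or {})
    params.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(params) - known
    if unknown:
        raise KeyError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**params)
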