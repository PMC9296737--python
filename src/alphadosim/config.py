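"""Run configuration: one hierarchical config whose defaults are the
printed study setup (the "paper" profile).  Any override is recorded in
the provenance log written next to the artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "paper_defaults"]


@dataclass
class GeometryConfig:
    source_window_radius_mm: float = 5.9
    emission_rate_per_s: float = 2.4e5
    well_inner_radius_mm: float = 8.1
    wall_height_mm: float = 17.0
    source_to_bottom_mm: float = 19.0
    water_layer_um: float = 20.0
    phantom_depth_um: float = 2.5
    region_side_mm: float = 4.0
    spectrum_peak_mev: float = 4.9
    spectrum_sd_mev: float = 0.3


@dataclass
class PhantomConfig:
    n_ellipse: int = 10_000
    axis_mean_um: float = 15.3
    axis_sd_um: float = 4.1
    target_ellipse_volume_um3: float = 930.0
    n_mesh: int = 105
    n_mesh_tiles: int = 95
    target_mesh_volume_um3: float = 1070.0
    mesh_deformation: float = 0.15


@dataclass
class SegmentationConfig:
    nucleus_sigma_px: float = 2.0
    focus_sigma_px: float = 1.0
    median_size_px: int = 21
    min_focus_area_px: int = 9
    large_focus_area_px: int = 30
    area_bounds_px: tuple = (2000, 12000)
    max_foci: int = 20


@dataclass
class StatsConfig:
    thinning_p: float = 0.2
    through_origin: bool = True
    max_rif_support: int = 15
    detection_fraction: float = 0.75
    background_all_mean: float = 2.2
    background_large_mean: float = 1.2


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    phantoms: PhantomConfig = field(default_factory=PhantomConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    exposure_times_s: tuple = (240, 480, 720)
    n_transmission_histories: int = 2_000_000
    n_pips_histories: int = 2_000_000
    seed: int = 0
    smoke: bool = False

    def apply_smoke(self) -> "RunConfig":
        """Desk-scale profile: ~100 nuclei, 1e5 histories, 1% exposure."""
        cfg = dataclasses.replace(self)
        cfg.smoke = True
        cfg.phantoms = dataclasses.replace(
            self.phantoms, n_ellipse=100, n_mesh=10, n_mesh_tiles=1)
        cfg.n_transmission_histories = 100_000
        cfg.n_pips_histories = 100_000
        return cfg

    @property
    def exposure_scale(self) -> float:
        return 0.01 if self.smoke else 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (("geometry", GeometryConfig),
                         ("phantoms", PhantomConfig),
                         ("segmentation", SegmentationConfig),
                         ("stats", StatsConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        seg = kwargs.get("segmentation")
        if seg is not None and isinstance(seg.area_bounds_px, list):
            seg.area_bounds_px = tuple(seg.area_bounds_px)
        if "exposure_times_s" in kwargs:
            kwargs["exposure_times_s"] = tuple(kwargs["exposure_times_s"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.get("profile") == "paper":
            data.pop("profile")
            base = paper_defaults().to_dict()
            base.update(data)
            data = base
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def paper_defaults() -> RunConfig:
    """The printed irradiation configuration (all defaults)."""
    return RunConfig()
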