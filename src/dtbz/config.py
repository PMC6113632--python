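"""Parameterization of the synthetic heart phantom and pipeline runs.

The phantom emulates an ex vivo post-infarct left ventricle imaged with
co-registered late gadolinium enhancement (LGE) MRI and diffusion tensor
MRI (DT-MRI): an LV annulus with an infarct wedge, a border-zone (BZ)
shell around it, per-region LGE signal-intensity plateaus, per-region
diffusion-tensor invariant distributions, spatially correlated invariant
fields, Rician image noise, and a small rigid offset between the LGE and
DT-MRI frames that the registration stage must recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

# Integer labels shared by every stage of the pipeline.
BACKGROUND, REMOTE, BZ, INFARCT = 0, 1, 2, 3
REGION_NAMES = {REMOTE: "remote", BZ: "bz", INFARCT: "infarct"}
INVARIANT_NAMES = ("adc", "fa", "mode")


def derive_rng(root_seed: int, *tokens: str | int) -> np.random.Generator:
    """Named random substream derived from one root seed.

    Tokens are hashed so that e.g. ("phantom", 3) and ("noise", 3) give
    independent, reproducible streams.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF]
    for t in tokens:
        entropy.append(zlib.crc32(str(t).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class RegionParams:
    """Per-region LGE signal statistics and tensor-invariant targets.

    ``adc_median`` is in mm^2/s; FA is unitless on [0, 1); tissue mode is
    unitless on [-1, 1].  ``invariant_dispersion`` holds the voxelwise
    spread of each invariant around its median on its natural scale:
    (log-SD of ADC, logit-SD of FA, additive SD of mode).
    """

    si_mean: float
    si_sd: float
    adc_median: float
    fa_median: float
    mode_median: float
    invariant_dispersion: tuple[float, float, float] = (0.10, 0.15, 0.08)

    def __post_init__(self) -> None:
        if self.si_sd <= 0:
            raise ValueError("si_sd must be > 0")
        if not 0.0 <= self.fa_median < 1.0:
            raise ValueError("fa_median must be in [0, 1)")
        if not -1.0 <= self.mode_median <= 1.0:
            raise ValueError("mode_median must be in [-1, 1]")
        if self.adc_median <= 0:
            raise ValueError("adc_median must be > 0")


@dataclass
class FiberModel:
    """Transmural helix-angle model for the phantom's primary eigenvectors.

    Helix angle interpolates linearly from endocardium to epicardium,
    the standard ventricular convention (+60 deg endo to -60 deg epi).
    """

    helix_angle_endo: float = 60.0
    helix_angle_epi: float = -60.0

    def __post_init__(self) -> None:
        for a in (self.helix_angle_endo, self.helix_angle_epi):
            if not -90.0 <= a <= 90.0:
                raise ValueError("helix angles must lie in [-90, 90] degrees")


@dataclass
class LVGeometry:
    """LV annulus geometry on the DT-MRI grid.

    Radii are in mm (in-plane).  Slices with index below ``apex_slice``
    are outside the heart, which gives the through-plane (apex) alignment
    of the registration stage something to find.
    """

    center: tuple[float, float] | None = None  # in-plane voxel coords; None -> grid center
    inner_radius: float = 18.0
    outer_radius: float = 30.0
    apex_slice: int = 2

    def __post_init__(self) -> None:
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner radius must be < outer radius")


@dataclass
class InfarctWedge:
    """Angular wedge of infarcted myocardium.

    ``center_angle`` / ``angular_extent`` in degrees; ``transmural_extent``
    is the fraction of the wall, endocardium outward, that the wedge
    occupies; ``slice_range`` is the inclusive [lo, hi] slice span.
    A zero angular or transmural extent yields a heart with no infarct.
    """

    center_angle: float = -90.0  # inferior wall
    angular_extent: float = 80.0
    transmural_extent: float = 1.0
    slice_range: tuple[int, int] = (4, 12)


def _default_region_params() -> dict[str, RegionParams]:
    # Invariant medians for each region; LGE SI plateaus chosen so the
    # threshold rules (halfway level; remote mean + 2 SD) separate cleanly.
    return {
        "normal": RegionParams(100.0, 10.0, 0.563e-3, 0.470, 0.743),
        "remote": RegionParams(100.0, 10.0, 0.573e-3, 0.464, 0.666),
        "bz": RegionParams(180.0, 15.0, 0.647e-3, 0.417, 0.621),
        "infarct": RegionParams(300.0, 30.0, 0.797e-3, 0.330, 0.515),
    }


def _default_correlation_lengths() -> dict[str, tuple[float, float, float]]:
    # 1/e autocorrelation lengths in voxels per axis (x, y, z).
    return {
        "normal": (3.0, 3.0, 1.8),
        "remote": (3.0, 3.0, 1.8),
        "bz": (1.2, 1.2, 1.1),
        "infarct": (1.7, 1.7, 1.2),
    }


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic heart."""

    grid_dims_dti: tuple[int, int, int] = (96, 96, 16)
    voxel_dims_dti: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lge_upsampling: tuple[int, int, int] = (3, 3, 9)
    lv_geometry: LVGeometry = field(default_factory=LVGeometry)
    infarct_wedge: InfarctWedge = field(default_factory=InfarctWedge)
    bz_shell_thickness: float = 3.0  # mm
    region_params: dict[str, RegionParams] = field(default_factory=_default_region_params)
    fiber_model: FiberModel = field(default_factory=FiberModel)
    correlation_lengths: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_correlation_lengths
    )
    dwi_snr: float = 59.0
    lge_snr: float = 10.0
    s0: float = 1000.0  # non-diffusion-weighted tissue signal, a.u.
    rigid_offset: tuple[float, float, float] = (1.0, -1.0, 0.0)  # mm, LGE frame
    heart_kind: str = "infarcted"  # "infarcted" | "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(u) < 1 for u in self.lge_upsampling):
            raise ValueError("lge_upsampling factors must be >= 1")
        if self.bz_shell_thickness <= 0:
            raise ValueError("bz_shell_thickness must be > 0")
        missing = {"normal", "remote", "bz", "infarct"} - set(self.region_params)
        if missing:
            raise ValueError(f"region_params missing regions: {sorted(missing)}")
        if self.heart_kind not in ("infarcted", "normal"):
            raise ValueError("heart_kind must be 'infarcted' or 'normal'")

    @classmethod
    def normal(cls, seed: int = 0, **kwargs) -> "PhantomSpec":
        """A control heart: no infarct wedge, myocardium uses 'normal' params."""
        wedge = InfarctWedge(angular_extent=0.0, transmural_extent=0.0)
        return cls(infarct_wedge=wedge, heart_kind="normal", seed=seed, **kwargs)

    @property
    def grid_dims_lge(self) -> tuple[int, int, int]:
        return tuple(d * u for d, u in zip(self.grid_dims_dti, self.lge_upsampling))

    @property
    def voxel_dims_lge(self) -> tuple[float, float, float]:
        return tuple(v / u for v, u in zip(self.voxel_dims_dti, self.lge_upsampling))

    def region_for_label(self, label: int) -> str:
        """Region-parameter key for a myocardial label on this heart."""
        if label == REMOTE and self.heart_kind == "normal":
            return "normal"
        return REGION_NAMES[label]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        if "lv_geometry" in d and isinstance(d["lv_geometry"], Mapping):
            g = dict(d["lv_geometry"])
            if g.get("center") is not None:
                g["center"] = tuple(g["center"])
            d["lv_geometry"] = LVGeometry(**g)
        if "infarct_wedge" in d and isinstance(d["infarct_wedge"], Mapping):
            w = dict(d["infarct_wedge"])
            w["slice_range"] = tuple(w["slice_range"])
            d["infarct_wedge"] = InfarctWedge(**w)
        if "fiber_model" in d and isinstance(d["fiber_model"], Mapping):
            d["fiber_model"] = FiberModel(**d["fiber_model"])
        if "region_params" in d:
            d["region_params"] = {
                k: (RegionParams(**{**v, "invariant_dispersion": tuple(v["invariant_dispersion"])})
                    if isinstance(v, Mapping) else v)
                for k, v in d["region_params"].items()
            }
        if "correlation_lengths" in d:
            d["correlation_lengths"] = {
                k: tuple(v) for k, v in d["correlation_lengths"].items()
            }
        for key in ("grid_dims_dti", "voxel_dims_dti", "lge_upsampling", "rigid_offset"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _listify(obj):
    """Tuples -> lists recursively, for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class BootstrapConfig:
    """Resampling parameters for the distribution-free statistics."""

    n_resamples_hist: int = 1000
    n_resamples_test: int = 10000
    n_bins: int = 32
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples_hist < 100 or self.n_resamples_test < 100:
            raise ValueError("bootstrap resample counts must be >= 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class RunConfig:
    """One full study: several infarcted hearts plus normal controls.

    Exactly one input mode is supported here: phantom simulation.  All
    per-heart randomness (geometry noise, image noise) and the bootstrap
    streams derive from ``seed`` via named substreams.
    """

    n_infarcted: int = 7
    n_normal: int = 7
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    myocardium_threshold_fraction: float = 0.5
    share_strides_across_invariants: bool = False
    randomize_rigid_offset: bool = True
    max_offset_voxels: int = 2
    bvec_path: str | None = None  # optional external gradient table (FSL dialect)
    bval_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "phantom" in d and isinstance(d["phantom"], Mapping):
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        if "bootstrap" in d and isinstance(d["bootstrap"], Mapping):
            d["bootstrap"] = BootstrapConfig(**d["bootstrap"])
        return cls(**d)
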