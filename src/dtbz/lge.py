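"""LGE signal-intensity segmentation of remote, border-zone and infarcted
myocardium, with down-sampling to the DT-MRI grid and morphological
refinement.

The classification follows the per-heart threshold rules: the infarct
threshold sits halfway between the mean signal intensity (SI) of a
remote-myocardium ROI and an infarct ROI; the border zone (BZ) is the
band of SI below that halfway level but more than two remote SDs above
the remote mean.  After down-sampling, infarct islands of three voxels
or fewer are dissolved into BZ, and BZ voxels farther than 3 mm from any
surviving infarct voxel revert to remote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import BACKGROUND, BZ, INFARCT, REMOTE

logger = logging.getLogger(__name__)

ISLAND_MAX_VOXELS = 3      # infarct components of this size or smaller dissolve to BZ
BZ_MAX_DISTANCE_MM = 3.0   # BZ farther than this from infarct reverts to remote


@dataclass
class LGEVolume:
    """Late gadolinium enhancement magnitude image."""

    si: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.si)) or np.any(self.si < 0):
            raise ValueError("LGE signal intensities must be finite and >= 0")


@dataclass
class LabelVolume:
    """Integer labels {0 background, 1 remote, 2 BZ, 3 infarct}."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.isin(self.labels, [BACKGROUND, REMOTE, BZ, INFARCT]).all():
            raise ValueError("labels must be in {0, 1, 2, 3}")

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def myocardium(self) -> np.ndarray:
        return self.labels != BACKGROUND


@dataclass
class ROIStats:
    """SI mean/SD inside the drawn remote and infarct seed ROIs."""

    mean_remote: float
    sd_remote: float
    mean_infarct: float
    sd_infarct: float
    n_remote: int
    n_infarct: int


@dataclass
class ThresholdSet:
    """SI cut points: infarct at/above ``t_half``, BZ strictly between."""

    t_half: float
    t_bz: float

    def __post_init__(self) -> None:
        if self.t_bz >= self.t_half:
            raise ValueError(
                f"BZ threshold ({self.t_bz:g}) must lie below the halfway "
                f"threshold ({self.t_half:g}); regions are not separable"
            )


def compute_roi_stats(lge: LGEVolume, remote_roi: np.ndarray,
                      infarct_roi: np.ndarray) -> ROIStats:
    """SI mean and sample SD inside each seed ROI."""
    remote_roi = np.asarray(remote_roi, bool)
    infarct_roi = np.asarray(infarct_roi, bool)
    if np.any(remote_roi & infarct_roi):
        raise ValueError("remote and infarct ROIs overlap")
    if not remote_roi.any() or not infarct_roi.any():
        raise ValueError("ROIs must be nonempty")
    r = lge.si[remote_roi].astype(float)
    i = lge.si[infarct_roi].astype(float)
    mean_r, mean_i = float(r.mean()), float(i.mean())
    if mean_i <= mean_r:
        raise ValueError(
            f"infarct ROI mean SI ({mean_i:g}) is not above remote mean "
            f"({mean_r:g}): no hyperenhancement to threshold"
        )
    sd = lambda x: float(x.std(ddof=1)) if x.size > 1 else 0.0
    return ROIStats(mean_r, sd(r), mean_i, sd(i), r.size, i.size)


def derive_thresholds(stats: ROIStats) -> ThresholdSet:
    """Halfway infarct threshold and remote-mean + 2 SD border-zone floor."""
    t_half = 0.5 * (stats.mean_remote + stats.mean_infarct)
    t_bz = stats.mean_remote + 2.0 * stats.sd_remote
    return ThresholdSet(t_half=t_half, t_bz=t_bz)


def classify_lge(lge: LGEVolume, myo_mask: np.ndarray,
                 thr: ThresholdSet) -> LabelVolume:
    """Threshold classification inside the myocardium mask.

    SI >= t_half -> infarct; t_bz < SI < t_half -> BZ; SI <= t_bz ->
    remote (boundary conventions fixed at the stated levels).
    """
    myo_mask = np.asarray(myo_mask, bool)
    labels = np.zeros(lge.si.shape, dtype=np.int16)
    labels[myo_mask] = REMOTE
    labels[myo_mask & (lge.si > thr.t_bz)] = BZ
    labels[myo_mask & (lge.si >= thr.t_half)] = INFARCT
    return LabelVolume(labels, lge.voxel_dims)


def downsample_labels(labels_lge: LabelVolume, target_dims: tuple[int, int, int],
                      target_voxel_dims: tuple[float, float, float]) -> LabelVolume:
    """Down-sample LGE-resolution labels to the DT-MRI grid.

    Each label's binary indicator is block-averaged in the slice
    direction to match the DT-MRI slice thickness, then resampled
    in-plane with bicubic interpolation.  Every target voxel takes the
    label with the largest resampled fraction; exact ties break toward
    the more severe label (infarct > BZ > remote > background).
    """
    src = labels_lge.labels
    factors = []
    for ax, (s, t) in enumerate(zip(src.shape, target_dims)):
        if s % t != 0:
            raise ValueError(f"axis {ax}: source dim {s} not an integer multiple of {t}")
        factors.append(s // t)
    fx, fy, fz = factors
    order = (INFARCT, BZ, REMOTE, BACKGROUND)  # severity order; argmax picks first max
    fractions = np.empty((4,) + tuple(target_dims), dtype=np.float64)
    for k, lab in enumerate(order):
        ind = (src == lab).astype(np.float64)
        # block average through-plane
        x, y, z = ind.shape
        ind = ind.reshape(x, y, z // fz, fz).mean(axis=3)
        # bicubic in-plane resampling
        ind = ndimage.zoom(ind, (1.0 / fx, 1.0 / fy, 1.0), order=3,
                           grid_mode=True, mode="grid-constant")
        fractions[k] = ind
    winner = np.argmax(fractions, axis=0)
    out = np.empty(tuple(target_dims), dtype=np.int16)
    for k, lab in enumerate(order):
        out[winner == k] = lab
    return LabelVolume(out, tuple(target_voxel_dims))


def refine_labels(labels: LabelVolume) -> LabelVolume:
    """Morphological refinement on the DT-MRI grid.

    (1) 6-connected infarct components of three voxels or fewer are
    relabeled BZ; (2) BZ voxels more than 3 mm (Euclidean, in mm) from
    the nearest surviving infarct voxel are relabeled remote.
    """
    lab = labels.labels.copy()
    infarct = lab == INFARCT
    comp, n = ndimage.label(infarct)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes <= ISLAND_MAX_VOXELS) + 1
        if small.size:
            logger.info("dissolving %d infarct island(s) of <= %d voxels into BZ",
                        small.size, ISLAND_MAX_VOXELS)
            lab[np.isin(comp, small)] = BZ
    surviving = lab == INFARCT
    bz = lab == BZ
    if surviving.any():
        dist = ndimage.distance_transform_edt(~surviving, sampling=labels.voxel_dims)
        lab[bz & (dist > BZ_MAX_DISTANCE_MM)] = REMOTE
    elif bz.any():
        logger.warning("no infarct voxels survive refinement; relabeling all BZ to remote")
        lab[bz] = REMOTE
    return LabelVolume(lab, labels.voxel_dims)


def compute_snr(volume: np.ndarray, tissue_roi: np.ndarray,
                background_roi: np.ndarray) -> float:
    """Mean tissue signal divided by the SD of an equal-area background ROI."""
    tissue_roi = np.asarray(tissue_roi, bool)
    background_roi = np.asarray(background_roi, bool)
    nt, nb = int(tissue_roi.sum()), int(background_roi.sum())
    if nt == 0 or nb == 0:
        raise ValueError("SNR ROIs must be nonempty")
    if nt != nb:
        raise ValueError(f"SNR ROIs must have equal area (tissue {nt}, background {nb})")
    sd_bg = float(np.asarray(volume)[background_roi].std(ddof=1))
    if sd_bg == 0:
        raise ValueError("background ROI has zero SD; cannot form SNR")
    return float(np.asarray(volume)[tissue_roi].mean()) / sd_bg
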