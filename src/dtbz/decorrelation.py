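"""Spatial decorrelation of invariant maps.

Voxelwise imaging data is spatially correlated, so voxels are not
independent samples.  Each region's autocorrelation function (ACF) is
estimated along every axis, summarized by its 1/e correlation length,
and the region is decimated on a lattice with that stride to produce
approximately independent samples — the unit of all downstream
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MIN_PAIRS_LAG1 = 50   # required pairs at lag 1 for a usable profile
MIN_PAIRS_LAG = 30    # lags with fewer pairs are truncated
ACF_THRESHOLD = float(np.exp(-1.0))


@dataclass
class ACFProfile:
    """Normalized spatial autocorrelation along one axis."""

    axis: int
    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values[0] != 1.0:
            raise ValueError("ACF at lag 0 must be 1")


@dataclass
class RegionSampleSet:
    """Spatially decorrelated scalar samples for one (heart, region, invariant)."""

    heart_id: str
    region: str
    invariant: str
    samples: np.ndarray
    strides: tuple[int, int, int]
    insufficient: bool = False

    @property
    def n(self) -> int:
        return int(self.samples.size)


def estimate_acf(values: np.ndarray, mask: np.ndarray, axis: int,
                 max_lag: int | None = None) -> ACFProfile:
    """Pearson-style ACF over in-mask voxel pairs separated along ``axis``.

    The region mean is subtracted and products are normalized by the
    region variance, so lag 0 is exactly 1.  Lags with fewer than 30
    pairs are truncated; a degenerate (zero-variance) region raises.
    """
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool) & np.isfinite(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("region too small for ACF estimation")
    mu = x.mean()
    var = x.var()
    if var == 0:
        raise ValueError("region has zero variance; ACF undefined")
    n = values.shape[axis]
    if max_lag is None:
        max_lag = n - 1
    lags = [0]
    acf = [1.0]
    for k in range(1, max_lag + 1):
        sl_a = [slice(None)] * values.ndim
        sl_b = [slice(None)] * values.ndim
        sl_a[axis] = slice(0, n - k)
        sl_b[axis] = slice(k, n)
        pair_ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        npairs = int(pair_ok.sum())
        if k == 1 and npairs < MIN_PAIRS_LAG1:
            raise ValueError(
                f"only {npairs} in-mask pairs at lag 1 (need >= {MIN_PAIRS_LAG1})"
            )
        if npairs < MIN_PAIRS_LAG:
            break
        va = values[tuple(sl_a)][pair_ok] - mu
        vb = values[tuple(sl_b)][pair_ok] - mu
        r = float(np.mean(va * vb) / var)
        lags.append(k)
        acf.append(float(np.clip(r, -1.0, 1.0)))
    return ACFProfile(axis=axis, lags=np.asarray(lags), values=np.asarray(acf))


def autocorrelation_length(profile: ACFProfile, rounded: bool = True) -> float:
    """1/e correlation length in voxels.

    The first crossing below 1/e is located by linear interpolation
    between the bracketing lags, then rounded to the nearest integer
    (minimum 1) for use as a decimation stride.  If the profile never
    drops below 1/e the maximum available lag is returned with a
    warning.
    """
    vals = profile.values
    lags = profile.lags
    below = np.flatnonzero(vals < ACF_THRESHOLD)
    if below.size == 0:
        logger.warning("ACF never drops below 1/e within %d lags; using max lag",
                       int(lags[-1]))
        length = float(lags[-1])
    else:
        j = int(below[0])
        v0, v1 = vals[j - 1], vals[j]
        length = float(lags[j - 1] + (v0 - ACF_THRESHOLD) / (v0 - v1))
    if rounded:
        return float(max(1, int(np.rint(length))))
    return max(length, 1.0)


def decimate(values: np.ndarray, mask: np.ndarray,
             strides: tuple[int, int, int], *, heart_id: str = "",
             region: str = "", invariant: str = "") -> RegionSampleSet:
    """Keep in-mask voxels on a lattice with the given per-axis strides.

    The lattice is anchored at the region bounding-box minimum.  NaN
    values are dropped.  Results with fewer than 10 samples are flagged
    insufficient.
    """
    if any(int(s) < 1 for s in strides):
        raise ValueError("strides must be >= 1")
    strides = tuple(int(s) for s in strides)
    mask = np.asarray(mask, bool)
    if not mask.any():
        return RegionSampleSet(heart_id, region, invariant,
                               np.empty(0), strides, insufficient=True)
    idx = np.nonzero(mask)
    origin = [int(i.min()) for i in idx]
    lattice = np.zeros(mask.shape, bool)
    lattice[tuple(slice(o, None, s) for o, s in zip(origin, strides))] = True
    keep = mask & lattice
    samples = np.asarray(values, float)[keep]
    samples = samples[np.isfinite(samples)]
    return RegionSampleSet(heart_id, region, invariant, samples, strides,
                           insufficient=samples.size < 10)
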