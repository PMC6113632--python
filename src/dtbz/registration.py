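"""Rigid translation registration of the LGE-derived myocardium mask to
the DT-MRI myocardium mask.

Through-plane alignment matches the most apical nonempty slice of the
two binary masks; in-plane alignment finds the single global integer
(dx, dy) maximizing the sum over slices of the 2D cross-correlation of
the binary masks.  Only integer-voxel translation is performed: the
residual misregistration is sub-voxel by construction and interpolating
labels would create mixed classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BACKGROUND
from .lge import LabelVolume


@dataclass
class RigidShift:
    """Integer voxel shift of one frame relative to another."""

    dx: int
    dy: int
    dz: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.dx, self.dy, self.dz)

    def negated(self) -> "RigidShift":
        return RigidShift(-self.dx, -self.dy, -self.dz)

    def in_mm(self, voxel_dims) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.as_tuple(), voxel_dims))


def align_apex(mask_a: np.ndarray, mask_b: np.ndarray, apex_low: bool = True) -> int:
    """Through-plane shift of a relative to b by apex alignment.

    Returns ``dz = apex_slice(a) - apex_slice(b)`` where the apex is the
    most apical nonempty slice (lowest index when ``apex_low``).
    """
    def apex(mask):
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask: cannot locate the apex")
        nonempty = np.flatnonzero(mask.any(axis=(0, 1)))
        return int(nonempty[0] if apex_low else nonempty[-1])

    return apex(mask_a) - apex(mask_b)


def inplane_xcorr_shift(mask_a: np.ndarray, mask_b: np.ndarray,
                        max_shift: int | None = None) -> tuple[int, int]:
    """Global in-plane shift of a relative to b by summed 2D cross-correlation.

    Scores ``sum_z sum_xy a[x+dx, y+dy, z] * b[x, y, z]`` over integer
    shifts within a +/- quarter-grid window (or ``max_shift``); ties
    break toward the smallest shift norm, then lexicographically.
    Through-plane alignment must already have been applied.
    """
    a = np.asarray(mask_a, float)
    b = np.asarray(mask_b, float)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    nx, ny = a.shape[:2]
    if max_shift is None:
        max_shift = min(nx, ny) // 4
    # circular cross-correlation slice-by-slice via FFT, summed over z
    fa = np.fft.rfftn(a, axes=(0, 1))
    fb = np.fft.rfftn(b, axes=(0, 1))
    c = np.fft.irfftn(np.conj(fa) * fb, s=(nx, ny), axes=(0, 1)).sum(axis=2)
    # c[(-dx) % nx, (-dy) % ny] = sum a(x+dx, y) b(x, y)
    scores = np.rint(c).astype(np.int64)
    best = None
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            s = scores[(-dx) % nx, (-dy) % ny]
            key = (-s, dx * dx + dy * dy, dx, dy)
            if best is None or key < best[0]:
                best = (key, (dx, dy))
    if best is None or best[0][0] == 0:
        raise ValueError("masks share no overlap at any candidate shift")
    return best[1]


def apply_rigid_translation(labels: LabelVolume, shift: RigidShift) -> LabelVolume:
    """Integer voxel translation of a label volume; vacated voxels become
    background.  No interpolation is performed."""
    lab = labels.labels
    for ax, (s, dim) in enumerate(zip(shift.as_tuple(), lab.shape)):
        if abs(s) > dim // 2:
            raise ValueError(f"shift {s} on axis {ax} exceeds half the grid ({dim})")
    out = np.full_like(lab, BACKGROUND)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift.as_tuple()):
        n = lab.shape[ax]
        if s >= 0:
            dst[ax] = slice(s, n)
            src[ax] = slice(0, n - s)
        else:
            dst[ax] = slice(0, n + s)
            src[ax] = slice(-s, n)
    out[tuple(dst)] = lab[tuple(src)]
    return LabelVolume(out, labels.voxel_dims)


def register_masks(mask_lge: np.ndarray, mask_dti: np.ndarray,
                   apex_low: bool = True,
                   max_shift: int | None = None) -> RigidShift:
    """Full rigid registration: apex alignment through-plane, then summed
    2D cross-correlation in-plane.  Returns the shift of the LGE-derived
    mask relative to the DT-MRI mask; apply its negation to the LGE
    labels to bring them into the DT-MRI frame."""
    dz = align_apex(mask_lge, mask_dti, apex_low=apex_low)
    rolled = np.roll(np.asarray(mask_lge, bool), -dz, axis=2)
    dx, dy = inplane_xcorr_shift(rolled, mask_dti, max_shift=max_shift)
    return RigidShift(dx, dy, dz)
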