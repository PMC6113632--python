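"""Diffusion tensor estimation and invariant maps.

Tensors are fit to the Stejskal-Tanner signal model
``S_i = S0 * exp(-b g_i^T D g_i)`` by ordinary least squares on the
log-transformed signal ratios, following the standard log-linear
reconstruction.  From the fitted tensor D three rotation-invariant maps
are derived:

* ADC, the apparent diffusion coefficient, ``trace(D)/3`` [mm^2/s] —
  the overall magnitude of diffusion, which rises as cellularity falls;
* FA, fractional anisotropy, ``sqrt(3/2) * ||A|| / ||D||`` with
  ``A = D - ADC*I`` the deviatoric tensor — the normalized magnitude of
  anisotropic diffusion on [0, 1], which falls with fibrosis;
* tissue mode, ``3*sqrt(6) * det(A/||A||)`` on [-1, 1] — the kind of
  anisotropy: +1 rod-like, 0 orthotropic/sheet-like, -1 planar.

For an isotropic tensor the deviatoric norm vanishes; FA is then 0 and
mode is undefined (NaN), and such voxels are excluded from downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import packaged_directions

_MAX_DESIGN_CONDITION = 1e6


@dataclass
class AcquisitionScheme:
    """Diffusion encoding: one b=0 measurement plus ``directions`` at ``b_value``."""

    b_value: float
    directions: np.ndarray  # (N, 3), unit rows

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if self.b_value <= 0:
            raise ValueError("b_value must be > 0")
        if self.directions.shape[0] < 6:
            raise ValueError("need at least 6 non-collinear directions")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit vectors")

    @classmethod
    def default(cls, b_value: float = 1000.0) -> "AcquisitionScheme":
        """b = 1000 s/mm^2 with the packaged 30-direction set."""
        return cls(b_value=b_value, directions=packaged_directions())

    def design_matrix(self) -> np.ndarray:
        """Rows [gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz] so that
        ``row @ dvec = g^T D g`` with dvec = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
        g = self.directions
        return np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])


@dataclass
class DWIStack:
    """One b=0 volume plus one diffusion-weighted volume per direction."""

    s0: np.ndarray            # (X, Y, Z)
    dwi: np.ndarray           # (N, X, Y, Z)
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.dwi.shape[1:] != self.s0.shape:
            raise ValueError("s0 and dwi grids differ")


@dataclass
class TensorField:
    """Per-voxel symmetric tensor as its six unique components."""

    components: np.ndarray    # (X, Y, Z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    mask: np.ndarray          # (X, Y, Z) bool, True where the fit is valid
    voxel_dims: tuple[float, float, float]

    def as_matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric matrices."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, mask: np.ndarray, voxel_dims) -> "TensorField":
        c = np.stack([
            m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
            m[..., 0, 1], m[..., 0, 2], m[..., 1, 2],
        ], axis=-1)
        return cls(c, np.asarray(mask, bool), tuple(voxel_dims))


@dataclass
class TensorEigenSystem:
    eigenvalues: np.ndarray   # (X, Y, Z, 3), descending
    eigenvectors: np.ndarray  # (X, Y, Z, 3, 3), columns match eigenvalues
    mask: np.ndarray


@dataclass
class InvariantMaps:
    adc: np.ndarray
    fa: np.ndarray
    mode: np.ndarray
    mask: np.ndarray


def fit_tensor_lls(dwi: DWIStack, scheme: AcquisitionScheme,
                   noise_floor: float = 0.0) -> TensorField:
    """Log-linear ordinary-least-squares tensor fit.

    Solves ``ln(S_i/S0) = -b g_i^T D g_i`` per voxel.  Voxels with
    ``S0 <= noise_floor`` or any non-positive diffusion-weighted signal
    cannot be log-transformed and are masked invalid.
    """
    G = scheme.design_matrix()
    cond = np.linalg.cond(G)
    if cond > _MAX_DESIGN_CONDITION:
        raise ValueError(
            f"gradient design matrix is rank deficient (condition number {cond:.3g})"
        )
    shape = dwi.s0.shape
    valid = (dwi.s0 > noise_floor) & np.all(dwi.dwi > 0, axis=0) & np.isfinite(dwi.s0)
    comps = np.zeros(shape + (6,), dtype=np.float64)
    if valid.any():
        s0 = dwi.s0[valid]
        sig = dwi.dwi[:, valid]
        y = np.log(sig / s0[None, :])                      # (N, M)
        # OLS: q = g^T D g = -y/b; dvec = pinv(G) @ q
        dvec = np.linalg.pinv(G) @ (-y / scheme.b_value)   # (6, M)
        comps[valid] = dvec.T
        bad = ~np.all(np.isfinite(dvec), axis=0)
        if bad.any():
            idx = np.where(valid)
            valid = valid.copy()
            valid[tuple(i[bad] for i in idx)] = False
    return TensorField(comps, valid, dwi.voxel_dims)


def eigendecompose(tensors: TensorField) -> TensorEigenSystem:
    """Symmetric eigendecomposition, eigenvalues sorted descending.

    Each eigenvector's sign is fixed so its largest-magnitude component
    is positive, making the output deterministic.  Voxels with
    non-finite components are masked.
    """
    mask = tensors.mask & np.all(np.isfinite(tensors.components), axis=-1)
    if not mask.any():
        raise ValueError("no valid voxels to decompose")
    m = tensors.as_matrices()
    evals = np.zeros(m.shape[:-2] + (3,))
    evecs = np.zeros_like(m)
    w, v = np.linalg.eigh(m[mask])          # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    # deterministic sign: largest-|component| positive
    arg = np.argmax(np.abs(v), axis=1, keepdims=True)
    signs = np.sign(np.take_along_axis(v, arg, axis=1))
    signs[signs == 0] = 1.0
    v = v * signs
    evals[mask] = w
    evecs[mask] = v
    return TensorEigenSystem(evals, evecs, mask)


def invariants_from_components(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ADC, FA, mode from stacked unique components (..., 6)."""
    dxx, dyy, dzz, dxy, dxz, dyz = (c[..., i] for i in range(6))
    adc = (dxx + dyy + dzz) / 3.0
    # deviatoric part
    axx, ayy, azz = dxx - adc, dyy - adc, dzz - adc
    norm_a2 = axx**2 + ayy**2 + azz**2 + 2 * (dxy**2 + dxz**2 + dyz**2)
    norm_d2 = dxx**2 + dyy**2 + dzz**2 + 2 * (dxy**2 + dxz**2 + dyz**2)
    norm_a = np.sqrt(norm_a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * norm_a / np.sqrt(norm_d2)
        det_a = (axx * (ayy * azz - dyz**2)
                 - dxy * (dxy * azz - dyz * dxz)
                 + dxz * (dxy * dyz - ayy * dxz))
        mode = 3.0 * np.sqrt(6.0) * det_a / norm_a**3
    # mode is ill-conditioned as the deviatoric part vanishes: treat
    # tensors with a relatively negligible deviatoric norm as isotropic
    iso = norm_a2 <= (1e-14) ** 2 + (1e-9) ** 2 * norm_d2
    fa = np.where(iso, 0.0, fa)
    fa = np.where(norm_d2 == 0, 0.0, fa)
    mode = np.where(iso, np.nan, np.clip(mode, -1.0, 1.0))
    return adc, fa, mode


def compute_invariants(tensors: TensorField) -> InvariantMaps:
    """ADC, FA and tissue-mode maps from a fitted tensor field.

    Isotropic (or zero) tensors get FA = 0 and mode = NaN; NaN mode is
    excluded from all downstream statistics.
    """
    adc, fa, mode = invariants_from_components(tensors.components)
    adc = np.where(tensors.mask, adc, 0.0)
    fa = np.where(tensors.mask, fa, 0.0)
    mode = np.where(tensors.mask, mode, np.nan)
    return InvariantMaps(adc, fa, mode, tensors.mask.copy())


def myocardium_mask_from_b0(dwi: DWIStack, threshold_fraction: float = 0.5) -> np.ndarray:
    """Myocardium mask by intensity threshold on the b=0 volume.

    A stand-in for tensor-based myocardial segmentation: keep voxels
    brighter than ``threshold_fraction`` times the 99th percentile of
    S0, then retain the largest 6-connected component.  Works because
    the susceptibility-matched bath around an ex vivo heart is nearly
    signal-free.
    """
    s0 = dwi.s0
    thr = threshold_fraction * np.percentile(s0, 99)
    raw = s0 > thr
    if not raw.any():
        raise ValueError("empty myocardium mask: no voxels above threshold")
    labels, n = ndimage.label(raw)  # 6-connectivity by default in 3D
    if n == 0:
        raise ValueError("empty myocardium mask after connected components")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep
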