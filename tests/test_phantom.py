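"""Phantom generator: geometry, invariant closed forms, field sampling,
and forward image simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtbz.config import BACKGROUND, BZ, INFARCT, REMOTE, PhantomSpec, InfarctWedge
from dtbz.phantom import (build_label_geometry, invariants_to_eigenvalues,
                          lge_frame_labels, sample_tensor_field, simulate_dwi,
                          simulate_lge)
from dtbz.tensor import AcquisitionScheme, TensorField, fit_tensor_lls, \
    invariants_from_components
from conftest import small_phantom_spec

TABLE_MEDIANS = {  # (adc mm^2/s, fa, mode) per region
    "normal": (0.563e-3, 0.470, 0.743),
    "remote": (0.573e-3, 0.464, 0.666),
    "bz": (0.647e-3, 0.417, 0.621),
    "infarct": (0.797e-3, 0.330, 0.515),
}


def forward_invariants(lam):
    """Independent forward route: invariants from a diagonal tensor."""
    c = np.zeros(np.shape(lam)[:-1] + (6,))
    c[..., :3] = lam
    return invariants_from_components(c)


class TestLabelGeometry:
    def test_zero_extent_wedge_gives_all_remote(self):
        spec = small_phantom_spec(
            infarct_wedge=InfarctWedge(angular_extent=0.0, transmural_extent=0.0))
        lab = build_label_geometry(spec).labels
        assert set(np.unique(lab)) == {BACKGROUND, REMOTE}

    def test_bz_shell_within_thickness_of_infarct(self, small_spec, small_labels):
        lab = small_labels.labels
        vx, vy, vz = small_spec.voxel_dims_dti
        inf = np.argwhere(lab == INFARCT) * [vx, vy, vz]
        bz = np.argwhere(lab == BZ) * [vx, vy, vz]
        assert len(bz) and len(inf)
        d2 = ((bz[:, None, :] - inf[None, :, :]) ** 2).sum(-1).min(axis=1)
        assert np.all(np.sqrt(d2) <= small_spec.bz_shell_thickness + 1e-9)

    def test_infarct_count_matches_bruteforce_wedge_oracle(self, small_spec, small_labels):
        """Independent per-voxel point-in-wedge test reproduces the count."""
        spec = small_spec
        geo, w = spec.lv_geometry, spec.infarct_wedge
        nx, ny, nz = spec.grid_dims_dti
        cx, cy = (nx - 1) / 2, (ny - 1) / 2
        count = 0
        for i in range(nx):
            for j in range(ny):
                r = np.hypot((i - cx) * spec.voxel_dims_dti[0],
                             (j - cy) * spec.voxel_dims_dti[1])
                if not (geo.inner_radius <= r <= geo.outer_radius):
                    continue
                ang = np.degrees(np.arctan2(j - cy, i - cx))
                d = (ang - w.center_angle + 180.0) % 360.0 - 180.0
                if abs(d) > w.angular_extent / 2:
                    continue
                frac = (r - geo.inner_radius) / (geo.outer_radius - geo.inner_radius)
                if frac > w.transmural_extent:
                    continue
                for k in range(max(w.slice_range[0], geo.apex_slice),
                               min(w.slice_range[1], nz - 1) + 1):
                    count += 1
        assert count == int((small_labels.labels == INFARCT).sum())

    def test_wedge_below_apex_raises_with_slice(self):
        spec = small_phantom_spec(
            infarct_wedge=InfarctWedge(slice_range=(0, 5)))
        with pytest.raises(ValueError, match="slice 0"):
            build_label_geometry(spec)


class TestInvariantsToEigenvalues:
    def test_isotropic(self):
        lam = invariants_to_eigenvalues(1.0e-3, 0.0, 0.7)
        assert np.allclose(lam, 1.0e-3)

    def test_prolate_closed_form(self):
        lam = invariants_to_eigenvalues(1.0e-3, 0.40825, 1.0)
        assert np.allclose(lam, [1.5e-3, 0.75e-3, 0.75e-3], atol=2e-8)

    @pytest.mark.parametrize("region", sorted(TABLE_MEDIANS))
    def test_region_median_roundtrip_and_positivity(self, region):
        adc, fa, mode = TABLE_MEDIANS[region]
        lam = invariants_to_eigenvalues(adc, fa, mode)
        assert np.all(np.diff(lam) <= 0) and np.all(lam > 0)
        a2, f2, m2 = forward_invariants(lam)
        assert abs(a2 - adc) / adc < 1e-10
        assert abs(f2 - fa) / fa < 1e-10
        assert abs(m2 - mode) / abs(mode) < 1e-10

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(adc=st.floats(0.3e-3, 1.2e-3), fa=st.floats(0.05, 0.9),
           mode=st.floats(-0.99, 0.99))
    def test_roundtrip_identity_property(self, adc, fa, mode):
        lam = invariants_to_eigenvalues(adc, fa, mode)
        assert lam[0] >= lam[1] >= lam[2]
        a2, f2, m2 = forward_invariants(lam)
        assert abs(a2 - adc) <= 1e-10 * adc
        assert abs(f2 - fa) <= 1e-10 * max(fa, 1e-3)
        assert abs(m2 - mode) <= 1e-8

    def test_mode_out_of_range_raises(self):
        with pytest.raises(ValueError, match="mode"):
            invariants_to_eigenvalues(1e-3, 0.5, 1.5)


class TestTensorFieldSampling:
    def test_zero_dispersion_gives_exact_medians(self, small_labels):
        spec = small_phantom_spec()
        for rp in spec.region_params.values():
            rp.invariant_dispersion = (0.0, 0.0, 0.0)
        field = sample_tensor_field(small_labels, spec)
        remote = small_labels.labels == REMOTE
        adc, fa, mode = invariants_from_components(field.components[remote])
        rp = spec.region_params["remote"]
        assert np.allclose(adc, rp.adc_median, rtol=1e-12)
        assert np.allclose(fa, rp.fa_median, rtol=1e-9)
        assert np.allclose(mode, rp.mode_median, atol=1e-9)

    def test_sample_median_near_region_median(self, small_labels):
        spec = small_phantom_spec(seed=21)
        field = sample_tensor_field(small_labels, spec)
        for label, region in ((REMOTE, "remote"), (INFARCT, "infarct")):
            m = small_labels.labels == label
            assert m.sum() > 1000
            adc, _, _ = invariants_from_components(field.components[m])
            target = spec.region_params[region].adc_median
            assert abs(np.median(adc) - target) / target < 0.02

    def test_same_seed_bit_identical(self, small_labels):
        a = sample_tensor_field(small_labels, small_phantom_spec(seed=3))
        b = sample_tensor_field(small_labels, small_phantom_spec(seed=3))
        assert np.array_equal(a.components, b.components)


class TestSimulateDWI:
    def test_isotropic_closed_form_noiseless(self, scheme):
        comps = np.zeros((2, 2, 2, 6))
        comps[..., :3] = 1.0e-3
        tf = TensorField(comps, np.ones((2, 2, 2), bool), (1, 1, 1))
        stack = simulate_dwi(tf, scheme, s0=100.0, snr=np.inf)
        assert np.allclose(stack.dwi, 100.0 * np.exp(-1.0), rtol=1e-12)

    def test_noiseless_fit_recovers_tensor(self, scheme, small_labels):
        spec = small_phantom_spec(seed=9)
        field = sample_tensor_field(small_labels, spec)
        stack = simulate_dwi(field, scheme, s0=100.0, snr=np.inf)
        fit = fit_tensor_lls(stack, scheme)
        m = field.mask
        assert np.allclose(fit.components[m], field.components[m],
                           rtol=1e-9, atol=1e-15)

    def test_background_noise_sd_matches_snr(self, scheme):
        comps = np.zeros((40, 40, 8, 6))
        mask = np.zeros((40, 40, 8), bool)  # all background
        tf = TensorField(comps, mask, (1, 1, 1))
        stack = simulate_dwi(tf, scheme, s0=100.0, snr=59.0, seed=4)
        sd = stack.dwi[:, ~mask].std()
        assert stack.dwi[:, ~mask].size >= 1e4
        assert abs(sd - 100.0 / 59.0) / (100.0 / 59.0) < 0.05

    def test_non_unit_direction_rejected(self, scheme):
        with pytest.raises(ValueError, match="unit"):
            AcquisitionScheme(1000.0, scheme.directions * 1.5)


class TestSimulateLGE:
    def test_zero_sd_gives_plateaus(self, small_labels):
        spec = small_phantom_spec(rigid_offset=(0.0, 0.0, 0.0))
        for rp in spec.region_params.values():
            rp.si_sd = 1e-9
        hi = lge_frame_labels(small_labels, spec)
        vol = simulate_lge(hi, spec)
        for label, region in ((REMOTE, "remote"), (BZ, "bz"), (INFARCT, "infarct")):
            m = hi.labels == label
            assert np.allclose(vol.si[m], spec.region_params[region].si_mean,
                               atol=1e-3)

    def test_remote_sample_mean(self, small_heart, small_spec):
        m = small_heart.labels_lge_frame.labels == REMOTE
        assert m.sum() > 1e4
        mean = small_heart.lge.si[m].mean()
        target = small_spec.region_params["remote"].si_mean
        assert abs(mean - target) / target < 0.02

    def test_zero_offset_centroids_coincide(self, small_labels):
        spec = small_phantom_spec(rigid_offset=(0.0, 0.0, 0.0))
        hi = lge_frame_labels(small_labels, spec)
        # voxel-center coordinates: (index + 1/2) * voxel size
        c_hi = (np.array(np.nonzero(hi.labels > 0)).mean(axis=1) + 0.5) \
            * hi.voxel_dims
        c_lo = (np.array(np.nonzero(small_labels.labels > 0)).mean(axis=1) + 0.5) \
            * small_labels.voxel_dims
        assert np.allclose(c_hi, c_lo, atol=0.1)


def test_phantom_determinism(small_spec, scheme):
    from dtbz.phantom import simulate_heart
    a = simulate_heart(small_spec, scheme)
    b = simulate_heart(small_spec, scheme)
    assert np.array_equal(a.dwi.dwi, b.dwi.dwi)
    assert np.array_equal(a.lge.si, b.lge.si)
    assert np.array_equal(a.labels_gt.labels, b.labels_gt.labels)
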