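"""Distortion physics primitives: field conversion, pushforward, unwarp,
smoothing and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from rpgdwi import (
    AP,
    PA,
    DisplacementField,
    FieldMap,
    Volume,
    displacement_from_fieldmap,
    forward_distort,
    gaussian_smooth,
    resample_linear,
    unwarp_apply,
)
from rpgdwi.core import GridError


def _const_field(vol: Volume, mm: float) -> DisplacementField:
    return DisplacementField(np.full(vol.shape, mm), vol.spacing, vol.pe_axis, vol.slice_axis)


class TestVolumeInvariants:
    def test_rejects_bad_spacing(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), (1.0, 0.0, 1.0))

    def test_rejects_equal_axes(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), (1, 1, 1), pe_axis=2, slice_axis=2)

    def test_rejects_nonfinite(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume(data, (1, 1, 1))


class TestDisplacementFromFieldmap:
    @pytest.mark.parametrize(
        "df_hz, bw, spacing, expected_mm",
        [
            (0.0, 17.5, 3.4, 0.0),
            (17.5, 17.5, 3.4, 3.4),  # one pixel-bandwidth = one pixel
            (35.0, 17.5, 3.4, 6.8),
        ],
    )
    def test_scaling(self, df_hz, bw, spacing, expected_mm):
        fm = FieldMap(np.full((4, 5, 3), df_hz), (spacing, spacing, 6.0))
        d = displacement_from_fieldmap(fm, bw)
        assert np.allclose(d.d, expected_mm)

    def test_nonpositive_bandwidth_rejected(self):
        fm = FieldMap(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError):
            displacement_from_fieldmap(fm, 0.0)

    def test_linearity(self, rng):
        df = rng.normal(size=(6, 6, 4)) * 30
        fm1 = FieldMap(df, (2, 2, 4))
        fm2 = FieldMap(2.5 * df, (2, 2, 4))
        d1 = displacement_from_fieldmap(fm1, 20.0)
        d2 = displacement_from_fieldmap(fm2, 20.0)
        assert np.allclose(d2.d, 2.5 * d1.d)


class TestForwardDistort:
    def test_zero_field_is_identity(self, small_volume):
        out = forward_distort(small_volume, _const_field(small_volume, 0.0), AP)
        assert np.allclose(out.data, small_volume.data)

    def test_constant_field_is_shift(self, small_volume):
        # 2 voxels along the PE axis (spacing 2 mm -> 4 mm)
        out = forward_distort(small_volume, _const_field(small_volume, 4.0), AP)
        assert np.allclose(out.data[:, 2:, :], small_volume.data[:, :-2, :])
        assert np.allclose(out.data[:, :2, :], 0.0)

    def test_compression_conserves_mass(self):
        """Linear compression of a uniform block: receivers collect all mass.

        Oracle: brute-force redistribution of each source voxel's intensity
        to its two nearest targets.
        """
        n = 32
        vol = Volume(np.zeros((1, n, 1)), (1, 1, 1), pe_axis=1, slice_axis=2)
        vol.data[0, 10:20, 0] = 1.0
        # displacement compressing [10, 20) linearly into 5 voxels
        d = np.zeros((1, n, 1))
        src = np.arange(10, 20)
        d[0, src, 0] = (15 + 0.5 * (src - 10)) - src
        fld = DisplacementField(d, (1, 1, 1), 1, 2)
        out = forward_distort(vol, fld, AP)

        oracle = np.zeros(n)
        for i in src:
            t = i + d[0, i, 0]
            i0 = int(np.floor(t))
            w = t - i0
            oracle[i0] += 1 - w
            if i0 + 1 < n:
                oracle[i0 + 1] += w
        assert np.allclose(out.data[0, :, 0], oracle)
        assert np.isclose(out.data.sum(), 10.0)

    def test_grid_mismatch_raises(self, small_volume):
        bad = DisplacementField(np.zeros((4, 4, 4)), small_volume.spacing)
        with pytest.raises(GridError):
            forward_distort(small_volume, bad, AP)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_mass_conservation_and_opposition(self, seed):
        """Per-PE-line mass is conserved for in-grid fields, and
        AP with d equals PA with -d voxel-for-voxel."""
        rng = np.random.default_rng(seed)
        vol = Volume(rng.random((4, 24, 3)) + 0.1, (2, 2, 4))
        d = ndimage.gaussian_filter(rng.normal(size=vol.shape), 3) * 20
        # keep all signal in-grid
        idx = np.arange(24)[None, :, None]
        d = np.clip(d, (1 - idx) * 2.0, (22 - idx) * 2.0)
        fld = DisplacementField(d, vol.spacing)
        ap = forward_distort(vol, fld, AP)
        line_in = vol.data.sum(axis=1)
        line_out = ap.data.sum(axis=1)
        assert np.allclose(line_in, line_out, rtol=1e-6)
        pa = forward_distort(vol, DisplacementField(-d, vol.spacing), PA)
        assert np.array_equal(ap.data, pa.data)

    def test_lost_fraction_reported(self, small_volume):
        out, lost = forward_distort(
            small_volume, _const_field(small_volume, 100.0), AP, return_lost_fraction=True
        )
        assert lost == pytest.approx(1.0)
        assert np.allclose(out.data, 0.0)


class TestUnwarpApply:
    def test_zero_field_identity(self, small_volume):
        out = unwarp_apply(small_volume, _const_field(small_volume, 0.0), AP)
        assert np.allclose(out.data, small_volume.data)

    def test_constant_field_pure_backshift(self, small_volume):
        # constant d: Jacobian is 1, pure translation by -2 voxels
        out = unwarp_apply(small_volume, _const_field(small_volume, 4.0), AP)
        assert np.allclose(out.data[:, :-2, :], small_volume.data[:, 2:, :], atol=1e-12)

    def test_round_trip_recovers_smooth_volume(self, rng):
        """Distort-then-unwarp is near-identity for smooth images and
        |d| <= 6 voxels, and reduces the error >= 10x vs no correction."""
        data = ndimage.gaussian_filter(rng.random((24, 48, 8)), 8)
        data = 1000 * (data - data.min()) / (data.max() - data.min())
        vol = Volume(data, (2.0, 2.0, 4.0))
        yy = np.arange(48) / 48.0
        d = 6.0 * 2.0 * np.exp(-0.5 * ((yy - 0.5) / 0.15) ** 2)  # mm; max 6 voxels
        fld = DisplacementField(np.broadcast_to(d[None, :, None], vol.shape).copy(), vol.spacing)
        distorted = forward_distort(vol, fld, AP)
        restored = unwarp_apply(distorted, fld, AP)
        interior = (slice(None), slice(4, 44), slice(None))
        rms_corr = np.sqrt(np.mean((restored.data[interior] - vol.data[interior]) ** 2))
        rms_raw = np.sqrt(np.mean((distorted.data[interior] - vol.data[interior]) ** 2))
        assert rms_corr < 0.02 * vol.data.max()
        assert rms_corr < 0.1 * rms_raw

    def test_jacobian_floor_no_negative_signal(self):
        vol = Volume(np.ones((1, 20, 1)), (1, 1, 1))
        # fold-over: steep decreasing displacement
        d = -np.arange(20.0) * 2
        fld = DisplacementField(d[None, :, None].copy(), vol.spacing)
        out = unwarp_apply(vol, fld, AP)
        assert np.all(out.data >= 0)


class TestGaussianSmooth:
    def test_zero_fwhm_identity(self, small_volume):
        assert np.array_equal(gaussian_smooth(small_volume, 0.0).data, small_volume.data)

    def test_constant_unchanged_and_mean_preserved(self, small_volume):
        const = small_volume.with_data(np.full(small_volume.shape, 7.0))
        assert np.allclose(gaussian_smooth(const, 12.0).data, 7.0)
        sm = gaussian_smooth(small_volume, 9.0)
        assert sm.data.mean() == pytest.approx(small_volume.data.mean(), rel=1e-6)

    def test_negative_fwhm_rejected(self, small_volume):
        with pytest.raises(ValueError):
            gaussian_smooth(small_volume, -1.0)

    def test_impulse_matches_sampled_kernel(self):
        """Impulse response equals the closed-form sampled Gaussian kernel."""
        vol = Volume(np.zeros((41, 41, 1)), (2.0, 4.0, 6.0), pe_axis=1, slice_axis=2)
        vol.data[20, 20, 0] = 1.0
        fwhm = 16.0
        out = gaussian_smooth(vol, fwhm).data[:, :, 0]
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.arange(41) - 20.0
        kx = np.exp(-0.5 * (x * 2.0 / sig) ** 2)
        ky = np.exp(-0.5 * (x * 4.0 / sig) ** 2)
        expected = np.outer(kx / kx.sum(), ky / ky.sum())
        assert np.allclose(out, expected, atol=1e-7)


class TestResampleLinear:
    def test_identity_grid(self, small_volume):
        out = resample_linear(small_volume, small_volume.shape, small_volume.spacing)
        assert np.allclose(out.data, small_volume.data)

    def test_downsampled_ramp_exact(self):
        # linear functions are reproduced exactly by linear interpolation
        x = np.arange(16, dtype=float)
        vol = Volume(np.broadcast_to(x[:, None, None], (16, 4, 4)).copy(), (1.0, 1.0, 1.0))
        out = resample_linear(vol, (8, 4, 4), (2.0, 1.0, 1.0))
        assert np.allclose(out.data[:, 0, 0], np.arange(8) * 2.0)

    def test_pointwise_against_direct_interpolation(self, rng):
        """Upsampling point-checked against an independent per-point
        trilinear interpolation oracle."""
        src = Volume(rng.random((8, 8, 8)), (2.0, 2.0, 2.0))
        out = resample_linear(src, (15, 15, 15), (1.0, 1.0, 1.0))
        for _ in range(10):
            tgt = tuple(rng.integers(0, 15, 3))
            # physical position -> source voxel coordinate
            pos = [t * 1.0 / 2.0 for t in tgt]
            i = [min(int(np.floor(p)), 6) for p in pos]
            f = [p - ii for p, ii in zip(pos, i)]
            val = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (
                            (f[0] if dx else 1 - f[0])
                            * (f[1] if dy else 1 - f[1])
                            * (f[2] if dz else 1 - f[2])
                        )
                        val += w * src.data[i[0] + dx, i[1] + dy, i[2] + dz]
            assert out.data[tgt] == pytest.approx(val, abs=1e-12)
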