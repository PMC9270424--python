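"""Grids and EPI distortion primitives.

Susceptibility-induced off-resonance displaces signal along the low-bandwidth
phase-encode (PE) axis of an EPI acquisition.  Two acquisitions with opposite
PE gradient polarity (AP / PA) exhibit exactly opposite displacements, which
is what reverse-polarity-gradient correction exploits.  This module provides
the shared volume/grid containers, the conservative forward distortion
operator (which creates signal pile-up), its Jacobian-modulated inverse, and
smoothing/resampling helpers used by the rest of the package.

Conventions
-----------
* Voxel indices are 0-based and voxel-centered; the physical coordinate of
  index ``i`` along an axis is ``i * spacing``.
* Displacement fields are stored in millimetres along the PE axis and are
  functions of the *undistorted* position: signal at true position ``x`` is
  observed at ``x + sign * d(x)`` where ``sign`` is +1 for AP and -1 for PA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "Polarity",
    "AP",
    "PA",
    "DisplacementField",
    "FieldMap",
    "GridError",
    "displacement_from_fieldmap",
    "forward_distort",
    "unwarp_apply",
    "gaussian_smooth",
    "resample_linear",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GridError(ValueError):
    """Raised when two objects that must share a grid do not."""


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, all strictly positive.
    pe_axis:
        Index of the phase-encode axis (where susceptibility displacement
        acts).
    slice_axis:
        Index of the through-plane axis (stations are stacked along it).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    pe_axis: int = 1
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.pe_axis == self.slice_axis:
            raise ValueError("pe_axis and slice_axis must differ")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this grid with different voxel values."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def same_grid(self, other: "Volume | DisplacementField | FieldMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and self.pe_axis == getattr(other, "pe_axis", self.pe_axis)
        )


@dataclass(frozen=True)
class Polarity:
    """Phase-encode gradient polarity: +1 for AP, -1 for PA."""

    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"Polarity sign must be +1 or -1, got {self.sign}")

    @property
    def name(self) -> str:
        return "AP" if self.sign == +1 else "PA"

    @classmethod
    def from_name(cls, name: str) -> "Polarity":
        try:
            return {"AP": AP, "PA": PA}[name.upper()]
        except KeyError:
            raise ValueError(f"Unknown polarity {name!r}; expected 'AP' or 'PA'") from None


AP = Polarity(+1)
PA = Polarity(-1)


@dataclass
class DisplacementField:
    """Voxel-wise displacement along the PE axis, in mm."""

    d: np.ndarray
    spacing: tuple[float, float, float]
    pe_axis: int = 1
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 3:
            raise ValueError("DisplacementField must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("DisplacementField contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.d.shape

    def in_voxels(self) -> np.ndarray:
        """Displacement expressed in PE-axis voxel units."""
        return self.d / self.spacing[self.pe_axis]

    def __neg__(self) -> "DisplacementField":
        return replace(self, d=-self.d)


@dataclass
class FieldMap:
    """Off-resonance map in Hz on a Volume grid."""

    df: np.ndarray
    spacing: tuple[float, float, float]
    pe_axis: int = 1
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.df = np.asarray(self.df, dtype=np.float64)
        if not np.all(np.isfinite(self.df)):
            raise ValueError("FieldMap contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.df.shape


def _check_grid(v: Volume, d: DisplacementField) -> None:
    if v.shape != d.shape:
        raise GridError(f"shape mismatch: volume {v.shape} vs field {d.shape}")
    if not np.allclose(v.spacing, d.spacing) or v.pe_axis != d.pe_axis:
        raise GridError("volume and displacement field grids differ")


def displacement_from_fieldmap(
    fm: FieldMap, pe_bandwidth_per_pixel: float, pe_spacing: float | None = None
) -> DisplacementField:
    """Convert off-resonance (Hz) to PE-axis displacement (mm).

    An off-resonance of one pixel-bandwidth shifts signal by exactly one
    PE pixel, so ``d_mm = df / bw_pp * pe_spacing``.  Linear in ``df``.
    """
    if pe_bandwidth_per_pixel <= 0:
        raise ValueError(f"pe_bandwidth_per_pixel must be > 0, got {pe_bandwidth_per_pixel}")
    if pe_spacing is None:
        pe_spacing = fm.spacing[fm.pe_axis]
    d = fm.df / pe_bandwidth_per_pixel * pe_spacing
    return DisplacementField(d, fm.spacing, fm.pe_axis, fm.slice_axis)


def forward_distort(
    v: Volume, d: DisplacementField, pol: Polarity, *, return_lost_fraction: bool = False
):
    """Apply EPI susceptibility distortion: conservative 1-D pushforward.

    Signal at true position ``x`` is deposited at ``x + pol.sign * d(x)``
    along the PE axis, split between the two nearest voxels by linear
    (cloud-in-cell) weights.  Intensity from compressed regions accumulates
    (signal pile-up); per-PE-line total signal is conserved up to signal
    pushed outside the grid, which is dropped.
    """
    _check_grid(v, d)
    pe = v.pe_axis
    data = np.moveaxis(v.data, pe, -1)
    dvox = np.moveaxis(d.in_voxels(), pe, -1)
    n = data.shape[-1]
    flat = data.reshape(-1, n)
    tgt = np.arange(n, dtype=np.float64) + pol.sign * dvox.reshape(-1, n)

    i0 = np.floor(tgt).astype(np.intp)
    w1 = tgt - i0  # weight for i0 + 1
    w0 = 1.0 - w1

    out = np.zeros_like(flat)
    rows = np.broadcast_to(np.arange(flat.shape[0], dtype=np.intp)[:, None], flat.shape)
    lost = 0.0
    for idx, w in ((i0, w0), (i0 + 1, w1)):
        ok = (idx >= 0) & (idx < n)
        np.add.at(out, (rows[ok], idx[ok]), flat[ok] * w[ok])
        lost += float(np.sum(flat[~ok] * w[~ok]))

    result = v.with_data(np.moveaxis(out.reshape(data.shape), -1, pe))
    if return_lost_fraction:
        total = float(np.sum(np.abs(v.data)))
        return result, (lost / total if total > 0 else 0.0)
    return result


def _sample_pe(arr_pe_last: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``arr`` along its last axis at positions
    ``pos`` (same shape), clamping to the edges."""
    n = arr_pe_last.shape[-1]
    pc = np.clip(pos, 0.0, n - 1.0)
    i0 = np.minimum(np.floor(pc).astype(np.intp), n - 2)
    w = pc - i0
    a0 = np.take_along_axis(arr_pe_last, i0, axis=-1)
    a1 = np.take_along_axis(arr_pe_last, i0 + 1, axis=-1)
    return a0 * (1.0 - w) + a1 * w


def unwarp_apply(v_distorted: Volume, d: DisplacementField, pol: Polarity) -> Volume:
    """Undo EPI distortion with Jacobian intensity modulation.

    ``corrected(x) = v_distorted(x + pol.sign * d(x)) * J(x)`` with
    ``J = 1 + pol.sign * ddvox/dx_pe`` (central differences in the interior,
    one-sided at the boundary), floored at 0 so fold-over yields no signal
    rather than negative signal.  The Jacobian factor compensates the signal
    pile-up that the forward pushforward creates in compressed regions.
    """
    _check_grid(v_distorted, d)
    pe = v_distorted.pe_axis
    data = np.moveaxis(v_distorted.data, pe, -1)
    dvox = np.moveaxis(d.in_voxels(), pe, -1)
    n = data.shape[-1]
    pos = np.arange(n, dtype=np.float64) + pol.sign * dvox
    sampled = _sample_pe(data, pos)
    jac = 1.0 + pol.sign * np.gradient(dvox, axis=-1)
    out = sampled * np.maximum(jac, 0.0)
    return v_distorted.with_data(np.moveaxis(out, -1, pe))


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with an isotropic FWHM in mm.

    Per-axis sigma (in voxels) is ``fwhm / (2*sqrt(2*ln 2)) / spacing``.
    Reflective boundaries preserve the mean intensity; ``fwhm_mm = 0``
    returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return v.with_data(v.data)
    sigma = [fwhm_mm * FWHM_TO_SIGMA / s for s in v.spacing]
    return v.with_data(
        ndimage.gaussian_filter(v.data, sigma=sigma, mode="reflect", truncate=6.0)
    )


def resample_linear(
    v: Volume,
    target_shape: Sequence[int],
    target_spacing: Sequence[float],
) -> Volume:
    """Trilinear resampling onto a new voxel-centered grid.

    Target index ``j`` maps to physical coordinate ``j * target_spacing``
    and is sampled in the source at ``phys / source_spacing``; coordinates
    outside the source extent take nearest-edge values.
    """
    target_shape = tuple(int(s) for s in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_shape) or any(s <= 0 for s in target_spacing):
        raise ValueError("target shape and spacing must be positive")
    coords = np.meshgrid(
        *[
            np.arange(ns) * ts / ss
            for ns, ts, ss in zip(target_shape, target_spacing, v.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    return Volume(out, target_spacing, v.pe_axis, v.slice_axis)
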