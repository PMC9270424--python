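"""ADC fitting, multi-station assembly and inter-station intensity matching.

The quantitative endpoint of whole-body DWI is the apparent diffusion
coefficient (ADC) map: per voxel, ``ln S(b)`` is regressed on ``b`` by
ordinary least squares and the negative slope is the ADC.  Stations are
assembled into a single whole-body volume by removing overlapping slices
(an equal number from each adjacent station, no intensity blending) and, for
visualisation, inter-station intensity differences can be harmonised by
histogram matching of the overlapping slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Volume

__all__ = [
    "ADCFitResult",
    "WholeBody",
    "fit_adc",
    "assemble_stations",
    "match_station_intensity",
]

DEFAULT_FIT_BS = (50.0, 400.0, 900.0)


@dataclass
class ADCFitResult:
    """Voxel-wise mono-exponential fit: ADC (1e-3 mm^2/s), fitted S0 and a
    validity mask (True where all requested b-value signals were > 0)."""

    adc: Volume
    s0_fit: Volume
    valid: np.ndarray


@dataclass
class WholeBody:
    """Single volume spanning all stations after overlap removal."""

    volume: Volume
    station_boundaries: tuple[int, ...]  # global slice indices of the seams

    def __post_init__(self) -> None:
        if list(self.station_boundaries) != sorted(set(self.station_boundaries)):
            raise ValueError("station boundaries must be strictly increasing")


def fit_adc(volumes: dict[float, Volume], fit_bs: Sequence[float] = DEFAULT_FIT_BS) -> ADCFitResult:
    """Mono-exponential log-linear least-squares ADC fit.

    Per voxel, OLS of ``ln S(b)`` on ``b`` over ``fit_bs`` gives
    ``slope = -ADC * 1e-3`` and ``intercept = ln S0``.  Voxels with any
    non-positive signal among the fitted b-values are marked invalid and
    assigned ADC = 0; negative ADC on valid voxels is reported as-is
    (perfusion or noise can produce it), never clamped.
    """
    fit_bs = [float(b) for b in fit_bs]
    if len(fit_bs) < 2:
        raise ValueError("need at least 2 b-values to fit ADC")
    missing = [b for b in fit_bs if b not in volumes]
    if missing:
        raise ValueError(f"b-values {missing} not present in the series")
    ref = volumes[fit_bs[0]]
    stack = np.stack([volumes[b].data for b in fit_bs], axis=0)
    valid = np.all(stack > 0, axis=0)
    logs = np.log(np.where(stack > 0, stack, 1.0))

    b = np.asarray(fit_bs)
    bc = b - b.mean()
    denom = float(np.sum(bc * bc))
    slope = np.tensordot(bc, logs, axes=(0, 0)) / denom
    intercept = logs.mean(axis=0) - slope * b.mean()

    adc = np.where(valid, -slope * 1e3, 0.0)
    s0 = np.where(valid, np.exp(intercept), 0.0)
    return ADCFitResult(adc=ref.with_data(adc), s0_fit=ref.with_data(s0), valid=valid)


def _overlap_removal(n_overlap: int) -> tuple[int, int]:
    """Slices to drop at a seam: (trailing from superior, leading from
    inferior).  Odd overlaps drop the extra slice from the superior station."""
    return (int(np.ceil(n_overlap / 2)), int(np.floor(n_overlap / 2)))


def assemble_stations(stations: Sequence[Volume], n_overlap: int) -> WholeBody:
    """Concatenate stations into one whole-body volume, removing overlaps.

    For each adjacent pair, ``ceil(n_overlap/2)`` trailing slices are removed
    from the superior (earlier) station and ``floor(n_overlap/2)`` leading
    slices from the inferior one; pure slice selection, no intensity
    modification.  Seam positions are recorded as global slice indices.
    """
    if n_overlap < 0:
        raise ValueError("n_overlap must be >= 0")
    if not stations:
        raise ValueError("no stations to assemble")
    drop_sup, drop_inf = _overlap_removal(n_overlap)
    first = stations[0]
    ax = first.slice_axis
    inplane = tuple(s for i, s in enumerate(first.shape) if i != ax)
    parts: list[np.ndarray] = []
    seams: list[int] = []
    total = 0
    for k, st in enumerate(stations):
        if tuple(s for i, s in enumerate(st.shape) if i != ax) != inplane:
            raise ValueError(f"station {k} in-plane grid differs")
        lo = drop_inf if k > 0 else 0
        hi = st.shape[ax] - (drop_sup if k < len(stations) - 1 else 0)
        if hi <= lo:
            raise ValueError(f"overlap {n_overlap} exceeds station {k}'s slices")
        sl = [slice(None)] * 3
        sl[ax] = slice(lo, hi)
        parts.append(st.data[tuple(sl)])
        total += hi - lo
        if k < len(stations) - 1:
            seams.append(total)
    data = np.concatenate(parts, axis=ax)
    return WholeBody(
        volume=Volume(data, first.spacing, first.pe_axis, first.slice_axis),
        station_boundaries=tuple(seams),
    )


def _overlap_slices(v: Volume, n_overlap: int, which: str) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[v.slice_axis] = slice(-n_overlap, None) if which == "trailing" else slice(0, n_overlap)
    return v.data[tuple(sl)]


def _quantile_map(src: np.ndarray, ref: np.ndarray, n_knots: int = 256) -> tuple[np.ndarray, np.ndarray]:
    qs = np.linspace(0.0, 1.0, n_knots)
    return np.quantile(src, qs), np.quantile(ref, qs)


def match_station_intensity(
    stations: Sequence[Volume], n_overlap: int, n_knots: int = 256
) -> list[Volume]:
    """Harmonise inter-station intensity by histogram matching of overlaps.

    Processing superior to inferior: station 1 is unchanged; for every later
    station the empirical CDF of its leading overlap slices is mapped onto
    the CDF of the previous (already matched) station's trailing overlap
    slices, and the resulting monotone mapping — linear interpolation between
    ``n_knots`` empirical quantiles — is applied to all of the station's
    voxels.  Intended for visualisation; quantitative maps are assembled
    without blending.
    """
    if n_overlap < 1:
        raise ValueError("histogram matching requires n_overlap >= 1")
    if len(stations) < 2:
        raise ValueError("need at least 2 stations to match")
    out = [stations[0].with_data(stations[0].data)]
    for k in range(1, len(stations)):
        ref = _overlap_slices(out[k - 1], n_overlap, "trailing")
        src = _overlap_slices(stations[k], n_overlap, "leading")
        xq, yq = _quantile_map(src.ravel(), ref.ravel(), n_knots)
        # np.interp requires strictly usable xp; collapse duplicate knots
        xq, uniq = np.unique(xq, return_index=True)
        yq = yq[uniq]
        if xq.size == 1:  # constant overlap: map everything to the ref value
            mapped = np.full_like(stations[k].data, yq[0])
        else:
            mapped = np.interp(stations[k].data, xq, yq)
        out.append(stations[k].with_data(mapped))
    return out
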