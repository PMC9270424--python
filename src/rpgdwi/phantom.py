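"""Synthetic multi-station whole-body DWI phantom with known ground truth.

Emulates the statistical and geometric structure a reverse-polarity-gradient
correction pipeline assumes: station-wise EPI acquisitions at several
b-values in both AP and PA polarity, susceptibility displacement confined to
the phase-encode axis with exactly opposite sign between polarities, signal
pile-up, per-station central-frequency offsets, inter-station intensity
scale differences, overlapping slices between adjacent stations, Rician
noise, and a distortion-free structural reference with tissue S0/ADC ground
truth and embedded lesion masks.

The forward model is geometric only: no k-space simulation, no eddy-current
distortion, no motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AP,
    PA,
    DisplacementField,
    FieldMap,
    Polarity,
    Volume,
    displacement_from_fieldmap,
    forward_distort,
    resample_linear,
)

__all__ = [
    "TissueSpec",
    "DEFAULT_TISSUES",
    "ProtocolConfig",
    "PhantomTruth",
    "StationSeries",
    "make_phantom",
    "simulate_signal",
    "simulate_acquisition",
    "structural_reference",
    "embed_lesion",
    "add_rician_noise",
]


@dataclass(frozen=True)
class TissueSpec:
    """Baseline signal (a.u.) and ADC (1e-3 mm^2/s) of one tissue class."""

    name: str
    s0: float
    adc: float


# Organ contrasts loosely follow healthy-tissue diffusion values: high-ADC
# fluid (bladder), intermediate parenchyma (kidney, liver, spleen, muscle),
# low-ADC bone/spine.  Fat suppression is not modelled; "fat" simply gets
# low s0.
DEFAULT_TISSUES: tuple[TissueSpec, ...] = (
    TissueSpec("liver", 550.0, 1.05),
    TissueSpec("spleen", 680.0, 0.85),
    TissueSpec("kidney", 820.0, 1.80),
    TissueSpec("psoas_muscle", 460.0, 1.40),
    TissueSpec("vertebral_disk", 700.0, 1.60),
    TissueSpec("urinary_bladder", 1000.0, 3.00),
    TissueSpec("pelvic_bone", 320.0, 0.45),
)

BODY_TISSUE = TissueSpec("soft_tissue", 600.0, 1.20)
SPINE_TISSUE = TissueSpec("spine", 420.0, 0.55)


@dataclass
class ProtocolConfig:
    """Acquisition geometry and noise of the simulated protocol.

    Defaults mirror a clinical whole-body protocol: axial stations of 6 mm
    slices, in-plane spacing ~3.4 mm (440 mm FOV / 128 matrix), b-values
    0/50/400/900 s/mm^2 with NSA 2/2/4/9, AP phase encoding along axis 1.
    The PE pixel bandwidth is a free model parameter (20 Hz/px) that sets
    the Hz-to-mm displacement scale.
    """

    n_stations: int = 5
    slices_per_station: int = 20
    n_overlap: int = 4
    matrix: tuple[int, int] = (96, 96)
    spacing: tuple[float, float, float] = (3.4, 3.4, 6.0)
    b_values: tuple[float, ...] = (0.0, 50.0, 400.0, 900.0)
    nsa_per_b: tuple[int, ...] = (2, 2, 4, 9)
    pe_bandwidth_per_pixel: float = 20.0
    noise_sigma: float = 20.0
    station_offset_max_hz: float = 4.0
    station_scale_jitter: float = 0.08
    field_bump_amplitudes_hz: tuple[float, ...] = (120.0, -90.0)
    rng_seed: int = 0
    pe_axis: int = 1
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if self.n_overlap >= self.slices_per_station:
            raise ValueError("n_overlap must be smaller than slices_per_station")
        bs = tuple(float(b) for b in self.b_values)
        if any(b < 0 for b in bs) or any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("b_values must be non-negative and strictly increasing")
        self.b_values = bs
        if len(self.nsa_per_b) != len(self.b_values):
            raise ValueError("nsa_per_b must match b_values")

    @property
    def n_slices_total(self) -> int:
        step = self.slices_per_station - self.n_overlap
        return step * (self.n_stations - 1) + self.slices_per_station

    @property
    def global_shape(self) -> tuple[int, int, int]:
        return (*self.matrix, self.n_slices_total)

    def slice_range(self, station: int) -> tuple[int, int]:
        """Half-open global slice interval covered by one station."""
        start = station * (self.slices_per_station - self.n_overlap)
        return (start, start + self.slices_per_station)

    def nsa(self, b: float) -> int:
        return self.nsa_per_b[self.b_values.index(float(b))]


@dataclass
class PhantomTruth:
    """Ground truth of the digital phantom, the oracle for all evaluations."""

    labels: np.ndarray
    label_names: dict[int, str]
    s0: np.ndarray
    adc: np.ndarray
    fieldmap: FieldMap
    spacing: tuple[float, float, float]
    station_offsets: np.ndarray  # Hz, one per station
    station_scales: np.ndarray
    cfg: ProtocolConfig
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.adc < 0) or np.any(self.s0 < 0):
            raise ValueError("phantom truth requires adc >= 0 and s0 >= 0")

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    def true_displacement(self, station: int | None = None) -> DisplacementField:
        """Ground-truth displacement (mm) on the global grid; adding one
        station's central-frequency offset if requested."""
        df = self.fieldmap.df
        if station is not None:
            df = df + self.station_offsets[station]
        fm = FieldMap(df, self.spacing, self.fieldmap.pe_axis, self.fieldmap.slice_axis)
        return displacement_from_fieldmap(fm, self.cfg.pe_bandwidth_per_pixel)

    def crop(self, arr: np.ndarray, station: int) -> np.ndarray:
        lo, hi = self.cfg.slice_range(station)
        sl = [slice(None)] * 3
        sl[self.cfg.slice_axis] = slice(lo, hi)
        return arr[tuple(sl)]


@dataclass
class StationSeries:
    """All b-value volumes of one station for one polarity."""

    station_index: int
    polarity: Polarity
    volumes: dict[float, Volume]
    slice_range: tuple[int, int]
    field: DisplacementField | None = None  # set by correction
    cost_trace: list | None = None  # per-level optimizer costs, set by correction

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise ValueError("all volumes of a station must share one grid")

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(sorted(self.volumes))


def _ellipsoid_mask(shape, spacing, centre_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre_mm, radii_mm))
    return q <= 1.0


def make_phantom(cfg: ProtocolConfig | None = None, seed: int | None = None) -> PhantomTruth:
    """Build the digital whole-body phantom.

    An elliptical body cylinder contains the organ set of ``DEFAULT_TISSUES``
    as seeded ellipsoids, plus a posterior spine column spanning all
    stations.  The off-resonance field is a smooth low-order background plus
    Gaussian bumps at two air-cavity interfaces (neck, abdomen) and
    per-station constant central-frequency offsets.  Deterministic given the
    seed.
    """
    cfg = cfg or ProtocolConfig()
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng(seed)
    shape = cfg.global_shape
    nx, ny, nz = shape
    sp = cfg.spacing

    # body: elliptical cylinder with a mild superior taper
    x = (np.arange(nx) - (nx - 1) / 2)[:, None, None]
    y = (np.arange(ny) - (ny - 1) / 2)[None, :, None]
    z = np.arange(nz)[None, None, :]
    rx = 0.42 * nx * (0.92 + 0.08 * np.cos(z / max(nz - 1, 1) * np.pi))
    ry = 0.34 * ny * (0.92 + 0.08 * np.cos(z / max(nz - 1, 1) * np.pi))
    body = (x / rx) ** 2 + (y / ry) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    names = {0: "background", 1: BODY_TISSUE.name}
    labels[body] = 1
    s0 = np.where(body, BODY_TISSUE.s0, 0.0)
    adc = np.where(body, BODY_TISSUE.adc, 0.0)

    # posterior spine column spanning all stations
    spine_centre = ((nx - 1) / 2 * sp[0], ((ny - 1) / 2 + 0.55 * 0.34 * ny) * sp[1])
    xg = np.arange(nx)[:, None] * sp[0]
    yg = np.arange(ny)[None, :] * sp[1]
    spine2d = (xg - spine_centre[0]) ** 2 + (yg - spine_centre[1]) ** 2 <= (1.6 * sp[0] * 3) ** 2
    spine = np.repeat(spine2d[:, :, None], nz, axis=2) & body
    labels[spine] = 2
    names[2] = SPINE_TISSUE.name
    s0[spine] = SPINE_TISSUE.s0
    adc[spine] = SPINE_TISSUE.adc

    # seeded ellipsoidal organs, fully inside the body
    extent = [n * s for n, s in zip(shape, sp)]
    for i, tissue in enumerate(DEFAULT_TISSUES):
        for attempt in range(40):
            radii = rng.uniform(
                [3.0 * sp[0], 3.0 * sp[1], 1.2 * sp[2]],
                [7.0 * sp[0], 7.0 * sp[1], 2.5 * sp[2]],
            )
            centre = rng.uniform(
                [0.25 * extent[0], 0.25 * extent[1], 0.10 * extent[2]],
                [0.75 * extent[0], 0.70 * extent[1], 0.90 * extent[2]],
            )
            mask = _ellipsoid_mask(shape, sp, centre, radii)
            if mask.any() and bool(np.all(body[mask])) and not np.any(spine[mask]):
                break
        else:
            raise RuntimeError(f"could not place organ {tissue.name} inside the body")
        lab = 3 + i
        labels[mask] = lab
        names[lab] = tissue.name
        s0[mask] = tissue.s0
        adc[mask] = tissue.adc

    # off-resonance: low-order background + air-cavity bumps
    xn = np.broadcast_to(x / (nx / 2), shape)
    yn = np.broadcast_to(y / (ny / 2), shape)
    zn = np.broadcast_to((z - nz / 2) / (nz / 2), shape)
    c = rng.uniform(-0.8, 0.8, size=4)
    df = c[0] * xn + c[1] * yn + c[2] * zn + c[3] * xn * yn

    bump_centres_frac = ((0.5, 0.32, 0.80), (0.5, 0.38, 0.45))  # neck, abdomen (anterior)
    for amp, cf in zip(cfg.field_bump_amplitudes_hz, bump_centres_frac):
        centre = [f * e for f, e in zip(cf, extent)]
        sig = (28.0, 24.0, 36.0)  # mm
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
        r2 = sum(((g - c0) / s1) ** 2 for g, c0, s1 in zip(grids, centre, sig))
        df = df + amp * np.exp(-0.5 * r2)

    offsets = rng.uniform(-cfg.station_offset_max_hz, cfg.station_offset_max_hz, cfg.n_stations)
    scales = 1.0 + rng.uniform(-cfg.station_scale_jitter, cfg.station_scale_jitter, cfg.n_stations)

    return PhantomTruth(
        labels=labels,
        label_names=names,
        s0=s0,
        adc=adc,
        fieldmap=FieldMap(df, sp, cfg.pe_axis, cfg.slice_axis),
        spacing=sp,
        station_offsets=offsets,
        station_scales=scales,
        cfg=cfg,
    )


def simulate_signal(truth: PhantomTruth, b: float) -> Volume:
    """Noiseless mono-exponential DWI signal S0 * exp(-b * ADC * 1e-3).

    ADC is in 1e-3 mm^2/s and b in s/mm^2.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    data = truth.s0 * np.exp(-b * truth.adc * 1e-3)
    return Volume(data, truth.spacing, truth.cfg.pe_axis, truth.cfg.slice_axis)


def add_rician_noise(data: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise (Rician)."""
    if sigma <= 0:
        return data.copy()
    re = data + rng.normal(0.0, sigma, data.shape)
    im = rng.normal(0.0, sigma, data.shape)
    return np.hypot(re, im)


def simulate_acquisition(
    truth: PhantomTruth, cfg: ProtocolConfig | None = None, seed: int | None = None
) -> list[StationSeries]:
    """Simulate the station-wise AP/PA acquisition of all b-values.

    Per station: the truth maps are cropped to the station's slice range
    (adjacent stations share ``n_overlap`` slices); the displacement field is
    derived from the global field map plus the station's central-frequency
    offset; the AP volume is the forward pushforward of the signal, the PA
    volume uses the exactly opposite displacement; the station intensity
    scale is applied; Rician noise with sigma = noise_sigma / sqrt(NSA(b))
    is added.  Deterministic per seed.  Returns one StationSeries per
    (station, polarity), AP first.
    """
    cfg = cfg or truth.cfg
    if seed is None:
        seed = cfg.rng_seed
    root = np.random.SeedSequence(seed)
    series: list[StationSeries] = []
    for k in range(cfg.n_stations):
        lo, hi = cfg.slice_range(k)
        d_global = truth.true_displacement(station=k)
        d_station = DisplacementField(
            truth.crop(d_global.d, k), cfg.spacing, cfg.pe_axis, cfg.slice_axis
        )
        for pol in (AP, PA):
            vols: dict[float, Volume] = {}
            for bi, b in enumerate(cfg.b_values):
                sig = Volume(
                    truth.crop(simulate_signal(truth, b).data, k),
                    cfg.spacing,
                    cfg.pe_axis,
                    cfg.slice_axis,
                )
                distorted = forward_distort(sig, d_station, pol)
                scaled = distorted.data * truth.station_scales[k]
                sigma = cfg.noise_sigma / math.sqrt(cfg.nsa_per_b[bi])
                # independent, reproducible stream per (station, polarity, b)
                ss = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(k, 0 if pol is AP else 1, bi)
                )
                stream = np.random.default_rng(ss)
                noisy = add_rician_noise(scaled, sigma, stream)
                vols[b] = Volume(noisy, cfg.spacing, cfg.pe_axis, cfg.slice_axis)
            series.append(StationSeries(k, pol, vols, (lo, hi)))
    return series


def structural_reference(
    truth: PhantomTruth, upsample_inplane: float = 2.0
) -> Volume:
    """Distortion-free structural reference on a finer in-plane grid.

    The baseline-signal map (b=0 contrast) resampled to a higher in-plane
    resolution stands in for the anatomical reference scan acquired in the
    same session: geometric evaluation needs only an undistorted reference,
    not a realistic structural contrast.
    """
    base = simulate_signal(truth, 0.0)
    shape = list(base.shape)
    spacing = list(base.spacing)
    for ax in range(3):
        if ax != truth.cfg.slice_axis:
            shape[ax] = int(round(shape[ax] * upsample_inplane))
            spacing[ax] = spacing[ax] / upsample_inplane
    return resample_linear(base, shape, spacing)


def embed_lesion(
    truth: PhantomTruth,
    centre_mm: tuple[float, float, float],
    radius_mm: float,
    adc_value: float,
    s0_value: float,
    name: str | None = None,
) -> PhantomTruth:
    """Embed a spherical lesion, overwriting adc/s0 (last write wins).

    The lesion mask is appended to ``lesion_masks``; a radius of 0 leaves the
    truth maps unchanged and records an empty mask.  The centre must lie
    inside the body.
    """
    idx = tuple(int(round(c / s)) for c, s in zip(centre_mm, truth.spacing))
    if not all(0 <= i < n for i, n in zip(idx, truth.labels.shape)) or truth.labels[idx] == 0:
        raise ValueError(f"lesion centre {centre_mm} mm is outside the body")
    mask = (
        _ellipsoid_mask(truth.labels.shape, truth.spacing, centre_mm, (radius_mm,) * 3)
        if radius_mm > 0
        else np.zeros(truth.labels.shape, dtype=bool)
    )
    s0 = truth.s0.copy()
    adc = truth.adc.copy()
    s0[mask] = s0_value
    adc[mask] = adc_value
    masks = dict(truth.lesion_masks)
    masks[name or f"lesion{len(masks) + 1}"] = mask
    return PhantomTruth(
        labels=truth.labels,
        label_names=truth.label_names,
        s0=s0,
        adc=adc,
        fieldmap=truth.fieldmap,
        spacing=truth.spacing,
        station_offsets=truth.station_offsets,
        station_scales=truth.station_scales,
        cfg=truth.cfg,
        lesion_masks=masks,
    )
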