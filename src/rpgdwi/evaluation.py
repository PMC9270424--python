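"""Quantitative geometric-accuracy evaluation.

Measures how well distortion-corrected DWI aligns with an undistorted
structural reference: mutual information between low-b DWI and the (resampled)
structural image per station, overlap/distance metrics between lesion
segmentations and their ground-truth masks (Dice, Euclidean distance of
geometric centers, average Hausdorff distance), ADC agreement between
conditions, paired two-sided Wilcoxon signed-rank tests and Bland–Altman
statistics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm
from skimage.filters import threshold_otsu

from .core import Volume, resample_linear
from .phantom import PhantomTruth, StationSeries
from .pipeline import DEFAULT_FIT_BS, assemble_stations, fit_adc

__all__ = [
    "ROIMask",
    "EvalReport",
    "mutual_information",
    "dice",
    "centroid_distance",
    "average_hausdorff",
    "bland_altman",
    "wilcoxon_signed_rank",
    "segment_lesion",
    "evaluate_dataset",
]


@dataclass
class ROIMask:
    """A named binary region on a regular grid (spacing in mm)."""

    mask: np.ndarray
    label: str
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class EvalReport:
    """Flat record list of metric values plus paired-test results."""

    records: list[dict] = field(default_factory=list)
    test_results: list[dict] = field(default_factory=list)

    def add(self, condition: str, where: str, metric: str, value: float, units: str = "") -> None:
        self.records.append(
            {"condition": condition, "where": where, "metric": metric,
             "value": float(value), "units": units}
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def tests_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.test_results)

    def values(self, metric: str, condition: str | None = None) -> dict[str, float]:
        return {
            r["where"]: r["value"]
            for r in self.records
            if r["metric"] == metric and (condition is None or r["condition"] == condition)
        }


def mutual_information(a: Volume, b: Volume, n_bins: int = 64) -> float:
    """Mutual information (nats) from the joint intensity histogram.

    Equal-width bins span each image's [min, max] over voxels where both are
    finite; zero-count cells contribute nothing.  Always >= 0 (up to
    round-off); 0 with a warning if either image is constant.
    """
    if a.shape != b.shape:
        raise ValueError("mutual_information requires volumes on the same grid")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = a.data.ravel()
    y = b.data.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant image in mutual_information; returning 0")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _check_masks(a: ROIMask, b: ROIMask, allow_empty: bool = False) -> None:
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks must share a grid")
    if not allow_empty and (a.n_voxels == 0 or b.n_voxels == 0):
        raise ValueError("empty ROI mask")


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * float(np.sum(a.mask & b.mask)) / (na + nb)


def _centroid_mm(m: ROIMask) -> np.ndarray:
    coords = np.argwhere(m.mask)
    return coords.mean(axis=0) * np.asarray(m.spacing)


def centroid_distance(a: ROIMask, b: ROIMask) -> float:
    """Euclidean distance (mm) between unweighted voxel-centre centroids."""
    _check_masks(a, b)
    return float(np.linalg.norm(_centroid_mm(a) - _centroid_mm(b)))


def _surface_voxels_mm(m: ROIMask) -> np.ndarray:
    """Physical coordinates of voxels with >= 1 face-neighbour outside."""
    strel = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(m.mask, structure=strel, border_value=0)
    surface = m.mask & ~interior
    return np.argwhere(surface) * np.asarray(m.spacing)


def average_hausdorff(a: ROIMask, b: ROIMask) -> float:
    """Average (mean symmetric) surface distance in mm.

    Surfaces are the face-connectivity boundary voxels; AVD is the mean of
    the two directed average nearest-surface distances.
    """
    _check_masks(a, b)
    sa = _surface_voxels_mm(a)
    sb = _surface_voxels_mm(b)
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def bland_altman(x, y) -> dict:
    """Bland–Altman agreement statistics for paired measurements.

    diffs = x - y; bias = mean(diffs); limits of agreement are
    bias ± 1.96 * sd(diffs) with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "diffs": diffs,
    }


def wilcoxon_signed_rank(x, y=None) -> dict:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; absolute differences are mid-ranked (ties
    share the average rank); the statistic is W = min(W+, W-).  For n <= 12
    with no tied ranks the p-value is exact by enumerating all 2^n sign
    assignments; otherwise a normal approximation with tie-corrected
    variance and a 0.5 continuity correction is used.  If every difference
    is zero, p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; Wilcoxon p-value set to 1")
        return {"W": 0.0, "p_two_sided": 1.0, "n": 0}
    if n < 3:
        warnings.warn("fewer than 3 nonzero differences; Wilcoxon test is uninformative")

    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1, dtype=float)
    # mid-ranks for ties
    for v in np.unique(absd):
        tie = absd == v
        if tie.sum() > 1:
            ranks[tie] = ranks[tie].mean()

    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    has_ties = np.unique(absd).size < n

    if n <= 12 and not has_ties:
        # exact: distribution of W+ over all 2^n sign assignments
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            wp = float(np.sum(ranks * np.asarray(signs)))
            if min(wp, ranks.sum() - wp) <= W:
                count += 1
        p = count / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction: subtract sum(t^3 - t)/48 over tied groups
        for v in np.unique(absd):
            t = int(np.sum(absd == v))
            if t > 1:
                var -= (t**3 - t) / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (W - mean + 0.5) / np.sqrt(var)  # W <= mean by construction
            p = 2.0 * norm.cdf(z)
    return {"W": W, "p_two_sided": float(min(max(p, 0.0), 1.0)), "n": n}


def segment_lesion(image: Volume, truth_mask: np.ndarray, dilate: int = 4) -> ROIMask:
    """Threshold-based stand-in for manual lesion segmentation.

    Otsu's threshold is computed within a dilated neighbourhood of the
    ground-truth mask and the bright component inside that neighbourhood is
    returned.  On a distorted image the segmented lesion is displaced and
    deformed relative to the truth, mimicking what a reader would outline.
    """
    neigh = ndimage.binary_dilation(truth_mask, iterations=dilate)
    vals = image.data[neigh]
    if vals.size == 0 or np.ptp(vals) == 0:
        return ROIMask(np.zeros_like(truth_mask), "lesion", image.spacing)
    thr = threshold_otsu(vals)
    return ROIMask(neigh & (image.data > thr), "lesion", image.spacing)


def _station_structural(structural: Volume, station: StationSeries, target: Volume) -> Volume:
    """Crop the structural reference to one station's slice extent and
    resample it in-plane to the DWI grid."""
    lo, hi = station.slice_range
    ax = structural.slice_axis
    # structural shares the slice grid (same slice spacing); crop then resample
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, hi)
    cropped = Volume(
        structural.data[tuple(sl)], structural.spacing, structural.pe_axis, structural.slice_axis
    )
    return resample_linear(cropped, target.shape, target.spacing)


def evaluate_dataset(
    nc: list[StationSeries] | None,
    dc_b0: list[StationSeries] | None,
    dc_b50: list[StationSeries] | None,
    structural: Volume,
    masks: dict[str, np.ndarray] | None = None,
    adc_rois: dict[str, np.ndarray] | None = None,
    *,
    low_b: float = 50.0,
    seg_b: float = 50.0,
    n_overlap: int | None = None,
    fit_bs=DEFAULT_FIT_BS,
    n_bins: int = 64,
) -> EvalReport:
    """Assemble the full evaluation report over the three conditions.

    Each condition list holds one series per station (for NC, the acquired
    AP series; for DC-*, the corrected series).  For every present condition (NC, DC-b0, DC-b50): station-wise MI between
    the low-b volume and the structural reference; per lesion mask,
    DSC/ED/AVD of the image-derived segmentation against truth (masks and
    ROIs are given on the whole-body grid, so station volumes are assembled
    first; ``n_overlap`` defaults to the overlap implied by the slice
    ranges); per ROI, the ADC mean and, versus NC, the paired ΔADC with
    Wilcoxon tests across ROIs and MI Wilcoxon tests across stations.
    """
    report = EvalReport()
    conditions = {"NC": nc, "DC-b0": dc_b0, "DC-b50": dc_b50}
    present = {k: v for k, v in conditions.items() if v}
    for name in conditions:
        if name not in present:
            warnings.warn(f"condition {name} missing; partial report")
    if not present:
        return report

    some = sorted(next(iter(present.values())), key=lambda s: s.station_index)
    if n_overlap is None:
        n_overlap = (
            max(0, some[0].slice_range[1] - some[1].slice_range[0]) if len(some) > 1 else 0
        )

    # --- station-wise MI against the structural reference
    for cond, stations in present.items():
        for st in sorted(stations, key=lambda s: s.station_index):
            if low_b not in st.volumes:
                warnings.warn(f"low b={low_b} missing in {cond} station {st.station_index}")
                continue
            ref = _station_structural(structural, st, st.volumes[low_b])
            mi = mutual_information(st.volumes[low_b], ref, n_bins)
            report.add(cond, f"station{st.station_index}", "MI", mi, "nats")

    for cond in ("DC-b0", "DC-b50"):
        if cond in present and "NC" in present:
            mi_nc = report.values("MI", "NC")
            mi_dc = report.values("MI", cond)
            keys = sorted(set(mi_nc) & set(mi_dc))
            if len(keys) >= 3:
                res = wilcoxon_signed_rank(
                    [mi_dc[k] for k in keys], [mi_nc[k] for k in keys]
                )
                report.test_results.append(
                    {"comparison": f"MI {cond} vs NC", "statistic": res["W"],
                     "p_value": res["p_two_sided"], "n": res["n"]}
                )

    def _assemble(stations, b) -> Volume | None:
        vols = [
            st.volumes[b]
            for st in sorted(stations, key=lambda s: s.station_index)
            if b in st.volumes
        ]
        if not vols:
            return None
        return assemble_stations(vols, n_overlap).volume

    # --- lesion segmentation metrics on the assembled seg_b image
    spacing = some[0].volumes[next(iter(some[0].volumes))].spacing
    for mask_name, truth_mask in (masks or {}).items():
        truth_roi = ROIMask(truth_mask, mask_name, spacing)
        if truth_roi.n_voxels == 0:
            continue
        for cond, stations in present.items():
            wb = _assemble(stations, seg_b)
            if wb is None or wb.shape != truth_mask.shape:
                warnings.warn(f"cannot segment {mask_name} for {cond}")
                continue
            seg = segment_lesion(wb, truth_mask)
            if seg.n_voxels == 0:
                warnings.warn(f"empty segmentation for {mask_name} in {cond}")
                continue
            report.add(cond, mask_name, "DSC", dice(seg, truth_roi))
            report.add(cond, mask_name, "ED", centroid_distance(seg, truth_roi), "mm")
            report.add(cond, mask_name, "AVD", average_hausdorff(seg, truth_roi), "mm")

    # --- ROI ADC means and NC-vs-DC differences
    if adc_rois:
        adc_by_cond: dict[str, Volume] = {}
        for cond, stations in present.items():
            try:
                per_station = [
                    fit_adc(st.volumes, fit_bs).adc
                    for st in sorted(stations, key=lambda s: s.station_index)
                ]
            except ValueError as exc:
                warnings.warn(f"ADC fit skipped for {cond}: {exc}")
                continue
            adc_by_cond[cond] = assemble_stations(per_station, n_overlap).volume
        for cond, adc_wb in adc_by_cond.items():
            for roi_name, roi in adc_rois.items():
                if roi.shape != adc_wb.shape or not roi.any():
                    continue
                report.add(cond, roi_name, "ADC_mean",
                           float(adc_wb.data[roi].mean()), "1e-3 mm^2/s")
        if "NC" in adc_by_cond:
            nc_means = report.values("ADC_mean", "NC")
            for cond in ("DC-b0", "DC-b50"):
                if cond not in adc_by_cond:
                    continue
                dc_means = report.values("ADC_mean", cond)
                keys = sorted(set(nc_means) & set(dc_means))
                for k in keys:
                    report.add(cond, k, "dADC_mean",
                               dc_means[k] - nc_means[k], "1e-3 mm^2/s")
                if len(keys) >= 3:
                    res = wilcoxon_signed_rank(
                        [nc_means[k] for k in keys], [dc_means[k] for k in keys]
                    )
                    report.test_results.append(
                        {"comparison": f"ADC {cond} vs NC", "statistic": res["W"],
                         "p_value": res["p_two_sided"], "n": res["n"]}
                    )
    return report
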