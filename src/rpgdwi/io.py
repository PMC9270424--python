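"""Dataset I/O: NIfTI volumes with JSON sidecars, manifests, and the
end-to-end workflow.

NIfTI does not encode the phase-encode axis or gradient polarity, so each
volume is written with a JSON sidecar carrying ``PhaseEncodingAxis`` and
``PhaseEncodingPolarity`` ("AP" | "PA").  A manifest JSON lists every file of
a simulated dataset together with the protocol and provenance (seed, package
version).  ``run_full`` realises the whole chain — simulate, estimate and
apply the distortion correction for the b0- and b50-based variants, fit ADC,
assemble whole-body volumes, evaluate — from a single YAML config.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .core import AP, DisplacementField, Polarity, Volume
from .evaluation import EvalReport, evaluate_dataset
from .phantom import (
    PhantomTruth,
    ProtocolConfig,
    StationSeries,
    embed_lesion,
    make_phantom,
    simulate_acquisition,
    structural_reference,
)
from .pipeline import assemble_stations, fit_adc, match_station_intensity
from .unwarp import UnwarpParams, correct_dataset

__all__ = [
    "save_volume",
    "load_volume",
    "save_dataset",
    "load_dataset",
    "run_full",
]

log = logging.getLogger("rpgdwi")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(
    v: Volume, path: str | Path, polarity: Polarity | None = None
) -> Path:
    """Write a volume as NIfTI-1 (.nii.gz) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), _affine(v.spacing)), path)
    sidecar = {
        "PhaseEncodingAxis": v.pe_axis,
        "SliceAxis": v.slice_axis,
        "Spacing": list(v.spacing),
    }
    if polarity is not None:
        sidecar["PhaseEncodingPolarity"] = polarity.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def load_volume(path: str | Path) -> tuple[Volume, Polarity | None]:
    """Read a NIfTI volume and its sidecar (if present)."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    pe_axis, slice_axis, pol = 1, 2, None
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        pe_axis = int(meta.get("PhaseEncodingAxis", pe_axis))
        slice_axis = int(meta.get("SliceAxis", slice_axis))
        if "PhaseEncodingPolarity" in meta:
            pol = Polarity.from_name(meta["PhaseEncodingPolarity"])
    return Volume(data, spacing, pe_axis, slice_axis), pol


def _station_filename(st: StationSeries, b: float) -> str:
    return f"station{st.station_index}_{st.polarity.name}_b{b:g}.nii.gz"


def save_dataset(
    outdir: str | Path,
    stations: list[StationSeries],
    truth: PhantomTruth | None = None,
    structural: Volume | None = None,
    cfg: ProtocolConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write a simulated dataset and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "provenance": {
            "package": "rpgdwi",
            "version": __version__,
            "seed": seed,
            "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stations": [],
    }
    for st in stations:
        entry = {
            "station_index": st.station_index,
            "polarity": st.polarity.name,
            "slice_range": list(st.slice_range),
            "volumes": {},
        }
        for b, vol in st.volumes.items():
            fn = _station_filename(st, b)
            save_volume(vol, outdir / fn, st.polarity)
            entry["volumes"][f"{b:g}"] = fn
        manifest["stations"].append(entry)
    if structural is not None:
        save_volume(structural, outdir / "structural.nii.gz")
        manifest["structural"] = "structural.nii.gz"
    if truth is not None:
        spacing, pe, sa = truth.spacing, truth.cfg.pe_axis, truth.cfg.slice_axis
        for name, arr in (
            ("labels", truth.labels),
            ("s0", truth.s0),
            ("adc", truth.adc),
            ("fieldmap", truth.fieldmap.df),
        ):
            save_volume(Volume(arr.astype(float), spacing, pe, sa), outdir / f"truth_{name}.nii.gz")
        manifest["truth"] = {n: f"truth_{n}.nii.gz" for n in ("labels", "s0", "adc", "fieldmap")}
        manifest["truth"]["label_names"] = {str(k): v for k, v in truth.label_names.items()}
        manifest["truth"]["station_offsets_hz"] = truth.station_offsets.tolist()
        manifest["truth"]["station_scales"] = truth.station_scales.tolist()
        manifest["lesion_masks"] = {}
        for name, mask in truth.lesion_masks.items():
            fn = f"mask_{name}.nii.gz"
            save_volume(Volume(mask.astype(float), spacing, pe, sa), outdir / fn)
            manifest["lesion_masks"][name] = fn
    if cfg is not None:
        (outdir / "protocol.yaml").write_text(yaml.safe_dump(asdict(cfg)))
        manifest["protocol"] = "protocol.yaml"
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_dataset(manifest_path: str | Path) -> dict:
    """Load a dataset from its manifest.

    Validation problems (missing files, inconsistent grids, unknown polarity
    tags) are aggregated and raised together as one error.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    errors: list[str] = []
    out: dict = {"stations": [], "manifest": manifest}

    def _load(rel: str):
        p = root / rel
        if not p.exists():
            errors.append(f"missing file: {rel}")
            return None, None
        try:
            return load_volume(p)
        except ValueError as exc:
            errors.append(f"{rel}: {exc}")
            return None, None

    grids = set()
    for entry in manifest.get("stations", []):
        vols: dict[float, Volume] = {}
        pol = None
        for bstr, rel in entry["volumes"].items():
            vol, p = _load(rel)
            if vol is None:
                continue
            vols[float(bstr)] = vol
            grids.add((vol.shape, vol.spacing, vol.pe_axis))
            if p is not None:
                if p.name != entry["polarity"]:
                    errors.append(f"{rel}: sidecar polarity {p.name} != manifest {entry['polarity']}")
                pol = p
        try:
            pol = pol or Polarity.from_name(entry["polarity"])
        except ValueError as exc:
            errors.append(str(exc))
            continue
        if vols:
            out["stations"].append(
                StationSeries(entry["station_index"], pol, vols, tuple(entry["slice_range"]))
            )
    if len(grids) > 1:
        errors.append(f"inconsistent station grids: {sorted(grids)}")
    if "structural" in manifest:
        vol, _ = _load(manifest["structural"])
        out["structural"] = vol
    if "truth" in manifest:
        out["truth_maps"] = {}
        for name in ("labels", "s0", "adc", "fieldmap"):
            vol, _ = _load(manifest["truth"][name])
            out["truth_maps"][name] = vol
        out["label_names"] = {int(k): v for k, v in manifest["truth"]["label_names"].items()}
    out["lesion_masks"] = {}
    for name, rel in manifest.get("lesion_masks", {}).items():
        vol, _ = _load(rel)
        if vol is not None:
            out["lesion_masks"][name] = vol.data > 0.5
    if "protocol" in manifest:
        p = root / manifest["protocol"]
        if p.exists():
            out["protocol"] = ProtocolConfig(**yaml.safe_load(p.read_text()))
        else:
            errors.append(f"missing file: {manifest['protocol']}")
    if errors:
        raise FileNotFoundError("dataset validation failed:\n  " + "\n  ".join(errors))
    return out


DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "rpgdwi_run",
    "protocol": {},
    "unwarp": {},
    "reference_bs": [0.0, 50.0],
    "lesions": "auto",  # place one high-|d| and one low-|d| lesion
    "save_volumes": False,
}


def _auto_lesions(truth: PhantomTruth) -> PhantomTruth:
    """Embed one lesion where the true displacement is large (>= 2 voxels)
    and one where it is negligible (< 0.25 voxel)."""
    cfg = truth.cfg
    pe_sp = truth.spacing[cfg.pe_axis]
    placed = truth
    for name, pick in (("lesion_hi_d", "hi"), ("lesion_lo_d", "lo")):
        best = None
        for k in range(cfg.n_stations):
            dvox = np.abs(truth.true_displacement(k).d) / pe_sp
            lo, hi = cfg.slice_range(k)
            body = truth.labels > 0
            zmask = np.zeros_like(body)
            sl = [slice(None)] * 3
            sl[cfg.slice_axis] = slice(lo + 2, hi - 2)
            zmask[tuple(sl)] = True
            cand = body & zmask
            if pick == "hi":
                cand &= dvox >= 2.0
            else:
                cand &= dvox < 0.15
            coords = np.argwhere(cand)
            if coords.size:
                centre = coords[len(coords) // 2]
                best = centre
                break
        if best is None:
            warnings.warn(f"no candidate location for {name}")
            continue
        centre_mm = tuple(float(c * s) for c, s in zip(best, truth.spacing))
        placed = embed_lesion(placed, centre_mm, 14.0, 2.5, 1200.0, name=name)
    return placed


def run_full(config: str | Path | dict) -> dict:
    """Run the full workflow from a YAML config (path or dict).

    simulate -> estimate/apply RPG correction (b0- and b50-based) -> ADC ->
    whole-body assembly (with intensity matching for display volumes) ->
    evaluation for the conditions NC, DC-b0 and DC-b50.  Deterministic given
    the config seed; returns the report plus in-memory results and writes the
    report CSV/JSON and a structured run log to ``outdir``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfgd = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfgd["seed"])
    outdir = Path(cfgd["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = ProtocolConfig(**cfgd["protocol"], rng_seed=seed)
    params = UnwarpParams(**cfgd["unwarp"])
    timings: dict[str, float] = {}

    def _stage(name):
        log.info("stage=%s seed=%d", name, seed)
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    _stage("simulate")
    truth = make_phantom(protocol, seed)
    if cfgd["lesions"] == "auto":
        truth = _auto_lesions(truth)
    stations = simulate_acquisition(truth, protocol, seed)
    structural = structural_reference(truth, upsample_inplane=1.0)
    _done("simulate")

    ap = [s for s in stations if s.polarity is AP]
    conditions: dict[str, list[StationSeries] | None] = {"NC": ap, "DC-b0": None, "DC-b50": None}
    traces: dict[str, list] = {}
    for ref_b in cfgd["reference_bs"]:
        cond = f"DC-b{ref_b:g}"
        has_ref = all(float(ref_b) in s.volumes for s in stations)
        if not has_ref:
            warnings.warn(f"reference b={ref_b} not acquired; skipping {cond}")
            continue
        _stage(cond)
        conditions[cond] = correct_dataset(stations, params, float(ref_b))
        _done(cond)

    _stage("evaluate")
    masks = {n: m for n, m in truth.lesion_masks.items() if m.any()}
    organ_rois = {
        name: truth.labels == lab
        for lab, name in truth.label_names.items()
        if lab >= 2
    }
    report = evaluate_dataset(
        conditions["NC"],
        conditions["DC-b0"],
        conditions["DC-b50"],
        structural,
        masks=masks,
        adc_rois=organ_rois,
        n_overlap=protocol.n_overlap,
    )
    _done("evaluate")

    wholebody: dict[str, Volume] = {}
    adc_maps: dict[str, Volume] = {}
    for cond, series in conditions.items():
        if not series:
            continue
        series = sorted(series, key=lambda s: s.station_index)
        low_b = [s.volumes[50.0] for s in series if 50.0 in s.volumes]
        if len(low_b) == len(series) and len(series) > 1:
            matched = match_station_intensity(low_b, protocol.n_overlap)
            wholebody[cond] = assemble_stations(matched, protocol.n_overlap).volume
        try:
            adc_stations = [fit_adc(s.volumes).adc for s in series]
            adc_maps[cond] = assemble_stations(adc_stations, protocol.n_overlap).volume
        except ValueError as exc:
            warnings.warn(f"ADC skipped for {cond}: {exc}")

    df = report.to_dataframe()
    df.to_csv(outdir / "report.csv", index=False)
    (outdir / "test_results.json").write_text(json.dumps(report.test_results, indent=1))
    cost_traces = {
        cond: {f"station{s.station_index}": s.cost_trace for s in series}
        for cond, series in conditions.items()
        if series and cond != "NC"
    }
    runlog = {
        "seed": seed,
        "version": __version__,
        "params": asdict(params),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "conditions": [k for k, v in conditions.items() if v],
        "cost_traces": cost_traces,
    }
    (outdir / "runlog.json").write_text(json.dumps(runlog, indent=1))
    if cfgd["save_volumes"]:
        save_dataset(outdir / "dataset", stations, truth, structural, protocol, seed)
        for cond, wb in wholebody.items():
            save_volume(wb, outdir / f"wholebody_b50_{cond.replace('-', '')}.nii.gz")
        for cond, adc in adc_maps.items():
            save_volume(adc, outdir / f"adc_{cond.replace('-', '')}.nii.gz")
    return {
        "report": report,
        "truth": truth,
        "stations": stations,
        "conditions": conditions,
        "structural": structural,
        "wholebody": wholebody,
        "adc": adc_maps,
        "outdir": outdir,
    }
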