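"""End-to-end orchestration: phantom (or external series) -> bias
correction -> fiducials & ROI -> boundary extraction -> slice
realignment -> threshold & depot segmentation -> void backfill -> rigid
series alignment -> morphometrics -> CSV / meshes / heat maps / JSON
manifest.  Deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as qm
from . import phantom as ph
from . import register as reg
from . import segment as sg
from .volio import (ScanSeries, VoxelVolume, get_logger, is_injected_stage, read_volume,
                    stage_sort_key, stage_timer, write_mesh, write_volume)

__all__ = [
    "RunConfig",
    "StageResult",
    "SeriesAnalysis",
    "PipelineStageError",
    "analyze_series",
    "run_pipeline",
    "summarize_runs",
    "reference_phantom_spec",
]

log = get_logger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    mode: str = "phantom"                 # "phantom" | "series"
    site: str = "thigh"
    input_dir: str | None = None          # series mode
    required_stages: tuple[str, ...] | None = None
    out_dir: str = "out"
    seed: int = 0
    threshold_method: str = "otsu"
    bias_order: int = 2
    capsule_wall_mm: float = 0.5
    reference_stage: str = "post_removal"
    roi_half_extent_mm: float = 48.0
    void_search_radius_mm: float = 6.0
    boundary_exclusion_radius_mm: float = 4.5
    cylinder_radius_mm: float = 10.0
    write_heatmaps: bool = True
    write_meshes: bool = True
    write_volumes: bool = True
    phantom_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class StageResult:
    stage: str
    roi: VoxelVolume
    fiducials: sg.FiducialSet
    id_sc_raw: sg.BoundarySurface
    sc_im_raw: sg.BoundarySurface
    id_sc: sg.BoundarySurface
    sc_im: sg.BoundarySurface
    shift_schedule: reg.SliceShiftSchedule
    dermis_mm: float
    cannula_xz: tuple[float, float]
    threshold: float | None = None
    seg: sg.DepotSegmentation | None = None
    tmap: qm.ThicknessMap | None = None


@dataclass
class SeriesAnalysis:
    site: str
    stages: list[str]
    results: dict[str, StageResult]
    transforms: dict[str, reg.RigidTransform]
    track: qm.SeriesThicknessTrack
    metrics: pd.DataFrame
    dermis_mm: float


def _void_mask(roi: VoxelVolume, id_sc: sg.BoundarySurface, sc_im: sg.BoundarySurface,
               cannula_xz, radius_mm: float, levels: dict) -> np.ndarray:
    """Near-zero-intensity cylinder about the cannula axis (metal void)."""
    dark = roi.intensities < 0.5 * (levels["background"] + levels["muscle"])
    ys = roi.axis_coords(1)
    band = (ys[None, :, None] > (id_sc.height_field - 3.0)[:, None, :]) \
        & (ys[None, :, None] < sc_im.height_field[:, None, :])
    xs, zs = roi.axis_coords(0), roi.axis_coords(2)
    lat = ((xs[:, None] - cannula_xz[0]) ** 2 + (zs[None, :] - cannula_xz[1]) ** 2) \
        <= radius_mm ** 2
    return dark & band & lat[:, None, :]


def _analyze_stage(vol: VoxelVolume, stage: str, config: RunConfig) -> StageResult:
    try:
        vol = reg.bias_correct(vol, order=config.bias_order)
        fids = sg.detect_fiducials(vol)
        roi = sg.extract_roi(vol, fids, config.roi_half_extent_mm)
        cents = fids.centroids
        cannula_xz = (float(cents[:, 0].mean()), float(cents[:, 2].mean()))
        levels = sg.estimate_class_levels(roi.intensities)
        cannula_in = stage not in ("naive", "post_removal")
        disk = (cannula_xz[0], cannula_xz[1], config.boundary_exclusion_radius_mm) \
            if cannula_in else None
        id_raw, im_raw = sg.extract_boundaries(roi, levels=levels, invalid_disk=disk)
        sched, id_corr, im_corr, _ = reg.realign_slices(id_raw, im_raw)
        # invalid (void) columns were first inpainted from the still-jagged
        # raw field; re-fill them now that the slices are consistent
        id_corr = sg.reinpaint(id_corr).smoothed()
        im_corr = sg.reinpaint(im_corr).smoothed()
        dermis = reg.estimate_dermal_thickness(fids, id_corr, config.capsule_wall_mm)
        res = StageResult(stage, roi, fids, id_raw, im_raw, id_corr, im_corr,
                          sched, dermis, cannula_xz)
        if is_injected_stage(stage) or stage == "post_removal":
            band = sg.sc_band_mask(roi, id_raw, im_raw)
            thr = sg.select_threshold(roi, method=config.threshold_method, mask=band)
            res.threshold = thr
            res.seg = sg.segment_depot(roi, thr, cannula_xz, id_sc=id_raw,
                                       cylinder_radius_mm=config.cylinder_radius_mm)
        return res
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError(stage, str(exc)) from exc


def analyze_series(series: ScanSeries, config: RunConfig) -> SeriesAnalysis:
    """Run the full correction + measurement chain on one series."""
    results: dict[str, StageResult] = {}
    for stage, vol in series.volumes.items():
        with stage_timer(f"stage {stage}", log):
            results[stage] = _analyze_stage(vol, stage, config)

    # rigid alignment of every stage onto the reference stage
    ref_stage = config.reference_stage if config.reference_stage in results \
        else series.stages[-1]
    ref = results[ref_stage]
    transforms: dict[str, reg.RigidTransform] = {ref_stage: reg.RigidTransform.identity()}
    for stage, res in results.items():
        if stage == ref_stage:
            continue
        try:
            transforms[stage] = reg.align_series(res.fiducials, ref.fiducials,
                                                 res.id_sc, ref.id_sc)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"align:{stage}", str(exc)) from exc

    # void backfill from the post-removal depot (cannula-in-situ stages only)
    ref_seg = results.get("post_removal").seg if "post_removal" in results else None
    for stage, res in results.items():
        if res.seg is None or not is_injected_stage(stage):
            continue
        levels = sg.estimate_class_levels(res.roi.intensities)
        void = _void_mask(res.roi, res.id_sc_raw, res.sc_im_raw, res.cannula_xz,
                          config.void_search_radius_mm, levels)
        if ref_seg is not None and void.any():
            t_ref_to_stage = transforms[stage].inverse().compose(
                transforms.get("post_removal", reg.RigidTransform.identity()))
            res.seg = reg.backfill_void(res.seg, void, ref_seg, t_ref_to_stage)

    # thickness maps
    for res in results.values():
        res.tmap = qm.thickness_map(res.id_sc, res.sc_im)

    # reference-point track across the series
    largest = series.largest_stage
    track = qm.track_reference_thickness(
        {s: r.id_sc for s, r in results.items()},
        {s: r.sc_im for s, r in results.items()},
        results[largest].seg.mesh if results[largest].seg is not None else None,
        largest, transforms)

    dermis = float(np.mean([r.dermis_mm for r in results.values()]))
    rows = []
    for stage, res in sorted(results.items(), key=lambda kv: stage_sort_key(kv[0])):
        row = {"site": series.site, "stage": stage,
               "thickness_mm": track.thickness_mm.get(stage, np.nan),
               "pct_change": track.percent_change.get(stage, np.nan),
               "dermis_mm": res.dermis_mm,
               "threshold": res.threshold if res.threshold is not None else np.nan}
        if res.seg is not None and res.seg.mask.any() and res.seg.mesh is not None:
            proj = qm.project_and_axes(res.seg.mesh, res.id_sc)
            d_id = qm.min_distance(res.seg.mesh, res.id_sc)
            d_im = qm.min_distance(res.seg.mesh, res.sc_im)
            row.update(volume_mL=qm.depot_volume(res.seg),
                       min_dist_id_sc_mm=d_id, min_dist_sc_im_mm=d_im,
                       depth_from_skin_mm=qm.depth_from_skin(d_id, dermis),
                       area_cm2=proj.projected_area_cm2,
                       axis_x_mm=proj.principal_x_mm, axis_y_mm=proj.principal_y_mm,
                       z_extent_mm=proj.z_extent_mm)
        else:
            row.update(volume_mL=np.nan, min_dist_id_sc_mm=np.nan, min_dist_sc_im_mm=np.nan,
                       depth_from_skin_mm=np.nan, area_cm2=np.nan,
                       axis_x_mm=np.nan, axis_y_mm=np.nan, z_extent_mm=np.nan)
        rows.append(row)
    cols = ["site", "stage", "volume_mL", "min_dist_id_sc_mm", "min_dist_sc_im_mm",
            "depth_from_skin_mm", "area_cm2", "axis_x_mm", "axis_y_mm", "z_extent_mm",
            "thickness_mm", "pct_change", "dermis_mm", "threshold"]
    df = pd.DataFrame(rows)[cols]
    return SeriesAnalysis(series.site, series.stages, results, transforms, track, df, dermis)


# ---------------------------------------------------------------------------
# Run + manifest
# ---------------------------------------------------------------------------

def reference_phantom_spec(site: str, seed: int = 0,
                           final_stage_thickness_mm: float | None = None,
                           **overrides) -> ph.PhantomSpec:
    """Site-preset phantom spec, optionally re-calibrated so the final
    stage's reference-point thickness hits a prescribed value (the
    intermediate stages keep the preset percent expansions)."""
    preset = dict(ph.SITE_PRESETS[site])
    preset.update(overrides)
    if final_stage_thickness_mm is not None:
        base = preset["sc_baseline_thickness_mm"]
        pct = list(preset["stage_expansion_pct"])
        pct[-1] = (final_stage_thickness_mm / base - 1.0) * 100.0
        preset["stage_expansion_pct"] = tuple(pct)
    return ph.PhantomSpec(site_label=site, seed=seed, **preset)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_series_dir(config: RunConfig) -> ScanSeries:
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(input_dir)
    volumes = {}
    for f in sorted(input_dir.glob("*.nii*")):
        stage = f.name.split(".")[0]
        try:
            stage_sort_key(stage)
        except ValueError:
            continue
        volumes[stage] = read_volume(f)
    if config.required_stages:
        for stage in config.required_stages:
            if stage not in volumes:
                raise PipelineStageError(
                    "load", f"missing stage file for stage {stage!r} in {input_dir}")
    if not volumes:
        raise PipelineStageError("load", f"no stage volumes found in {input_dir}")
    return ScanSeries(site=config.site, volumes=volumes)


def run_pipeline(config: RunConfig) -> tuple[dict, SeriesAnalysis]:
    """Execute one run; returns (manifest, analysis) and writes outputs.

    Outputs under ``config.out_dir``: per-stage volumes (phantom mode),
    depot masks and meshes, ``metrics.csv``, thickness histograms, heat
    maps with a site-fixed colour scale, and ``manifest.json`` recording
    every parameter and output checksum.  Identical config + seed yields
    byte-identical metrics.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(config)}, "seed": config.seed, "outputs": {}}
    if config.mode == "phantom":
        spec = reference_phantom_spec(config.site, seed=config.seed,
                                      **config.phantom_overrides)
        series, truth = ph.generate_series(spec)
        if config.write_volumes:
            ph.write_series(series, truth, out_dir / "volumes")
    elif config.mode == "series":
        series = _load_series_dir(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    analysis = analyze_series(series, config)

    metrics_path = out_dir / "metrics.csv"
    analysis.metrics.to_csv(metrics_path, index=False, float_format="%.6g")
    manifest["stages"] = analysis.stages
    manifest["n_depot_rows"] = len([s for s in analysis.stages if is_injected_stage(s)])
    manifest["dermis_mm"] = analysis.dermis_mm
    manifest["reference_point_mm"] = analysis.track.reference_point_mm.tolist()
    manifest["transforms"] = {s: t.to_dict() for s, t in analysis.transforms.items()}
    manifest["thresholds"] = {s: r.threshold for s, r in analysis.results.items()
                              if r.threshold is not None}

    if config.write_meshes:
        mesh_dir = out_dir / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for stage, res in analysis.results.items():
            if res.seg is not None and res.seg.mesh is not None:
                write_mesh(res.seg.mesh, mesh_dir / f"depot_{stage}.stl")
            write_mesh(res.id_sc.mesh, mesh_dir / f"id_sc_{stage}.stl", open_sheet=True)
            write_mesh(res.sc_im.mesh, mesh_dir / f"sc_im_{stage}.stl", open_sheet=True)
    if config.write_heatmaps:
        hm_dir = out_dir / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        vmin = min(r.tmap.values_mm[r.tmap.valid_mask].min() for r in analysis.results.values())
        vmax = max(r.tmap.values_mm[r.tmap.valid_mask].max() for r in analysis.results.values())
        for stage, res in analysis.results.items():
            qm.render_heatmap(res.tmap, hm_dir / f"thickness_{stage}.png",
                              vmin=float(vmin), vmax=float(vmax),
                              title=f"{analysis.site} {stage}")
        manifest["heatmap_scale_mm"] = [float(vmin), float(vmax)]
    hist_rows = []
    for stage, res in analysis.results.items():
        for lo, hi_, p in zip(res.tmap.hist_edges_mm[:-1], res.tmap.hist_edges_mm[1:],
                              res.tmap.hist_pct):
            hist_rows.append({"site": analysis.site, "stage": stage,
                              "bin_lo_mm": lo, "bin_hi_mm": hi_, "pct": p})
    pd.DataFrame(hist_rows).to_csv(out_dir / "thickness_histograms.csv",
                                   index=False, float_format="%.6g")

    for f in sorted(out_dir.rglob("*")):
        if f.is_file() and f.suffix in (".csv", ".json", ".stl", ".nii", ".gz"):
            manifest["outputs"][str(f.relative_to(out_dir))] = _sha256(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest, analysis


def summarize_runs(manifest_paths) -> pd.DataFrame:
    """Descriptive statistics (n, mean, SEM, SD, min, max) per site x stage
    over several run manifests."""
    frames = []
    key_cfg = None
    for p in manifest_paths:
        p = Path(p)
        man = json.loads((p if p.name == "manifest.json" else p / "manifest.json").read_text())
        cfg = man["config"]
        sig = (cfg.get("threshold_method"), cfg.get("bias_order"), cfg.get("reference_stage"))
        if key_cfg is None:
            key_cfg = sig
        elif sig != key_cfg:
            raise ValueError("manifests come from incompatible configurations")
        run_dir = p if p.is_dir() else p.parent
        frames.append(pd.read_csv(run_dir / "metrics.csv"))
    if not frames:
        raise ValueError("need at least one manifest")
    alldf = pd.concat(frames, ignore_index=True)
    num_cols = [c for c in alldf.columns if c not in ("site", "stage")]
    grouped = alldf.groupby(["site", "stage"])[num_cols]
    out = grouped.agg(["count", "mean", "sem", "std", "min", "max"])
    # a single observation has zero spread, not undefined spread
    for col in out.columns:
        if col[1] in ("sem", "std"):
            out[col] = out[col].fillna(0.0)
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out.reset_index()
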