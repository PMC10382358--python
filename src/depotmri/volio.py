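"""Volume and mesh I/O, series containers, config and logging.

The canonical in-memory unit is :class:`VoxelVolume` -- a 3-D grayscale
array with anisotropic physical spacing.  Axis convention (fixed for the
whole package): axis 0 is the lateral in-plane direction ``x``, axis 1 is
the in-plane depth direction ``y`` (skin at small ``y``, muscle at large
``y``), axis 2 is the slice-stacking direction ``z``.  Physical
coordinates are millimetres; the centre of voxel ``(i, j, k)`` sits at
``origin_mm + (i, j, k) * spacing_mm``.  All distances are in mm, all
volumes in mm^3 and converted to mL (1 mL = 1000 mm^3) only for
reporting.

NIfTI (via nibabel) is the reference on-disk volume format; a DICOM
series directory can be read (and optionally written) because clinical
source data arrive as DICOM stacks.  Meshes go through trimesh
(STL/PLY/OBJ).
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

__all__ = [
    "VoxelVolume",
    "ScanSeries",
    "stage_sort_key",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "write_dicom_series",
    "read_mesh",
    "write_mesh",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "load_config",
    "get_logger",
    "stage_timer",
    "MetadataError",
]

# Canonical stage labels of an injection series.  Injected stages are
# named after the cumulative volume ("v2", "v5", "v10", ...); a series
# may omit stages (not every site received every volume).
BASE_STAGES = ("naive", "insertion", "post_removal")


class MetadataError(ValueError):
    """Raised when a volume lacks the spacing metadata needed for mm-scale
    measurements."""


def stage_sort_key(stage: str) -> float:
    """Ordering key: naive < insertion < v2 < v5 < ... < post_removal."""
    if stage == "naive":
        return 0.0
    if stage == "insertion":
        return 1.0
    if stage == "post_removal":
        return 1e9
    if stage.startswith("v"):
        try:
            return 2.0 + float(stage[1:])
        except ValueError:
            pass
    raise ValueError(f"unknown stage label: {stage!r}")


def is_injected_stage(stage: str) -> bool:
    return stage.startswith("v") and stage not in BASE_STAGES


@dataclass
class VoxelVolume:
    """3-D grayscale volume with physical spacing.

    Parameters
    ----------
    intensities:
        ``(nx, ny, nz)`` non-negative array (float).
    spacing_mm:
        Voxel spacing ``(dx, dy, dz)`` in mm; ``dz`` is the slice pitch
        (slice thickness plus skip).
    origin_mm:
        Physical coordinate of the centre of voxel ``(0, 0, 0)``.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stage: str | None = None
    site: str | None = None
    axial: bool = True

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise MetadataError(f"spacing must be three positive reals, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along ``axis`` (mm)."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def copy(self, intensities: np.ndarray | None = None) -> "VoxelVolume":
        return VoxelVolume(
            intensities=self.intensities.copy() if intensities is None else intensities,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            stage=self.stage,
            site=self.site,
            axial=self.axial,
        )


@dataclass
class ScanSeries:
    """Ordered set of co-located volumes for one injection site."""

    site: str
    volumes: dict[str, VoxelVolume] = field(default_factory=dict)
    fiducials: dict = field(default_factory=dict)   # stage -> FiducialSet
    transforms: dict = field(default_factory=dict)  # stage -> RigidTransform to reference

    def __post_init__(self) -> None:
        for stage, vol in self.volumes.items():
            stage_sort_key(stage)  # validates label
            if vol.site is not None and vol.site != self.site:
                raise ValueError(f"stage {stage} has site {vol.site!r}, series is {self.site!r}")
        self.volumes = dict(sorted(self.volumes.items(), key=lambda kv: stage_sort_key(kv[0])))

    @property
    def stages(self) -> list[str]:
        return list(self.volumes)

    @property
    def injected_stages(self) -> list[str]:
        return [s for s in self.volumes if is_injected_stage(s)]

    @property
    def largest_stage(self) -> str:
        inj = self.injected_stages
        if not inj:
            raise ValueError("series has no injected stage")
        return inj[-1]


# ---------------------------------------------------------------------------
# NIfTI read / write
# ---------------------------------------------------------------------------

def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii / .nii.gz); spacing goes to the affine,
    stage/site labels to the header description."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.intensities.astype(np.float64), affine)
    img.header["descrip"] = f"stage={volume.stage or ''};site={volume.site or ''}".encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI volume or a DICOM series directory into a VoxelVolume.

    Raises :class:`MetadataError` when spacing metadata is missing or
    inconsistent -- distance measurements are meaningless without it.
    """
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: NIfTI pixdim (voxel spacing) missing or non-positive")
    data = np.asarray(img.dataobj, dtype=float)
    stage = site = None
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    for part in descrip.split(";"):
        if part.startswith("stage=") and part[6:]:
            stage = part[6:]
        if part.startswith("site=") and part[5:]:
            site = part[5:]
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    return VoxelVolume(data, tuple(float(z) for z in zooms), origin, stage=stage, site=site)


# ---------------------------------------------------------------------------
# DICOM series (read always supported; write is a convenience export)
# ---------------------------------------------------------------------------

def write_dicom_series(volume: VoxelVolume, out_dir: str | Path) -> Path:
    """Export a volume as an axial DICOM series (one file per slice) with
    correct PixelSpacing / SpacingBetweenSlices tags.

    Intensities are rounded to uint16; use NIfTI for lossless round-trips.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dx, dy, dz = volume.spacing_mm
    nx, ny, nz = volume.shape
    series_uid = generate_uid(entropy_srcs=["depotmri", str(volume.stage), str(volume.site)])
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[series_uid, str(k)])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.SeriesDescription = f"stage={volume.stage or ''};site={volume.site or ''}"
        ds.InstanceNumber = k + 1
        # slice array stored row=y, col=x
        sl = np.clip(np.round(volume.intensities[:, :, k].T), 0, 65535).astype(np.uint16)
        ds.Rows, ds.Columns = sl.shape
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]
        ds.SpacingBetweenSlices = f"{dz:.6f}"
        ds.SliceThickness = f"{dz:.6f}"
        ds.ImagePositionPatient = [
            f"{volume.origin_mm[0]:.6f}",
            f"{volume.origin_mm[1]:.6f}",
            f"{volume.origin_mm[2] + k * dz:.6f}",
        ]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = sl.tobytes()
        ds.save_as(out_dir / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return out_dir


def read_dicom_series(series_dir: str | Path) -> VoxelVolume:
    """Read an axial DICOM series directory.

    Hard errors when PixelSpacing or between-slice spacing is absent, or
    when the slice spacing is inconsistent within the series.
    """
    import pydicom

    series_dir = Path(series_dir)
    files = sorted(series_dir.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {series_dir}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(getattr(d, "InstanceNumber", 0)))
    first = slices[0]
    if "PixelSpacing" not in first:
        raise MetadataError(f"{series_dir}: missing required tag PixelSpacing")
    dy, dx = (float(v) for v in first.PixelSpacing)
    positions = [getattr(d, "ImagePositionPatient", None) for d in slices]
    if "SpacingBetweenSlices" in first:
        dz = float(first.SpacingBetweenSlices)
    elif all(p is not None for p in positions) and len(slices) > 1:
        zs = np.array([float(p[2]) for p in positions])
        dz = float(np.diff(zs).mean())
    else:
        raise MetadataError(
            f"{series_dir}: missing required tag SpacingBetweenSlices "
            "(and slice positions are unavailable)"
        )
    if len(slices) > 1 and all(p is not None for p in positions):
        zs = np.array([float(p[2]) for p in positions])
        steps = np.diff(zs)
        if steps.size and (np.max(steps) - np.min(steps)) > 1e-3:
            raise MetadataError(f"{series_dir}: inconsistent slice spacing within series")
    stage = site = None
    desc = str(getattr(first, "SeriesDescription", ""))
    for part in desc.split(";"):
        if part.startswith("stage=") and part[6:]:
            stage = part[6:]
        if part.startswith("site=") and part[5:]:
            site = part[5:]
    data = np.stack([np.asarray(d.pixel_array, dtype=float).T for d in slices], axis=2)
    origin = (0.0, 0.0, 0.0)
    if positions[0] is not None:
        origin = (float(positions[0][0]), float(positions[0][1]), float(positions[0][2]))
    return VoxelVolume(data, (dx, dy, dz), origin, stage=stage, site=site)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh: trimesh.Trimesh, path: str | Path, open_sheet: bool = False) -> Path:
    """Write a triangle mesh (STL/PLY/OBJ by extension), vertex units mm.

    ``open_sheet=True`` flags boundary sheets that are legitimately
    non-watertight (the tissue interfaces); a closed mesh is expected
    otherwise but only degenerate (zero-triangle) meshes are rejected.
    """
    path = Path(path)
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("refusing to write a degenerate (zero-triangle) mesh")
    if not open_sheet and not mesh.is_watertight:
        get_logger(__name__).warning("mesh %s is not watertight and was not flagged open", path.name)
    mesh.export(str(path))
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return m


# ---------------------------------------------------------------------------
# Truth sidecar (documented JSON schema)
# ---------------------------------------------------------------------------
# Schema: {"schema": "depotmri-truth-1", "site": str, "dermis_thickness_mm":
#   float, "stages": {stage: {"true_depot_volume_mL": float,
#   "reference_thickness_mm": float, "transform": {"rotation": 3x3,
#   "translation_mm": [3]}, "slice_shifts_mm": [[sx, sy], ...],
#   "id_sc_height_mm"/"sc_im_height_mm"/"thickness_map_mm": 2-D lists,
#   "depot_mask_rle": flat run-length [run0, run1, ...] of the C-ordered
#   mask starting with a zero-run, "mask_shape": [nx, ny, nz]}}}


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]])).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            out[pos: pos + r] = True
        pos += r
        val = not val
    return out.reshape(shape)


def write_truth_sidecar(truth, path: str | Path) -> Path:
    """Serialise a PhantomTruth to the JSON sidecar schema above."""
    path = Path(path)
    doc = {
        "schema": "depotmri-truth-1",
        "site": truth.site,
        "dermis_thickness_mm": truth.dermis_thickness_mm,
        "stages": {},
    }
    for stage, st in truth.stages.items():
        entry = {
            "true_depot_volume_mL": st.true_depot_volume_mL,
            "reference_thickness_mm": st.reference_thickness_mm,
            "transform": {
                "rotation": np.asarray(st.rotation).tolist(),
                "translation_mm": np.asarray(st.translation_mm).tolist(),
            },
            "slice_shifts_mm": np.asarray(st.slice_shifts_mm).tolist(),
            "id_sc_height_mm": np.asarray(st.id_sc_height_mm).round(4).tolist(),
            "sc_im_height_mm": np.asarray(st.sc_im_height_mm).round(4).tolist(),
            "thickness_map_mm": np.asarray(st.thickness_map_mm).round(4).tolist(),
            "mask_shape": list(st.depot_mask.shape),
            "depot_mask_rle": _rle_encode(st.depot_mask),
            "void_mask_rle": _rle_encode(st.void_mask),
        }
        doc["stages"][stage] = entry
    path.write_text(json.dumps(doc))
    return path


def read_truth_sidecar(path: str | Path) -> dict:
    """Read the truth sidecar back into plain arrays (dict form)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "depotmri-truth-1":
        raise ValueError("not a depotmri truth sidecar")
    for entry in doc["stages"].values():
        shape = tuple(entry.pop("mask_shape"))
        entry["depot_mask"] = _rle_decode(entry.pop("depot_mask_rle"), shape)
        entry["void_mask"] = _rle_decode(entry.pop("void_mask_rle"), shape)
        for key in ("id_sc_height_mm", "sc_im_height_mm", "thickness_map_mm"):
            entry[key] = np.asarray(entry[key], dtype=float)
    return doc


# ---------------------------------------------------------------------------
# Config and logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML or TOML pipeline configuration file into a dict."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(path.read_text()) or {}
    if path.suffix == ".toml":
        import tomllib

        return tomllib.loads(path.read_text())
    raise ValueError(f"unsupported config format: {path.suffix}")


def get_logger(name: str = "depotmri") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logging.getLogger("depotmri").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root = logging.getLogger("depotmri")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(label: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage."""
    logger = logger or get_logger()
    t0 = time.perf_counter()
    yield
    logger.info("%s finished in %.2f s", label, time.perf_counter() - t0)
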