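"""Readers and writers for 4D-flow datasets, masks, plane sets, configs and tables.

All volumetric data travel as NIfTI-1 (one 4D file per velocity component plus one
4D magnitude file), with a JSON sidecar carrying geometry and timing metadata that
NIfTI headers express poorly (frame times in ms, VENC, heart rate).  Array layout
in memory is ``(frame, z, y, x)`` for scalar fields and ``(component, frame, z, y,
x)`` for velocity, with components ordered ``(vx, vy, vz)`` along the physical
x/y/x axes.  On disk the arrays are transposed to the NIfTI-native ``(x, y, z, t)``
order.

Physical coordinates are in mm with the voxel-center convention: voxel index ``i``
sits at position ``(i + 0.5) * voxel_size`` from the volume corner.  Velocity is
in cm/s throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("flow4d.io")

#: Site labels the pipeline knows about; free-text extensions are accepted with a
#: logged notice.
KNOWN_SITES = frozenset({"TV", "MPA", "RPA", "LPA", "aorta", "RV", "LV"})


class FlowIOError(ValueError):
    """Raised for malformed, inconsistent or missing on-disk inputs."""


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------

@dataclass
class FlowDataset:
    """Time-resolved magnitude + 3-component velocity volumes.

    Attributes
    ----------
    magnitude : (T, Z, Y, X) array
        Signal magnitude, arbitrary units (segmentation carrier).
    velocity : (3, T, Z, Y, X) array
        Velocity components (vx, vy, vz) in cm/s.
    voxel_size : float
        Isotropic voxel edge in mm.
    frame_times : (T,) array
        Start time of each cardiac frame in ms; strictly increasing from 0.
    venc : float
        Velocity-encoding limit in cm/s.
    heart_rate : float, optional
        Beats/min; derivable from the cycle duration when omitted.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    voxel_size: float
    frame_times: np.ndarray
    venc: float
    heart_rate: float | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude)
        self.velocity = np.asarray(self.velocity)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.magnitude.ndim != 4:
            raise FlowIOError("magnitude must be 4D (frame, z, y, x)")
        if self.velocity.ndim != 5 or self.velocity.shape[0] != 3:
            raise FlowIOError("velocity must have shape (3, frame, z, y, x)")
        if self.velocity.shape[1:] != self.magnitude.shape:
            raise FlowIOError(
                f"velocity grid {self.velocity.shape[1:]} does not match "
                f"magnitude grid {self.magnitude.shape}"
            )
        if self.frame_times.shape != (self.magnitude.shape[0],):
            raise FlowIOError("frame_times length must equal the number of frames")
        if self.frame_times[0] != 0 or np.any(np.diff(self.frame_times) <= 0):
            raise FlowIOError("frame_times must be strictly increasing, starting at 0")
        if self.voxel_size <= 0:
            raise FlowIOError("voxel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[1:]

    @property
    def frame_duration(self) -> float:
        """Inter-frame spacing in ms (uniform retrospective gating assumed)."""
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def cycle_duration(self) -> float:
        """Cardiac cycle length in ms (frames tile the cycle uniformly)."""
        return self.frame_duration * self.n_frames

    def derived_heart_rate(self) -> float:
        """Heart rate in beats/min; stored value wins over the cycle-derived one."""
        if self.heart_rate is not None:
            return self.heart_rate
        return 60000.0 / self.cycle_duration


@dataclass
class MaskVolume:
    """Integer label volume, static ``(z, y, x)`` or per-frame ``(t, z, y, x)``."""

    labels: np.ndarray
    label_map: dict[str, int]
    voxel_size: float
    slice_thickness: float | None = None  # mm; defaults to voxel_size
    gap: float = 0.0  # inter-slice gap in mm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (3, 4):
            raise FlowIOError("labels must be 3D (z,y,x) or 4D (t,z,y,x)")
        if self.labels.min() < 0:
            raise FlowIOError("labels must be nonnegative")
        if self.slice_thickness is None:
            self.slice_thickness = self.voxel_size

    @property
    def is_dynamic(self) -> bool:
        return self.labels.ndim == 4

    def frame(self, f: int) -> np.ndarray:
        return self.labels[f] if self.is_dynamic else self.labels


# ---------------------------------------------------------------------------
# NIfTI dataset I/O
# ---------------------------------------------------------------------------

_COMPONENT_FILES = ("vel_x.nii", "vel_y.nii", "vel_z.nii")
_MAGNITUDE_FILE = "mag.nii"
_META_FILE = "flow_meta.json"


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = 0.5 * voxel_size  # voxel-center convention
    return aff


def _to_nifti_order(vol_tzyx: np.ndarray) -> np.ndarray:
    # (t, z, y, x) -> (x, y, z, t)
    return np.transpose(vol_tzyx, (3, 2, 1, 0))


def _from_nifti_order(vol_xyzt: np.ndarray) -> np.ndarray:
    return np.transpose(vol_xyzt, (3, 2, 1, 0))


def write_flow_dataset(ds: FlowDataset, out_dir: str | Path) -> Path:
    """Write a dataset as NIfTI-1 component files plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(ds.voxel_size)
    for c, name in enumerate(_COMPONENT_FILES):
        nib.save(nib.Nifti1Image(_to_nifti_order(ds.velocity[c]), aff), out / name)
    nib.save(nib.Nifti1Image(_to_nifti_order(ds.magnitude), aff), out / _MAGNITUDE_FILE)
    meta = {
        "voxel_size_mm": ds.voxel_size,
        "frame_times_ms": [float(t) for t in ds.frame_times],
        "venc_cm_per_s": ds.venc,
        "heart_rate_bpm": ds.heart_rate,
        "axis_order": "arrays stored (x, y, z, t); components are (vx, vy, vz)",
        "velocity_units": "cm/s",
    }
    (out / _META_FILE).write_text(json.dumps(meta, indent=1))
    logger.info("wrote flow dataset to %s", out)
    return out


def read_flow_dataset(path: str | Path) -> FlowDataset:
    """Read a dataset written by :func:`write_flow_dataset`.

    Raises
    ------
    FlowIOError
        If any expected file is missing (the error lists the expected filenames)
        or the component shapes disagree (the error names the offending file).
    """
    d = Path(path)
    expected = [*_COMPONENT_FILES, _MAGNITUDE_FILE, _META_FILE]
    missing = [n for n in expected if not (d / n).exists()]
    if missing:
        raise FlowIOError(
            f"missing files in {d}: {missing}; a flow dataset directory must "
            f"contain {expected}"
        )
    meta = json.loads((d / _META_FILE).read_text())
    mag = _from_nifti_order(np.asarray(nib.load(d / _MAGNITUDE_FILE).dataobj))
    comps = []
    for name in _COMPONENT_FILES:
        arr = _from_nifti_order(np.asarray(nib.load(d / name).dataobj))
        if arr.shape != mag.shape:
            raise FlowIOError(
                f"{name}: shape {arr.shape} does not match magnitude {mag.shape}"
            )
        comps.append(arr)
    return FlowDataset(
        magnitude=mag,
        velocity=np.stack(comps, axis=0),
        voxel_size=float(meta["voxel_size_mm"]),
        frame_times=np.asarray(meta["frame_times_ms"], dtype=float),
        venc=float(meta["venc_cm_per_s"]),
        heart_rate=meta.get("heart_rate_bpm"),
    )


_MASK_FILE = "mask.nii"
_MASK_META = "mask_meta.json"


def write_mask(mask: MaskVolume, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = mask.labels
    if mask.is_dynamic:
        arr = _to_nifti_order(arr)
    else:
        arr = np.transpose(arr, (2, 1, 0))
    nib.save(nib.Nifti1Image(arr.astype(np.int16), _affine(mask.voxel_size)), out / _MASK_FILE)
    meta = {
        "label_map": mask.label_map,
        "voxel_size_mm": mask.voxel_size,
        "slice_thickness_mm": mask.slice_thickness,
        "gap_mm": mask.gap,
    }
    (out / _MASK_META).write_text(json.dumps(meta, indent=1))
    return out


def read_mask(path: str | Path) -> MaskVolume:
    d = Path(path)
    missing = [n for n in (_MASK_FILE, _MASK_META) if not (d / n).exists()]
    if missing:
        raise FlowIOError(f"missing files in {d}: {missing}")
    meta = json.loads((d / _MASK_META).read_text())
    arr = np.asarray(nib.load(d / _MASK_FILE).dataobj)
    if arr.ndim == 4:
        arr = _from_nifti_order(arr)
    else:
        arr = np.transpose(arr, (2, 1, 0))
    return MaskVolume(
        labels=arr.astype(np.int32),
        label_map={k: int(v) for k, v in meta["label_map"].items()},
        voxel_size=float(meta["voxel_size_mm"]),
        slice_thickness=meta.get("slice_thickness_mm"),
        gap=float(meta.get("gap_mm", 0.0)),
    )


# ---------------------------------------------------------------------------
# Plane sets
# ---------------------------------------------------------------------------

def read_plane_set(path: str | Path) -> list:
    """Read a JSON plane-set file into :class:`~flow4d.planeflow.CutPlane` objects.

    Non-unit normals are normalized with a logged notice; a zero normal or a
    duplicated plane name is an error.  Unknown site names are accepted (free-text
    extension of the vocabulary) with a notice.
    """
    from .planeflow import CutPlane  # deferred to avoid an import cycle

    raw = json.loads(Path(path).read_text())
    entries = raw["planes"] if isinstance(raw, dict) else raw
    if not entries:
        logger.warning("plane set %s is empty", path)
        return []
    planes: list[CutPlane] = []
    seen: set[str] = set()
    for e in entries:
        validate_keys(
            e,
            {"name", "origin_mm", "normal", "half_extent_mm", "grid_step_mm", "lumen_source"},
            context=f"plane entry in {path}",
        )
        name = e["name"]
        if name in seen:
            raise FlowIOError(f"duplicate plane name {name!r} in {path}")
        seen.add(name)
        if name not in KNOWN_SITES:
            logger.info("plane site %r is outside the known vocabulary %s", name, sorted(KNOWN_SITES))
        normal = np.asarray(e["normal"], dtype=float)
        nrm = np.linalg.norm(normal)
        if nrm == 0:
            raise FlowIOError(f"plane {name!r}: normal must be nonzero")
        if not np.isclose(nrm, 1.0):
            logger.info("plane %r: normalizing non-unit normal (|n|=%.4g)", name, nrm)
        planes.append(
            CutPlane(
                name=name,
                origin=np.asarray(e["origin_mm"], dtype=float),
                normal=normal / nrm,
                half_extent=float(e.get("half_extent_mm", 20.0)),
                grid_step=float(e.get("grid_step_mm", 1.0)),
                lumen_source=e.get("lumen_source", "mask"),
            )
        )
    return planes


def write_plane_set(planes: Sequence, path: str | Path) -> Path:
    payload = {
        "planes": [
            {
                "name": p.name,
                "origin_mm": [float(v) for v in p.origin],
                "normal": [float(v) for v in p.normal],
                "half_extent_mm": p.half_extent,
                "grid_step_mm": p.grid_step,
                "lumen_source": p.lumen_source,
            }
            for p in planes
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


# ---------------------------------------------------------------------------
# Configs and tables
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file into a plain dict."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise FlowIOError(f"config {p} must contain a mapping at top level")
    return data


def validate_keys(d: Mapping, allowed: set[str], context: str = "config") -> None:
    """Reject unknown keys so typos never pass silently."""
    unknown = set(d) - set(allowed)
    if unknown:
        raise FlowIOError(
            f"{context}: unknown keys {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )


def results_table(records: Sequence[Mapping]) -> pd.DataFrame:
    """Assemble long-format results: (subject, condition, site, metric, value, unit).

    One record per (subject, condition, site, metric); units must be nonempty.
    """
    df = pd.DataFrame.from_records(
        records, columns=["subject", "condition", "site", "metric", "value", "unit"]
    )
    if len(df) and (df["unit"].isna() | (df["unit"] == "")).any():
        raise FlowIOError("every results record needs a nonempty unit")
    key = ["subject", "condition", "site", "metric"]
    if len(df) and df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)][key].drop_duplicates()
        raise FlowIOError(f"duplicate results records: {dupes.to_dict('records')}")
    return df
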