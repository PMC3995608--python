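"""Ventricular volumetry from segmentation stacks.

Volumes follow the slice-summation (Simpson) method used with stacked cine
imaging: per frame, the chamber volume is the sum over slices of the labelled
in-plane area times the slice increment (thickness + gap).  With isotropic
voxels and contiguous slices this reduces to voxel counting, which keeps the
analytic-ellipsoid oracle exact.

End-diastole and end-systole are taken as the extrema of the volume-time curve
rather than fixed frames: picking the largest and smallest volume is the
automatable equivalent of the reader's choice of end-diastolic and end-systolic
images.  Ejection fraction is reported as a fraction; a helper converts to
percent for resistance models that expect RVEF on the percent scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow_io import MaskVolume

logger = logging.getLogger("flow4d.volumetry")


class VolumetryError(ValueError):
    pass


@dataclass
class VolumeCurve:
    """Chamber volume (mL) per cardiac frame."""

    chamber: str
    times: np.ndarray  # ms
    volume: np.ndarray  # mL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.volume = np.asarray(self.volume, float)
        if self.times.shape != self.volume.shape:
            raise VolumetryError("times and volume must have equal length")
        if np.any(self.volume < 0):
            raise VolumetryError("volumes must be nonnegative")


@dataclass
class VentricularMetrics:
    """EDV/ESV-derived functional metrics for one chamber.

    Invariants: ``SV = EDV - ESV`` exactly, ``EF = SV / EDV`` in [0, 1],
    ``CO = SV * heart_rate`` in mL/min.
    """

    chamber: str
    edv: float  # mL
    esv: float  # mL
    sv: float  # mL
    ef: float  # fraction
    co: float  # mL/min
    heart_rate: float  # beats/min


def volume_curve(
    masks: MaskVolume,
    chamber_label: str,
    frame_times: np.ndarray,
) -> VolumeCurve:
    """Slice-summation volume of one labelled chamber at every frame.

    ``volume(f) = sum_slices area(slice) * (slice_thickness + gap)`` with
    ``area = labelled-voxel count * in-plane voxel area``.  An empty label at a
    single frame yields 0 mL with a warning; a label absent at all frames is an
    error.
    """
    if chamber_label not in masks.label_map:
        raise VolumetryError(
            f"label {chamber_label!r} not in mask (has {sorted(masks.label_map)})"
        )
    lab = masks.label_map[chamber_label]
    if not masks.is_dynamic:
        raise VolumetryError("per-frame masks are required for a volume curve")
    n_t = masks.labels.shape[0]
    if len(frame_times) != n_t:
        raise VolumetryError("frame_times length must match the mask's frame count")
    area_mm2 = masks.voxel_size**2
    dz = masks.slice_thickness + masks.gap
    vols = np.empty(n_t)
    for f in range(n_t):
        per_slice = (masks.labels[f] == lab).sum(axis=(1, 2))  # counts per z-slice
        vols[f] = per_slice.sum() * area_mm2 * dz / 1000.0  # mm^3 -> mL
        if vols[f] == 0:
            logger.warning("chamber %r empty at frame %d", chamber_label, f)
    if np.all(vols == 0):
        raise VolumetryError(f"label {chamber_label!r} is empty at every frame")
    return VolumeCurve(chamber=chamber_label, times=np.asarray(frame_times, float), volume=vols)


def ventricular_metrics(curve: VolumeCurve, heart_rate: float) -> VentricularMetrics:
    """EDV, ESV, SV, EF and CO from a volume-time curve.

    EDV/ESV are the curve extrema.  ``heart_rate`` is in beats/min; CO is
    reported in mL/min.
    """
    if len(curve.volume) < 2:
        raise VolumetryError("need at least 2 frames")
    edv = float(curve.volume.max())
    esv = float(curve.volume.min())
    if edv == 0:
        raise VolumetryError("EDV is zero; ejection fraction undefined")
    sv = edv - esv
    return VentricularMetrics(
        chamber=curve.chamber,
        edv=edv,
        esv=esv,
        sv=sv,
        ef=sv / edv,
        co=sv * heart_rate,
        heart_rate=heart_rate,
    )


def ef_percent(metrics: VentricularMetrics) -> float:
    """Ejection fraction on the percent scale (as resistance models expect)."""
    return 100.0 * metrics.ef


def average_slices(stack: np.ndarray, k: int = 3, slice_axis: int = 0) -> np.ndarray:
    """Average non-overlapping groups of ``k`` contiguous slices.

    Mirrors the acquisition-side trick of averaging three contiguous slices to
    reduce the number needing manual segmentation.  A trailing remainder group is
    averaged as-is; the effective slice thickness of group ``g`` is its member
    count times the input thickness.
    """
    if k < 1:
        raise VolumetryError("k must be at least 1")
    stack = np.asarray(stack)
    stack = np.moveaxis(stack, slice_axis, 0)
    n = stack.shape[0]
    if n < k:
        raise VolumetryError(f"need at least k={k} slices, got {n}")
    groups = [stack[i : i + k].mean(axis=0) for i in range(0, n, k)]
    return np.moveaxis(np.stack(groups, axis=0), 0, slice_axis)


def reformat_short_axis(
    volume: np.ndarray,
    origin: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    voxel_size: float,
    slice_spacing: float,
    out_shape: tuple[int, int, int],
    in_plane_spacing: float | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Trilinearly resample a volume onto an oblique (e.g. short-axis) stack.

    Parameters
    ----------
    volume : (Z, Y, X) array
        Source volume on the isotropic grid (voxel-center convention).
    origin : (3,) mm
        World position of the output voxel (slice 0, row 0, col 0).
    u, v : (3,) unit vectors
        In-plane row/column directions; must be orthonormal.  Slices advance
        along ``cross(u, v)``.
    slice_spacing : mm
        Distance between output slices.
    out_shape : (n_slices, n_rows, n_cols)

    Out-of-volume samples are set to ``background``; a fully-background result
    logs a warning.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if not (
        np.isclose(np.linalg.norm(u), 1.0)
        and np.isclose(np.linalg.norm(v), 1.0)
        and np.isclose(np.dot(u, v), 0.0, atol=1e-8)
    ):
        raise VolumetryError("in-plane axes must be orthonormal unit vectors")
    if in_plane_spacing is None:
        in_plane_spacing = voxel_size
    n = np.cross(u, v)
    ns, nr, nc = out_shape
    S, R, C = np.meshgrid(np.arange(ns), np.arange(nr), np.arange(nc), indexing="ij")
    pts = (
        np.asarray(origin, float)[None, :]
        + S.reshape(-1, 1) * slice_spacing * n[None, :]
        + R.reshape(-1, 1) * in_plane_spacing * u[None, :]
        + C.reshape(-1, 1) * in_plane_spacing * v[None, :]
    )
    idx = (pts / voxel_size - 0.5)[:, ::-1].T  # (z, y, x) fractional indices
    out = ndimage.map_coordinates(
        np.asarray(volume, float), idx, order=1, mode="constant", cval=background
    ).reshape(out_shape)
    if np.allclose(out, background):
        logger.warning("short-axis reformat lies fully outside the source volume")
    return out
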