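"""Cutplane flow quantification, jet peak velocity, and streamline tracing.

The measurement model follows standard 4D-flow practice: an oriented 2D plane is
placed across a vessel, through-plane velocity (velocity vector dotted with the
plane normal) is sampled on a regular in-plane grid by trilinear interpolation,
and the volumetric flow rate at each cardiac frame is the surface integral of
through-plane velocity over the lumen.

Lumen handling.  The lumen on the plane comes from a labelled 3D mask sampled
nearest-neighbour (default) or, as a fallback, from a speed threshold at 10% of
the in-plane maximum.  The *flux* integral uses the lumen dilated by one voxel:
trilinear interpolation spreads the velocity of wall voxels into a one-voxel
partial-volume ramp outside the voxelized lumen, and integrating over the dilated
support recovers that flux (without it, flow through a ~6 mm radius vessel at
1.3 mm voxels is underestimated by ~10%).  Mean and peak velocity use the
undilated lumen: mean velocity is flow divided by the undilated lumen area,
i.e. the usual cross-sectional average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .flow_io import FlowDataset, MaskVolume

logger = logging.getLogger("flow4d.planeflow")


class PlaneFlowError(ValueError):
    """Raised when a plane or ROI cannot be measured."""


# ---------------------------------------------------------------------------
# Frame-series primitives (shared with the phantom's analytic ground truth)
# ---------------------------------------------------------------------------

def net_flow_series(times_ms: np.ndarray, q_ml_s: np.ndarray, cycle_ms: float) -> float:
    """Periodic trapezoidal integral of a flow-rate series over one cycle, in mL.

    The first frame is re-appended at ``cycle_ms`` to close the cycle.
    """
    t = np.append(np.asarray(times_ms, float), cycle_ms)
    q = np.append(np.asarray(q_ml_s, float), q_ml_s[0])
    return float(np.trapezoid(q, t) / 1000.0)


def time_to_peak_flow_series(times_ms: np.ndarray, q_ml_s: np.ndarray) -> float:
    """Time (ms from frame 0) of the maximal flow rate; earliest frame wins ties."""
    q = np.asarray(q_ml_s, float)
    return float(np.asarray(times_ms, float)[int(np.argmax(q))])


def time_to_peak_accel_series(times_ms: np.ndarray, q_ml_s: np.ndarray) -> float:
    """Time of the steepest inter-frame flow increase before the flow peak.

    The forward difference ``(q[f+1] - q[f]) / dt`` is scanned over intervals
    ending at or before the time-to-peak-flow frame; the reported time is the
    start of the winning interval, earliest interval on ties.  If the flow peaks
    at frame 0 there is no rising interval and 0 ms is returned.
    """
    t = np.asarray(times_ms, float)
    q = np.asarray(q_ml_s, float)
    f_peak = int(np.argmax(q))
    if f_peak == 0:
        return 0.0
    accel = np.diff(q[: f_peak + 1]) / np.diff(t[: f_peak + 1])
    return float(t[int(np.argmax(accel))])


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CutPlane:
    """An oriented square sampling plane.

    ``origin`` (mm) is the plane center, ``normal`` the unit through-plane
    direction, ``half_extent`` the half-width of the sampled square (mm) and
    ``grid_step`` the in-plane sampling pitch (mm).
    """

    name: str
    origin: np.ndarray
    normal: np.ndarray
    half_extent: float
    grid_step: float
    lumen_source: str = "mask"  # "mask" | "speed_threshold"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.normal = np.asarray(self.normal, float)
        nrm = np.linalg.norm(self.normal)
        if nrm == 0:
            raise PlaneFlowError(f"plane {self.name!r}: zero normal")
        self.normal = self.normal / nrm
        if self.half_extent <= 0 or self.grid_step <= 0:
            raise PlaneFlowError(f"plane {self.name!r}: extent and step must be positive")
        if self.lumen_source not in ("mask", "speed_threshold"):
            raise PlaneFlowError(f"plane {self.name!r}: unknown lumen_source")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane vectors, chosen deterministically."""
        n = self.normal
        e = np.zeros(3)
        e[int(np.argmin(np.abs(n)))] = 1.0
        u = np.cross(n, e)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def grid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(P, 3) world points of the sampling grid and the grid's 2D shape."""
        offs = np.arange(-self.half_extent, self.half_extent + self.grid_step / 2, self.grid_step)
        u, v = self.basis()
        S, T = np.meshgrid(offs, offs, indexing="ij")
        pts = (
            self.origin[None, :]
            + S.reshape(-1, 1) * u[None, :]
            + T.reshape(-1, 1) * v[None, :]
        )
        return pts, S.shape


@dataclass
class PlaneSample:
    """One frame's in-plane sampling: through-plane velocity and lumen masks."""

    vtp: np.ndarray  # (A, B) through-plane velocity, cm/s
    lumen: np.ndarray  # (A, B) bool, undilated lumen
    flux_region: np.ndarray  # (A, B) bool, lumen dilated by one voxel
    in_bounds: np.ndarray  # (A, B) bool


@dataclass
class FlowCurve:
    """Per-frame flow quantities through one plane."""

    site: str
    times: np.ndarray  # ms
    q: np.ndarray  # mL/s
    mean_velocity: np.ndarray  # cm/s, flow / lumen area
    peak_velocity: np.ndarray  # cm/s, signed value of largest |v| in lumen
    lumen_area: np.ndarray  # cm^2
    cycle_duration: float  # ms

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("q", "mean_velocity", "peak_velocity", "lumen_area"):
            if len(getattr(self, name)) != n:
                raise PlaneFlowError(f"FlowCurve.{name}: length mismatch")
        if np.any(self.lumen_area < 0):
            raise PlaneFlowError("lumen_area must be nonnegative")


@dataclass
class FlowSummary:
    """Cycle-level summary of a flow curve."""

    site: str
    net_flow: float  # mL/cycle
    ttp_flow: float  # ms
    ttp_accel: float  # ms
    peak_velocity_over_cycle: float  # cm/s (|.|); the TRV when site == "TV"
    mean_velocity_over_cycle: float  # cm/s


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _world_to_index(pts_xyz: np.ndarray, voxel_size: float) -> np.ndarray:
    """(P, 3) world mm -> (3, P) fractional indices in (z, y, x) order."""
    idx = pts_xyz / voxel_size - 0.5
    return idx[:, ::-1].T  # (x,y,z) columns -> rows (z,y,x)


def interp_velocity(ds: FlowDataset, pts_xyz: np.ndarray, frame: int) -> np.ndarray:
    """Trilinear velocity vectors (P, 3) in cm/s at world points; 0 outside."""
    coords = _world_to_index(pts_xyz, ds.voxel_size)
    out = np.empty((pts_xyz.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            ds.velocity[c, frame], coords, order=1, mode="constant", cval=0.0
        )
    return out


def points_in_volume(ds: FlowDataset, pts_xyz: np.ndarray) -> np.ndarray:
    ext = np.array(ds.grid_shape[::-1], float) * ds.voxel_size  # (x, y, z)
    return np.all((pts_xyz >= 0) & (pts_xyz <= ext), axis=1)


# ---------------------------------------------------------------------------
# Plane sampling
# ---------------------------------------------------------------------------

def _lumen_on_plane(
    ds: FlowDataset,
    plane: CutPlane,
    pts: np.ndarray,
    shape: tuple[int, int],
    frame: int,
    vtp: np.ndarray,
    mask: MaskVolume | None,
    speed: np.ndarray,
) -> np.ndarray:
    if plane.lumen_source == "mask":
        if mask is None:
            raise PlaneFlowError(
                f"plane {plane.name!r}: lumen_source='mask' but no mask supplied"
            )
        if plane.name not in mask.label_map:
            raise PlaneFlowError(
                f"plane {plane.name!r}: no such label in mask (has {sorted(mask.label_map)})"
            )
        coords = _world_to_index(pts, mask.voxel_size)
        labels = ndimage.map_coordinates(
            mask.frame(frame), coords, order=0, mode="constant", cval=0
        )
        return (labels == mask.label_map[plane.name]).reshape(shape)
    # speed-threshold fallback: 10% of the in-plane maximum speed at this frame
    smax = speed.max()
    if smax == 0:
        return np.zeros(shape, dtype=bool)
    return (speed >= 0.1 * smax).reshape(shape)


def sample_plane(
    ds: FlowDataset,
    plane: CutPlane,
    frame: int,
    mask: MaskVolume | None = None,
) -> PlaneSample:
    """Sample through-plane velocity and lumen membership on the plane grid.

    Points outside the volume are non-lumen and contribute zero velocity.
    """
    pts, shape = plane.grid_points()
    inb = points_in_volume(ds, pts)
    if not inb.any():
        raise PlaneFlowError(f"plane {plane.name!r} lies fully outside the volume")
    vel = interp_velocity(ds, pts, frame)
    vtp = (vel @ plane.normal).reshape(shape)
    speed = np.linalg.norm(vel, axis=1)
    lumen = _lumen_on_plane(ds, plane, pts, shape, frame, vtp, mask, speed)
    lumen &= inb.reshape(shape)
    # one voxel of dilation (in grid cells, Chebyshev metric) plus one extra ring
    # so the flux region covers the full partial-volume ramp of the wall voxels
    n_dilate = max(1, int(np.ceil(ds.voxel_size / plane.grid_step))) + 1
    flux_region = (
        ndimage.binary_dilation(lumen, structure=np.ones((3, 3), bool), iterations=n_dilate)
        & inb.reshape(shape)
    )
    return PlaneSample(vtp=vtp, lumen=lumen, flux_region=flux_region, in_bounds=inb.reshape(shape))


def auto_orient(ds: FlowDataset, seed_point: np.ndarray, frame: int) -> np.ndarray:
    """Unit normal aligned with the local mean flow direction.

    Averages velocity vectors over voxel centers within a 3-voxel-radius ball of
    ``seed_point`` at the given (typically peak-systolic) frame.
    """
    seed_point = np.asarray(seed_point, float)
    h = ds.voxel_size
    r_vox = 3
    center_idx = seed_point / h - 0.5  # (x, y, z)
    nz, ny, nx = ds.grid_shape
    ranges = []
    for dim, ci in zip((nx, ny, nz), center_idx):
        lo = max(0, int(np.floor(ci)) - r_vox)
        hi = min(dim - 1, int(np.ceil(ci)) + r_vox)
        if lo > hi:
            raise PlaneFlowError("seed point lies outside the volume")
        ranges.append(np.arange(lo, hi + 1))
    IX, IY, IZ = np.meshgrid(*ranges, indexing="ij")
    d2 = (IX - center_idx[0]) ** 2 + (IY - center_idx[1]) ** 2 + (IZ - center_idx[2]) ** 2
    sel = d2 <= r_vox**2
    if not sel.any():
        raise PlaneFlowError("seed neighborhood is empty")
    mean_v = np.array(
        [ds.velocity[c, frame][IZ[sel], IY[sel], IX[sel]].mean() for c in range(3)]
    )
    nrm = np.linalg.norm(mean_v)
    if nrm < 1e-6:
        raise PlaneFlowError(
            "no net flow near the seed point; supply the plane normal manually"
        )
    return mean_v / nrm


# ---------------------------------------------------------------------------
# Flow curves and summaries
# ---------------------------------------------------------------------------

def flow_curve(
    ds: FlowDataset,
    plane: CutPlane,
    mask: MaskVolume | None = None,
) -> FlowCurve:
    """Per-frame flow rate, mean and peak velocity, and lumen area through a plane.

    ``q(f)`` sums through-plane velocity times the grid-cell area over the flux
    region (mL/s); mean velocity is ``q / lumen_area``; peak velocity is the
    largest-|.| through-plane sample in the undilated lumen.
    """
    n_t = ds.n_frames
    cell_cm2 = plane.grid_step**2 / 100.0
    q = np.zeros(n_t)
    mean_v = np.zeros(n_t)
    peak_v = np.zeros(n_t)
    area = np.zeros(n_t)
    any_lumen = False
    for f in range(n_t):
        s = sample_plane(ds, plane, f, mask=mask)
        area[f] = s.lumen.sum() * cell_cm2
        if not s.lumen.any():
            continue
        any_lumen = True
        q[f] = s.vtp[s.flux_region].sum() * cell_cm2
        mean_v[f] = q[f] / area[f]
        in_lumen = s.vtp[s.lumen]
        peak_v[f] = in_lumen[np.argmax(np.abs(in_lumen))]
    if not any_lumen:
        raise PlaneFlowError(f"plane {plane.name!r}: empty lumen at every frame")
    return FlowCurve(
        site=plane.name,
        times=ds.frame_times.copy(),
        q=q,
        mean_velocity=mean_v,
        peak_velocity=peak_v,
        lumen_area=area,
        cycle_duration=ds.cycle_duration,
    )


def net_flow(curve: FlowCurve) -> float:
    """Net flow per cycle (mL), periodic trapezoid of the flow-rate series."""
    if len(curve.times) < 4:
        raise PlaneFlowError("need at least 4 frames to integrate a cycle")
    return net_flow_series(curve.times, curve.q, curve.cycle_duration)


def time_to_peak_flow(curve: FlowCurve) -> float:
    if len(curve.times) < 4:
        raise PlaneFlowError("need at least 4 frames")
    return time_to_peak_flow_series(curve.times, curve.q)


def time_to_peak_acceleration(curve: FlowCurve) -> float:
    if len(curve.times) < 4:
        raise PlaneFlowError("need at least 4 frames")
    return time_to_peak_accel_series(curve.times, curve.q)


def summarize(curve: FlowCurve) -> FlowSummary:
    return FlowSummary(
        site=curve.site,
        net_flow=net_flow(curve),
        ttp_flow=time_to_peak_flow(curve),
        ttp_accel=time_to_peak_acceleration(curve),
        peak_velocity_over_cycle=float(np.max(np.abs(curve.peak_velocity))),
        mean_velocity_over_cycle=float(np.mean(curve.mean_velocity)),
    )


@dataclass
class PeakVelocityResult:
    value: float  # cm/s, |through-plane velocity| at the maximum
    frame: int
    position: np.ndarray  # world mm of the maximizing grid point


def peak_jet_velocity(
    ds: FlowDataset,
    plane: CutPlane,
    mask: MaskVolume | None = None,
    restrict_to_lumen: bool = False,
) -> PeakVelocityResult:
    """Peak |through-plane velocity| over the plane ROI and all frames (the TRV).

    By default the ROI is every in-volume grid point of the plane; with
    ``restrict_to_lumen`` the undilated lumen is used instead.
    """
    pts, shape = plane.grid_points()
    best = PeakVelocityResult(value=-1.0, frame=-1, position=np.zeros(3))
    for f in range(ds.n_frames):
        s = sample_plane(ds, plane, f, mask=mask)
        roi = s.lumen if restrict_to_lumen else s.in_bounds
        if not roi.any():
            continue
        vabs = np.where(roi, np.abs(s.vtp), -np.inf)
        flat = int(np.argmax(vabs))
        if vabs.ravel()[flat] > best.value:
            best = PeakVelocityResult(
                value=float(vabs.ravel()[flat]), frame=f, position=pts[flat]
            )
    if best.frame < 0:
        raise PlaneFlowError(f"plane {plane.name!r}: empty ROI")
    return best


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

def trace_streamlines(
    ds: FlowDataset,
    seed_points: np.ndarray,
    frame: int,
    step: float | None = None,
    max_len: int = 2000,
    speed_tol: float = 1e-2,
) -> list[np.ndarray]:
    """Fixed-step 4th-order (RK4) streamlines of one frame's velocity field.

    ``step`` is the spatial step in mm (default: voxel/4).  Integration is in
    arc length — each RK4 step advances ~``step`` mm along the local flow
    direction — and terminates at the volume boundary, after ``max_len`` steps,
    or where speed falls below ``speed_tol`` cm/s.  Seeds outside the volume are
    skipped with a warning.
    """
    if step is None:
        step = ds.voxel_size / 4.0
    seed_points = np.atleast_2d(np.asarray(seed_points, float))
    polylines: list[np.ndarray] = []

    def vfield(p: np.ndarray) -> np.ndarray:
        return interp_velocity(ds, p[None, :], frame)[0]

    for seed in seed_points:
        if not points_in_volume(ds, seed[None, :])[0]:
            logger.warning("streamline seed %s is outside the volume; skipped", seed)
            continue
        pts = [seed.copy()]
        p = seed.copy()
        for _ in range(max_len):
            v1 = vfield(p)
            s1 = np.linalg.norm(v1)
            if s1 < speed_tol:
                break
            dt = step / s1  # arc-length parametrization
            k1 = v1
            k2 = vfield(p + 0.5 * dt * k1)
            k3 = vfield(p + 0.5 * dt * k2)
            k4 = vfield(p + dt * k3)
            p_new = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not points_in_volume(ds, p_new[None, :])[0]:
                break
            pts.append(p_new)
            p = p_new
        polylines.append(np.array(pts))
    return polylines
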