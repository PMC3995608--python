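"""Shared fixtures: small phantoms and session-scoped study runs.

The end-to-end study is expensive (12 phantoms at 64^3 x 20 frames), so each
noise condition is run once per session and shared between the pipeline tests
and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import flow4d as f4
from flow4d.study import StudyConfig, run_study


def steady_tube_spec(
    radius_mm: float = 10.0,
    q_ml_s: float = 10 * np.pi,
    profile: str = "plug",
    grid: int = 48,
    n_frames: int = 20,
    noise_sd: float = 0.0,
    axis: str = "z",
    seed: int = 0,
) -> f4.PhantomSpec:
    """A straight constant-flow tube through the grid center."""
    h = 1.3
    c = grid * h / 2.0
    lo, hi = 5.0, grid * h - 5.0
    ends = {
        "z": ((c, c, lo), (c, c, hi)),
        "x": ((lo, c, c), (hi, c, c)),
        "xy": ((lo, lo, c), (hi, hi, c)),
    }[axis]
    wf = f4.WaveformSpec(
        cycle_duration=1000.0,
        n_frames=n_frames,
        systole_fraction=0.5,
        peak_flow=q_ml_s,
        diastolic_baseline=q_ml_s,
    )
    return f4.PhantomSpec(
        grid_shape=(grid, grid, grid),
        waveforms={"tube": wf},
        vessels=(f4.VesselSegment("tube", *ends, radius=radius_mm, profile=profile),),
        noise_sd=noise_sd,
        seed=seed,
    )


def bifurcation_spec(noise_sd: float = 0.0, seed: int = 11) -> f4.PhantomSpec:
    """The default cohort's MPA->RPA/LPA + aorta geometry at 64^3 x 20."""
    member = f4.make_cohort(1, f4.CohortParams(noise_sd=noise_sd), seed=seed)[0]
    return member.spec


def center_plane(spec: f4.PhantomSpec, name: str = "tube", **kw) -> f4.CutPlane:
    v = next(x for x in spec.vessels if x.name == name)
    mid = (np.asarray(v.start_point) + np.asarray(v.end_point)) / 2.0
    kw.setdefault("half_extent", 2.0 * v.radius)
    kw.setdefault("grid_step", spec.voxel_size / 2.0)
    return f4.CutPlane(name, origin=mid, normal=v.axis, **kw)


@pytest.fixture(scope="session")
def study_default(tmp_path_factory):
    """The default 6-subject study (noise 5 cm/s), with outputs on disk."""
    out = tmp_path_factory.mktemp("study_default")
    report = run_study(StudyConfig(n_subjects=6, seed=1, out_dir=str(out)))
    return report, out


@pytest.fixture(scope="session")
def study_noiseless():
    """The same cohort measured without velocity noise."""
    return run_study(StudyConfig(n_subjects=6, seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def study_high_noise():
    """The same cohort at triple the default velocity noise."""
    return run_study(StudyConfig(n_subjects=6, seed=1, noise_sd=15.0))
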