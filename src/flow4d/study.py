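"""End-to-end desk-scale study on a synthetic paired pre/post cohort.

Pipeline order: generate the cohort → quantify flow at the tricuspid valve, MPA,
RPA, LPA and aorta cutplanes → ventricular volumetry from the magnitude-image
segmentations → assemble per-measurement hemodynamic records → fit the linear
TRV/Q_P → PVR model against the catheter reference → Bland-Altman agreement of
every PVR estimate against the reference → tables, figures, and a ground-truth
recovery report.

All randomness flows from the single master seed through per-subject spawned
streams, so a fixed seed gives byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, hemodynamics as hemo, planeflow, volumetry
from .flow_io import MaskVolume, results_table, validate_keys
from .phantom import (
    CohortMember,
    CohortParams,
    GroundTruth,
    PhantomSpec,
    make_cohort,
    make_ventricle_phantom,
    make_vessel_phantom,
)
from .planeflow import CutPlane, FlowSummary

logger = logging.getLogger("flow4d.study")

_CSV_FLOAT_FORMAT = "%.10g"


class StudyError(RuntimeError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Study-level knobs; everything else comes from :class:`CohortParams`."""

    n_subjects: int = 6
    seed: int = 0
    model: str = "refit"  # "refit" | "paper"
    noise_sd: float = 5.0  # cm/s velocity noise
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_frames: int = 20
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("refit", "paper"):
            raise StudyError(f"model must be 'refit' or 'paper', got {self.model!r}")
        if self.n_subjects < 1:
            raise StudyError("n_subjects must be at least 1")

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            noise_sd=self.noise_sd,
            grid_shape=self.grid_shape,
            n_frames=self.n_frames,
        )


_CONFIG_KEYS = {
    "n_subjects", "seed", "model", "noise_sd", "grid_shape", "n_frames", "out_dir",
}


def study_config_from_dict(d: dict) -> StudyConfig:
    """Build a config from a JSON/YAML-loaded mapping; unknown keys are rejected."""
    validate_keys(d, _CONFIG_KEYS, context="study config")
    if "grid_shape" in d:
        d = {**d, "grid_shape": tuple(d["grid_shape"])}
    return StudyConfig(**d)


# ---------------------------------------------------------------------------
# Per-subject measurement
# ---------------------------------------------------------------------------

@dataclass
class SubjectMeasurement:
    """Everything measured from one synthetic acquisition."""

    subject: str
    condition: str
    flow: dict[str, FlowSummary]  # per site
    trv: float  # cm/s
    metrics: dict[str, volumetry.VentricularMetrics]  # per chamber
    record: hemo.HemodynamicRecord


def default_planes(spec: PhantomSpec) -> list[CutPlane]:
    """Cutplanes perpendicular to each vessel at mid-length, plus the jet plane.

    Half-extent is twice the vessel radius; the in-plane step is half a voxel,
    which keeps net flow stable under grid refinement.
    """
    planes = []
    step = spec.voxel_size / 2.0
    for v in spec.vessels:
        mid = (np.asarray(v.start_point, float) + np.asarray(v.end_point, float)) / 2.0
        planes.append(
            CutPlane(
                name=v.name,
                origin=mid,
                normal=v.axis,
                half_extent=2.0 * v.radius,
                grid_step=step,
            )
        )
    if spec.jet is not None:
        j = spec.jet
        origin = np.asarray(j.origin, float) + 0.5 * j.axial_length * np.asarray(
            j.direction, float
        )
        planes.append(
            CutPlane(
                name="TV",
                origin=origin,
                normal=np.asarray(j.direction, float),
                half_extent=3.0 * j.core_radius,
                grid_step=step,
            )
        )
    return planes


def measure_subject(member: CohortMember) -> SubjectMeasurement:
    """Run flow quantification and volumetry on one cohort member's phantoms."""
    sid, cond = member.subject_id, member.condition
    try:
        ds, truth = make_vessel_phantom(member.spec)
        planes = {p.name: p for p in default_planes(member.spec)}
        flow: dict[str, FlowSummary] = {}
        for site in ("MPA", "RPA", "LPA", "aorta"):
            curve = planeflow.flow_curve(ds, planes[site], mask=truth.lumen)
            flow[site] = planeflow.summarize(curve)
        trv = planeflow.peak_jet_velocity(ds, planes["TV"], mask=truth.lumen).value
    except Exception as e:
        raise StudyError(f"flow quantification failed for {sid}/{cond}: {e}") from e

    try:
        vds, masks, _ = make_ventricle_phantom(member.spec)
        metrics = {}
        for chamber in ("RV", "LV"):
            curve = volumetry.volume_curve(masks, chamber, vds.frame_times)
            metrics[chamber] = volumetry.ventricular_metrics(curve, vds.derived_heart_rate())
    except Exception as e:
        raise StudyError(f"volumetry failed for {sid}/{cond}: {e}") from e

    hr = member.spec.heart_rate
    qp_ml = flow["MPA"].net_flow
    qp_lmin = hemo.ml_cycle_to_l_min(qp_ml, hr)
    ratio, convention = hemo.trv_qp_ratio(trv, qp_lmin)
    record = hemo.HemodynamicRecord(
        subject=sid,
        condition=cond,
        mpap=member.rhc.mpap,
        pcwp=member.rhc.pcwp,
        co_thermodilution=member.rhc.co,
        trv=trv,
        qp_ml_cycle=qp_ml,
        qp_l_min=qp_lmin,
        qs_ml_cycle=flow["aorta"].net_flow,
        pvr_rhc=hemo.pvr_rhc(member.rhc.mpap, member.rhc.pcwp, member.rhc.co),
        pvr_cmr=hemo.pvr_cmr(
            flow["MPA"].mean_velocity_over_cycle,
            volumetry.ef_percent(metrics["RV"]),
        ),
        ratio_convention=convention,
    )
    return SubjectMeasurement(
        subject=sid, condition=cond, flow=flow, trv=trv, metrics=metrics, record=record
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    config: StudyConfig
    measurements: list[SubjectMeasurement]
    records: list[hemo.HemodynamicRecord]
    model: hemo.PVRModelCoefficients
    fit: agreement.LinearFit  # TRV/Q_P ratio vs PVR_RHC
    volumes_table: pd.DataFrame
    flow_table: pd.DataFrame
    ttp_table: pd.DataFrame
    pvr_table: pd.DataFrame
    agreement_summary: dict
    recovery: pd.DataFrame


def _ratio(rec: hemo.HemodynamicRecord) -> float:
    return hemo.trv_qp_ratio(rec.trv, rec.qp_l_min)[0]


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline; deterministic under ``config.seed``."""
    logger.info("generating cohort: %d subjects, seed %d", config.n_subjects, config.seed)
    cohort = make_cohort(config.n_subjects, config.cohort_params(), seed=config.seed)

    measurements = [measure_subject(m) for m in cohort]
    records = [m.record for m in measurements]

    ratios = np.array([_ratio(r) for r in records])
    pvr_ref = np.array([r.pvr_rhc for r in records])
    fit = agreement.fit_linear(ratios, pvr_ref)
    if config.model == "refit":
        model = hemo.PVRModelCoefficients(
            slope=fit.slope, intercept=fit.intercept, source="refit"
        )
    else:
        model = hemo.PAPER_MODEL
    for r in records:
        r.pvr_4dflow = hemo.pvr_4dflow(_ratio(r), model)

    volumes_table = _volumes_table(measurements)
    flow_table = _flow_table(measurements)
    ttp_table = _ttp_table(measurements)
    pvr_table = _pvr_table(records)

    pvr_4d = np.array([r.pvr_4dflow for r in records])
    pvr_cmr_arr = np.array([r.pvr_cmr for r in records])
    ba_4d = agreement.bland_altman(pvr_4d, pvr_ref)
    ba_cmr = agreement.bland_altman(pvr_cmr_arr, pvr_ref)
    mpap_fit = agreement.fit_linear(ratios, np.array([r.mpap for r in records]))
    agreement_summary = {
        "seed": config.seed,
        "n_records": len(records),
        "model": {
            "source": model.source,
            "slope": model.slope,
            "intercept": model.intercept,
            "ratio_convention": model.ratio_convention,
        },
        "ratio_vs_pvr_rhc": {"pearson_r": fit.pearson_r, "slope": fit.slope,
                             "intercept": fit.intercept, "n": fit.n},
        "ratio_vs_mpap": {"pearson_r": mpap_fit.pearson_r},
        "bland_altman_pvr4dflow_vs_rhc": vars(ba_4d),
        "bland_altman_pvrcmr_vs_rhc": vars(ba_cmr),
        "difference_direction": "estimate minus reference",
    }

    truths = {(m.subject_id, m.condition): m.truth for m in cohort}
    recovery = recovery_report(measurements, truths)

    report = StudyReport(
        config=config,
        measurements=measurements,
        records=records,
        model=model,
        fit=fit,
        volumes_table=volumes_table,
        flow_table=flow_table,
        ttp_table=ttp_table,
        pvr_table=pvr_table,
        agreement_summary=agreement_summary,
        recovery=recovery,
    )
    if config.out_dir is not None:
        write_report(report, Path(config.out_dir))
    return report


def _volumes_table(measurements: list[SubjectMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for chamber, met in m.metrics.items():
            for metric, value, unit in (
                ("EDV", met.edv, "mL"),
                ("ESV", met.esv, "mL"),
                ("SV", met.sv, "mL"),
                ("EF", met.ef, "fraction"),
                ("CO", met.co, "mL/min"),
            ):
                rows.append(
                    dict(subject=m.subject, condition=m.condition, site=chamber,
                         metric=metric, value=value, unit=unit)
                )
    return results_table(rows)


def _flow_table(measurements: list[SubjectMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for site, s in m.flow.items():
            rows.append(
                dict(subject=m.subject, condition=m.condition, site=site,
                     metric="net_flow", value=s.net_flow, unit="mL/cycle")
            )
        rows.append(
            dict(subject=m.subject, condition=m.condition, site="RPA+LPA",
                 metric="net_flow",
                 value=m.flow["RPA"].net_flow + m.flow["LPA"].net_flow,
                 unit="mL/cycle")
        )
        rpa_pct, lpa_pct = hemo.relative_branch_flow(
            m.flow["RPA"].net_flow, m.flow["LPA"].net_flow
        )
        rows.append(
            dict(subject=m.subject, condition=m.condition, site="RPA",
                 metric="relative_flow", value=rpa_pct, unit="percent")
        )
        rows.append(
            dict(subject=m.subject, condition=m.condition, site="LPA",
                 metric="relative_flow", value=lpa_pct, unit="percent")
        )
        rows.append(
            dict(subject=m.subject, condition=m.condition, site="global",
                 metric="Qp/Qs",
                 value=hemo.qp_qs(m.flow["MPA"].net_flow, m.flow["aorta"].net_flow),
                 unit="ratio")
        )
    return results_table(rows)


def _ttp_table(measurements: list[SubjectMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for site in ("MPA", "RPA", "LPA"):
            s = m.flow[site]
            rows.append(
                dict(subject=m.subject, condition=m.condition, site=site,
                     metric="TTP_flow", value=s.ttp_flow, unit="ms")
            )
            rows.append(
                dict(subject=m.subject, condition=m.condition, site=site,
                     metric="TTP_acceleration", value=s.ttp_accel, unit="ms")
            )
    return results_table(rows)


def _pvr_table(records: list[hemo.HemodynamicRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject=r.subject,
                condition=r.condition,
                mpap_mmHg=r.mpap,
                pcwp_mmHg=r.pcwp,
                co_L_min=r.co_thermodilution,
                trv_cm_s=r.trv,
                qp_mL_cycle=r.qp_ml_cycle,
                qp_L_min=r.qp_l_min,
                qs_mL_cycle=r.qs_ml_cycle,
                trv_qp_ratio=_ratio(r),
                ratio_convention=r.ratio_convention,
                pvr_rhc_wu=r.pvr_rhc,
                pvr_cmr_wu=r.pvr_cmr,
                pvr_4dflow_wu=r.pvr_4dflow,
            )
            for r in records
        ]
    )


def recovery_report(
    measurements: list[SubjectMeasurement],
    truths: dict[tuple[str, str], GroundTruth],
) -> pd.DataFrame:
    """Absolute and relative error of every measured quantity vs ground truth."""
    rows = []
    for m in measurements:
        key = (m.subject, m.condition)
        if key not in truths:
            raise StudyError(f"no ground truth for subject {key}")
        t = truths[key]

        def add(metric: str, measured: float, true: float, unit: str) -> None:
            err = measured - true
            rows.append(
                dict(subject=m.subject, condition=m.condition, metric=metric,
                     measured=measured, truth=true, abs_error=abs(err),
                     rel_error=abs(err) / abs(true) if true != 0 else np.nan,
                     unit=unit)
            )

        for site in ("MPA", "RPA", "LPA", "aorta"):
            add(f"net_flow_{site}", m.flow[site].net_flow, t.net_flow[site], "mL/cycle")
        add("TRV", m.trv, t.jet_peak_velocity, "cm/s")
        for chamber in ("RV", "LV"):
            met = m.metrics[chamber]
            add(f"EDV_{chamber}", met.edv, t.edv[chamber], "mL")
            add(f"ESV_{chamber}", met.esv, t.esv[chamber], "mL")
            add(f"SV_{chamber}", met.sv, t.edv[chamber] - t.esv[chamber], "mL")
            add(
                f"EF_{chamber}",
                met.ef,
                (t.edv[chamber] - t.esv[chamber]) / t.edv[chamber],
                "fraction",
            )
        add(
            "Qp/Qs",
            hemo.qp_qs(m.flow["MPA"].net_flow, m.flow["aorta"].net_flow),
            t.net_flow["MPA"] / t.net_flow["aorta"],
            "ratio",
        )
        rpa_pct, _ = hemo.relative_branch_flow(
            m.flow["RPA"].net_flow, m.flow["LPA"].net_flow
        )
        rpa_true, _ = hemo.relative_branch_flow(t.net_flow["RPA"], t.net_flow["LPA"])
        add("relative_flow_RPA", rpa_pct, rpa_true, "percent")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_report(report: StudyReport, out_dir: Path) -> None:
    """CSV tables, a JSON summary and figures; deterministic byte content."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("volumes", report.volumes_table),
        ("flows", report.flow_table),
        ("ttp", report.ttp_table),
        ("pvr", report.pvr_table),
        ("recovery", report.recovery),
    ):
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    (out_dir / "summary.json").write_text(
        json.dumps(report.agreement_summary, indent=1, sort_keys=True)
    )

    ratios = np.array([_ratio(r) for r in report.records])
    pvr_ref = np.array([r.pvr_rhc for r in report.records])
    pvr_4d = np.array([r.pvr_4dflow for r in report.records])
    agreement.scatter_with_fit(
        ratios, pvr_ref, report.fit,
        xlabel="TRV/Q_P (cm/s per L/min)", ylabel="PVR_RHC (WU)",
        path=out_dir / "fit_ratio_vs_pvr.png",
    )
    agreement.bland_altman_plot(
        pvr_4d, pvr_ref, agreement.bland_altman(pvr_4d, pvr_ref),
        label_a="PVR_4Dflow", label_b="PVR_RHC",
        path=out_dir / "bland_altman_pvr.png",
    )
    logger.info("study outputs written to %s", out_dir)
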