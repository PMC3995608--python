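# Methods

## Measurement model

### Cutplane flow

A cutplane is an oriented square sampling grid (origin, unit normal,
half-extent, in-plane step) placed perpendicular to a vessel. Through-plane
velocity is the dot product of the trilinearly interpolated velocity vector
with the plane normal; the volumetric flow rate at cardiac frame *f* is the
sum of through-plane velocity times cell area over the lumen, in mL/s. Net
flow per cycle is the periodic trapezoidal integral of that series (the first
frame re-appended at the cycle end). Mean velocity is flow divided by lumen
area — the usual cross-sectional average — and peak velocity is the
largest-magnitude through-plane sample inside the lumen.

Lumen membership on the plane comes from a labelled 3D mask sampled
nearest-neighbour (default) or, when no mask is available, from a speed
threshold at 10% of the in-plane maximum. The *flux* integral runs over the
lumen dilated by one voxel: trilinear interpolation spreads the velocity of
wall voxels into a one-voxel partial-volume ramp just outside the voxelized
lumen, and without that ring the flow through a 4–6 mm radius vessel at 1.3 mm
voxels is underestimated by roughly 10%. Mean and peak velocity use the
undilated lumen.

Defaults: in-plane step of half a voxel and half-extent of twice the vessel
radius (when planes are generated from a phantom). These choices make net flow
stable to within 1% under grid refinement and plane translation along a
straight vessel.

### Time-to-peak indices

Time-to-peak flow is the time (ms from frame 0, the R-wave analogue) of the
frame with maximal flow rate. Time-to-peak acceleration — for which no
standard discrete definition exists — is defined here as the start time of the
inter-frame interval with the largest forward difference `(q[f+1] − q[f])/Δt`,
searched over intervals ending at or before the flow-peak frame, which
guarantees `0 ≤ TTP_accel ≤ TTP_flow`. Ties break to the earliest frame
everywhere, and times are reported at frame resolution (50 ms at 20 frames /
1000 ms): sub-frame interpolation would invent precision the 20-frame
reconstruction does not have.

### Jet peak velocity (TRV)

The peak tricuspid-regurgitation velocity is the maximum |through-plane
velocity| over the valve-plane ROI and all frames; the frame and in-plane
position of the maximum are returned so the placement can be audited.
Through-plane velocity (not speed) is used, consistent with a plane placed
perpendicular to the jet; whether a clinical reading is a speed or a
through-plane component is ambiguous in practice, and for a plane aligned with
the jet axis the two coincide. Streamlines (fixed-step RK4 on one frame's
velocity field, arc-length parametrized, terminating at the boundary, a step
cap, or stagnation) support placing that plane.

### Volumetry

Chamber volume per frame is slice-summation: labelled in-plane area times
slice increment (thickness + gap), summed over slices — voxel counting when
slices are contiguous isotropic voxels. EDV and ESV are the extrema of the
volume–time curve (the automatable equivalent of picking the end-diastolic and
end-systolic images), SV = EDV − ESV, EF = SV/EDV as a *fraction*, CO =
SV × HR in mL/min. A helper converts EF to percent for the resistance model
below. Slice averaging (groups of k=3, trailing remainder averaged as-is) and
trilinear oblique reformatting to a short-axis stack mirror how
volumetric magnitude data are prepared for manual segmentation.

### Resistance estimates

All three estimators return Wood units (WU = mmHg·min/L):

- `PVR_RHC = (mPAP − PCWP) / CO` — the catheter reference (Ohm's law).
- `PVR_CMR = 19.38 − 4.62·ln(v̄_PA) − 0.08·RVEF` with v̄_PA the cycle-averaged
  MPA mean velocity in cm/s and RVEF in **percent** (the published scale of
  that model; treated here as an assumption since the percent-vs-fraction
  convention is not stated alongside the formula).
- `PVR_4Dflow = slope·(TRV/Q_P) + intercept`. The shipped "paper" coefficients
  are (0.16, −7.25); the default pipeline behaviour is to *refit* them on the
  cohort being analysed, because a line derived under acute embolic conditions
  is unlikely to transfer to other etiologies.

The TRV/Q_P ratio has no published unit convention (plausible conventions
differ by two orders of magnitude), so the package fixes a default — TRV in
cm/s over Q_P in L/min — and records the convention with every result and
model. Note also that the source literature is internally inconsistent about
the ratio's orientation (Q_P/TRV in one place, TRV/Q_P in the derivation and
figures); this package follows the derivation, TRV/Q_P. The modified Bernoulli
gradient `ΔP = 4v²` (v in m/s) is provided for pressure surrogacy.

### Agreement statistics

Ordinary least squares with intercept (constant-y inputs are flagged
degenerate with slope and r reported as 0), Pearson correlation on the same
pairs, Bland-Altman bias with 1.96·SD(n−1) limits of agreement (no
small-sample t correction, matching the bias ± 1.96·SD convention), and the
two-sided paired Student's t-test. Differences are first-argument-minus-second
throughout, stated on every output. Because OLS residuals sum to zero, the
Bland-Altman bias between a refit model's predictions and the observations it
was fitted to is exactly zero — the mechanism behind a zero bias reported for
a regression-derived estimate on its own derivation cohort.

## The synthetic phantom

### What it emulates

One phantom is a 64³ grid of 1.3 mm isotropic voxels over 20 uniformly spaced
cardiac frames (frame f starts at f·cycle/20; per-frame values are
instantaneous samples at frame start). It contains:

- straight cylindrical vessels (MPA bifurcating into RPA/LPA, plus an aorta)
  carrying axial flow with a plug or parabolic (Poiseuille) profile, driven by
  a half-sine systolic waveform on a diastolic baseline; child vessels split
  the parent's flow by exact branch fractions;
- an optional jet with a Gaussian radial velocity core (the
  tricuspid-regurgitation analogue), active during systolic frames;
- ellipsoidal RV/LV blood pools whose semi-axes interpolate linearly from
  end-diastole to end-systole (frame ≈ 40% of the cycle) and back, rendered as
  per-frame label masks;
- independent Gaussian noise per velocity component, voxel and frame
  (default SD 5 cm/s); magnitude images are a noise-free segmentation carrier.

Every programmed quantity — per-vessel flow curve and net flow, TTP indices,
jet peak velocity, per-frame chamber volumes — is recorded analytically before
voxelization and noise, as the oracle for the measurement stages. Ground-truth
net flow and TTP indices are defined at frame resolution (periodic trapezoid /
argmax of the 20 frame samples), so measured-vs-truth comparisons carry no
quadrature term; the frame-sampled trapezoid converges at O(h²) to the
continuous integral and matches a 10⁴-sample quadrature within 1% from ~50
frames upward.

### Voxelization and the acquisition model

Lumen membership is strict voxel-center (a voxel is lumen iff its center lies
inside the analytic cylinder/ellipsoid; no antialiasing), which keeps
voxel-count oracles exact. The *velocity field*, however, is box-filtered at
lumen boundaries: wall and end voxels carry the voxel-averaged analytic
velocity (supersampled 4×4×4), exactly as finite spatial resolution
partial-volume-averages a real phase-contrast acquisition. This matters
quantitatively: with binary velocity support, the discrete flux through a
plane inherits the ±2–4% cross-section quantization of a 4–6 mm cylinder at
1.3 mm voxels; with box filtering, measured net flows recover the programmed
values to ~0.4% and MPA vs RPA+LPA conservation holds to ~0.3%.

Aliasing (wrapping velocities beyond the VENC into the encoded band) is
available but off by default.

### The cohort

`make_cohort` draws paired pre/post measurements for n subjects, emulating an
acute embolization protocol: each subject is scanned and catheterized at
baseline and again after resistance is raised. Defaults target anesthetized
beagle physiology:

| parameter | default | note |
|---|---|---|
| heart rate | N(85, 8) bpm | assumption — not reported for the source model; chosen so SV ≈ 14 mL gives CO ≈ 1.2 L/min |
| RV EDV | N(35, 4) mL | RVEF 0.42 pre → 0.36 post |
| Qp/Qs | N(0.98, 0.05) | shunt-free up to measurement spread |
| PCWP | N(6, 1.5) mmHg | |
| true PVR | N(2.4, 0.9) pre, N(9.8, 3.0) post, WU | |
| RPA share of branch flow | N(0.61, 0.03) | |
| velocity noise | 5 cm/s SD | |

mPAP is constructed as PCWP + PVR·CO; the post-embolization resistance is
raised to a floor when needed so every subject satisfies the protocol's
">2× baseline mPAP" criterion. The jet peak velocity is tied to the programmed
resistance through the inverse of the linear TRV/Q_P model (ratio =
(PVR + 7.25)/0.16, plus N(0, 2) jitter), so the cohort genuinely embodies the
relationship the pipeline later refits — correlation and coefficient-recovery
checks are meaningful rather than tautological noise. Thermodilution CO
carries 2% multiplicative noise. All randomness derives from one master seed
via per-subject spawned streams; identical seeds give byte-identical cohorts
and study outputs.

### What the phantom does not emulate

No k-space acquisition, radial undersampling or reconstruction artifacts; no
respiratory motion; no eddy-current/background-phase offsets; no Rician
magnitude noise; vessels are straight cylinders without curvature, taper,
compliance or secondary flow; chambers are ellipsoids without trabeculation or
papillary muscles; the jet has no entrainment or pressure recovery. Passing
tests therefore demonstrate that the *measurement and estimation chain* is
correct and internally consistent at realistic geometry, resolution and noise
— not that it is robust to the segmentation ambiguity, motion and phase-error
confounds of in-vivo data.

## Numerical choices

- Physical coordinates in mm, voxel-center convention (index i at
  (i + 0.5)·voxel); velocity cm/s; flow mL/s; net flow mL/cycle.
- Trilinear interpolation for velocity and reformats; nearest-neighbour for
  label masks; points outside the volume are non-lumen and contribute zero.
- Ties break to the earliest frame in every argmax.
- Degenerate inputs are errors with named fields (zero plane normal, constant
  regression x, zero-variance paired differences, EDV = 0), warnings when a
  quantity remains well-defined (empty chamber at one frame, mPAP < PCWP,
  VENC exceeded without aliasing), or documented conventions (constant-y
  regression → slope 0, flagged).
- Streamline integration: RK4 with arc-length steps of a quarter voxel by
  default; a solid-body-rotation orbit closes with <1% radius drift per
  revolution at that step.

## Validation problem sizes

The test suite runs tube and bifurcation phantoms at 48³–64³ × 20 frames, the
full 6-subject study (12 phantom pairs at 64³) at noise SDs of 0, 5 and
15 cm/s, 200-subject regression-recovery cohorts, 100-waveform TTP oracle
scans, and 1000-replicate type-I-error calibration of the paired t-test —
sizes chosen so the complete suite exercises every stage end to end in a few
minutes on one CPU.

## Known limitations

- EDV/ESV from curve extrema can differ from fixed-frame readings when the
  volume curve is noisy or multi-modal.
- The TRV/Q_P unit convention is a package choice; comparisons against
  externally reported ratios must check conventions first.
- TTP indices are frame-resolution; at 20 frames the quantization is
  cycle/20 (≈ 35–50 ms at canine heart rates).
- `PVR_CMR` uses coefficients derived in human cohorts; on the synthetic
  canine-scale cohort it tracks the reference ordering but not its magnitude,
  and no recovery claim is made for it.
- The peak-velocity statistic is max-biased under noise: its error grows with
  noise SD roughly as the extreme value of the ROI's noise field (≲4 SD),
  which the noise-sweep tests quantify.
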