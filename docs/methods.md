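# Methods

## Overview

`vasculens` couples an analysis pipeline for intravital window-chamber
time-lapse movies with a synthetic scene generator whose ground truth is
known analytically. The pipeline stages run in the order
align → mask → partition → perfusion calls → morphometry / kinetics →
statistics; the generator emulates the acquisition protocol, the tracer
pharmacokinetics and the perfusion scenarios of a vascular-intervention
experiment, so that every pipeline estimate can be checked against truth.

## Acquisition model

The default schedule reproduces the imaging protocol of such experiments:
two fast series at 20-s intervals covering 2 min each, separated by a 20-s
pause (treatment, when applicable, happens in that pause, at t = 130 s),
then a slow series at 2-min intervals covering 58 min — 44 frames, 16-bit,
with the tracer injected at t = 0 (the first frame is therefore a true
pre-injection background frame, which the perfusion detector uses for its
background statistics). Frames are 420 × 420 px at 1 µm/px by default; the
tumour ROI is a polygon inset 10% from the field edges (≈ 0.113 mm²).

## Synthetic scene model

**Vessel network.** `n = 8` vessels cross the field as slightly tortuous
polylines (heading jitter SD 0.08 rad per 3-px step) on jittered rows
spread over the ROI's row extent. Each centreline is confined to a band
around its row sized so that adjacent vessel cross-sections cannot touch:
one connected component per vessel is a structural requirement — the
perfusion detector calls whole components, and the ground-truth timelines
are per segment. Diameters are N(20, 3) µm, truncated at ±2.5 SD (keeps
neighbours disjoint without biasing the mean) and clipped to > 2 px
(resolvable); after sampling, all diameters are rescaled so the ROI
length-weighted mean diameter is exactly 20 µm — the control-arm `D_V` the
pipeline is expected to recover. The published experiments report no
density or topology statistics, so the density and tortuosity are chosen
to qualitatively resemble published window-chamber fields; nothing
downstream depends on them beyond component disjointness.

Ground truth is computed analytically, not from the raster: segment
lengths are ROI-clipped polyline lengths (shapely), `A_V = Σ lᵢ·dᵢ`,
`A_T` is the exact polygon area, and `FVD = L_V/A_T`, `D_V = A_V/L_V` hold
exactly by construction.

**Tracer kinetics.** Plasma (intravascular) tracer follows a
mono-exponential rise `C_iv(t) = A·(1 − e^{−(t−t₀)/τ})` with
τ = 120/ln 5 ≈ 74.6 s, so the curve reaches exactly 80% of its plateau
2 min after injection — the filling behaviour reported for healthy tumour
vessels. The plateau is 30 000 counts over a background of 100 counts.
Extravasation is one-way accumulation `dC_ev/dt = k_perm·C_iv(t)`, with
the rate forced to zero before a configurable onset delay and whenever the
supplying vessel is unperfused (no intravascular tracer ⇒ no efflux);
there is no backflux, because observed extravascular levels stay far below
intravascular ones within an hour. Inside the simulator the leak is
integrated on a 5-s grid and sampled at the frame times, so an onset
falling between two slow-series frames is not lost; the public
`extravascular_concentration` function integrates on the caller's grid.
Leaked tracer is rendered into a 25-µm-wide halo around the leaking
vessel, which keeps extravasation spatially associated with re-perfused
vessels (and detectable only there).

**Perfusion scenarios.** Perfusion is binary per segment per timepoint
(the underlying observable is "tracer detected / not detected", not a flow
rate). Control and bleomycin-only arms never lock. The EP arm locks every
segment at treatment and re-perfuses a configurable fraction (default
half) with staggered onsets (default: first re-perfusion 600 s after
treatment, 60-s stagger). The ECT arm locks permanently, with at most a
peripheral fraction re-perfusing (default none). A dedicated EP variant
re-perfuses only the larger-diameter half of a bimodal (4 × 14 µm,
4 × 40 µm) network, making the true perfused-subset `D_V` exactly twice
the 20-µm control value.

**Noise and drift.** Gaussian read noise (SD 30 counts), intensity-scaled
shot noise (variance equal to the intensity), and optional field drift
applied as the integer-rounded cumulative per-frame displacement — integer
by design, so translation-only registration can recover it exactly.
Rendering uses centreline dilation with no anti-aliasing: masks are
pixel-exact, at the cost of a ±1 px quantisation of vessel width (≤ 5% on
a 20-µm vessel at 1 µm/px, the dominant bias in recovered `D_V`).

## Analysis pipeline

**Registration** is translation-only at integer pixels: the window-chamber
preparation is rigid and the morphometry tolerances make subpixel
refinement unnecessary. The shift between frames is the argmax of an FFT
cross-correlation of mean-subtracted frames, searched over ±10% of the
frame size. The reference is the first frame acquired after the injection
— a pre-injection frame is uniform background with nothing to register on.
Constant frames align trivially at (0, 0); out-of-field pixels are filled
with the frame's median.

**Vessel mask.** Maximum projection over the pre-treatment frames
(vessels are tracer-filled there, and the post-treatment leak halo —
which would pull a global threshold — has not yet developed), Otsu
threshold, opening with a 1-px disk, removal of 8-connected components
under 25 px. Hand corrections enter as explicit add/remove mask files,
`(mask ∪ add) \ remove`, with overlapping corrections rejected. The
extravascular compartment is `ROI ∧ ¬vessel`; together with
`ROI ∧ vessel` it partitions the ROI exactly at every frame.

**Perfusion calls.** A vessel-mask component is perfused at frame t when
its median intensity exceeds the background mean + 3 SD (background =
extravascular pixels of the pre-injection frame; explicit statistics can
be supplied when no pre-injection frame exists). Component-level calls
keep speckle from fragmenting a vessel. Perfusion is observable only once
tracer has arrived: during the first ~40 s after injection the calls
necessarily lag the true flow state, which is a property of the
measurement, not of the detector.

**Morphometry.** Skeletons are one-pixel medial axes
(`skimage.morphology.skeletonize`); length is adjacency-weighted — 1 px
per orthogonal neighbour pair, √2 per diagonal pair, each pair counted
once — because raw pixel counting overestimates diagonal vessels by up to
41%. `FVD = L_V/A_T`; `D_V = A_V/L_V` is reported as missing (NaN) when
`L_V = 0` (complete lock) so that group averages are not dragged toward
zero by fully locked tumours, while FVD is genuinely 0 there.

**Kinetics readouts.** Compartment curves are per-frame means over the
mask pixels, normalised to the curve's own maximum (Imax = 100%).
`filling_time` returns the earliest sampled timestamp at which the
normalised curve reaches the target fraction (sample resolution; onsets
cannot honestly be stated finer than one frame interval).
`lock_duration` is the span from treatment until the FVD series first
exceeds 5% of its pre-treatment baseline, with the endpoint linearly
interpolated between the bracketing frames; if FVD never re-emerges the
duration is censored at the end of the observation window. The 5%
threshold operationalises "complete lock" (no quantitative definition
exists in the literature; visually it corresponds to essentially no
perfused vessels). `leakage_onset` is the first timestamp at which the
extravascular relative-variation series exceeds its pre-treatment mean by
2 SD for 2 consecutive frames, reported relative to treatment. The
persistence filter suppresses single-frame spikes; with ~30 post-treatment
frames the rule still carries a few-percent false-positive rate on a flat
noisy series, which is inherent to a 2-SD criterion. The noise band is
estimated over all pre-treatment frames (the post-filling window alone can
contain a single frame — too few for an SD); the relative-variation
denominator uses the post-filling window, when the vessels are ~80%
filled. For protocols where the tracer is injected only after treatment,
the baseline policy is an explicit flag (`pre_treatment` /
`first_post_filling`) rather than a guess.

**Statistics.** Shapiro–Wilk normality screen per group; two groups →
two-sample t-test (rank-based Mann–Whitney fallback when the screen fails,
flagged in the report); more than two → one-way ANOVA with all-pairs
comparisons adjusted by the in-house Holm–Šidák step-down
(`adjusted₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^{m−i+1}`, monotonised, α = 0.05).
Dispersion is reported as SEM. Group comparison defaults to per-timepoint
tests (a summary mode averaging post-treatment values per subject is also
available); two identical constant groups are reported as p = 1.

## Numerical choices and degenerate inputs

Timestamps must be strictly increasing; masks must match the frame grid;
empty masks, empty ROIs, constant reference images and zero baselines all
raise typed errors (`ConfigError` / `DataError` / `AnalysisError`, mapped
to CLI exit codes 2/3/4). Ties in Otsu thresholding follow scikit-image.
Skeleton end effects bound the rectangle-fixture tolerance at 5%.
Coordinates are 0-based row-major pixels; polygon ROIs use even-odd fill;
all external lengths are µm via the pixel size.

## Problem sizes

The default scenes (44 frames of 420 × 420 px, 8 vessels) make each
simulate-plus-analyse cycle run in roughly ten seconds, so the whole
recovery suite and the acceptance script complete in a few minutes on one
core; the sizes were chosen as the smallest at which raster quantisation
(±1 px on a 20-px vessel) stays within the stated tolerances.

## What the synthetic scenes do and do not show

The generator reproduces the *observables* the pipeline consumes —
filling kinetics, binary perfusion timelines, leak accumulation, noise,
drift — not the physiology behind them: no haemodynamics or flow
velocities, no vasoconstriction mechanics, no two-phase endothelial
response, no photobleaching, no two-dye spectral imaging (late
re-perfusion imaging would be emulated as a second single-channel stack),
and no deformable tissue motion (drift is rigid and integer). Vessels are
non-crossing by construction, whereas real tumour vasculature branches
and overlaps in projection — real masks therefore need the hand-correction
step the pipeline exposes. Passing recovery tests consequently shows that
the measurement chain is unbiased at the stated tolerances under this
image-formation model; it does not validate the biology, and performance
on real movies will additionally depend on segmentation quality and
non-rigid motion.
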