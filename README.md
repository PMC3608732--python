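# vasculens

Quantitative analysis of intravital window-chamber movies of tumour
vasculature, plus a seeded synthetic movie generator with analytic ground
truth.

## The problem

In a dorsal window chamber, tumour blood vessels are imaged through a cover
glass by fluorescence microscopy after intravenous injection of a 70-kDa
labelled dextran. Vascular-targeted interventions (electroporation, or
electroporation combined with a cytotoxic drug — electrochemotherapy) shut
down tumour blood flow ("vascular lock"), change which vessels re-perfuse,
and make vessel walls leaky. Quantifying a time-lapse movie of such an
experiment means answering four questions:

* how fast do the vessels fill with tracer after injection;
* how long does the vascular lock last;
* which vessels are perfused at each timepoint, summarised as the
  **functional vascular density** `FVD = L_V / A_T` (perfused-vessel
  skeleton length per tumour area, µm⁻¹) and the **perfused-vessel
  diameter** `D_V = A_V / L_V` (vascular area over skeleton length — a
  length-weighted mean diameter, µm);
* when does tracer start leaking into the tissue (extravasation onset).

`vasculens` implements this workflow as a tested, reproducible pipeline:
translation registration of the time-lapse stack, vessel-network masking
(Otsu threshold + morphological cleanup, with optional hand-drawn
add/remove correction masks), compartment partition into intravascular and
extravascular space within a tumour ROI, per-timepoint perfusion calls at
the vessel-component level, skeleton-based morphometry, Imax-normalised
intensity curves (percent of the maximum mean fluorescence intensity of the
observation period), and the derived readouts. A group-comparison module
(Shapiro–Wilk screen, t-test / one-way ANOVA, Holm–Šidák step-down
adjustment, SEM reporting) covers the downstream statistics.

Because no raw movies are publicly deposited for this kind of experiment,
the package ships a first-class synthetic scene generator
(`vasculens.simulate`): vessel networks rendered as dilated tortuous
centrelines, mono-exponential plasma filling, gated one-way extravasation,
binary per-segment perfusion scenarios (control / bleomycin / EP / ECT),
read + shot noise and integer-pixel field drift — with every ground-truth
quantity recorded analytically in a `SceneTruth` object.

## Worked example

```python
import numpy as np
from vasculens.scenes import control_scene
from vasculens.pipeline import analyze_stack
from vasculens.simulate import VesselNetworkSpec, roi_mask_from_polygon

stack, truth = control_scene(seed=1)          # 44 frames, 420x420 px, 1 um/px
spec = VesselNetworkSpec(seed=1)
roi = roi_mask_from_polygon(spec.roi_polygon(), stack.frame_shape)
res = analyze_stack(stack, roi)

i = int(np.argmin(np.abs(res["aligned"].timestamps - 120)))
print(f"normalized intensity at 2 min: {res['iv_curve'].normalized[i]:.1f} % of Imax")
print(f"D_V at 2 min: {res['records'][i].dv_um:.1f} um  (truth {truth.dv_um:.1f} um)")
print(f"filling time to 80%: {res['readouts']['filling_time_s']:.0f} s")
```

prints

```
normalized intensity at 2 min: 80.1 % of Imax
D_V at 2 min: 20.6 um  (truth 20.0 um)
filling time to 80%: 120 s
```

i.e. the simulated control vessels reach 80% of their maximal fluorescence
2 minutes after injection, and the pipeline recovers the calibrated 20-µm
length-weighted diameter from the rendered movie to within a few percent.

The same pipeline is scriptable from the shell:

```bash
vasculens simulate --config cfg.yaml --seed 1 --out run/
vasculens analyze  --stack run/stack.tif --config cfg.yaml --out run/analysis/
vasculens compare  --group EP=runA/analysis,runB/analysis \
                   --group ECT=runC/analysis,runD/analysis --out run/stats/
```

`analyze` writes `curves.csv`, `morphometry.csv` (columns `time_s, L_V_um,
A_V_um2, A_T_um2, FVD_per_um, D_V_um`), `shifts.csv`, QC overlays and a
`report.json` with the scalar readouts (`filling_time_s`,
`lock_duration_s`, `lock_censored`, `leakage_onset_s`) and full parameter
provenance.

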