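# qmi — serial quantitative MRI of acute cortical microinfarcts

Acute cortical microinfarcts (A-CMI) are tiny (<5 mm) ischemic lesions of
the cerebral cortex, visible for a few weeks as hyperintensities on
diffusion-weighted imaging (DWI) and then usually invisible on structural
follow-up MRI. A key open question in cerebral small-vessel-disease imaging
is what these lesions leave behind. Iron-sensitive quantitative MRI offers
an answer: the apparent transverse relaxation rate R2\* (=1/T2\*) increases
with local iron concentration, so a persistent post-lesional **rise of R2\***
at the infarct site indicates iron accumulation (microhemorrhage,
neuroinflammation or neurodegeneration) even when the lesion itself has
"disappeared".

`qmi` implements the full serial-imaging analysis that tests this
hypothesis, as a tested, reproducible pipeline over synthetic monthly
multi-modal studies:

1. **Synthetic cohort** (`qmi.phantom`) — a three-compartment brain
   (CSF / cortical GM / WM, with R2\* ≈ 1 / 15 / 30 s⁻¹) scanned at 10
   monthly visits: 6-echo gradient-echo magnitude+phase (ΔTE = 4.92 ms,
   0.8 × 0.8 × 2.0 mm voxels), a multi-echo spin-echo series, and R1 /
   DWI-trace / MD / FA maps. Small cortical lesions follow the acute →
   post-lesional trajectory (DWI ↑, MD ↓, R1 ↓, R2 ↓, R2\* ↓ acutely;
   R2\* overshoot afterwards). Ground truth is retained.
2. **R2\* mapping** (`qmi.relaxometry`) — closed-form trapezoidal-rule
   estimator. For mono-exponential decay dS/dTE = −R2\*·S,

   R2\* = (S₁ − S_N) / ∫ S dTE,  with the integral approximated by the
   trapezoidal rule over the sampled echoes. A nonlinear least-squares
   mono-exponential fit serves as the accuracy oracle; R2 comes from a
   log-linear fit of the spin-echo decay.
3. **SWI construction** (`qmi.swi`) — homodyne high-pass phase filtering
   (12 × 12 Hamming k-space kernel), a negative-phase linear mask raised
   to m = 4, and echo averaging.
4. **A-CMI screening** (`qmi.screen`) — the rating criteria (<5 mm,
   DWI-hyperintense, cortex-restricted, MD hypo-/isointense) as a
   deterministic z-score detector over 26-connected components.
5. **Longitudinal extraction** (`qmi.longitudinal`) — a one-voxel control
   shell around each lesion (dilate-and-subtract), ROI means gated by the
   R2\* acceptance window 5–30 s⁻¹ (excluding CSF- and WM-dominated
   voxels), lesion-minus-control differences, realignment to onset, and
   subtraction of the pre-onset mean.
6. **Inference** (`qmi.stats`) — one-way repeated-measures ANOVA over the
   three stages (pre-lesional / lesional / post-lesional) and post-hoc
   two-tailed paired t tests, implemented from the sums-of-squares
   formulas (no sphericity correction).

`qmi.pipeline` orchestrates all of it; the `qmi` CLI exposes each stage.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default 15-lesion cohort and write tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py   # cohort + truth table
python 02_relaxometry_maps.py  # R2*/R2 maps vs truth
python 03_swi_images.py        # SWI lesion conspicuity
python 04_screen_acmi.py       # detector vs truth masks
python 05_extract_longitudinal.py
python 06_stage_inference.py
```

The final script prints (exact output):

```
repeated-measures ANOVA (effect of stage):
  dwi_b1000  F(2,28) =   528.81, p = 5.76e-23 *
  md         F(2,28) =   267.99, p = 5.53e-19 *
  fa         F(2,28) =     0.64, p = 5.32e-01
  r1         F(2,28) =   155.13, p = 7.09e-16 *
  r2         F(2,28) =   169.14, p = 2.33e-16 *
  r2star     F(2,28) =   365.41, p = 8.68e-21 *
post-lesional vs pre-lesional R2*: t(14) = 9.54, p = 1.67e-07, direction +
(positive = R2* increase, consistent with iron accumulation)
```

Reading: every parameter with an injected lesion trajectory shows a
significant stage effect (FA, unchanged by design, does not), the acute
visit shows the ischemic signature (DWI up; MD, R1, R2, R2\* down), and
at the last follow-up R2\* sits **above** its pre-lesional level — the
iron-accumulation signature the analysis is built to detect. The
normalized group means from `05_extract_longitudinal.py` are
pre +0.10, lesional −2.92, post-lesional +1.79 s⁻¹.

The same run is available as one command:

```bash
qmi run --out results/pipeline --seed 1
```

## Layout

```
src/qmi/          library (phantom, relaxometry, swi, screen,
                  longitudinal, stats, pipeline, io, cli)
analysis/         numbered narrative drivers
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance.py
docs/methods.md   model, parameters, numerical choices, limitations
results/          tables written by the analysis drivers
```
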