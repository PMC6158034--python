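# vesicoloc

Object-based, per-vesicle colocalization analysis of three-channel 3D
super-resolution (SIM-class) image stacks of immunolabelled secretory
vesicles — plus the secretion, gene-expression and calcium statistics used
alongside such imaging in enteroendocrine-cell studies.

## The problem

Enteroendocrine L-cells of the colon store several peptide hormones
(INSL5, GLP-1, PYY). Whether a single dense-core vesicle stores one
hormone or all of them is a question that pixel/volume-overlap
colocalization answers badly: edge pixels of a genuinely triple-labelled
vesicle register as "single-labelled volume" and bias the result. The
object-based alternative implemented here scores each *vesicle*:

1. **Detection** — per channel, bright spots via a three-class Otsu
   histogram split (top class) and dim spots via binary Otsu plus a strict
   component-size gate, 12 < np < 250 voxels; candidates from all channels
   are pooled and de-duplicated (two coordinates within 2 pixels are one
   vesicle; the brighter survives).
2. **Sub-pixel localization** — per channel, least-squares fitting of
   anisotropic 3D Gaussians (sum-of-Gaussians for overlapping windows,
   shared constant offset).
3. **Chromatic registration** — channels are translated so their mean
   vesicle positions coincide, removing chromatic aberration.
4. **Separation prefilter** — a vesicle is kept only if its three
   per-channel positions are pairwise < 200 nm apart; larger separations
   indicate a neighbouring vesicle was picked up in one channel.
5. **Intensity classification** — images are normalized to their
   per-channel maximum; vesicle intensity is the mean inside a 150 nm
   spherical mask minus the per-channel mean-of-volume background. A
   channel is *positive* above 0.05, *empty* below 0.02, indeterminate in
   between. Categories: single / double / triple / indeterminate.
6. **Sizing** — per channel, σ of a 1D Gaussian fitted to the x-axis line
   profile; only fits with R² > 0.75 enter the size distribution (median
   σ and FWHM = 2√(2 ln 2)·σ, bootstrap 95% CIs).

Because no public image data exist for this assay, the package ships a
first-class synthetic-stack generator (`vesicoloc.synthetic`): vesicles as
anisotropic 3D Gaussian spots with configurable label mixtures, per-channel
chromatic shifts, Poisson/Gaussian noise and full ground truth — the
substrate for every validation in the test suite, including the in-silico
analogue of the single-primary/three-secondaries control experiment.

The statistics side (`vesicoloc.secretion`) covers protein-normalized
secretion fold changes against same-culture controls, Dunn post-hoc tests
(tie-corrected, Holm-adjusted), inter-hormone Pearson correlations, qPCR
relative expression (2^ΔCT vs a housekeeper, undetermined CT → 40, ratio
paired t-tests) and calcium fold responses with Wilcoxon signed-rank tests.

## Worked example

`examples/01_simulate_and_classify.py` simulates a cell with 120 vesicles
(80% triple-labelled nominal mixture), injects sub-pixel chromatic shifts,
and runs the full pipeline:

```
simulated vesicles:        120 (75.8% triple in truth)
detected candidates:       168
prefilter-passing (<200nm):148
categories: single=13 double=9 triple=95 indeterminate=31
percentages of determinate vesicles: single 11.1%  double 7.7%  triple 81.2%
estimated chromatic correction (nm, z/y/x):
  INSL5: [0. 0. 0.]
  PYY: [ -3.5  24.7 -20.8]
  GLP1: [ 13.8 -20.4   8.7]
```

The determinate-category percentages track the realized simulation truth
(75.8% triple) within sampling noise, extra detections beyond 120 are noise
candidates that end up excluded or indeterminate, and the estimated
corrections recover the injected (0, 30, −20) and (20, −20, 10) nm shifts.
The other examples cover the secondary-antibody control, sizing, secretion
statistics, and expression/calcium analysis.

A thin CLI mirrors the library:
`vesicoloc simulate | detect | analyze | stats` (see `--help`).

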