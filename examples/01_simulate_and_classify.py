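"""Simulate one labelled cell and run the vesicle-contents pipeline.

Builds a three-channel stack of 120 vesicles (80% triple-labelled, the
rest split between single- and double-labelled), runs detection,
sub-pixel localization, chromatic registration, the <200 nm separation
prefilter and intensity classification, then prints the per-cell category
table next to the simulated truth.
"""

import numpy as np

import vesicoloc as v

cfg = v.ImagingConfig(
    shape_voxels=(20, 192, 192),
    noise_gaussian_sd=0.1,                       # peak SNR 10
    chromatic_shift_nm=((0, 0, 0), (0, 30, -20), (20, -20, 10)),
    seed=42,
)
fractions = v.category_fractions(single=0.1, double=0.1, triple=0.8)
truth = v.sample_vesicle_field(120, fractions, 400.0, rng_seed=42, config=cfg)
cell = v.render_stack(truth, cfg)

result = v.analyze_cell(cell.channels, cell_id="demo")
s = result.summary

true_triple = 100.0 * np.mean([t.category == "triple" for t in truth])
print(f"simulated vesicles:        {len(truth)} ({true_triple:.1f}% triple in truth)")
print(f"detected candidates:       {s.n_detected}")
print(f"prefilter-passing (<200nm):{s.n_prefilter_pass}")
print(f"categories: single={s.n_single} double={s.n_double} triple={s.n_triple} "
      f"indeterminate={s.n_indeterminate}")
print(f"percentages of determinate vesicles: "
      f"single {s.pct_single:.1f}%  double {s.pct_double:.1f}%  triple {s.pct_triple:.1f}%")
print(f"estimated chromatic correction (nm, z/y/x):")
for c, name in enumerate(v.CHANNELS):
    print(f"  {name}: {np.round(result.chromatic_offsets_nm[c], 1)}")
# The triple percentage should track the simulated 80% within a few points;
# the chromatic corrections should recover the injected shifts.
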