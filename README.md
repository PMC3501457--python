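# voltfp — tissue fingerprinting from differential pulse voltammograms

`voltfp` is an analysis pipeline for *tissue electrochemical
fingerprinting*: deciding which organ a biological extract came from using
nothing but its Brdicka-reaction voltammogram.  In the Brdicka reaction,
thiol-rich proteins — above all metallothionein (MT) — catalyse hydrogen
evolution at a mercury electrode in a cobalt/ammonia electrolyte.  A
differential-pulse scan from −0.7 V to −1.8 V yields a current–potential
curve with characteristic catalytic peaks (Co1, RS₂Co, Cat1, Cat2) whose
shape differs between organs (liver, blood, kidney, brain, eye, spleen,
heart, femoral muscle, gonad).

The original rat measurements behind this kind of analysis are not
publicly deposited, so the package ships a first-class synthetic-data
module that generates voltammogram campaigns with the same statistical
structure (9 tissues × 8 rats × 5 replicates = 360 curves, 518 samples
per curve, a handful of failed measurements), and runs the full analysis
on them:

1. **Cleaning** — replicate groups are screened for dramatically deviating
   curves (8 corrupt measurements; 360 → 352 analysed curves).
2. **Local extremes** — a first-order FIR difference, a signum-like
   normalisation (0 → +0.5) and a second difference locate each curve's
   local extremes; close pairs are merged (default minimum distance
   5 samples ≈ 10 mV) and the catalytic minima RS₂Co/Cat1/Cat2 and maxima
   Max1–Max3 are named by potential windows.  Seven tissues show exactly
   six extremes; blood and muscle show at most four and are excluded from
   the extreme-based feature sets (280 → 275 curves).
3. **Wavelet attributes** — each curve is truncated 518 → 512 = 2⁹
   samples and decomposed with the Haar Simple Wavelet transform; the
   inverse at level *k* gives 2ᵏ derived attributes `w{k}coef{j}`, the
   curve's mean over 2ᵏ equal-width steps (32 attributes at level 5).
4. **Classification** — decision trees (information gain, minimal leaf
   size 10) under stratified 10-fold cross-validation, with pooled
   confusion matrices and per-class precision/recall, for three
   representations: the 3 named minima, all 6 extremes, and the 32
   wavelet attributes.
5. **Segment line families** — between Cat2 and the last maximum Max3
   each curve has a near-linear stretch.  The line *y = kE + q* is fitted
   by OLS to the *m* = 11 samples centred on the segment's inflection
   point.  Within a tissue the (k, q) pairs satisfy *q = αk + β*, which
   is equivalent to all lines sharing the point ⟨−α, β⟩; −α correlates
   with the tissue's MT level.
6. **RadViz** — the attributes `w5coef24…w5coef27` covering the segment
   are projected onto four circular anchors (normalised spring rule);
   each tissue's points form a line.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic campaign (seed 1) and write small tables under `results/`:

```sh
python analysis/01_simulate_dataset.py
python analysis/04_classify_tissues.py
python analysis/05_segment_line_families.py
```

prints, among other things:

```
generated 360 curves (9 tissues x 8 rats x 5 replicates), 8 corrupted
minima3   : accuracy 94.91% +-4.88%  (275 curves, 7 tissues)
extremes6 : accuracy 98.17% +-2.60%  (275 curves, 7 tissues)
wavelet32 : accuracy 99.43% +-1.20%  (352 curves, 9 tissues)
...
352 segment fits across 9 tissue families
correlation of -alpha with metallothionein level: r = 72%
```

The accuracy ordering (named minima < all extremes ≤ wavelet attributes)
mirrors the behaviour of the representations on real tissue data; the
absolute numbers are higher than on real measurements because synthetic
within-tissue variability is simpler than biological variability.  The
per-tissue line-family table shows each tissue's fitted (α, β), the
intersection point ⟨−α, β⟩ near the inflection potential (≈ −1.5 V), and
q-on-k correlation r² ≈ 1.

The same pipeline is scriptable end to end:

```sh
voltfp run-all --seed 1 --out-dir results/run
```

or, as a library:

```python
from voltfp import (DatasetSpec, make_tissue_profiles, generate_dataset,
                    clean_dataset, build_feature_table, cross_validate)
from voltfp.synthetic import DEFAULT_OUTLIER_FLAGS

profiles = make_tissue_profiles(seed=1)
spec = DatasetSpec(outlier_flags=list(DEFAULT_OUTLIER_FLAGS), seed=1)
curves, _ = clean_dataset(generate_dataset(spec, profiles),
                          manual_flags=list(DEFAULT_OUTLIER_FLAGS))
cv = cross_validate(build_feature_table(curves, "wavelet32"))
print(f"{cv.accuracy_mean:.2f}% +-{cv.accuracy_sd:.2f}%")
```

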