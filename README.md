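# tbmoco

Inter-frame motion correction and kinetic quantification for **dynamic
total-body PET**.

Long-axial-field-of-view scanners acquire the whole body in a single 60-min
dynamic FDG scan, but patients move — mostly after the first ~10 minutes —
and inter-frame misalignment corrupts SUV images, time-activity curves and
voxelwise kinetic parameters. `tbmoco` implements an image-based correction
framework for this problem, together with the kinetic modeling and
evaluation machinery needed to quantify its effect, and a synthetic dynamic
phantom generator (with exported ground-truth motion fields, organ masks
and parameter maps) that serves as the test substrate.

## What it does

* **SyN-seq** (the main strategy): the 10-60-min data, rebinned to 1-min
  frames, are corrected by registering each frame to its *previous
  neighbour* with a symmetric diffeomorphic (greedy SyN-style) engine
  driven by local cross-correlation; per-frame total motion fields are
  obtained by concatenating the pairwise fields back to the reference
  (frame 40), and each frame is resampled exactly once.
* **SyN-mid** and **Aff-seq** comparison strategies: direct registration of
  every frame to a mid reference (frame 70, NMI-seeded), and sequential
  9-parameter affine (Powell/NCC, three pyramid levels) with exact
  matrix-product concatenation.
* **Kinetics**: irreversible two-tissue-compartment modeling
  (`CT = Ki*intCp + (K1 k2/(k2+k3)) exp(-(k2+k3)t) (*) Cp`, with
  `Ki = K1 k3/(k2+k3)`), bounded NLS fitting of TACs and voxel maps,
  image-derived input function extraction from an aortic ROI, the fitting
  residual `FR = sum_k sum_j (I_k(x_j) - Ihat_k(x_j,p))^2`, and Patlak
  graphical analysis as an independent cross-check of Ki.
* **Evaluation**: per-frame mutual-information and dice alignment curves
  against the reference, 50%-of-max region-growing tumor delineation with
  SUVmean improvement percentages, and inter-subject coefficient of
  variation (`CV = SD/mean`, population SD) of kinetic parameters.

Dynamic series are 4-D NIfTI with a `<name>.frames.json` timing sidecar;
fields are vector NIfTI in mm; input functions and metric curves are TSV.

## Worked example

```python
import numpy as np
import tbmoco as tb
from tbmoco.phantom import small_test_spec, generate
from tbmoco.correction import syn_seq
from tbmoco.evaluation import alignment_curves
from tbmoco.kinetics import fit_tac

spec = small_test_spec(seed=7)            # 16 x 1-min frames, motion from frame 12
dyn, truth = generate(spec)
ref = tb.reference_frame_index(spec.schedule, 600.0)   # -> 10

corrected = syn_seq(dyn, ref)
before = alignment_curves(dyn, ref)
after = alignment_curves(corrected.corrected, ref)
post = before["frame"] > ref
print("post-onset dice:  %.3f -> %.3f" %
      (before.loc[post, "dice"].mean(), after.loc[post, "dice"].mean()))

mask = truth.organ_masks["liver"]
for label, series in (("uncorrected", dyn), ("SyN-seq", corrected.corrected)):
    tac = series.data[:, mask].mean(axis=1)
    fit = fit_tac(tac, truth.cp, spec.schedule)
    print("%-12s liver 2TC fit residual (RMS): %.1f Bq/ml" % (label, fit.fr_rms))
```

Output from this exact script:

```
post-onset dice:  0.967 -> 0.992
uncorrected  liver 2TC fit residual (RMS): 51.0 Bq/ml
SyN-seq      liver 2TC fit residual (RMS): 36.1 Bq/ml
```

i.e. the correction raises post-onset body-mask overlap with the reference
frame from 0.97 to 0.99, and the liver time-activity curve from the
corrected series is substantially better explained by the irreversible
two-tissue-compartment model (the motion-induced jumps that the model
cannot fit are removed).

A command-line interface covers the same pipeline
(`tbmoco phantom | correct | fit | evaluate | pipeline`); every run writes a
provenance JSON with the configuration echo, seeds and input hashes, e.g.

```bash
tbmoco phantom --seed 7 --out run/phantom
tbmoco correct --method syn-seq --ref-frame 10 \
    --in run/phantom/dynamic.nii.gz --out run/corrected.nii.gz \
    --fields-dir run/fields
```

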