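# spinemorph

Vertebral morphometry and insufficiency-fracture classification for
mid-sagittal lumbar-spine MRI, with a synthetic spine phantom so that the
entire pipeline is testable without clinical data.

The pipeline mirrors a deployed automated reading system:

1. **preprocess** — select the eligible sagittal T2 sequence (TE ≥ 80 ms,
   TR ≥ 3000 ms, thickness 2–4 mm, in-plane ≤ 0.8 mm), keep the central
   slice (center-left for even counts), resample to 0.6 × 0.6 mm, fit a
   448 × 320 canvas, and map 12-bit intensities to [0, 1] via
   `min(v / 2500, 1)`.
2. **segmentation** — a pluggable binary vertebra-mask stage: an *oracle*
   backend (ground-truth phantom labels, optionally corrupted with seeded
   holes/satellites/jitter) and a trainable pure-NumPy U-net
   (5 encoder blocks of two conv-BN-ReLU stacks, filters 32→512, four skip
   connections, Dice loss, Adam) with hand-written backpropagation.
   The Dice coefficient is provided as the overlap metric.
3. **geometry** — mask cleanup (hole filling, small-cluster and
   far-from-column cluster removal), cranial→caudal vertebra labeling, and
   corner detection by three strategies (basin-hopping IoU optimization
   from the minimum-area bounding rectangle, k-cosine curvature maxima of
   the concave border hull, and robust side-line intersections), with the
   quad that maximizes mask-polygon overlap selected.
4. **morphometry** — anterior/posterior/central heights, superior/inferior
   endplate concavity depths, and the signed vertebral angle; classification
   into wedge / concave / crush deformities at the healthy-population
   mean − 3 SD ratio bounds (strict inequality, precedence
   crush > wedge > concave).  The shipped default norms are **non-clinical
   placeholders**; supply your own norms file for any real use.
5. **stats** — ICC (two-way random, absolute agreement, single measures by
   default, F-based CI, Koo bands), Cohen's kappa (Landis–Koch bands),
   Bland–Altman limits of agreement, sensitivity/specificity/accuracy with
   exact Clopper–Pearson CIs, and the CI-overlap significance rule.
6. **phantom** — renders 5–7 stacked vertebral bodies with circular-arc
   endplate depressions, configurable wedge/concave/crush deformities,
   per-vertebra tilt and additive noise; analytic ground truth (corners,
   morphometry, fracture status) is computed from the generating shapes.

## Command line

```bash
spinemorph simulate --config phantom.yaml --seed 7 --out out/phantom --png
spinemorph measure  --input out/phantom/image.nii --labels out/phantom/labels.nii \
                    --config pipe.yaml --out out/report --case-id demo
spinemorph classify --measurements meas.csv --norms norms.json --out calls.csv
spinemorph evaluate --calls calls.csv --strata site --out metrics.csv
spinemorph agreement --ratings ratings.csv --out agreement.csv
```

Exit codes: 0 success, 2 input error, 3 stage failure.

## Python API sketch

```python
from spinemorph import PhantomConfig, Deformity, generate_phantom
from spinemorph.pipeline import PipelineConfig, run_measure

slc, labels, truth = generate_phantom(PhantomConfig(n_vertebrae=5))
report = run_measure(slc, PipelineConfig(labels=["L1", "L2", "L3", "L4", "L5"]),
                     oracle_labels=labels)
print(report.to_frame())
```

DICOM input requires the optional `pydicom` package; NIfTI and PNG work out
of the box.
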