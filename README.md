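# plusquant

Quantification of the vessel characteristics that define **Plus disease** in
retinopathy of prematurity (ROP), for researchers working with segmented
posterior-pole fundus images. Plus disease — the severe vascular form of ROP
in preterm infants — is diagnosed from abnormal *tortuosity* and *dilation*
of the retinal vessels, a judgment known to vary between experts. Given a
binary vessel mask and the optic-disc location, `plusquant` measures those
signs objectively and classifies images as Plus vs non-Plus.

## What it computes

**Tortuosity.** Each vessel centerline (skeletonized, spur-pruned, split at
junctions) is fitted with a parametric cubic spline γ(t) = (x(t), y(t)).
Curvature is

κ(t) = |x′y″ − y′x″| / (x′² + y′²)^(3/2)

and segment tortuosity is the arc-length-normalized integral of the squared
curvature derivative,

T = ∫ (κ′(s))² ds / L_c,  L_c = ∫ √(x′² + y′²) dt,

which is 0 for a straight vessel and for a smooth circular arc, and large for
the corkscrew vessels of Plus disease.

**Features per image** (region in parentheses):

| feature | definition |
|---|---|
| F1 | mean T of the 5 most tortuous segments (entire image) |
| F2 | mean T of all segments in the 5DD zone |
| F3 | mean of the top 1% of pooled curvature samples (entire image) |
| F4 | diameter of the thickest segment (5DD zone) |
| F5 | vessel density: vessel pixels / rest of the vascularized region |

The *5DD zone* is the annulus reaching five disc diameters beyond the
optic-disc border. Diameters come from the distance transform at a seeded
random third of each centerline's pixels; the vascularized region is a
disc-footprint morphological dilation of the mask.

**Classification.** Features are standardized, weighted and selected by the
feature-weighting variant of neighborhood component analysis (NCA), projected
onto the first three principal components, and classified by an RBF-kernel
SVM (C = 1), evaluated by repeated stratified tenfold cross-validation with
all transforms fitted inside each training fold.

**Rater agreement.** Cohen's kappa and absolute agreement between raters,
between sessions of one rater, and of each rater against the majority-vote
reference standard.

**Synthetic phantoms.** A generator draws constant-width ribbons around
analytic curves (lines, arcs, sinusoids) and whole two-class cohorts of
vessel trees, with ground-truth curvature/tortuosity tables computed by
dense quadrature on the analytic curves — so the entire pipeline is testable
without clinical data.

## Worked example

```bash
plusquant synth    --out demo/data --n-per-class 7 --shape 512 512 --seed 4
plusquant features --mask-dir demo/data --seed 4 --out demo/feat
printf 'cv:\n  folds: 5\n  repeats: 5\n' > demo/cfg.yaml
plusquant classify --features demo/feat/features.csv --config demo/cfg.yaml \
                   --seed 1 --out demo/report.json
plusquant agreement --labels demo/data/rater_labels.csv \
                    --session 1 --session2 2 --out demo/agreement.json
```

which prints

```
wrote 14 images to demo/data
wrote features for 14 images (0 flagged) to demo/feat
accuracy 0.957 +/- 0.039 (5x5-fold CV, n=14)
wrote agreement statistics to demo/agreement.json
```

`demo/feat/features.csv` holds one row per image (first rows shown):

```
image_id       F1        F4       F5 label
  img000 0.000006 21.090280 0.360985  Plus
  img001 0.000010 22.485031 0.349210  Plus
  img002 0.000012 18.681977 0.294116  Plus
  img003 0.000025 18.670581 0.293431  Plus
```

F1 is in px⁻⁴ (tortuosity), F4 in pixels (the venule caliber), F5
dimensionless (density). Plus-class phantoms are generated with winding,
wide, numerous vessels, and the classifier separates them from the quiet
class at 0.957 ± 0.039 accuracy over 5 repeats of 5-fold CV on this small
demo. `demo/agreement.json` contains, e.g., the first rater pair's
chance-corrected agreement (kappa 0.4717, absolute agreement 71.43% over 14
images, simulated raters flipping labels at 5–15% error), with the full 2×2
contingencies included for audit.

As a library:

```python
import plusquant as pq

mask = pq.read_mask("demo/data/img000_mask.png")
disc = pq.OpticDiscSpec.from_json("demo/data/img000_disc.json")
features, segments = pq.extract_image_features(mask, disc, seed=0, image_id="img000")
print(features["F1"], features["F4"], features["F5"])
```

Every tunable (spline spacing, pruning lengths, dilation radius, SVM C,
folds, seeds, ...) lives in a YAML config validated against the full key
set; each command echoes the configuration and its hash into its outputs.
See `docs/methods.md` for the estimators, their parameters and the design
rationale.

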