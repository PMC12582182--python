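# petnorm

MR-free spatial normalization and Braak-stage SUVR quantification for tau
PET, with a built-in synthetic phantom cohort for end-to-end validation.

## The problem

Quantifying regional tau burden from a PET scan requires warping the scan
into a standard template space where the ROIs are defined.  The
conventional route needs a paired structural MR (rigid PET→MR
coregistration, then nonlinear MR→template normalization), which raises
cost and limits clinical throughput.  `petnorm` implements the MR-free
alternative: a cascaded coarse-to-fine convolutional model predicts the
nonlinear deformation field **from the PET volume alone**; one forward pass
and one trilinear resampling put the scan into template space.  Regional
SUVR is then

    SUVR(ROI) = mean activity over ROI voxels / mean activity over cerebellar gray

over the Braak-stage composites (I–II, III–IV, V–VI), the metatemporal
composite, entorhinal cortex (EC) and inferior temporal gyrus (ITG).  A
statistics layer provides the validation and clinical-association analyses:
intraclass correlation against ground truth, one-/two-sided Pearson
correlations with explicit Bonferroni families, CDR-based staging, quintile
stratification of episodic-memory performance, and a longitudinal analysis
of whether baseline EC/ITG uptake predicts cognitive decline via the change
ratio `(post − pre)/(pre + 0.1)`.

Training is unsupervised registration: the model maximizes the similarity
(global NCC) between the warped image and the template, plus a diffusion
smoothness penalty.  During training the field predicted from the PET is
applied to the *paired* anatomical volume and scored against the template —
so the model trains against a contrast-consistent target while staying
MR-free at inference.  A transfer-learning path fine-tunes a model
pretrained on one tracer profile (e.g. amyloid-like, diffuse) to another
(tau-like, staged) at a 10× reduced learning rate.

Because real imaging cohorts cannot ship with a package, `petnorm.phantom`
generates the entire study bench: a synthetic textured template and ROI
atlas, smooth invertible deformations with guaranteed-positive Jacobians,
native-space PET/MR pairs with known regional SUVR, and cohorts whose
cognitive scores are stochastically linked to tau burden.  Every downstream
number can therefore be checked against exact ground truth.  See
`docs/methods.md` for the model, the generator, and their assumptions.

## Worked example

```python
import numpy as np
from petnorm import phantom, registration, quantify, stats

shape = (32, 32, 32)
template, atlas = phantom.make_template(shape, seed=7)
subjects = []
for i in range(12):
    field = phantom.sample_deformation(shape, amplitude=2.0, smoothness=4.0, seed=300 + i)
    stage = ["CN", "CN", "MCI", "AD"][i % 4]
    subjects.append(phantom.synthesize_subject(template, atlas, stage, field,
                                               noise_sd=0.03, seed=i, texture_seed=7))

model = registration.RegistrationModel(shape, hidden=8, seed=0)
model, _ = registration.train(model, subjects, template,
                              registration.TrainConfig(iterations=300, lr=3e-3, seed=0))

warped, field = registration.normalize(subjects[0].pet_native, model)  # PET only
table = quantify.compute_suvr(warped, atlas)
```

Running the full version of this (`python examples/03_suvr_and_agreement.py`,
about two minutes) prints:

```
ICC (absolute agreement) of MR-free SUVR vs ground truth:
  Braak12        0.993  (95% CI 0.980-1.000)
  Braak34        0.993  (95% CI 0.980-1.000)
  Braak56        0.987  (95% CI 0.960-1.000)
  metatemporal   0.993  (95% CI 0.980-1.000)
```

An ICC near 1 means the MR-free SUVR estimates agree with the phantom's
ground-truth SUVR almost interchangeably — the absolute-agreement variant
would be pulled down by any systematic offset, not just by noise.  The other
examples cover the phantom's ground truth (`01`), deformation recovery
(`02`), and the clinical statistics (`04`): on a 300-subject phantom cohort
the metatemporal SUVR correlates with MMSE at r ≈ −0.57, and baseline
EC/ITG uptake predicts subsequent decline (r ≈ −0.22 to −0.55, all
significant after the 6-fold Bonferroni adjustment), mirroring the
association structure such cohorts show in practice.

A thin CLI wraps the same functions for shell pipelines:

```bash
petnorm demo-phantom --out cohort/ --n 5 --shape 32
petnorm train --template cohort/template.nii.gz --subjects ... --anatomy ... --out model.npz
petnorm normalize --in pet.nii.gz --model model.npz --out warped.nii.gz --field field.nii.gz
petnorm suvr --pet warped.nii.gz --atlas cohort/atlas.nii.gz --roles cohort/atlas_roles.tsv --out suvr.csv
petnorm classic --pet pet.nii.gz --mr mr.nii.gz --template template.nii.gz --out warped.nii.gz
```

Real NIfTI templates and label atlases can be supplied in place of the
phantom ones wherever a path is accepted.

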