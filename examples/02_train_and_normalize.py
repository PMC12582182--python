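"""Train the MR-free normalization model on a small phantom set.

Trains the cascaded deformation-prediction network on ten (PET, MR) phantom
pairs — the field is predicted from the PET alone; the paired MR only enters
the training loss — then normalizes a held-out subject from its PET only and
reports how much of the known deformation was recovered.

Takes a couple of minutes on one CPU.  Larger cohorts and more iterations
(see scripts/acceptance.py) improve recovery further.
"""

import numpy as np

from petnorm import phantom, registration
from petnorm.grid import endpoint_error

shape = (32, 32, 32)
template, atlas = phantom.make_template(shape, seed=7)


def make_subject(i):
    field = phantom.sample_deformation(shape, amplitude=2.0, smoothness=4.0,
                                       seed=200 + i)
    stage = ["CN", "MCI", "AD"][i % 3]
    return phantom.synthesize_subject(template, atlas, stage, field,
                                      noise_sd=0.03, seed=i, texture_seed=7)


train_set = [make_subject(i) for i in range(10)]
held_out = make_subject(99)

model = registration.RegistrationModel(shape, hidden=8, seed=0)
config = registration.TrainConfig(loss="ncc", lam=3.0, lr=3e-3,
                                  iterations=800, seed=0)
model, history = registration.train(model, train_set, template, config)
print(f"training loss: {history[0]:.4f} (start) -> "
      f"{np.mean(history[-20:]):.4f} (end)")

warped, field = registration.normalize(held_out.pet_native, model)
mask = template.data > 0.05 * template.data.max()
e_model = endpoint_error(field.disp, held_out.true_field.disp, mask)
e_zero = endpoint_error(np.zeros_like(field.disp), held_out.true_field.disp, mask)
print(f"held-out mean endpoint error: {e_model:.2f} voxels "
      f"(doing nothing: {e_zero:.2f}) -> {100 * (1 - e_model / e_zero):.0f}% "
      f"of the deformation recovered")
print(f"template similarity (NCC loss, lower is better): "
      f"{registration.similarity_loss(held_out.pet_native, template):.4f} before, "
      f"{registration.similarity_loss(warped, template):.4f} after")
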