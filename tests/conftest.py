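"""Shared fixtures.

The expensive trained-model fixture is session-scoped and only built when a
test that needs it runs; everything else uses small grids (24^3) so the bulk
of the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from petnorm import phantom, registration


@pytest.fixture(scope="session")
def template_atlas_32():
    return phantom.make_template((32, 32, 32), seed=7)


@pytest.fixture(scope="session")
def template_atlas_24():
    return phantom.make_template((24, 24, 24), seed=5)


def make_validation_subject(template, atlas, index: int, stage: str, *,
                            amplitude=2.0, noise_frac=0.05, texture_seed=7):
    """One phantom subject under the validation-cohort conditions:
    amplitude-2 smoothness-4 deformation, PET noise at 5% of mean activity."""
    field = phantom.sample_deformation(template.shape, amplitude=amplitude,
                                       smoothness=4.0, seed=20_000 + index)
    # noise level is a fraction of the mean painted activity (about 0.66 in
    # head+background units the painter produces)
    ref_uptake, _ = phantom.paint_uptake(atlas, stage, texture_seed=texture_seed)
    noise_sd = noise_frac * float(ref_uptake.mean())
    return phantom.synthesize_subject(template, atlas, stage, field,
                                      noise_sd=noise_sd, seed=30_000 + index,
                                      texture_seed=texture_seed,
                                      subject_id=f"sub-{index:04d}")


@pytest.fixture(scope="session")
def validation_cohort_40(template_atlas_32):
    template, atlas = template_atlas_32
    stages = phantom.stratified_stages(40, seed=10_000)
    return [make_validation_subject(template, atlas, i, stages[i])
            for i in range(40)]


@pytest.fixture(scope="session")
def heldout_cohort_20(template_atlas_32):
    template, atlas = template_atlas_32
    stages = phantom.stratified_stages(20, seed=10_500)
    return [make_validation_subject(template, atlas, 500 + i, stages[i])
            for i in range(20)]


@pytest.fixture(scope="session")
def trained_model_32(template_atlas_32, validation_cohort_40):
    """The cascaded model trained on the 40-subject validation cohort."""
    template, _ = template_atlas_32
    model = registration.RegistrationModel(template.shape, hidden=8, seed=0)
    config = registration.TrainConfig(iterations=1200, seed=0, lr=3e-3, lam=3.0)
    model, history = registration.train(model, validation_cohort_40, template, config)
    assert np.isfinite(history).all()
    return model
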