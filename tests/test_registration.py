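import numpy as np
import pytest

from petnorm import phantom, registration
from petnorm.registration import (AugmentRanges, ModelLoadError,
                                  RegistrationModel, TrainConfig, augment,
                                  fine_tune, normalize, regularizer,
                                  similarity_loss, train, warp)
from petnorm.volumes import DeformationField, ShapeError, Volume3D


def brute_force_warp(image, disp):
    """Independent per-voxel trilinear resampling oracle (zero padding)."""
    out = np.zeros(image.shape)
    nx, ny, nz = image.shape

    def sample(x, y, z):
        x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                    w = ((1 - abs(x - xi)) * (1 - abs(y - yi)) * (1 - abs(z - zi)))
                    if 0 <= xi < nx and 0 <= yi < ny and 0 <= zi < nz and w > 0:
                        acc += w * image[xi, yi, zi]
        return acc

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = sample(i + disp[i, j, k, 0], j + disp[i, j, k, 1],
                                      k + disp[i, j, k, 2])
    return out


class TestWarp:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(10, 10, 10))
        out = warp(img, DeformationField.zero((10, 10, 10)))
        assert np.array_equal(out, img)

    def test_integer_shift_is_exact_copy_inside_bounds(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(10, 10, 10))
        disp = np.zeros((10, 10, 10, 3))
        disp[..., 2] = 3.0
        out = warp(img, DeformationField(disp))
        assert np.allclose(out[:, :, :7], img[:, :, 3:], atol=1e-12)
        assert np.allclose(out[:, :, 7:], 0.0)

    def test_matches_per_voxel_interpolation_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(8, 8, 8))
        disp = rng.uniform(-2.5, 2.5, (8, 8, 8, 3))
        out = warp(img, DeformationField(disp))
        assert np.allclose(out, brute_force_warp(img, disp), atol=1e-6)

    def test_nearest_preserves_label_values(self):
        labels = np.zeros((8, 8, 8))
        labels[2:5, 2:5, 2:5] = 4.0
        disp = np.full((8, 8, 8, 3), 0.3)
        out = warp(labels, DeformationField(disp), interpolation="nearest")
        assert set(np.unique(out)) <= {0.0, 4.0}

    def test_grid_mismatch_raises(self):
        with pytest.raises(ShapeError):
            warp(np.ones((8, 8, 8)), DeformationField.zero((10, 10, 10)))


class TestSimilarityLoss:
    def test_identical_images_are_zero(self):
        img = np.random.default_rng(0).normal(size=(8, 8, 8))
        assert similarity_loss(img, img, "mse") == pytest.approx(0.0, abs=1e-15)
        assert similarity_loss(img, img, "ncc") == pytest.approx(0.0, abs=1e-12)

    def test_ncc_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        tpl = rng.normal(size=(8, 8, 8))
        warped = 2.5 * tpl + 0.7
        assert similarity_loss(warped, tpl, "ncc") == pytest.approx(0.0, abs=1e-12)
        expected_mse = float((((2.5 - 1) * tpl + 0.7) ** 2).mean())
        assert similarity_loss(warped, tpl, "mse") == pytest.approx(expected_mse)

    def test_matches_hand_computed_oracle_on_3x3x3(self):
        a = np.arange(27, dtype=float).reshape(3, 3, 3)
        b = (a % 5) + 1.0
        ac = a.ravel() - a.mean()
        bc = b.ravel() - b.mean()
        ncc = float(ac @ bc) / np.sqrt(float(ac @ ac) * float(bc @ bc))
        assert similarity_loss(a, b, "ncc") == pytest.approx(1 - ncc, abs=1e-12)
        assert similarity_loss(a, b, "mse") == pytest.approx(
            float(((a - b) ** 2).mean()), abs=1e-12)

    def test_constant_image_guard(self):
        tpl = np.random.default_rng(0).normal(size=(8, 8, 8))
        assert similarity_loss(np.ones((8, 8, 8)), tpl, "ncc") == 1.0


class TestRegularizer:
    def test_zero_and_constant_fields_cost_nothing(self):
        assert regularizer(DeformationField.zero((8, 8, 8))) == 0.0
        const = DeformationField(np.full((8, 8, 8, 3), 2.5))
        assert regularizer(const) == 0.0

    def test_linear_ramp_matches_finite_difference_oracle(self):
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 0] = np.arange(8)[:, None, None]
        # forward differences: along x the x-component steps by exactly 1 at
        # 7*8*8 positions; all other differences vanish
        total_elements = 3 * (7 * 8 * 8) * 3
        expected = (7 * 8 * 8) / total_elements
        assert regularizer(DeformationField(disp)) == pytest.approx(expected,
                                                                    abs=1e-12)


class TestAugment:
    def test_zero_ranges_is_identity(self):
        img = np.random.default_rng(0).normal(size=(12, 12, 12))
        out = augment(img, AugmentRanges(), seed=3)
        assert out is img

    def test_same_seed_identical(self):
        img = np.random.default_rng(1).normal(size=(12, 12, 12))
        ranges = AugmentRanges(noise_sd=0.1, translation=2, rotation_deg=5)
        a = augment(img, ranges, seed=11)
        b = augment(img, ranges, seed=11)
        assert np.array_equal(a, b)

    def test_translation_matches_warp_oracle_and_round_trips(self):
        """A translation-only augmentation equals resampling through the
        corresponding constant displacement (pull semantics), and warping
        back with the inverse translation restores a smooth image's interior
        up to interpolation loss."""
        from scipy import ndimage as ndi

        rng = np.random.default_rng(2)
        img = ndi.gaussian_filter(rng.normal(size=(16, 16, 16)), 2.0)
        ranges = AugmentRanges(translation=3.0)
        moved = augment(img, ranges, seed=5)
        # the translation actually drawn (same generator protocol)
        trans = np.random.default_rng(5).uniform(-3, 3, 3)
        disp = np.broadcast_to(trans, (16, 16, 16, 3)).copy()
        oracle = warp(img, DeformationField(disp))
        interior = (slice(4, -4),) * 3
        assert np.allclose(moved[interior], oracle[interior], atol=1e-10)
        back = warp(moved, DeformationField(-disp))
        # double fractional interpolation of a smooth image: small, not exact
        assert np.abs(back[interior] - img[interior]).max() < 0.02


class TestModelBasics:
    def test_untrained_model_predicts_exact_zero_field(self, template_atlas_24):
        template, _ = template_atlas_24
        model = RegistrationModel(template.shape, seed=0, template=template)
        pet = np.random.default_rng(0).uniform(0, 2, template.shape)
        warped, field = normalize(pet, model)
        assert not np.any(field.disp)
        assert np.allclose(warped, pet)

    def test_normalize_is_deterministic(self, template_atlas_24, tiny_trained_model):
        template, _ = template_atlas_24
        pet = np.random.default_rng(1).uniform(0, 2, template.shape)
        w1, f1 = normalize(pet, tiny_trained_model)
        w2, f2 = normalize(pet, tiny_trained_model)
        assert np.array_equal(w1, w2) and np.array_equal(f1.disp, f2.disp)

    def test_grid_not_divisible_by_four_rejected(self):
        with pytest.raises(ShapeError):
            RegistrationModel((30, 30, 30))

    def test_checkpoint_round_trip_and_corruption(self, tmp_path, template_atlas_24,
                                                  tiny_trained_model):
        template, _ = template_atlas_24
        path = tmp_path / "model.ckpt.npz"
        tiny_trained_model.save(path)
        back = RegistrationModel.load(path)
        pet = np.random.default_rng(2).uniform(0, 2, template.shape)
        f1 = tiny_trained_model.predict_field(pet)
        f2 = back.predict_field(pet)
        assert np.array_equal(f1.disp, f2.disp)
        # a corrupted checkpoint must raise, not silently reinitialize
        path.write_bytes(path.read_bytes()[: path.stat().st_size // 2])
        with pytest.raises(ModelLoadError):
            RegistrationModel.load(path)


@pytest.fixture(scope="session")
def tiny_training_setup(template_atlas_24):
    template, atlas = template_atlas_24
    subs = []
    for i in range(6):
        field = phantom.sample_deformation(template.shape, 2.0, 4.0, seed=70 + i)
        subs.append(phantom.synthesize_subject(template, atlas,
                                               ["CN", "MCI", "AD"][i % 3], field,
                                               noise_sd=0.03, seed=i,
                                               texture_seed=5))
    return template, atlas, subs


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_training_setup):
    template, _, subs = tiny_training_setup
    model = RegistrationModel(template.shape, hidden=8, seed=0)
    config = TrainConfig(iterations=150, seed=0, lr=3e-3, lam=1.0)
    model, _ = train(model, subs, template, config)
    return model


class TestTraining:
    def test_self_registration_leaves_field_small(self, template_atlas_24):
        """Training on the template itself: the predicted field stays below
        half a voxel on average (there is nothing to correct)."""
        template, _ = template_atlas_24
        model = RegistrationModel(template.shape, hidden=8, seed=0)
        config = TrainConfig(iterations=50, seed=0, lam=1.0)
        model, _ = train(model, [template], template, config)
        field = model.predict_field(template)
        assert field.magnitude().mean() < 0.5

    def test_fixed_seed_reproduces_history_bitwise(self, tiny_training_setup):
        template, _, subs = tiny_training_setup
        hists = []
        for _ in range(2):
            model = RegistrationModel(template.shape, hidden=8, seed=0)
            config = TrainConfig(iterations=20, seed=0)
            _, hist = train(model, subs, template, config)
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_loss_descends_on_phantom_set(self, tiny_training_setup,
                                          tiny_trained_model):
        template, _, subs = tiny_training_setup
        model = RegistrationModel(template.shape, hidden=8, seed=0)
        config = TrainConfig(iterations=200, seed=0, lr=3e-3, lam=1.0)
        _, hist = train(model, subs, template, config)
        assert np.mean(hist[-20:]) < hist[0]

    def test_trained_model_beats_zero_field(self, tiny_training_setup,
                                            tiny_trained_model, template_atlas_24):
        """On a fresh phantom the predicted field has lower endpoint error
        than doing nothing, and improves template similarity."""
        from petnorm.grid import endpoint_error

        template, atlas = template_atlas_24
        field = phantom.sample_deformation(template.shape, 2.0, 4.0, seed=901)
        sub = phantom.synthesize_subject(template, atlas, "MCI", field,
                                         noise_sd=0.03, seed=55, texture_seed=5)
        warped, pred = normalize(sub.pet_native, tiny_trained_model)
        mask = template.data > 0.05 * template.data.max()
        e_model = endpoint_error(pred.disp, field.disp, mask)
        e_zero = endpoint_error(np.zeros_like(pred.disp), field.disp, mask)
        assert e_model < e_zero

    def test_empty_subject_list_rejected(self, template_atlas_24):
        template, _ = template_atlas_24
        with pytest.raises(ValueError):
            train(RegistrationModel(template.shape), [], template, TrainConfig())


class TestFineTune:
    def test_zero_iterations_is_identity(self, tiny_trained_model, tmp_path,
                                         template_atlas_24):
        template, _ = template_atlas_24
        path = tmp_path / "pre.npz"
        tiny_trained_model.save(path)
        tuned, hist = fine_tune(path, [template], template,
                                TrainConfig(iterations=0))
        assert hist == []
        for a, b in zip(tiny_trained_model.params(), tuned.params()):
            assert np.array_equal(a.data, b.data)

    def test_unreadable_checkpoint_raises_load_error(self, tmp_path,
                                                     template_atlas_24):
        template, _ = template_atlas_24
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a checkpoint at all")
        with pytest.raises(ModelLoadError):
            fine_tune(path, [template], template, TrainConfig(iterations=1))
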