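"""MR-free spatial normalization by cascaded deformation-field prediction.

The model takes a native-space PET (or MR) volume as its only input and
predicts the nonlinear deformation field that resamples it onto the template
grid.  It is a two-stage cascade:

* the **coarse** stage sees the volume at quarter resolution and predicts a
  low-resolution displacement grid, upsampled trilinearly to the full grid —
  this captures the smooth bulk of the deformation (including its affine-like
  component);
* the **fine** stage sees the coarse-warped volume at full resolution and
  predicts a residual displacement.

Both stages are small fully convolutional networks whose inputs are the
intensity-normalized moving image, the template, and three normalized
coordinate channels (a convolution alone is translation-equivariant, so the
coordinate channels supply the absolute position information that mapping to
a fixed template requires).  The composed field is
``phi(v) = phi_fine(v) + phi_coarse(v + phi_fine(v))``, stored
template->native with pull semantics, so a single resampling of the input
through ``phi`` reproduces the cascade's warp.

Training is unsupervised: it minimizes
``similarity_loss(warp(input, predicted field), template)
+ lambda * (diffusion(phi_coarse) + diffusion(phi_fine))``
over randomly drawn (optionally augmented) training volumes, with Adam.
There is no ground-truth field anywhere in the objective; known fields exist
only in the phantom module, for evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import _nn, grid
from .volumes import DeformationField, ShapeError, Volume3D, require_congruent


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""

    def __init__(self, iteration: int, message: str):
        super().__init__(f"iteration {iteration}: {message}")
        self.iteration = iteration


class ModelLoadError(RuntimeError):
    """Checkpoint unreadable or architecture-incompatible."""


# ---------------------------------------------------------------------------
# similarity / regularity functionals (module surface; array or Volume3D input)


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume3D) else np.asarray(v, dtype=np.float64)


def warp(volume: Volume3D | np.ndarray, field: DeformationField,
         interpolation: str = "trilinear") -> Volume3D | np.ndarray:
    """Resample a volume through a displacement field (pull semantics).

    ``out[v] = volume(v + disp[v])``; samples outside the grid are zero.
    ``nearest`` is for label maps.  The field grid defines the output grid and
    must match the volume grid.
    """
    arr = _as_array(volume)
    if arr.shape != field.grid_shape:
        raise ShapeError(f"volume grid {arr.shape} != field grid {field.grid_shape}")
    out = grid.warp_array(arr, field.disp, interpolation=interpolation)
    if isinstance(volume, Volume3D):
        return volume.like(out)
    return out


def similarity_loss(warped, template, kind: str = "ncc") -> float:
    """Dissimilarity between two congruent volumes; 0 is a perfect match.

    ``mse`` is the mean squared difference.  ``ncc`` is one minus the global
    normalized cross-correlation (invariant to affine intensity rescaling);
    a zero-variance image makes the correlation undefined and returns the
    guard value 1.
    """
    a, b = _as_array(warped), _as_array(template)
    require_congruent(a.shape, b.shape)
    if kind == "mse":
        return float(((a - b) ** 2).mean())
    if kind == "ncc":
        ac = a.ravel() - a.mean()
        bc = b.ravel() - b.mean()
        a2, b2 = float(ac @ ac), float(bc @ bc)
        if a2 <= 0.0 or b2 <= 0.0:
            return 1.0
        return 1.0 - float(ac @ bc) / np.sqrt(a2 * b2)
    raise ValueError(f"unknown similarity kind {kind!r}")


def regularizer(field: DeformationField) -> float:
    """Diffusion penalty: mean squared forward-difference gradient of the field."""
    d = np.moveaxis(field.disp, -1, 0)
    total, ssq = 0, 0.0
    for ax in (1, 2, 3):
        hi = [slice(None)] * 4
        lo = [slice(None)] * 4
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        diff = d[tuple(hi)] - d[tuple(lo)]
        ssq += float((diff**2).sum())
        total += diff.size
    return ssq / total


def augment(volume: Volume3D | np.ndarray, ranges: "AugmentRanges | None",
            seed: int) -> Volume3D | np.ndarray:
    """Random rigid jitter plus additive Gaussian noise (training-time only).

    Translation is uniform within +/- ``translation`` voxels per axis, rotation
    uniform within +/- ``rotation_deg`` per axis about the volume center,
    resampled trilinearly; noise is N(0, noise_sd).  All-zero ranges return
    the input unchanged (bit-exact).
    """
    if ranges is None:
        ranges = AugmentRanges()
    arr = _as_array(volume)
    rng = np.random.default_rng(seed)
    out = arr
    if ranges.translation > 0 or ranges.rotation_deg > 0:
        trans = rng.uniform(-ranges.translation, ranges.translation, 3)
        angles = rng.uniform(-ranges.rotation_deg, ranges.rotation_deg, 3)
        rot = _rotation_matrix(angles)
        center = (np.asarray(arr.shape) - 1) / 2.0
        offset = center - rot @ center + trans
        out = ndimage.affine_transform(arr, rot, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    if ranges.noise_sd > 0:
        out = out + rng.normal(0.0, ranges.noise_sd, arr.shape)
    if out is arr:
        return volume
    return volume.like(out) if isinstance(volume, Volume3D) else out


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AugmentRanges:
    """Augmentation amplitudes; zero disables each component."""

    noise_sd: float = 0.0
    translation: float = 0.0
    rotation_deg: float = 0.0


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``lr=None`` resolves to 1e-3 for :func:`train` and to a 10x smaller 1e-4
    for :func:`fine_tune`.  ``lam`` weights the diffusion regularizer applied
    to both cascade stages.
    """

    loss: str = "ncc"
    lam: float = 1.0
    lr: Optional[float] = None
    iterations: int = 200
    batch_size: int = 1
    augment: AugmentRanges = dc_field(default_factory=AugmentRanges)
    seed: int = 0
    fine_tune_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("regularizer weight must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if isinstance(self.augment, dict):
            self.augment = AugmentRanges(**self.augment)


# ---------------------------------------------------------------------------
# the cascaded model


class _ConvStage:
    """Three 3x3x3 conv layers; the last layer is zero-initialized so the
    stage starts out predicting the zero field.  ``out_sigma > 0`` appends a
    fixed Gaussian smoothing of the predicted displacement — a structural
    smoothness prior on top of the diffusion penalty, so the stage can only
    express fields at least as smooth as the deformations being modeled."""

    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator,
                 out_sigma: float = 0.0):
        def he(shape):
            fan_in = shape[1] * 27
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        self.out_sigma = out_sigma
        self.w1 = _nn.parameter(he((hidden, in_ch, 3, 3, 3)))
        self.b1 = _nn.parameter(np.zeros(hidden))
        self.w2 = _nn.parameter(he((hidden, hidden, 3, 3, 3)))
        self.b2 = _nn.parameter(np.zeros(hidden))
        self.w3 = _nn.parameter(np.zeros((3, hidden, 3, 3, 3)))
        self.b3 = _nn.parameter(np.zeros(3))

    def params(self) -> List[_nn.Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def forward(self, x: _nn.Tensor) -> Tuple[_nn.Tensor, _nn.Tensor]:
        """Returns (predicted displacement, last hidden feature map)."""
        h = _nn.leaky_relu(_nn.conv3d(x, self.w1, self.b1))
        h = _nn.leaky_relu(_nn.conv3d(h, self.w2, self.b2))
        out = _nn.conv3d(h, self.w3, self.b3)
        if self.out_sigma > 0:
            out = _nn.smooth3(out, self.out_sigma)
        return out, h


def _coord_channels(shape: Tuple[int, int, int]) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def _avg_pool(x: np.ndarray, k: int) -> np.ndarray:
    nx, ny, nz = x.shape
    return x.reshape(nx // k, k, ny // k, k, nz // k, k).mean(axis=(1, 3, 5))


def _normalize_intensity(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt((x**2).mean())
    return x / (rms + 1e-12)


class RegistrationModel:
    """Cascaded coarse-to-fine deformation predictor on a fixed template grid.

    Parameters
    ----------
    grid_shape:
        Template grid; each dimension must be divisible by 4 (the coarse
        stage works at quarter resolution).
    hidden:
        Channel width of both conv stages.
    seed:
        Weight initialization seed (zero-initialized output layers make the
        untrained model predict the exact zero field regardless of seed).
    template:
        Optional template volume; it can also be supplied later via
        :func:`train`.  Required before :meth:`predict_field`.
    """

    COARSE_FACTOR = 4

    def __init__(self, grid_shape: Sequence[int], hidden: int = 8, seed: int = 0,
                 template: Optional[Volume3D | np.ndarray] = None):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        if any(n % self.COARSE_FACTOR for n in self.grid_shape):
            raise ShapeError(f"grid {self.grid_shape} not divisible by {self.COARSE_FACTOR}")
        self.hidden = int(hidden)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.coarse = _ConvStage(8, hidden, rng)
        self.fine = _ConvStage(8, hidden, rng, out_sigma=1.5)
        # global affine head on pooled coarse-feature moments (zeroth and
        # first spatial moments; zero-initialized, so the untrained model
        # still predicts the exact zero field)
        self.wa = _nn.parameter(np.zeros((12, hidden * 4)))
        self.ba = _nn.parameter(np.zeros(12))
        self.template: Optional[np.ndarray] = None
        self._coords_full = _coord_channels(self.grid_shape)
        low = tuple(n // self.COARSE_FACTOR for n in self.grid_shape)
        self._coords_low = _coord_channels(low)
        self._low_shape = low
        # voxel coordinates centered on the volume, for the affine head
        axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2 for n in self.grid_shape]
        self._centered = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
        if template is not None:
            self.set_template(template)

    # -- template ----------------------------------------------------------
    def set_template(self, template: Volume3D | np.ndarray) -> None:
        arr = _as_array(template)
        if arr.shape != self.grid_shape:
            raise ShapeError(f"template grid {arr.shape} != model grid {self.grid_shape}")
        self._install_template(_normalize_intensity(arr))

    def _install_template(self, normalized: np.ndarray) -> None:
        """Install an already-normalized template (bit-exact on reload)."""
        self.template = normalized
        self._template_low = _avg_pool(self.template, self.COARSE_FACTOR)
        # spatial gradients of the template, used as force-feature channels:
        # (moving - template) * grad(template) is the first-order mismatch
        # force driving intensity-based registration
        self._tgrad = np.stack(np.gradient(self.template), axis=0)
        self._tgrad_low = np.stack(np.gradient(self._template_low), axis=0)

    # -- forward -----------------------------------------------------------
    def _forward_graph(self, volume: np.ndarray, anatomy: Optional[np.ndarray] = None):
        """Build the training graph; returns (coarse disp, fine disp, final warped).

        The deformation is always predicted from ``volume`` (the PET at
        inference time).  When ``anatomy`` is given — the paired structural
        volume during training — the returned warped image is the anatomy
        resampled through the predicted cascade, so the similarity loss is
        evaluated between the standardized anatomy and the template while the
        prediction itself remains PET-only.
        """
        if self.template is None:
            raise ModelLoadError("model has no template; call set_template or train first")
        xn = _normalize_intensity(volume)
        x_low = _avg_pool(xn, self.COARSE_FACTOR)
        diff_low = x_low - self._template_low
        coarse_in = _nn.Tensor(np.concatenate(
            [x_low[None], self._template_low[None],
             diff_low[None] * self._tgrad_low, self._coords_low], axis=0))
        disp_low, hidden_low = self.coarse.forward(coarse_in)
        disp_grid = _nn.upsample3(disp_low, self.COARSE_FACTOR, self.grid_shape)
        # global affine component from spatial moments of the coarse features
        # (zeroth + first moments carry position and orientation, which plain
        # average pooling discards); the grid part carries the residual
        # smooth deformation
        moments = _nn.global_mean(_nn.stack_channels(
            [hidden_low,
             _nn.mul_const(hidden_low, self._coords_low[0]),
             _nn.mul_const(hidden_low, self._coords_low[1]),
             _nn.mul_const(hidden_low, self._coords_low[2])]))
        affine_params = _nn.dense(moments, self.wa, self.ba)
        disp_aff = _nn.affine_field(affine_params, self._centered)
        disp_c = _nn.add(disp_grid, disp_aff)
        warped1 = _nn.warp(xn, disp_c)
        diff = _nn.add_const(warped1, -self.template)
        fine_in = _nn.stack_channels(
            [warped1, self.template,
             _nn.mul_const(diff, self._tgrad[0]),
             _nn.mul_const(diff, self._tgrad[1]),
             _nn.mul_const(diff, self._tgrad[2]),
             self._coords_full[0], self._coords_full[1], self._coords_full[2]])
        disp_f, _ = self.fine.forward(fine_in)
        if anatomy is None:
            warped_mid = warped1
            warped2 = _nn.warp(warped1, disp_f)
        else:
            an = _normalize_intensity(anatomy)
            warped_mid = _nn.warp(an, disp_c)
            warped2 = _nn.warp(warped_mid, disp_f)
        # diffusion is applied to the nonparametric parts only: a global
        # affine is smooth by construction and should not be shrunk
        return disp_c, disp_f, warped2, warped_mid, (disp_grid, disp_f)

    def params(self) -> List[_nn.Tensor]:
        return self.coarse.params() + self.fine.params() + [self.wa, self.ba]

    def predict_field(self, volume: Volume3D | np.ndarray) -> DeformationField:
        """Composed template->native field from a single forward pass."""
        disp_c, disp_f, _, _, _ = self._forward_graph(_as_array(volume))
        outer = np.moveaxis(disp_c.data, 0, -1)
        inner = np.moveaxis(disp_f.data, 0, -1)
        return DeformationField(grid.compose_displacements(outer, inner))

    # -- checkpoint --------------------------------------------------------
    def arch_descriptor(self) -> Dict:
        return {"grid_shape": list(self.grid_shape), "hidden": self.hidden,
                "coarse_factor": self.COARSE_FACTOR, "stages": 2, "layers": 3}

    def arch_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.arch_descriptor(), sort_keys=True).encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: architecture hash + parameters (+ template)."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        if self.template is not None:
            arrays["template"] = self.template
        header = json.dumps({"arch": self.arch_descriptor(), "hash": self.arch_hash(),
                             "seed": self.seed})
        np.savez(str(path), __meta__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RegistrationModel":
        try:
            with np.load(str(path)) as npz:
                meta = json.loads(bytes(npz["__meta__"]).decode())
                arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        except Exception as exc:  # unreadable / truncated / not an archive
            raise ModelLoadError(f"cannot read checkpoint {path}: {exc}") from exc
        arch = meta.get("arch", {})
        model = cls(arch.get("grid_shape", ()), hidden=arch.get("hidden", 0),
                    seed=meta.get("seed", 0))
        if model.arch_hash() != meta.get("hash"):
            raise ModelLoadError("architecture hash mismatch in checkpoint")
        for i, p in enumerate(model.params()):
            stored = arrays.get(f"p{i}")
            if stored is None or stored.shape != p.data.shape:
                raise ModelLoadError(f"parameter {i} missing or mis-shaped in checkpoint")
            p.data = stored.astype(np.float64)
        if "template" in arrays:
            model._install_template(arrays["template"].astype(np.float64))
        return model

    def copy(self) -> "RegistrationModel":
        m = RegistrationModel(self.grid_shape, self.hidden, self.seed)
        for src, dst in zip(self.params(), m.params()):
            dst.data = src.data.copy()
        if self.template is not None:
            m._install_template(self.template.copy())
        return m


# ---------------------------------------------------------------------------
# training


def _unpack_subject(s) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """(prediction input, optional paired anatomy) from a training element.

    Accepts a bare volume, an ``(input, anatomy)`` pair, or a
    :class:`~petnorm.volumes.PhantomSubject` (PET input, MR anatomy).
    """
    from .volumes import PhantomSubject

    if isinstance(s, PhantomSubject):
        anat = None if s.mr_native is None else _as_array(s.mr_native)
        return _as_array(s.pet_native), anat
    if isinstance(s, tuple):
        inp, anat = s
        return _as_array(inp), (None if anat is None else _as_array(anat))
    return _as_array(s), None


def train(model: RegistrationModel, subjects: Sequence,
          template: Volume3D | np.ndarray, config: TrainConfig,
          _lr_default: float = 1e-3) -> Tuple[RegistrationModel, List[float]]:
    """Unsupervised training of the cascade; returns (model, loss history).

    Each subject is either a bare volume or a (PET, MR) pair (also accepted:
    :class:`~petnorm.volumes.PhantomSubject`).  The deformation is predicted
    from the first element only; when a paired anatomy is present the
    similarity is measured between the *anatomy* warped by the predicted
    field and the template — the paired-anatomy supervision that lets a
    PET-only predictor be trained against an anatomical template whose tissue
    contrast the PET does not share.  Inference never uses the anatomy.

    Each iteration draws ``batch_size`` random training subjects (with
    replacement), optionally augments them (the same rigid jitter is applied
    to both volumes of a pair), and takes one Adam step on the mean of
    ``similarity + lam * diffusion`` over the batch.  Fully deterministic
    under ``config.seed``.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one training subject")
    model.set_template(template)
    vols = [_unpack_subject(s) for s in subjects]
    require_congruent(*(v[0].shape for v in vols), model.grid_shape)
    lr = config.lr if config.lr is not None else _lr_default
    opt = _nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(config.seed)
    aug = config.augment
    do_aug = aug.noise_sd > 0 or aug.translation > 0 or aug.rotation_deg > 0
    history: List[float] = []
    for it in range(config.iterations):
        opt.zero_grad()
        total: Optional[_nn.Tensor] = None
        for _ in range(config.batch_size):
            idx = int(rng.integers(len(vols)))
            vol, anat = vols[idx]
            if do_aug:
                aug_seed = int(rng.integers(2**31 - 1))
                vol = augment(vol, aug, seed=aug_seed)
                if anat is not None:
                    anat = augment(anat, aug, seed=aug_seed)
            disp_c, disp_f, warped, warped_mid, reg_parts = model._forward_graph(vol, anat)
            if config.loss == "ncc":
                sim = _nn.ncc_loss(warped, model.template)
                sim_mid = _nn.ncc_loss(warped_mid, model.template)
            elif config.loss == "mse":
                sim = _nn.mse_loss(warped, model.template)
                sim_mid = _nn.mse_loss(warped_mid, model.template)
            else:
                raise ValueError(f"unknown loss {config.loss!r}")
            # deep supervision: the coarse stage also matches the template on
            # its own (half weight), keeping bulk alignment in the coarse field
            sim = _nn.add(sim, _nn.scale(sim_mid, 0.5))
            reg = _nn.add(_nn.diffusion_reg(reg_parts[0]), _nn.diffusion_reg(reg_parts[1]))
            term = _nn.add(sim, _nn.scale(reg, config.lam))
            total = term if total is None else _nn.add(total, term)
        loss = _nn.scale(total, 1.0 / config.batch_size)
        value = loss.item()
        if not np.isfinite(value):
            raise TrainingError(it, f"non-finite loss {value}")
        loss.backward()
        opt.step()
        history.append(value)
    return model, history


def fine_tune(pretrained: str | Path | RegistrationModel,
              subjects: Sequence[Volume3D | np.ndarray],
              template: Volume3D | np.ndarray,
              config: TrainConfig) -> Tuple[RegistrationModel, List[float]]:
    """Transfer learning: resume from a pretrained checkpoint at reduced rate.

    Initializes from the pretrained weights and trains with a default learning
    rate of 1e-4 (10x below the from-scratch default) unless ``config.lr``
    overrides it.  Zero iterations returns the pretrained weights unchanged.
    """
    if isinstance(pretrained, RegistrationModel):
        model = pretrained.copy()
    else:
        model = RegistrationModel.load(pretrained)
    if config.iterations == 0:
        model.set_template(template)
        return model, []
    return train(model, subjects, template, config, _lr_default=1e-4)


def normalize(pet: Volume3D | np.ndarray, model: RegistrationModel
              ) -> Tuple[Volume3D | np.ndarray, DeformationField]:
    """MR-free spatial normalization: one forward pass, one resampling.

    Returns the PET resampled onto the template grid through the composed
    predicted field, and the field itself (template->native, voxel units).
    """
    arr = _as_array(pet)
    if arr.shape != model.grid_shape:
        raise ShapeError(f"input grid {arr.shape} != model grid {model.grid_shape}")
    field = model.predict_field(arr)
    warped = grid.warp_array(arr, field.disp)
    if isinstance(pet, Volume3D):
        return pet.like(warped), field
    return warped, field
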