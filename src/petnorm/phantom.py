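"""Synthetic head phantoms with known deformations and known regional uptake.

Everything downstream (registration, the classic baseline, SUVR
quantification, the validation statistics) is exercised on phantoms from this
module, so no external image or atlas download is ever needed.  The phantom
emulates the *structure* of the real problem — a common template, per-subject
smooth invertible deformations relating native space to template space,
ROI-dependent tracer uptake with a cerebellar-gray reference, additive noise,
and cognitive scores stochastically tied to tau burden — not PET physics or
anatomical realism.

Geometry.  The template head is a nested pair of ellipsoids ("gray" shell and
"white" core) plus an inferior-posterior cerebellum; seven ROI blobs stand in
for the Braak-stage composites (entorhinal + contralateral for stages I-II,
inferior-temporal + contralateral for III-IV, frontal + occipital for V-VI),
with the metatemporal composite the union of the temporal blobs.  The role
taxonomy of the real Braak/Desikan-Killiany parcellation is reproduced; the
anatomy is schematic.

Truth convention.  For each subject a smooth template->native pull field ``g``
is sampled; the native image is synthesized through the numerical inverse of
``g`` so that resampling the native image through ``g`` recovers the
template-space image.  ``true_suvr`` is computed from the painted
template-space uptake before warping and noise; the cerebellar gray paints at
the reference level, so its own SUVR is 1 by construction.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import grid
from .volumes import (CohortRecord, DeformationField, PhantomSubject, ROIAtlas,
                      Volume3D)

STAGES = ("CN", "MCI", "AD")

#: Template tissue intensities (arbitrary MR-like units).
_TISSUE_INTENSITY = {"gray": 0.8, "white": 1.0, "cerebellum": 0.85}

#: Baseline tracer uptake of plain tissue, relative to cerebellar gray = 1.
_TISSUE_UPTAKE = {"gray": 1.0, "white": 0.7, "cerebellum": 1.0, "background": 0.0}

#: Atlas labels.  0 is background (including plain gray/white tissue).
LABEL_ROLES: Dict[int, Tuple[str, ...]] = {
    0: ("background",),
    1: ("Braak12", "metatemporal", "EC"),
    2: ("Braak12",),
    3: ("Braak34", "metatemporal", "ITG"),
    4: ("Braak34", "metatemporal"),
    5: ("Braak56",),
    6: ("Braak56",),
    7: ("cerebellar_gray",),
}

#: Stage-dependent uptake painted into each ROI label (tau profile).
#: CN sits near the tissue baseline; MCI elevates the early Braak stages;
#: AD elevates all stages, strongest in Braak I-II — a schematic rendering of
#: the canonical entorhinal-to-neocortex tau progression.
TAU_PROFILE: Dict[str, Dict[int, float]] = {
    "CN": {1: 1.15, 2: 1.10, 3: 1.10, 4: 1.05, 5: 1.00, 6: 1.00},
    "MCI": {1: 1.70, 2: 1.60, 3: 1.50, 4: 1.40, 5: 1.15, 6: 1.15},
    "AD": {1: 2.30, 2: 2.20, 3: 2.10, 4: 2.00, 5: 1.70, 6: 1.65},
}

#: "Amyloid-like" profile: diffuse cortical elevation, no Braak gradient.
#: Used to exercise transfer learning between two tracers.
AMYLOID_PROFILE: Dict[str, Dict[int, float]] = {
    "CN": {lab: 1.05 for lab in range(1, 7)},
    "MCI": {lab: 1.45 for lab in range(1, 7)},
    "AD": {lab: 1.60 for lab in range(1, 7)},
}


class PhantomError(RuntimeError):
    pass


def _ellipsoid(shape: Sequence[int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    coords = grid.grid_coords(tuple(shape))
    return (((coords - center) / semi) ** 2).sum(axis=-1) <= 1.0


def _anatomical_texture(shape: Tuple[int, ...], seed: int = 0,
                        sigma_frac: float = 0.09, sd: float = 0.10) -> np.ndarray:
    """Smooth, spatially asymmetric intensity texture (folding-like detail).

    Real brain images carry fine anatomical structure everywhere; a perfectly
    smooth nested-ellipsoid head would be nearly rotation-symmetric, leaving
    parts of a deformation invisible to any intensity-based registration.
    This texture is a deterministic function of the template seed, so the
    whole cohort shares one textured anatomy, as real cohorts share one brain
    plan.
    """
    rng = np.random.default_rng(seed + 915_017)
    sigma = sigma_frac * min(shape)
    tex = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    tex *= sd / (tex.std() + 1e-12)
    return tex


def _tissue_masks(shape: Tuple[int, ...]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(brain, white, cerebellum) masks shared by template and uptake painting."""
    n = np.asarray(shape, dtype=np.float64)
    brain_c = n * np.array([0.5, 0.5, 0.54])
    brain_s = n * np.array([0.42, 0.40, 0.36])
    brain = _ellipsoid(shape, brain_c, brain_s)
    white = _ellipsoid(shape, brain_c, brain_s * 0.62)
    cereb = _ellipsoid(shape, n * np.array([0.5, 0.30, 0.20]),
                       n * np.array([0.17, 0.14, 0.11]))
    return brain, white, cereb


def make_template(shape: Sequence[int] = (32, 32, 32), seed: int = 0
                  ) -> Tuple[Volume3D, ROIAtlas]:
    """Synthetic template head and congruent ROI atlas.

    Blob centers and radii are jittered deterministically from ``seed``; the
    overall layout is fixed so that ROI roles always land in plausible places
    (temporal blobs inferior-lateral, stage V-VI blobs frontal/occipital,
    cerebellum inferior-posterior).
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 24:
        raise PhantomError(f"each dimension must be >= 24, got {shape}")
    rng = np.random.default_rng(seed)
    n = np.asarray(shape, dtype=np.float64)

    tissue = np.zeros(shape)
    brain, white, cereb = _tissue_masks(shape)
    tissue[brain] = _TISSUE_INTENSITY["gray"]
    tissue[white] = _TISSUE_INTENSITY["white"]
    tissue[cereb] = _TISSUE_INTENSITY["cerebellum"]

    # label blobs: (label, fractional center, fractional radius)
    layout = [
        (1, (0.32, 0.44, 0.40), 0.115),  # entorhinal, left medial temporal
        (2, (0.68, 0.44, 0.40), 0.110),  # Braak I-II contralateral
        (3, (0.24, 0.56, 0.48), 0.120),  # inferior temporal gyrus, left
        (4, (0.76, 0.56, 0.48), 0.115),  # Braak III-IV contralateral
        (5, (0.50, 0.74, 0.66), 0.125),  # Braak V-VI frontal
        (6, (0.50, 0.30, 0.66), 0.120),  # Braak V-VI occipital
    ]
    labels = np.zeros(shape, dtype=np.int16)
    labels[cereb] = 7
    for lab, frac_c, frac_r in layout:
        center = n * np.asarray(frac_c) + rng.uniform(-0.015, 0.015, 3) * n
        radius = n * frac_r * rng.uniform(0.95, 1.05)
        blob = _ellipsoid(shape, center, np.full(3, 1.0) * radius)
        labels[blob & brain & (labels == 0)] = lab
    atlas = ROIAtlas(labels, dict(LABEL_ROLES))

    head = brain | cereb
    tissue[head] *= 1.0 + _anatomical_texture(shape, seed)[head]
    template = ndimage.gaussian_filter(tissue, sigma=0.7)
    return Volume3D(np.clip(template, 0.0, None)), atlas


class DeformationGenerationError(RuntimeError):
    """Could not produce a field with min Jacobian determinant > 0.1."""


def sample_deformation(shape: Sequence[int], amplitude: float = 2.0,
                       smoothness: float = 4.0, seed: int = 0,
                       max_retries: int = 10) -> DeformationField:
    """Smooth random displacement plus a small random affine component.

    The random part is white noise Gaussian-smoothed with ``smoothness``
    voxels and rescaled so the maximum displacement magnitude is
    ``amplitude`` voxels; the affine part adds a rotation/scale/translation
    jitter proportional to ``amplitude``.  Fields whose minimum interior
    Jacobian determinant is not above 0.1 are rescaled by 0.8 and retried (up
    to ``max_retries``), guaranteeing invertible ground truth.
    ``amplitude=0`` returns the exact zero field.
    """
    shape = tuple(int(n) for n in shape)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if amplitude == 0:
        return DeformationField.zero(shape)
    rng = np.random.default_rng(seed)

    noise = rng.normal(size=(*shape, 3))
    for c in range(3):
        noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=smoothness)
    mag = np.sqrt((noise**2).sum(axis=-1)).max()
    smooth_part = noise / (mag + 1e-12) * amplitude

    # small affine jitter about the center, scaled with amplitude
    scale = amplitude / max(shape)
    lin = np.eye(3) + rng.uniform(-scale, scale, (3, 3))
    trans = rng.uniform(-0.25 * amplitude, 0.25 * amplitude, 3)
    coords = grid.grid_coords(shape)
    center = (np.asarray(shape, dtype=np.float64) - 1) / 2
    affine_part = (coords - center) @ (lin - np.eye(3)).T + trans

    disp = smooth_part + affine_part
    for _ in range(max_retries + 1):
        if grid.jacobian_determinant(disp).min() > 0.1:
            return DeformationField(disp)
        disp = disp * 0.8
    raise DeformationGenerationError(
        f"min Jacobian determinant still <= 0.1 after {max_retries} rescales")


def paint_uptake(atlas: ROIAtlas, stage: str,
                 profile: Optional[Dict[str, Dict[int, float]]] = None,
                 roi_jitter_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None,
                 smooth_sigma: float = 0.6,
                 texture_seed: Optional[int] = None
                 ) -> Tuple[np.ndarray, Dict[str, float]]:
    """Template-space uptake map plus the true SUVR it implies.

    Non-ROI tissue uses the tissue baselines; each ROI label paints at its
    stage profile value, optionally multiplied by a per-label lognormal
    jitter (between-subject biological variability).  ``texture_seed`` (the
    template's seed) modulates tissue uptake with the same anatomical texture
    as the template, since tracer distribution follows the underlying
    anatomy.  A light Gaussian smoothing softens label boundaries; true SUVR
    is the ROI mean over the smoothed map divided by its cerebellar-gray
    mean, i.e. exactly what ideal quantification of the unwarped, noise-free
    image would return.
    """
    if profile is None:
        profile = TAU_PROFILE
    if stage not in profile:
        raise PhantomError(f"unknown stage {stage!r}")
    rng = rng or np.random.default_rng(0)
    labels = atlas.labels
    shape = labels.shape
    brain, white, cereb = _tissue_masks(shape)
    uptake = np.zeros(shape)
    uptake[brain] = _TISSUE_UPTAKE["gray"]
    uptake[white] = _TISSUE_UPTAKE["white"]
    uptake[labels == 7] = _TISSUE_UPTAKE["cerebellum"]
    for lab, level in profile[stage].items():
        jit = float(np.exp(rng.normal(0.0, roi_jitter_sd))) if roi_jitter_sd > 0 else 1.0
        uptake[labels == lab] = level * jit
    if texture_seed is not None:
        head = brain | cereb
        uptake[head] *= 1.0 + _anatomical_texture(shape, texture_seed)[head]
    if smooth_sigma > 0:
        uptake = ndimage.gaussian_filter(uptake, sigma=smooth_sigma)
    ref = float(uptake[atlas.mask("cerebellar_gray")].mean())
    true_suvr = {}
    for role in ("Braak12", "Braak34", "Braak56", "metatemporal", "EC", "ITG",
                 "cerebellar_gray"):
        m = atlas.mask(role)
        if m.any():
            true_suvr[role] = float(uptake[m].mean()) / ref
    return uptake, true_suvr


def synthesize_subject(template: Volume3D, atlas: ROIAtlas, stage: str,
                       field: DeformationField, noise_sd: float = 0.0,
                       seed: int = 0,
                       profile: Optional[Dict[str, Dict[int, float]]] = None,
                       uptake_map: Optional[np.ndarray] = None,
                       roi_jitter_sd: float = 0.10,
                       texture_seed: Optional[int] = None,
                       mr_noise_sd: Optional[float] = None,
                       subject_id: str = "sub-000") -> PhantomSubject:
    """One native-space PET/MR pair with ground-truth field and SUVR.

    ``field`` is the template->native pull field that will exactly normalize
    the subject; the native images are built through its numerical inverse.
    ``uptake_map`` overrides the painted map entirely (used by tests to paint
    uniform activity); otherwise :func:`paint_uptake` is used with the given
    stage profile and jitter.  PET is multiplied by a random global activity
    scale (SUVR is invariant to it) and Gaussian noise of absolute standard
    deviation ``noise_sd`` is added.  The MR receives its own noise:
    ``mr_noise_sd`` if given, else 2% of the MR's RMS intensity (structural
    MR is far less noisy than PET); noise-free PET implies noise-free MR, so
    the exact round-trip identities hold.
    """
    if field.grid_shape != template.shape:
        raise PhantomError("deformation field is not on the template grid")
    rng = np.random.default_rng(seed)
    if uptake_map is not None:
        pet_t = np.asarray(uptake_map, dtype=np.float64)
        ref = float(pet_t[atlas.mask("cerebellar_gray")].mean())
        if ref <= 0:
            raise PhantomError("cerebellar gray mean must be positive")
        true_suvr = {role: float(pet_t[atlas.mask(role)].mean()) / ref
                     for role in ("Braak12", "Braak34", "Braak56", "metatemporal",
                                  "EC", "ITG", "cerebellar_gray")
                     if atlas.mask(role).any()}
    else:
        pet_t, true_suvr = paint_uptake(atlas, stage, profile=profile,
                                        roi_jitter_sd=roi_jitter_sd, rng=rng,
                                        texture_seed=texture_seed)

    if np.any(field.disp):
        inv = grid.invert_displacement(field.disp)
        pet_native = grid.warp_array(pet_t, inv)
        mr_native = grid.warp_array(template.data, inv)
    else:
        pet_native = pet_t.copy()
        mr_native = template.data.copy()

    activity_scale = float(rng.uniform(0.5, 2.0))
    pet_native = pet_native * activity_scale
    if noise_sd > 0:
        pet_native = pet_native + rng.normal(0.0, noise_sd * activity_scale,
                                             pet_native.shape)
        if mr_noise_sd is None:
            mr_noise_sd = 0.02 * float(np.sqrt((mr_native**2).mean()))
        if mr_noise_sd > 0:
            mr_native = mr_native + rng.normal(0.0, mr_noise_sd, mr_native.shape)

    return PhantomSubject(
        subject_id=subject_id, stage=stage, true_suvr=true_suvr,
        pet_native=template.like(pet_native), mr_native=template.like(mr_native),
        true_field=field)


# ---------------------------------------------------------------------------
# cohorts


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def stratified_stages(n: int, stage_mix: Sequence[float] = (0.59, 0.33, 0.08),
                      seed: int = 0) -> List[str]:
    """Stage labels honoring the mix exactly: ``round(n * mix)`` per stage
    (largest-remainder rounding), deterministically permuted by seed.

    Used for validation cohorts, where an unlucky i.i.d. draw with almost no
    AD subjects would collapse the between-subject variance that agreement
    statistics need.
    """
    mix = np.asarray(stage_mix, dtype=np.float64)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
        raise ValueError("stage_mix must be three nonnegative numbers summing to 1")
    raw = n * mix
    counts = np.floor(raw).astype(int)
    for _ in range(n - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    labels = np.repeat(STAGES, counts)
    return list(np.random.default_rng(seed).permutation(labels))


def make_cohort(n: int, stage_mix: Sequence[float] = (0.59, 0.33, 0.08),
                effect: float = 8.0, noise_sd_scores: float = 4.0,
                n_visits: int = 1, seed: int = 0, *,
                template: Optional[Volume3D] = None,
                atlas: Optional[ROIAtlas] = None,
                volumes: bool = False, shape: Sequence[int] = (32, 32, 32),
                amplitude: float = 2.0, smoothness: float = 4.0,
                noise_sd_pet: float = 0.0,
                decline_per_year: float = 2.5,
                texture_seed: Optional[int] = None
                ) -> List[Tuple[PhantomSubject, List[CohortRecord]]]:
    """Cohort of phantom subjects with tau-linked cognitive scores.

    The default stage mix (59% CN / 33% MCI / 8% AD) mirrors a typical
    memory-clinic research cohort.  Cross-sectionally,
    ``MMSE = 29 - effect * (metatemporal SUVR - 1) + noise`` (MoCA likewise
    from 28), clipped to [0, 30]; the four memory probabilities use a logistic
    link with the same sign convention (higher tau, lower recall), with the
    nondurable probability bounded by 0.5.  Longitudinally each later visit
    decrements the scores in proportion to the baseline mean of EC and ITG
    SUVR excess, so baseline tau burden predicts decline.  Exam dates are
    jittered around the roughly annual scan dates.

    With ``volumes=False`` (default) no images are synthesized — subjects
    carry only stage and true SUVR — which is what the statistics tests and
    large-n Monte-Carlo checks need.  With ``volumes=True`` a template/atlas
    pair (given or generated from ``seed``) and per-subject deformations and
    noisy native volumes are produced.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    stage_mix = np.asarray(stage_mix, dtype=np.float64)
    if stage_mix.shape != (3,) or np.any(stage_mix < 0) or abs(stage_mix.sum() - 1) > 1e-9:
        raise ValueError("stage_mix must be three nonnegative numbers summing to 1")
    rng = np.random.default_rng(seed)
    if volumes:
        if template is None or atlas is None:
            template, atlas = make_template(shape, seed=seed)
            if texture_seed is None:
                texture_seed = seed
    elif atlas is None:
        # scores-only mode still needs an atlas to define true SUVR geometry
        _, atlas = make_template(shape, seed=seed)
        if texture_seed is None:
            texture_seed = seed

    stages = rng.choice(STAGES, size=n, p=stage_mix)
    out: List[Tuple[PhantomSubject, List[CohortRecord]]] = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        stage = str(stages[i])
        sub_seed = int(rng.integers(2**31 - 1))
        if volumes:
            fld = sample_deformation(template.shape, amplitude=amplitude,
                                     smoothness=smoothness,
                                     seed=int(rng.integers(2**31 - 1)))
            subject = synthesize_subject(template, atlas, stage, fld,
                                         noise_sd=noise_sd_pet, seed=sub_seed,
                                         texture_seed=texture_seed,
                                         subject_id=sid)
        else:
            srng = np.random.default_rng(sub_seed)
            _, true_suvr = paint_uptake(atlas, stage, roi_jitter_sd=0.10, rng=srng,
                                        texture_seed=texture_seed)
            subject = PhantomSubject(subject_id=sid, stage=stage, true_suvr=true_suvr)

        mt = subject.true_suvr["metatemporal"]
        ec_itg = 0.5 * (subject.true_suvr["EC"] + subject.true_suvr["ITG"])
        if stage == "CN":
            cdr = 0.0
        elif stage == "MCI":
            cdr = 0.5
        else:
            cdr = float(rng.choice([0.5, 1.0, 2.0], p=[0.2, 0.6, 0.2]))

        records: List[CohortRecord] = []
        base_mmse = 29.0 - effect * (mt - 1.0)
        base_moca = 28.0 - effect * (mt - 1.0)
        logit_noise = noise_sd_scores / 10.0
        for visit in range(n_visits):
            # later visits decline in proportion to baseline EC/ITG burden
            drop = decline_per_year * max(ec_itg - 1.0, 0.0) * visit
            mmse = base_mmse - drop + rng.normal(0.0, noise_sd_scores)
            moca = base_moca - drop + rng.normal(0.0, noise_sd_scores)
            logit_shift = 0.4 * (mt - 1.0) + 0.3 * max(ec_itg - 1.0, 0.0) * visit
            imm = _sigmoid(1.0 - 2.0 * logit_shift + rng.normal(0.0, logit_noise))
            dly = _sigmoid(0.5 - 2.0 * logit_shift + rng.normal(0.0, logit_noise))
            dur = _sigmoid(0.8 - 2.0 * logit_shift + rng.normal(0.0, logit_noise))
            nond = 0.5 * _sigmoid(0.2 - 2.0 * logit_shift + rng.normal(0.0, logit_noise))
            scan_date = int(visit * 365 + rng.integers(-15, 16)) if visit else 0
            exam_date = int(scan_date + rng.integers(-20, 21))
            records.append(CohortRecord(
                subject_id=sid, visit=visit, scan_date=scan_date, exam_date=exam_date,
                cdr_global=cdr, mmse=float(np.clip(mmse, 0, 30)),
                moca=float(np.clip(moca, 0, 30)),
                immediate_recall_1=float(np.clip(imm, 0, 1)),
                delayed_recall_1=float(np.clip(dly, 0, 1)),
                recall_nondurable=float(np.clip(nond, 0, 0.5)),
                recall_durable=float(np.clip(dur, 0, 1))))
        out.append((subject, records))
    return out


def cohort_tables(cohort: List[Tuple[PhantomSubject, List[CohortRecord]]]):
    """(suvr_table, cohort_table) DataFrames for the stats module / CSV export.

    The SUVR table carries the ground-truth SUVR rows (pipeline
    ``native_truth``); estimated rows from a real pipeline run can be
    concatenated with it.
    """
    import pandas as pd

    suvr_rows = []
    rec_rows = []
    for subject, records in cohort:
        for role, val in subject.true_suvr.items():
            suvr_rows.append({"subject_id": subject.subject_id, "scan_id": f"{subject.subject_id}_v0",
                              "pipeline": "native_truth", "roi_role": role, "suvr": val})
        for r in records:
            rec_rows.append(vars(r).copy())
    return pd.DataFrame(suvr_rows), pd.DataFrame(rec_rows)
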