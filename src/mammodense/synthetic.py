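"""Synthetic mammogram generator with known ground-truth density.

Clinical mammograms with expert breast masks are rarely shareable, so every
stage of the pipeline is exercised on synthetic images whose dense-tissue
layout is known exactly:

* the breast mask is a half-ellipse flush with the chest-wall edge of the
  frame with a triangular pectoral corner removed, mimicking a contoured
  MLO projection;
* the dense-tissue field is a Gaussian random field (white noise convolved
  with a Gaussian kernel of standard deviation ``corr_length``), optionally
  tilted by a linear anterior–posterior ramp, and thresholded at the
  quantile that yields the requested overall percent density exactly (to
  one pixel);
* the rendered image draws dense and lucent tissue from two gray bands,
  applies a small blur and additive Gaussian noise, and blacks out the
  background.

Cohorts mimic the longitudinal study design: per subject a left-entry,
left-exit and right-exit image, the right exit being the mirror of the left
exit (MLO laterality convention), with an optional entry-to-exit shift in
percent density and correlation length.  All randomness flows from one seed
through per-subject, per-image ``SeedSequence`` spawns, so cohorts are
reproducible and stable when ``n_subjects`` changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .segmentation import MammogramImage

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "ExitShift",
    "SyntheticSubject",
    "generate_breast_mask",
    "generate_density_field",
    "render_mammogram",
    "generate_cohort",
    "DEFAULT_GROUP_MIX",
]

# Target overall PD -> fraction of subjects, mirroring the unequal density
# strata of a middle-aged screening cohort (sparse very-dense tail).
DEFAULT_GROUP_MIX: dict[float, float] = {15.0: 0.24, 30.0: 0.32, 50.0: 0.30, 65.0: 0.14}


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic generator.

    Defaults emulate a processed screening mammogram: a 480x360 frame at
    0.033 cm/px puts the full-scale breast mask near 100 cm2, typical of a
    cropped MLO view.  ``corr_length`` (px) sets the texture scale of the
    dense-tissue field; the default of 24 px (~0.8 cm) gives fibroglandular
    clusters about half a grid cell across, which yields clearly positive
    regional autocorrelation as observed in real breasts.
    ``anterior_weight`` > 0 piles density toward the nipple side (negative
    values reverse the ramp toward the chest wall); the default of 1.6
    field standard deviations per breast length makes anterior zonal PD
    roughly double posterior zonal PD, the pattern seen in sparser
    breasts where glandular tissue clusters behind the nipple.
    ``noise_sd`` is additive gray-level noise on the rendered image.
    """

    image_height_px: int = 480
    image_width_px: int = 360
    pixel_spacing_cm: float = 0.033
    breast_scale: float = 1.0
    target_pd: float = 35.0
    corr_length: float = 24.0
    anterior_weight: float = 1.6
    noise_sd: float = 5.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 48 or self.image_width_px < 48:
            raise ValueError("image dimensions must be at least 48x48")
        if not 0 < self.breast_scale <= 1:
            raise ValueError("breast_scale must be in (0, 1]")
        if not 0 <= self.target_pd <= 100:
            raise ValueError("target_pd must be in [0, 100]")
        if self.corr_length <= 0:
            raise ValueError("corr_length must be positive")
        if self.pixel_spacing_cm <= 0:
            raise ValueError("pixel_spacing_cm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """True dense-tissue layout of one synthetic image."""

    dense_map: np.ndarray
    mask: np.ndarray
    true_overall_pd: float

    def __post_init__(self) -> None:
        if (self.dense_map & ~self.mask).any():
            raise ValueError("dense_map must be a subset of the mask")
        if not 0 <= self.true_overall_pd <= 100:
            raise ValueError("true_overall_pd outside [0, 100]")

    def mirrored(self) -> "GroundTruth":
        return GroundTruth(np.fliplr(self.dense_map), np.fliplr(self.mask),
                           self.true_overall_pd)


@dataclass(frozen=True)
class ExitShift:
    """Entry-to-exit change applied to every subject.

    ``pd_shift`` (percentage points) is added to the exit-image target PD;
    ``corr_factor`` multiplies the exit correlation length.  The default
    emulates the longitudinal observation that density autocorrelation
    weakens over the follow-up interval while overall PD stays similar:
    exit texture is slightly finer-grained (corr_factor < 1) with a small
    PD gain.
    """

    pd_shift: float = 2.5
    corr_factor: float = 0.85


@dataclass
class SyntheticSubject:
    """One simulated woman: three images with ground truth and metadata."""

    subject_id: str
    age_entry: float
    stratum_pd: float        # density stratum the subject was drawn from
    target_pd_exit: float    # stratum plus subject-level jitter
    breast_scale: float
    images: dict[str, MammogramImage]
    truths: dict[str, GroundTruth]

    SLOTS = ("left_entry", "left_exit", "right_exit")


def generate_breast_mask(params: SyntheticParams) -> np.ndarray:
    """Breast mask: chest-wall half-ellipse with a pectoral corner cut.

    The mask is flush with the left image edge (canonical left-breast MLO
    orientation: chest wall left, nipple right), single-connected, with
    area scaling linearly in ``breast_scale`` (both semi-axes scale with
    its square root).
    """
    h, w = params.image_height_px, params.image_width_px
    s = np.sqrt(params.breast_scale)
    semi_y = 0.46 * h * s
    semi_x = 0.92 * w * s
    cy = h / 2.0

    rows, cols = np.ogrid[:h, :w]
    ellipse = (cols / semi_x) ** 2 + ((rows - cy) / semi_y) ** 2 <= 1.0

    # Pectoral cut: remove the triangle at the top chest-wall corner.
    cut_w = 0.30 * w * s
    cut_h = 0.42 * h * s
    pect_top = cy - semi_y  # mask's top extent at the chest wall
    pectoral = (cols / cut_w) + ((rows - pect_top) / cut_h) < 1.0
    return ellipse & ~pectoral


def generate_density_field(
    mask: np.ndarray,
    target_pd: float,
    corr_length: float,
    anterior_weight: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> GroundTruth:
    """Dense map as the top quantile of a smoothed random field in the mask.

    White noise over the full frame is convolved with a Gaussian kernel of
    standard deviation ``corr_length`` (the spatial correlation length),
    standardized over the mask, tilted by ``anterior_weight`` standard
    deviations per breast length toward the anterior (nipple) side, and cut
    at the value that marks exactly ``round(target_pd/100 * |mask|)``
    pixels dense — achieved PD is exact to one pixel by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx == 0:
        raise ValueError("empty mask")
    if not 0 <= target_pd <= 100:
        raise ValueError("target_pd must be in [0, 100]")
    if corr_length <= 0:
        raise ValueError("corr_length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    field_ = gaussian_filter(rng.standard_normal(mask.shape), sigma=corr_length,
                             mode="constant")
    vals = field_[mask]
    sd = vals.std()
    if sd > 0:
        field_ = (field_ - vals.mean()) / sd

    if anterior_weight:
        cols = np.flatnonzero(mask.any(axis=0))
        span = max(int(cols[-1]) - int(cols[0]), 1)
        ramp = (np.arange(mask.shape[1]) - cols[0]) / span
        field_ = field_ + anterior_weight * ramp[None, :]

    k = int(round(target_pd / 100.0 * npx))
    dense = np.zeros(mask.shape, dtype=bool)
    if k > 0:
        flat_idx = np.flatnonzero(mask)
        masked_vals = field_.ravel()[flat_idx]
        top = np.argpartition(masked_vals, npx - k)[npx - k:]
        dense.ravel()[flat_idx[top]] = True
    return GroundTruth(dense_map=dense, mask=mask, true_overall_pd=100.0 * k / npx)


def render_mammogram(
    gt: GroundTruth,
    params: SyntheticParams,
    seed: int | np.random.Generator | None = None,
    laterality: str = "L",
    timepoint: str = "entry",
    subject_id: str = "syn",
) -> MammogramImage:
    """Render the ground truth as an 8-bit grayscale mammogram.

    Dense tissue is drawn at gray 200, lucent tissue at 60; a Gaussian blur
    of ``blur_sigma`` softens tissue boundaries, additive noise of sd
    ``noise_sd`` is applied inside the mask, and the background outside the
    mask is filled with black, so nothing outside the breast can be read as
    dense tissue.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.where(gt.dense_map, 200.0, 60.0)
    if params.blur_sigma > 0:
        img = gaussian_filter(img, sigma=params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.where(gt.mask, img, 0.0)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if laterality == "R":
        # right breasts are mirrored templates; ground truth must match
        pixels = np.fliplr(pixels)
    return MammogramImage(pixels=pixels, pixel_spacing_cm=params.pixel_spacing_cm,
                          laterality=laterality, timepoint=timepoint,
                          subject_id=subject_id)


def _allocate_groups(n: int, mix: dict[float, float]) -> list[float]:
    """Largest-remainder allocation of n subjects to target-PD strata."""
    pds = sorted(mix)
    weights = np.array([mix[p] for p in pds], dtype=float)
    weights = weights / weights.sum()
    ideal = weights * n
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(ideal - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    out: list[float] = []
    for p, c in zip(pds, counts):
        out.extend([p] * c)
    return out


def generate_cohort(
    n_subjects: int = 50,
    group_mix: dict[float, float] | None = None,
    exit_shift: ExitShift | None = None,
    seed: int = 0,
    params: SyntheticParams | None = None,
    pd_jitter_sd: float = 3.0,
    size_coupling: float = 0.007,
) -> list[SyntheticSubject]:
    """Simulate a longitudinal cohort of paired mammograms.

    Per subject: a left-entry image, a left-exit image (same breast mask,
    independent texture realization, parameters moved by ``exit_shift``),
    and a right-exit image that mirrors the left exit.  Subjects' exit
    target PDs are drawn from ``group_mix`` strata with Gaussian jitter of
    ``pd_jitter_sd`` percentage points; breast size is negatively coupled
    to density through ``size_coupling`` (breast_scale drops by that much
    per PD point), emulating the smaller-denser-breast association.

    Reproducibility: subject ``i`` derives its random streams from
    ``SeedSequence(seed).spawn`` child ``i``, so subject-level output is
    unchanged when ``n_subjects`` grows.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    params = params or SyntheticParams()
    exit_shift = exit_shift if exit_shift is not None else ExitShift()
    mix = group_mix or DEFAULT_GROUP_MIX
    strata = np.array(sorted(mix), dtype=float)
    weights = np.array([mix[s] for s in strata], dtype=float)
    weights = weights / weights.sum()

    subjects: list[SyntheticSubject] = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        streams = [np.random.default_rng(s) for s in child.spawn(5)]
        attr_rng, entry_field, entry_noise, exit_field, exit_noise = streams

        # stratum drawn i.i.d. per subject (not allocated across the cohort)
        # so subject-level output is stable when n_subjects changes
        stratum = float(attr_rng.choice(strata, p=weights))
        pd_exit = float(np.clip(stratum + attr_rng.normal(0, pd_jitter_sd), 1.0, 99.0))
        pd_entry = float(np.clip(pd_exit - exit_shift.pd_shift, 1.0, 99.0))
        scale = float(np.clip(1.05 - size_coupling * pd_exit + attr_rng.normal(0, 0.04),
                              0.40, 1.00))
        age = float(np.clip(attr_rng.normal(50.3, 4.7), 40.0, 60.0))
        sid = f"S{i:03d}"
        p = replace(params, breast_scale=scale)

        mask = generate_breast_mask(p)
        gt_entry = generate_density_field(mask, pd_entry, p.corr_length,
                                          p.anterior_weight, entry_field)
        gt_exit = generate_density_field(mask, pd_exit,
                                         p.corr_length * exit_shift.corr_factor,
                                         p.anterior_weight, exit_field)
        img_entry = render_mammogram(gt_entry, p, entry_noise, "L", "entry", sid)
        img_exit = render_mammogram(gt_exit, p, exit_noise, "L", "exit", sid)
        img_right = MammogramImage(pixels=np.fliplr(img_exit.pixels),
                                   pixel_spacing_cm=p.pixel_spacing_cm,
                                   laterality="R", timepoint="exit", subject_id=sid)

        subjects.append(SyntheticSubject(
            subject_id=sid,
            age_entry=age,
            stratum_pd=stratum,
            target_pd_exit=pd_exit,
            breast_scale=scale,
            images={"left_entry": img_entry, "left_exit": img_exit,
                    "right_exit": img_right},
            truths={"left_entry": gt_entry, "left_exit": gt_exit,
                    "right_exit": gt_exit.mirrored()},
        ))
    return subjects
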