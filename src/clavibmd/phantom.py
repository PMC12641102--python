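"""Synthetic chest-radiograph phantom cohorts with ground-truth clavicle
masks and latent bone-mineral density (BMD).

Each phantom image contains

* a smooth thorax-like background with low-contrast rib-band texture and a
  weak global intensity trend with BMD (a deliberate non-clavicular
  shortcut, emulating overall radiographic density),
* two mirrored, gently curved clavicle bars whose cortical thickness and
  mean intensity increase strictly with the latent BMD — the clinically
  meaningful signal,
* optionally a small bright radiopaque marker in the upper-right corner
  whose appearance is independent of BMD (a pure confounder), and
* additive Gaussian noise.

The ground-truth mask is the union of the two clavicle bars.  The whole
cohort is a pure function of :class:`CohortParams` (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SEXES = ("male", "female")

# moment-matched to a pooled mixture mean 0.898 and SD ~0.188 g/cm²
# at a 69.5 % female fraction; male mean > female mean
DEFAULT_BMD_MEAN = {"female": 0.860, "male": 0.985}
DEFAULT_BMD_SD = {"female": 0.180, "male": 0.175}
DEFAULT_AGE_MEAN = 63.3
DEFAULT_AGE_SD = 14.6

# intensity model (all in normalized [0,1] display units)
_BMD_LO, _BMD_HI = 0.2, 1.6
_BONE_BASE = 0.50          # clavicle interior intensity at BMD = _BMD_LO
_BONE_GAIN = 0.10          # added intensity across the full BMD range
_RIM_BOOST = 0.08          # cortical-rim brightening
_BG_COUPLING = 0.12        # lower-torso soft-tissue shift per g/cm² around 0.898
_MARKER_INTENSITY = 0.98


@dataclass
class CohortParams:
    """Knobs of the synthetic cohort; defaults emulate the study population
    (n = 1600, 69.5 % female, pooled BMD 0.898 ± 0.188 g/cm²)."""

    n_cases: int = 1600
    female_fraction: float = 0.695
    bmd_mean_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_BMD_MEAN))
    bmd_sd_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_BMD_SD))
    bmd_clip: tuple = (_BMD_LO, _BMD_HI)
    image_size: int = 64
    noise_sd: float = 0.02
    marker_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        lo, hi = self.bmd_clip
        if not lo < hi:
            raise ValueError("bmd_clip must satisfy low < high")
        if self.image_size % 16 != 0:
            raise ValueError("image_size must be divisible by 16")
        for sex in SEXES:
            if self.bmd_sd_by_sex[sex] < 0:
                raise ValueError("bmd SD must be >= 0")


@dataclass
class PhantomSample:
    """One synthetic case: the image, its clavicle mask, and the latent truth."""

    case_id: str
    sex: str
    age: float
    bmd_true: float
    image: np.ndarray   # 2-D float in [0, 1]
    mask: np.ndarray    # 2-D uint8 in {0, 1}, same shape


def sample_demographics(params: CohortParams) -> list[tuple[str, str]]:
    """Deterministic (case_id, sex) list with exactly
    round(n_cases * female_fraction) females, shuffled by the cohort seed."""
    params.validate()
    n = params.n_cases
    n_female = round(n * params.female_fraction)
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    rng = np.random.default_rng([params.seed, 100])
    rng.shuffle(sexes)
    width = max(4, len(str(max(n, 1))))
    return [(f"case_{i:0{width}d}", sex) for i, sex in enumerate(sexes)]


def sample_bmd(demographics: list[tuple[str, str]],
               params: CohortParams) -> np.ndarray:
    """Latent BMD per case from the sex-specific normal, clipped."""
    params.validate()
    for sex in SEXES:
        if params.bmd_sd_by_sex[sex] < 0:
            raise ValueError("bmd SD must be >= 0")
    rng = np.random.default_rng([params.seed, 101])
    lo, hi = params.bmd_clip
    out = np.empty(len(demographics))
    for i, (_cid, sex) in enumerate(demographics):
        mu = params.bmd_mean_by_sex[sex]
        sd = params.bmd_sd_by_sex[sex]
        out[i] = np.clip(rng.normal(mu, sd) if sd > 0 else mu, lo, hi)
    return out


def _sample_ages(demographics, params) -> np.ndarray:
    rng = np.random.default_rng([params.seed, 102])
    return np.clip(rng.normal(DEFAULT_AGE_MEAN, DEFAULT_AGE_SD,
                              len(demographics)), 20.0, 91.0)


def _bmd_scale(bmd: float) -> float:
    """Map BMD to [0, 1] over the supported physiological range."""
    return (float(bmd) - _BMD_LO) / (_BMD_HI - _BMD_LO)


def _clavicle_geometry(size: int, bmd: float, jitter: np.ndarray):
    """Centerlines and half-thickness (pixels) of the two clavicle bars.

    ``jitter`` is a 3-vector of per-case anatomical variation: vertical
    offset, curvature scale, and left/right asymmetry (all dimensionless).
    """
    x = np.arange(size)
    t = _bmd_scale(bmd)
    half = size * (0.018 + 0.030 * t)           # cortical thickness grows with BMD
    dy0, curve, asym = jitter
    bars = []
    for left in (True, False):
        if left:
            x0, x1 = 0.07 * size, 0.45 * size
            u = (x - x0) / (x1 - x0)
        else:
            x0, x1 = 0.55 * size, 0.93 * size
            u = (x1 - x) / (x1 - x0)
        side = -asym if left else asym
        # gentle S-curve around 30 % image height, drooping laterally
        yc = size * (0.28 + dy0 + side + 0.05 * u
                     + (0.03 + curve) * np.sin(np.pi * u))
        valid = (u >= 0) & (u <= 1)
        bars.append((yc, valid))
    return bars, half


def render_phantom(bmd_true: float, params: CohortParams,
                   per_case_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, mask) pair for a latent BMD value."""
    params.validate()
    lo, hi = params.bmd_clip
    if not lo <= bmd_true <= hi:
        raise ValueError(f"bmd_true {bmd_true} outside clip bounds {params.bmd_clip}")
    size = params.image_size
    rng = np.random.default_rng(per_case_seed)
    # anatomical jitter drawn first so geometry is seed-stable regardless of
    # whether noise is enabled
    jitter = np.array([rng.uniform(-0.02, 0.02),    # vertical offset
                       rng.uniform(-0.01, 0.01),    # curvature
                       rng.uniform(-0.01, 0.01)])   # asymmetry
    soft_tissue_noise = rng.normal(0.0, 0.10)       # per-case correlate error
    exposure_gain = rng.normal(1.0, 0.06)           # per-case exposure jitter
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size

    # thorax-like background: vertical gradient, mediastinal column, rib bands
    bg = 0.22 + 0.10 * yy
    bg += 0.08 * np.exp(-((xx - 0.5) ** 2) / 0.02)
    bg += 0.03 * np.sin(2 * np.pi * (6.0 * yy + 0.10 * np.sin(2 * np.pi * xx)))
    # soft-tissue density in a lower-torso band: a NOISY BMD correlate and a
    # deliberate non-clavicular shortcut, spatially disjoint from the clavicles
    bg += _BG_COUPLING * (float(bmd_true) - 0.898 + soft_tissue_noise) \
        * np.exp(-((yy - 0.82) ** 2) / 0.012)

    bars, half = _clavicle_geometry(size, bmd_true, jitter)
    rows = np.arange(size, dtype=np.float64)[:, None]
    mask = np.zeros((size, size), dtype=bool)
    rim = np.zeros((size, size), dtype=bool)
    for yc, valid in bars:
        dist = np.abs(rows - yc[None, :])
        inside = (dist <= half) & valid[None, :]
        mask |= inside
        rim |= inside & (dist > 0.6 * half)

    t = _bmd_scale(bmd_true)
    image = bg.copy()
    image[mask] = _BONE_BASE + _BONE_GAIN * t
    image[rim] += _RIM_BOOST

    image *= exposure_gain

    if params.marker_enabled:
        r0, r1 = int(0.05 * size), max(int(0.05 * size) + 2, int(0.11 * size))
        c0, c1 = int(0.86 * size), max(int(0.86 * size) + 3, int(0.95 * size))
        image[r0:r1, c0:c1] = _MARKER_INTENSITY

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, image.shape)
    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def generate_cohort(params: CohortParams) -> list[PhantomSample]:
    """Full deterministic cohort: demographics, latent BMD, rendered images."""
    demo = sample_demographics(params)
    bmd = sample_bmd(demo, params)
    ages = _sample_ages(demo, params)
    seeds = np.random.SeedSequence([params.seed, 103]).generate_state(
        max(len(demo), 1)) % (2 ** 31)
    samples = []
    for i, (cid, sex) in enumerate(demo):
        image, mask = render_phantom(float(bmd[i]), params, int(seeds[i]))
        samples.append(PhantomSample(cid, sex, float(ages[i]), float(bmd[i]),
                                     image.astype(np.float32), mask))
    return samples


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 shift_frac: tuple[float, float] = (0.0, 0.0),
                 rotate_deg: float = 0.0,
                 hflip: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric transform identically to image and mask.

    ``shift_frac`` is (row, col) shift as a fraction of the image size;
    rotation is about the image centre.  Out-of-frame regions are
    zero-filled and the mask is re-binarized after interpolation.  The
    identity transform returns bit-identical arrays.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes must match")
    if shift_frac == (0.0, 0.0) and rotate_deg == 0.0 and not hflip:
        return image.copy(), mask.copy()
    img = image.astype(np.float64)
    msk = mask.astype(np.float64)
    if hflip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if rotate_deg != 0.0:
        img = ndimage.rotate(img, rotate_deg, reshape=False, order=1,
                             mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, rotate_deg, reshape=False, order=1,
                             mode="constant", cval=0.0)
    if shift_frac != (0.0, 0.0):
        dy = shift_frac[0] * image.shape[0]
        dx = shift_frac[1] * image.shape[1]
        img = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
        msk = ndimage.shift(msk, (dy, dx), order=1, mode="constant", cval=0.0)
    return (np.clip(img, 0.0, 1.0).astype(image.dtype),
            (msk > 0.5).astype(mask.dtype))


def sample_augmentation(rng: np.random.Generator,
                        max_shift_frac: float = 0.10,
                        max_rotate_deg: float = 10.0,
                        flip_prob: float = 0.5) -> dict:
    """Draw random augmentation parameters (shifts, rotation, flip)."""
    return {
        "shift_frac": (float(rng.uniform(-max_shift_frac, max_shift_frac)),
                       float(rng.uniform(-max_shift_frac, max_shift_frac))),
        "rotate_deg": float(rng.uniform(-max_rotate_deg, max_rotate_deg)),
        "hflip": bool(rng.random() < flip_prob),
    }
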