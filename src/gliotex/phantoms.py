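"""Synthetic tumor phantoms with tunable histogram and texture contrast.

Two phantom families emulate the imaging contrast the grading problem
rests on.  LGG-like lesions are homogeneous: a smooth Gaussian random
field (long correlation length) over a roughly elliptical mask, giving a
unimodal intensity histogram and low local contrast.  GBM-like lesions
add a bright irregular enhancing rim around a dark necrotic core plus
short-correlation-length speckle, giving a bimodal histogram and high
local contrast.  Class separability is a single knob that interpolates
the GBM-like generating parameters between "identical to LGG-like"
(separability 0) and fully expressed (separability 1).

All randomness flows from integer seeds through ``numpy.random``'s
SeedSequence spawning, so the same spec always yields the same image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import GeometryError, RoiImage

LGG, GBM = 0, 1

#: Generating parameters of the two classes at full separability.
LGG_DEFAULTS = dict(smoothness=4.0, noise_sd=40.0,
                    ring_contrast=0.0, core_fraction=0.0)
GBM_DEFAULTS = dict(smoothness=1.0, noise_sd=80.0,
                    ring_contrast=0.9, core_fraction=0.45)


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; identical specs give identical images.

    Attributes
    ----------
    class_label : int
        0 = LGG-like, 1 = GBM-like (labels the archetype; the texture is
        governed entirely by the numeric fields below).
    image_size : int
        Side length of the square image, pixels.
    roi_radius : float
        Major semi-axis of the elliptical tumor mask, pixels.
    base_intensity : float
        Mean in-ROI intensity, arbitrary scanner units.
    noise_sd : float
        SD of the Gaussian-random-field texture, intensity units.
    smoothness : float
        Correlation length of the texture field, pixels; large = smooth.
    ring_contrast : float
        Relative rim brightening (fraction of base intensity); 0 = none.
    core_fraction : float
        Dark-core radius as a fraction of the ROI radius, in [0, 1).
    seed : int
        Seed of the phantom's private RNG.
    """

    class_label: int
    image_size: int = 64
    roi_radius: float = 22.0
    base_intensity: float = 400.0
    noise_sd: float = 40.0
    smoothness: float = 4.0
    ring_contrast: float = 0.0
    core_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.roi_radius <= 0:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("core_fraction must lie in [0, 1)")


def _grf(shape: Tuple[int, int], corr_len: float,
         rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian random field with given correlation length."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=corr_len,
                            mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_phantom(spec: PhantomSpec) -> RoiImage:
    """Render one tumor phantom and its elliptical ROI mask."""
    n = spec.image_size
    if 2 * spec.roi_radius >= n:
        raise GeometryError(
            f"ROI diameter {2 * spec.roi_radius} exceeds image size {n}"
        )
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0
    # mildly eccentric, randomly oriented ellipse
    ecc = rng.uniform(0.75, 0.95)
    ang = rng.uniform(0, np.pi)
    u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
    v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
    rho = np.sqrt((u / spec.roi_radius) ** 2
                  + (v / (spec.roi_radius * ecc)) ** 2)
    mask = rho <= 1.0

    img = np.full((n, n), 0.05 * spec.base_intensity)
    img[mask] = spec.base_intensity
    if spec.ring_contrast > 0:
        # irregular enhancing rim: radial bump whose radius is modulated
        # by low-order angular harmonics
        phi = np.arctan2(v, u)
        wobble = sum(
            rng.uniform(0.0, 0.08) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
            for k in (2, 3, 5)
        )
        rho_rim = 0.72 + wobble
        rim = np.exp(-(((rho - rho_rim) / 0.12) ** 2))
        img += spec.ring_contrast * spec.base_intensity * rim * mask
    if spec.core_fraction > 0:
        # necrotic core: smooth drop toward CSF-like low signal
        core = 1.0 / (1.0 + np.exp((rho - spec.core_fraction) / 0.04))
        img -= 0.75 * spec.base_intensity * core * mask
    img += spec.noise_sd * _grf((n, n), spec.smoothness, rng)
    img = np.clip(img, 0.0, None)
    return RoiImage(pixels=img, mask=mask,
                    case_id=f"phantom-{'gbm' if spec.class_label else 'lgg'}"
                            f"-{spec.seed}")


def _interp(a: float, b: float, t: float) -> float:
    return a + t * (b - a)


def gbm_params(separability: float) -> dict:
    """GBM-like generating parameters at a given separability in [0, 1]."""
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    return {
        k: _interp(LGG_DEFAULTS[k], GBM_DEFAULTS[k], separability)
        for k in LGG_DEFAULTS
    }


def generate_cohort(
    n_lgg: int = 71,
    n_gbm: int = 34,
    separability: float = 1.0,
    seed: int = 0,
    image_size: int = 64,
) -> Tuple[List[RoiImage], np.ndarray]:
    """Generate a labeled cohort of phantoms (default 71 LGG / 34 GBM).

    Per-case size and intensity are jittered reproducibly from the master
    seed.  At separability 0 the two classes share one generating
    distribution; at 1 they are widely separated.

    Returns
    -------
    images : list of RoiImage
    labels : ndarray of int, 0 = LGG-like, 1 = GBM-like
    """
    if n_lgg < 1 or n_gbm < 1:
        raise ValueError("class counts must be >= 1")
    gbm = gbm_params(separability)
    children = np.random.SeedSequence(seed).spawn(n_lgg + n_gbm)
    images: List[RoiImage] = []
    labels = np.concatenate([np.zeros(n_lgg, int), np.ones(n_gbm, int)])
    for k, (ss, lab) in enumerate(zip(children, labels)):
        jit = np.random.default_rng(ss)
        params = dict(LGG_DEFAULTS) if lab == LGG else dict(gbm)
        spec = PhantomSpec(
            class_label=int(lab),
            image_size=image_size,
            roi_radius=jit.uniform(0.75, 1.05) * image_size * 0.33,
            base_intensity=jit.uniform(0.9, 1.1) * 400.0,
            noise_sd=jit.uniform(0.85, 1.15) * params["noise_sd"],
            smoothness=max(0.5, jit.uniform(0.85, 1.15) * params["smoothness"]),
            ring_contrast=params["ring_contrast"],
            core_fraction=params["core_fraction"],
            seed=int(jit.integers(0, 2**31 - 1)),
        )
        img = generate_phantom(spec)
        img.case_id = f"case-{k:03d}-{'gbm' if lab else 'lgg'}"
        images.append(img)
    return images, labels
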