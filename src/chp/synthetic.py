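"""Synthetic nuclei with known topology.

Two generators:

* ring phantoms — disjoint dark annuli on a bright background, whose
  homology profile is known analytically (each ring contributes exactly
  one hole from its own intensity up to the background intensity, where
  the whole mask floods and every hole fills);
* textured nuclei — seeded placement of dark chromatin granules inside
  an elliptical nucleus, emulating the texture contrast between
  histotypes: fine granular chromatin (adenocarcinoma-like), coarse
  clumped chromatin (squamous-like), and densely packed chromatin that
  fills the nucleus (small-cell-like), where holes vanish because the
  foreground floods without enclosing background.

Phantoms provide exact ground truth; textures provide realism.  Holes
in textures arise from granule contact, not from explicit rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .features import ClassificationRule
from .profile import HomologyProfile, NucleusImage

# ---------------------------------------------------------------------------
# Ring phantoms


@dataclass(frozen=True)
class Ring:
    center: tuple[float, float]  # (row, col)
    inner_radius: float
    outer_radius: float
    intensity: int


@dataclass(frozen=True)
class PhantomSpec:
    """Disjoint dark annuli on a bright elliptical mask."""

    image_size: int
    background_intensity: int
    rings: tuple[Ring, ...]

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        if not 1 <= self.background_intensity <= 255:
            raise ValueError("background_intensity must be in [1, 255]")
        for r in self.rings:
            if not 0 <= r.intensity < self.background_intensity:
                raise ValueError(
                    "ring intensity must be darker than the background"
                )
            if r.inner_radius < 1.5:
                raise ValueError("inner_radius must be >= 1.5 (hole needs interior)")
            if r.outer_radius - r.inner_radius < 2:
                raise ValueError("ring width must be >= 2 pixels")
        for i, a in enumerate(self.rings):
            for b in self.rings[i + 1 :]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.outer_radius + b.outer_radius + 2:
                    raise ValueError("annuli must be pairwise disjoint")


def make_ring_phantom(spec: PhantomSpec) -> tuple[NucleusImage, HomologyProfile]:
    """Rasterize a phantom and return it with its exact expected profile.

    Expected curve: b1(t) = number of rings with intensity <= t while
    t is below the background intensity, and 0 from the background
    intensity onward (the mask floods solid).
    """
    n = spec.image_size
    img = np.full((n, n), spec.background_intensity, dtype=np.uint8)
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    semi = n / 2.0 - 1.0
    mask = ((rr - c) / semi) ** 2 + ((cc - c) / semi) ** 2 <= 1.0
    for ring in spec.rings:
        d = np.hypot(rr - ring.center[0], cc - ring.center[1])
        band = (d >= ring.inner_radius) & (d <= ring.outer_radius)
        if not (mask | ~band).all():
            raise ValueError("ring extends outside the mask ellipse")
        img[band] = ring.intensity
    curve = np.zeros(256, dtype=int)
    for t in range(spec.background_intensity):
        curve[t] = sum(1 for r in spec.rings if r.intensity <= t)
    expected = HomologyProfile(tuple(curve))
    return NucleusImage(img, mask), expected


# ---------------------------------------------------------------------------
# Textured nuclei


@dataclass(frozen=True)
class TextureClassParams:
    """Seeded chromatin-texture recipe for one nucleus class."""

    class_name: str
    granule_count: int
    granule_radius: tuple[float, float]
    granule_intensity: tuple[int, int]
    background_intensity: int
    nucleus_radius: int
    noise_sd: float
    seed: int
    noise_corr: float = 1.5  # noise correlation length, px

    def __post_init__(self):
        lo, hi = self.granule_radius
        if not (0 < lo <= hi):
            raise ValueError("granule_radius range must be positive and ordered")
        if hi >= self.nucleus_radius:
            raise ValueError("granule radius must be smaller than the nucleus radius")
        ilo, ihi = self.granule_intensity
        if not (0 <= ilo <= ihi <= 255):
            raise ValueError("granule_intensity range must lie in [0, 255]")
        if not 0 <= self.background_intensity <= 255:
            raise ValueError("background_intensity must lie in [0, 255]")
        if self.granule_count < 1:
            raise ValueError("granule_count must be positive")


def make_textured_nucleus(params: TextureClassParams) -> NucleusImage:
    """Place dark granule disks inside an elliptical nucleus.

    Granules are filled disks composited darkest-wins.  Additive
    Gaussian noise, spatially correlated over ``noise_corr`` pixels as
    camera noise on real micrographs is (uncorrelated speckle would
    flood the profile with spurious single-pixel holes near the
    background intensity), is rounded and clamped to [0, 255] before the
    mask is applied.  Identical (params, seed) give a bit-identical
    image.
    """
    rng = np.random.default_rng(params.seed)
    R = params.nucleus_radius
    n = 2 * (R + 4)
    img = np.full((n, n), float(params.background_intensity))
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    mask = np.hypot(rr - c, cc - c) <= R
    lo, hi = params.granule_radius
    ilo, ihi = params.granule_intensity
    for _ in range(params.granule_count):
        # uniform position over the nucleus disk, granule kept inside
        rad = rng.uniform(lo, hi)
        rho = (R - rad) * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        gy = c + rho * math.sin(theta)
        gx = c + rho * math.cos(theta)
        inten = float(rng.integers(ilo, ihi + 1))
        disk = np.hypot(rr - gy, cc - gx) <= rad
        img[disk] = np.minimum(img[disk], inten)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, 1.0, img.shape)
        if params.noise_corr > 0:
            from scipy import ndimage

            noise = ndimage.gaussian_filter(noise, params.noise_corr)
            noise /= noise.std()
        img = img + params.noise_sd * noise
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return NucleusImage(img, mask)


def generate_cohort(
    class_specs: list[tuple[TextureClassParams, int]], master_seed: int
) -> list[tuple[NucleusImage, str]]:
    """Generate labeled nuclei, one reproducible seed per nucleus.

    Per-nucleus seeds derive from ``master_seed`` via a SeedSequence, so
    the cohort is deterministic and the per-class streams independent.
    """
    total = sum(n for _, n in class_specs)
    seeds = np.random.SeedSequence(master_seed).generate_state(max(total, 1))
    seeds = [int(s) & 0x7FFFFFFF for s in seeds]
    out: list[tuple[NucleusImage, str]] = []
    k = 0
    for params, n in class_specs:
        if n < 1:
            raise ValueError("each class needs n >= 1")
        for _ in range(n):
            out.append(
                (make_textured_nucleus(replace(params, seed=seeds[k])), params.class_name)
            )
            k += 1
    return out


# ---------------------------------------------------------------------------
# Shipped presets
#
# Illustrative texture recipes, not biological ground truth.  The three
# classes differ in granule size, number and packing so that the
# pipeline's class ordering mirrors the clinical one: densely packed
# chromatin floods the nucleus and suppresses holes (lowest b1MAX);
# fine granules in a small nucleus give the highest hole density.

PRESETS: dict[str, TextureClassParams] = {
    "fine_granular": TextureClassParams(
        class_name="fine_granular",
        granule_count=220,
        granule_radius=(1.5, 2.5),
        granule_intensity=(40, 110),
        background_intensity=200,
        nucleus_radius=40,
        noise_sd=3.0,
        seed=0,
    ),
    "coarse": TextureClassParams(
        class_name="coarse",
        granule_count=60,
        granule_radius=(4.0, 8.0),
        granule_intensity=(30, 100),
        background_intensity=200,
        nucleus_radius=55,
        noise_sd=3.0,
        seed=0,
    ),
    "dense_packed": TextureClassParams(
        class_name="dense_packed",
        granule_count=260,
        granule_radius=(4.0, 7.0),
        granule_intensity=(30, 90),
        background_intensity=200,
        nucleus_radius=35,
        noise_sd=3.0,
        seed=0,
    ),
}

# Histotype each texture class emulates.
PRESET_LABELS: dict[str, str] = {
    "fine_granular": "adeno",
    "coarse": "squamous",
    "dense_packed": "small_cell",
}

# Classification cutoffs for the shipped presets, tuned once on an
# independent tuning cohort (master_seed 999, n = 30 per class) as the
# midpoints between adjacent class feature ranges, then frozen.  The
# clinical defaults (25, 0.05) belong to a different imaging resolution
# and do not transfer to these synthetic image scales.
PRESET_RULE = ClassificationRule(b1max_cutoff=38.0, density_cutoff=0.0035)
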