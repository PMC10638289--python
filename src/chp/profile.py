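"""Chromatin homology profile: b1 versus binarization threshold.

A nucleus image is swept through all 256 binarization levels.  At
threshold ``t`` a pixel is foreground (chromatin, rendered black) iff it
lies inside the nucleus mask and its intensity is <= t — dark chromatin
appears first, and the foreground only grows as t increases (a
sublevel-set filtration).  The resulting curve b1(t) is the chromatin
homology profile; its maximum is b1MAX and the first threshold at which
b1 reaches the hole threshold (default 5) is the Homology Value (HV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .betti import betti_numbers

DEFAULT_HOLE_THRESHOLD = 5


@dataclass(frozen=True)
class NucleusImage:
    """An 8-bit nucleus photomicrograph with a coregistered mask.

    ``intensity`` holds brightness values in [0, 255] (0 = dark);
    ``mask`` is True inside the nucleus.  Both arrays share one shape
    and the mask must contain at least one inside pixel.
    """

    intensity: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        inten = np.asarray(self.intensity)
        mask = np.asarray(self.mask).astype(bool)
        if inten.ndim != 2:
            raise ValueError(f"intensity must be 2D, got shape {inten.shape}")
        if inten.shape != mask.shape:
            raise ValueError(
                f"intensity shape {inten.shape} != mask shape {mask.shape}"
            )
        if inten.min() < 0 or inten.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not mask.any():
            raise ValueError("mask has no inside pixel")
        object.__setattr__(self, "intensity", inten.astype(np.uint8))
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class HomologyProfile:
    """b1 at every binarization parameter t = 0..255, with summaries.

    ``hv`` is None when the curve never reaches ``hole_threshold``.
    """

    b1_curve: tuple[int, ...]
    hole_threshold: int = DEFAULT_HOLE_THRESHOLD
    b1max: int = field(init=False)
    hv: int | None = field(init=False)

    def __post_init__(self):
        if len(self.b1_curve) != 256:
            raise ValueError(f"b1_curve must have 256 entries, got {len(self.b1_curve)}")
        curve = tuple(int(v) for v in self.b1_curve)
        if any(v < 0 for v in curve):
            raise ValueError("b1 values must be non-negative")
        object.__setattr__(self, "b1_curve", curve)
        object.__setattr__(self, "b1max", max(curve))
        object.__setattr__(self, "hv", _first_reaching(curve, self.hole_threshold))


def _first_reaching(curve, threshold: int) -> int | None:
    for t, v in enumerate(curve):
        if v >= threshold:
            return t
    return None


def binarize(nucleus: NucleusImage, t: int) -> np.ndarray:
    """Binary image at threshold t: inside-mask pixels with intensity <= t."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    return nucleus.mask & (nucleus.intensity <= t)


def compute_profile(
    nucleus: NucleusImage, hole_threshold: int = DEFAULT_HOLE_THRESHOLD
) -> HomologyProfile:
    """Sweep all 256 thresholds and record b1 at each.

    The foreground is constant on threshold runs between consecutive
    intensity values present inside the mask, so b1 is computed once per
    distinct inside intensity and filled forward; the returned curve
    still covers every t in 0..255.
    """
    inside = nucleus.intensity[nucleus.mask]
    distinct = np.unique(inside)
    curve = np.zeros(256, dtype=int)
    prev = 0
    last_b1 = 0
    for v in distinct:
        curve[prev:v] = last_b1
        last_b1 = betti_numbers(binarize(nucleus, int(v))).b1
        prev = int(v)
    curve[prev:] = last_b1
    # below the darkest inside pixel the foreground is empty
    curve[: int(distinct[0])] = 0
    return HomologyProfile(tuple(curve), hole_threshold=hole_threshold)


def b1max_of(profile: HomologyProfile) -> int:
    """Maximum of the b1 curve (b1MAX)."""
    return max(profile.b1_curve)


def hv_of(
    profile: HomologyProfile, hole_threshold: int = DEFAULT_HOLE_THRESHOLD
) -> int | None:
    """Homology Value: smallest t with b1 >= hole_threshold, or None."""
    return _first_reaching(profile.b1_curve, hole_threshold)
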