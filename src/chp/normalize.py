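"""Brightness normalization.

Staining and exposure vary between images, and the Homology Value is
sensitive to a global brightness offset (darker nuclei reach any given
threshold earlier).  Two corrections are provided:

* group-level median-offset correction — shift one group's feature
  values by the difference of the group medians;
* per-nucleus Brightness-Index (BI) correction — shift each nucleus so
  that its modal in-mask intensity sits at a common target (127, the
  midpoint of the 8-bit brightness scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import NucleusImage

DEFAULT_BI_TARGET = 127


@dataclass(frozen=True)
class BrightnessSummary:
    """In-mask intensity histogram plus its mode (the Brightness Index)."""

    histogram: np.ndarray  # 256 counts over intensities 0..255
    bi: int


def brightness_index(nucleus: NucleusImage) -> BrightnessSummary:
    """Histogram of inside-mask intensities and its mode.

    The BI is the intensity with the highest pixel count; ties break
    toward the lower intensity.
    """
    inside = nucleus.intensity[nucleus.mask]
    hist = np.bincount(inside, minlength=256)
    bi = int(np.argmax(hist))  # argmax returns the first (lowest) maximum
    return BrightnessSummary(histogram=hist, bi=bi)


def bi_correct(nucleus: NucleusImage, target: int = DEFAULT_BI_TARGET) -> NucleusImage:
    """Shift inside-mask intensities so the BI lands on ``target``.

    The shift is additive (target - BI) with clamping to [0, 255];
    outside-mask pixels are untouched.  When no clamping occurs the
    corrected image has brightness_index == target, and applying the
    correction twice is a no-op.
    """
    if not 0 <= target <= 255:
        raise ValueError(f"target must be in [0, 255], got {target}")
    shift = target - brightness_index(nucleus).bi
    inten = nucleus.intensity.astype(np.int16)
    inten[nucleus.mask] = np.clip(inten[nucleus.mask] + shift, 0, 255)
    return NucleusImage(inten.astype(np.uint8), nucleus.mask)


def median_offset(reference_values, target_values) -> float:
    """median(reference) - median(target).

    The caller adds the returned offset to every target value to align
    the two groups.  The median of an even-sized list is the mean of the
    two central values.  Generic over any feature (HV, b1MAX, ...);
    antisymmetric under swapping the two groups.
    """
    ref = np.asarray(reference_values, dtype=float)
    tgt = np.asarray(target_values, dtype=float)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("both value lists must be non-empty")
    return float(np.median(ref) - np.median(tgt))
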