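"""Per-nucleus features and the cutoff-based histotype classifier.

Features per nucleus: b1MAX, HV, BI, the bounding-box diagonal of the
mask (ns, an easily reproduced size proxy), its square ns² (an area
proxy), and the chromatin density b1MAX/ns².  The classifier is a fixed
decision tree over univariate cutoffs:

    HV >= hv_cutoff            -> non_cancerous   (optional stage, off
                                                   by default; cancer
                                                   nuclei have lower HV)
    b1max < b1max_cutoff       -> small_cell
    density >= density_cutoff  -> adeno
    otherwise                  -> squamous

Values equal to a cutoff fall on the ">=" side.  All lengths are in
pixels and density in holes/pixel²; the density cutoff therefore depends
on image resolution.  An optional µm/pixel calibration can be applied to
ns multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LABELS = ("squamous", "adeno", "small_cell", "non_cancerous")

DEFAULT_B1MAX_CUTOFF = 25.0
DEFAULT_DENSITY_CUTOFF = 0.05


@dataclass(frozen=True)
class FeatureRecord:
    """The feature vector of one nucleus, plus an optional class label."""

    nucleus_id: str
    b1max: int
    hv: int | None
    bi: int
    ns: float
    ns2: float
    density: float
    label: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not math.isclose(self.ns2, self.ns * self.ns, rel_tol=1e-9):
            raise ValueError("ns2 must equal ns squared")


@dataclass(frozen=True)
class ClassificationRule:
    """Cutoff hierarchy for histotype calls.

    ``hv_cutoff`` enables the cancer/non-cancer stage when set; it ships
    disabled because no validated default exists.
    """

    b1max_cutoff: float = DEFAULT_B1MAX_CUTOFF
    density_cutoff: float = DEFAULT_DENSITY_CUTOFF
    hv_cutoff: float | None = None

    def __post_init__(self):
        if self.b1max_cutoff <= 0 or self.density_cutoff <= 0:
            raise ValueError("cutoffs must be strictly positive")
        if self.hv_cutoff is not None and self.hv_cutoff <= 0:
            raise ValueError("hv_cutoff must be strictly positive")


def ns_diagonal(mask) -> float:
    """Diagonal length of the tight bounding box of the mask, in pixels.

    The box spans w x h pixels (inclusive extents); ns = sqrt(w² + h²).
    A single pixel gives sqrt(2).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask has no inside pixel")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    h = rows[-1] - rows[0] + 1
    w = cols[-1] - cols[0] + 1
    return float(math.hypot(w, h))


def chromatin_density(b1max: int, ns: float) -> float:
    """Holes per squared pixel: b1max / ns²."""
    if ns <= 0:
        raise ValueError(f"ns must be positive, got {ns}")
    if b1max < 0:
        raise ValueError(f"b1max must be non-negative, got {b1max}")
    return b1max / (ns * ns)


def classify(record: FeatureRecord, rule: ClassificationRule | None = None) -> str:
    """Apply the cutoff hierarchy to one feature record."""
    rule = rule or ClassificationRule()
    if rule.hv_cutoff is not None:
        if record.hv is None:
            raise ValueError(
                f"record {record.nucleus_id!r} is missing 'hv', "
                "required when hv_cutoff is set"
            )
        if record.hv >= rule.hv_cutoff:
            return "non_cancerous"
    if record.b1max < rule.b1max_cutoff:
        return "small_cell"
    if record.density >= rule.density_cutoff:
        return "adeno"
    return "squamous"


def extract_features(
    nucleus,
    nucleus_id: str,
    label: str | None = None,
    *,
    hole_threshold: int = 5,
    bi_target: int | None = None,
) -> FeatureRecord:
    """Full per-nucleus feature extraction.

    Reports the raw (pre-correction) BI; when ``bi_target`` is given the
    profile is computed on the BI-corrected image.
    """
    from .normalize import bi_correct, brightness_index
    from .profile import compute_profile

    bi = brightness_index(nucleus).bi
    if bi_target is not None:
        nucleus = bi_correct(nucleus, target=bi_target)
    prof = compute_profile(nucleus, hole_threshold=hole_threshold)
    ns = ns_diagonal(nucleus.mask)
    return FeatureRecord(
        nucleus_id=nucleus_id,
        b1max=prof.b1max,
        hv=prof.hv,
        bi=bi,
        ns=ns,
        ns2=ns * ns,
        density=chromatin_density(prof.b1max, ns),
        label=label,
    )


def evaluate_cutoff(values, labels, cutoff: float, positive_direction: str = "high"):
    """Sensitivity and specificity of a single-cutoff test.

    ``labels`` are binary (truthy = positive class).  With
    ``positive_direction="high"`` a value >= cutoff is called positive;
    with ``"low"``, a value < cutoff (mirroring the classifier's
    boundary convention).  Returns (sensitivity, specificity).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    if y.all() or not y.any():
        raise ValueError("both label classes must be present")
    if positive_direction == "high":
        pred = v >= cutoff
    elif positive_direction == "low":
        pred = v < cutoff
    else:
        raise ValueError(f"positive_direction must be 'high' or 'low', got {positive_direction!r}")
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    return tp / (tp + fn), tn / (tn + fp)
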