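"""Betti numbers of 2D binary images.

Digital-topology convention, fixed and not configurable: foreground
(chromatin) is 8-connected, background is 4-connected.  This is the
standard Jordan-curve-consistent pairing — a closed 8-connected foreground
loop separates its 4-connected interior from the exterior, and a 2x2
checkerboard is one component with no hole rather than a paradoxical
"loop around nothing".

b0 counts connected foreground components.  b1 counts holes: background
components with no 4-connected path to the image border.  The image is
padded with a one-pixel background frame before counting so that border
handling is uniform (every background pixel touching the original border
belongs to the single outer component).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import ndimage

# 8-connectivity structuring element for foreground labeling.
_STRUCT_8 = np.ones((3, 3), dtype=bool)
# 4-connectivity (cross) for background labeling; scipy's default.
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


class BettiPair(NamedTuple):
    """Zero- and one-dimensional Betti numbers of a binary image."""

    b0: int
    b1: int


def _as_binary(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2D image, got shape {a.shape}")
    return a.astype(bool)


def count_components(img, which: str = "foreground", connectivity: int = 8) -> int:
    """Number of maximal connected pixel sets of one phase.

    Parameters
    ----------
    img : array-like of bool
        Binary image; truthy pixels are foreground.
    which : {"foreground", "background"}
        Phase to count.
    connectivity : {4, 8}
        4 = edge-adjacency only; 8 = edges and diagonals.
    """
    a = _as_binary(img)
    if which == "background":
        a = ~a
    elif which != "foreground":
        raise ValueError(f"which must be 'foreground' or 'background', got {which!r}")
    if connectivity == 8:
        structure = _STRUCT_8
    elif connectivity == 4:
        structure = _STRUCT_4
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    _, n = ndimage.label(a, structure=structure)
    return int(n)


def betti_numbers(img) -> BettiPair:
    """Betti numbers (b0, b1) of a binary image.

    b0 is the number of 8-connected foreground components.  b1 is the
    number of 4-connected background components fully enclosed by
    foreground, i.e. with no background path to the border.
    """
    a = _as_binary(img)
    _, b0 = ndimage.label(a, structure=_STRUCT_8)
    # Pad with a background ring: every border-touching background
    # component merges into the single outer component, so holes are
    # exactly the remaining components.
    padded_bg = np.pad(~a, 1, constant_values=True)
    _, n_bg = ndimage.label(padded_bg, structure=_STRUCT_4)
    b1 = n_bg - 1  # the outer component always exists
    return BettiPair(int(b0), int(b1))


def euler_number(img) -> int:
    """Euler characteristic of the foreground under 8-connectivity.

    Computed by bit-quad counting — a pass over all 2x2 pixel
    neighbourhoods of the padded image — so it is independent of the
    component labeling used by :func:`betti_numbers`.  For any image,
    ``euler_number(img) == b0 - b1``.
    """
    a = _as_binary(img)
    p = np.pad(a, 1).astype(np.uint8)
    # Encode each 2x2 window as a 4-bit pattern.
    code = p[:-1, :-1] + 2 * p[:-1, 1:] + 4 * p[1:, :-1] + 8 * p[1:, 1:]
    counts = np.bincount(code.ravel(), minlength=16)
    q1 = counts[1] + counts[2] + counts[4] + counts[8]  # one fg pixel
    q3 = counts[7] + counts[11] + counts[13] + counts[14]  # three fg pixels
    qd = counts[6] + counts[9]  # diagonal pairs
    # 8-connectivity bit-quad formula: diagonals connect, so each
    # diagonal pair removes a component merge rather than creating one.
    return int(q1 - q3 - 2 * qd) // 4
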