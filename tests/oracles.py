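"""Independent brute-force oracles for topological counts.

Queue-based flood fill over explicit pixel neighbourhoods, sharing no
code with the package's labeling-based implementation.
"""

from collections import deque

import numpy as np

OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
OFFSETS_8 = OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_count(img, phase: bool, connectivity: int) -> int:
    """Number of connected components of one phase by BFS flood fill."""
    a = np.asarray(img, dtype=bool)
    offsets = OFFSETS_8 if connectivity == 8 else OFFSETS_4
    h, w = a.shape
    seen = np.zeros_like(a)
    count = 0
    for i in range(h):
        for j in range(w):
            if a[i, j] == phase and not seen[i, j]:
                count += 1
                seen[i, j] = True
                q = deque([(i, j)])
                while q:
                    y, x = q.popleft()
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and a[ny, nx] == phase and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
    return count


def betti_oracle(img) -> tuple[int, int]:
    """(b0, b1) by flood fill.

    b0: foreground components under 8-connectivity.  b1: flood the
    background (4-connected) of the padded image starting from every
    border pixel, then count the background components that were never
    reached — those are the enclosed holes.
    """
    a = np.asarray(img, dtype=bool)
    b0 = flood_count(a, True, 8)
    padded = np.pad(a, 1, constant_values=False)
    h, w = padded.shape
    seen = np.zeros_like(padded)
    q = deque()
    for i in range(h):
        for j in range(w):
            if (i in (0, h - 1) or j in (0, w - 1)) and not padded[i, j]:
                if not seen[i, j]:
                    seen[i, j] = True
                    q.append((i, j))
    while q:
        y, x = q.popleft()
        for dy, dx in OFFSETS_4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not padded[ny, nx] and not seen[ny, nx]:
                seen[ny, nx] = True
                q.append((ny, nx))
    enclosed = ~padded & ~seen
    b1 = flood_count(enclosed, True, 4)
    return b0, b1
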