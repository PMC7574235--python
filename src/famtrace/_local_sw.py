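"""Numba kernel for local affine-gap protein alignment with traceback.

Three-state (match / gap-in-a / gap-in-b) Smith-Waterman over a
precomputed substitution slice; a gap of length L costs
``gap_open + L * gap_extend``.  Pointer matrices allow exact traceback;
ties prefer the diagonal, then gap-in-b, then gap-in-a, and the first
maximum in row-major order, making results deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2 ** 28)


@njit(cache=True)
def sw_align(sub, gap_open, gap_extend):
    n, m = sub.shape
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (consume b)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (consume a)
    # pointers: M: 0 stop, 1 diag, 2 from Ix, 3 from Iy
    #           Ix/Iy: 1 opened from M, 2 extended
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_x = M[i, j - 1] + gap_open + gap_extend
            ext_x = Ix[i, j - 1] + gap_extend
            if open_x >= ext_x:
                Ix[i, j] = open_x
                ptr_x[i, j] = 1
            else:
                Ix[i, j] = ext_x
                ptr_x[i, j] = 2
            open_y = M[i - 1, j] + gap_open + gap_extend
            ext_y = Iy[i - 1, j] + gap_extend
            if open_y >= ext_y:
                Iy[i, j] = open_y
                ptr_y[i, j] = 1
            else:
                Iy[i, j] = ext_y
                ptr_y[i, j] = 2
            cand = 0
            came = 0
            diag = M[i - 1, j - 1] + sub[i - 1, j - 1]
            if diag > cand:
                cand = diag
                came = 1
            if Iy[i, j] > cand:
                cand = Iy[i, j]
                came = 3
            if Ix[i, j] > cand:
                cand = Ix[i, j]
                came = 2
            M[i, j] = cand
            ptr_m[i, j] = came
            if cand > best:
                best = cand
                best_i = i
                best_j = j
    return best, best_i, best_j, ptr_m, ptr_x, ptr_y
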