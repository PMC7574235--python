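"""Numba kernel for splice-aware protein-to-genome alignment.

The dynamic program aligns a protein query to a genomic window, reading the
window three bases at a time.  States per (genome position i, query position
j): codon-boundary state ``C``, affine gap states ``GX`` (query residue
unmatched) and ``GY`` (genome codon unmatched).  Introns may open at any
``GT`` and close at any ``AG`` at least ``min_intron`` bases later, in any
codon phase (a codon may be split by an intron; the pending bases are
recovered from the recorded open position).  Frameshifts are modelled as
1-2 base genomic jumps with a heavy penalty; in-frame stop codons are
accepted with a heavy penalty (they are the pseudogene signal).

Alignment is local (Smith-Waterman style) over the window.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2 ** 28)

# pointer codes for the C state
P_START = 0
P_DIAG = 1
P_FROM_GX = 2
P_FROM_GY = 3
P_FS1 = 4
P_FS2 = 5
P_CLOSE0 = 6
P_CLOSE1 = 7
P_CLOSE2 = 8

STOP_AA = 23  # index of '*' in the protein alphabet


@njit(cache=True)
def _sub_score(b1, b2, b3, q_aa, smat, codon_aa, stop_pen):
    if b1 > 3 or b2 > 3 or b3 > 3:
        aa = 22  # X
    else:
        aa = codon_aa[b1 * 25 + b2 * 5 + b3]
    if aa == STOP_AA:
        return stop_pen
    return smat[aa, q_aa]


@njit(cache=True)
def fill(dna, q, smat, codon_aa, go, ge, fs_pen, stop_pen, intron_pen,
         min_intron):
    n = dna.shape[0]
    m = q.shape[0]
    C = np.full((n + 1, m + 1), 0, dtype=np.int32)
    GX = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    GY = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrC = np.zeros((n + 1, m + 1), dtype=np.uint8)
    auxC = np.full((n + 1, m + 1), -1, dtype=np.int32)
    ptrGX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrGY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    # running intron-open maxima per query position and codon phase
    Mp0 = np.full(m + 1, NEG, dtype=np.int32)
    Tp0 = np.full(m + 1, -1, dtype=np.int32)
    Mp1 = np.full((m + 1, 4), NEG, dtype=np.int32)
    Tp1 = np.full((m + 1, 4), -1, dtype=np.int32)
    Mp2 = np.full((m + 1, 16), NEG, dtype=np.int32)
    Tp2 = np.full((m + 1, 16), -1, dtype=np.int32)

    best = 0
    best_i = 0
    best_j = 0

    for i in range(n + 1):
        # apply delayed intron opens (one delay per closing geometry so the
        # GT..AG distance is always >= min_intron)
        t0 = i - min_intron
        if t0 >= 0 and t0 + 1 < n and dna[t0] == 2 and dna[t0 + 1] == 3:
            for j in range(m + 1):
                v = C[t0, j]
                if v > Mp0[j]:
                    Mp0[j] = v
                    Tp0[j] = t0
        t1 = i - min_intron - 2
        if t1 >= 1 and t1 + 1 < n and dna[t1] == 2 and dna[t1 + 1] == 3:
            b = dna[t1 - 1]
            if b <= 3:
                for j in range(m + 1):
                    v = C[t1 - 1, j]
                    if v > Mp1[j, b]:
                        Mp1[j, b] = v
                        Tp1[j, b] = t1
        t2 = i - min_intron - 1
        if t2 >= 2 and t2 + 1 < n and dna[t2] == 2 and dna[t2 + 1] == 3:
            b1 = dna[t2 - 2]
            b2 = dna[t2 - 1]
            if b1 <= 3 and b2 <= 3:
                bb = b1 * 4 + b2
                for j in range(m + 1):
                    v = C[t2 - 2, j]
                    if v > Mp2[j, bb]:
                        Mp2[j, bb] = v
                        Tp2[j, bb] = t2

        close0_ok = i >= 2 and dna[i - 2] == 0 and dna[i - 1] == 2
        close1_ok = i >= 4 and dna[i - 4] == 0 and dna[i - 3] == 2
        close2_ok = i >= 3 and dna[i - 3] == 0 and dna[i - 2] == 2

        for j in range(m + 1):
            # GY: genome codon vs gap in query
            if i >= 3:
                open_gy = C[i - 3, j] + go + ge
                ext_gy = GY[i - 3, j] + ge
                if open_gy >= ext_gy:
                    GY[i, j] = open_gy
                    ptrGY[i, j] = 1
                else:
                    GY[i, j] = ext_gy
                    ptrGY[i, j] = 2
            # GX: query residue vs gap in genome
            if j >= 1:
                open_gx = C[i, j - 1] + go + ge
                ext_gx = GX[i, j - 1] + ge
                if open_gx >= ext_gx:
                    GX[i, j] = open_gx
                    ptrGX[i, j] = 1
                else:
                    GX[i, j] = ext_gx
                    ptrGX[i, j] = 2

            cand = 0
            kind = P_START
            aux = -1
            if i >= 3 and j >= 1:
                v = C[i - 3, j - 1] + _sub_score(
                    dna[i - 3], dna[i - 2], dna[i - 1], q[j - 1], smat,
                    codon_aa, stop_pen)
                if v > cand:
                    cand = v
                    kind = P_DIAG
            if GX[i, j] > cand:
                cand = GX[i, j]
                kind = P_FROM_GX
            if GY[i, j] > cand:
                cand = GY[i, j]
                kind = P_FROM_GY
            if i >= 1 and C[i - 1, j] + fs_pen > cand:
                cand = C[i - 1, j] + fs_pen
                kind = P_FS1
            if i >= 2 and C[i - 2, j] + fs_pen > cand:
                cand = C[i - 2, j] + fs_pen
                kind = P_FS2
            if close0_ok and Mp0[j] + intron_pen > cand:
                cand = Mp0[j] + intron_pen
                kind = P_CLOSE0
                aux = Tp0[j]
            if close1_ok and j >= 1:
                for b in range(4):
                    if Mp1[j - 1, b] > NEG:
                        v = Mp1[j - 1, b] + intron_pen + _sub_score(
                            b, dna[i - 2], dna[i - 1], q[j - 1], smat,
                            codon_aa, stop_pen)
                        if v > cand:
                            cand = v
                            kind = P_CLOSE1
                            aux = Tp1[j - 1, b]
            if close2_ok and j >= 1:
                for bb in range(16):
                    if Mp2[j - 1, bb] > NEG:
                        v = Mp2[j - 1, bb] + intron_pen + _sub_score(
                            bb // 4, bb % 4, dna[i - 1], q[j - 1], smat,
                            codon_aa, stop_pen)
                        if v > cand:
                            cand = v
                            kind = P_CLOSE2
                            aux = Tp2[j - 1, bb]
            C[i, j] = cand
            ptrC[i, j] = kind
            auxC[i, j] = aux
            if cand > best:
                best = cand
                best_i = i
                best_j = j

    return best, best_i, best_j, ptrC, auxC, ptrGX, ptrGY
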