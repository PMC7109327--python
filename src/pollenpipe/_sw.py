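"""Affine-gap local alignment (Gotoh) kernels, numba-compiled.

Conventions (mirrored by any independent reimplementation that wants
column-identical results):

* a gap of length k costs ``gap_open + (k-1) * gap_extend`` (both
  negative);
* cell tie-break priority: diagonal > vertical (gap in reference) >
  horizontal (gap in query) > stop;
* the best cell is the first (smallest i, then smallest j) achieving
  the maximal score; traceback follows the stored pointers.

'N' (code 4) never matches anything, including itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))


@njit(cache=True)
def sw_core(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = r.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in query (horizontal)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in reference (vertical)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 vert, 3 horiz
    ptrE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended from E
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if ee > eo:
                E[i, j] = ee
                ptrE[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fe > fo:
                F[i, j] = fe
                ptrF[i, j] = 1
            else:
                F[i, j] = fo
            if qi == r[j - 1] and qi < 4:
                d = H[i - 1, j - 1] + match
            else:
                d = H[i - 1, j - 1] + mismatch
            h = d
            p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(2)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(3)
            if h <= 0:
                h = np.int32(0)
                p = np.uint8(0)
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


@njit(cache=True)
def sw_traceback(ptrH, ptrE, ptrF, q, r, bi, bj):  # pragma: no cover
    i = bi
    j = bj
    length = 0
    matches = 0
    mismatches = 0
    gap_cols = 0
    gap_opens = 0
    state = 0  # 0 = H, 1 = E (horizontal), 2 = F (vertical)
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # consume a reference base (gap in query)
            length += 1
            gap_cols += 1
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                gap_opens += 1
                state = 0
        else:  # consume a query base (gap in reference)
            length += 1
            gap_cols += 1
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                gap_opens += 1
                state = 0
    return i, j, length, matches, mismatches, gap_cols, gap_opens


def sw_align_codes(q: np.ndarray, r: np.ndarray, match: int, mismatch: int,
                   gap_open: int, gap_extend: int):
    """Best local alignment of encoded sequences.

    Returns None when the optimal score is 0 (no positive-scoring local
    alignment), else a dict with score, 0-based half-open intervals on
    query and reference, and column counts.
    """
    best, bi, bj, ptrH, ptrE, ptrF = sw_core(
        q, r, np.int32(match), np.int32(mismatch), np.int32(gap_open), np.int32(gap_extend)
    )
    if best <= 0:
        return None
    qi, rj, length, matches, mismatches, gap_cols, gap_opens = sw_traceback(
        ptrH, ptrE, ptrF, q, r, bi, bj
    )
    return dict(
        score=int(best),
        q_start=int(qi),
        q_end=int(bi),
        r_start=int(rj),
        r_end=int(bj),
        length=int(length),
        matches=int(matches),
        mismatches=int(mismatches),
        gap_columns=int(gap_cols),
        gap_opens=int(gap_opens),
    )
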