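"""Affine-gap semi-global alignment dynamic program (numba-compiled).

Terminal gaps on either sequence are free (overlap alignment); an internal
gap of length L costs ``gap_open + L * gap_extend``.  At least one aligned
column is always produced, so for hostile pairs the optimal score can be
negative (an "empty" all-terminal-gap alignment is not considered).

Among co-optimal alignments the kernel deterministically prefers, in
order: higher score, more matches, fewer alignment columns.  The
lexicographic objective is exact under dynamic programming because every
tie-break component accumulates additively along an alignment path, so
adding a common suffix preserves the lexicographic order of prefixes.

Sequences arrive as uint8 code arrays (A=0..T=3, ambiguous=4); a column is
a match only when both codes are equal and unambiguous, so N never matches
anything, including another N.

State is kept in int32 (cell-contiguous layout, two rolling rows); scores
are bounded by a few times the sequence length, so the caller guards
against inputs long enough to approach the int32 range.
"""

import numpy as np
from numba import njit

NEG = -(1 << 28)

#: Longest sequence the int32 kernel accepts (keeps |score| << 2**28).
MAX_LEN = 2_000_000


@njit(cache=True)
def semiglobal_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Return (score, matches, columns, q_start, q_end, r_start, r_end).

    Columns counts every alignment column between the first and last aligned
    pair (internal gaps included, terminal overhangs excluded); spans are
    0-based half-open on each input.
    """
    m = a.shape[0]
    n = b.shape[0]
    go = np.int32(gap_open + gap_extend)  # cost of a gap's first column
    ge = np.int32(gap_extend)
    neg = np.int32(NEG)

    # Three states per cell -- M: column is an aligned pair; X: gap
    # consuming a (vertical); Y: gap consuming b (horizontal).  Per-cell
    # components (axis 1): score, matches, -columns, start_i, start_j.
    pm = np.zeros((n + 1, 5), np.int32)
    px = np.zeros((n + 1, 5), np.int32)
    py = np.zeros((n + 1, 5), np.int32)
    cm = np.zeros((n + 1, 5), np.int32)
    cx = np.zeros((n + 1, 5), np.int32)
    cy = np.zeros((n + 1, 5), np.int32)
    for j in range(n + 1):
        px[j, 0] = neg
        py[j, 0] = neg
        pm[j, 4] = j  # free leading gap: alignment may start at (0, j)

    best_s = neg
    best_m = np.int32(0)
    best_c = np.int32(0)
    best_si = np.int32(0)
    best_sj = np.int32(0)
    best_ei = 0
    best_ej = 0

    for i in range(1, m + 1):
        ai = a[i - 1]
        # boundary cell (i, 0): M = fresh start at (i, 0); X/Y invalid
        cm[0, 0] = 0
        cm[0, 1] = 0
        cm[0, 2] = 0
        cm[0, 3] = i
        cm[0, 4] = 0
        cx[0, 0] = neg
        cy[0, 0] = neg
        # scalar copies of row-i cells at (i, j-1) for the Y recurrence
        dm_s = np.int32(0)
        dm_m = np.int32(0)
        dm_c = np.int32(0)
        dm_i = np.int32(i)
        dm_j = np.int32(0)
        y_s = neg
        y_m = np.int32(0)
        y_c = np.int32(0)
        y_i = np.int32(0)
        y_j = np.int32(0)
        for j in range(1, n + 1):
            # --- M: diagonal from best of M/X/Y at (i-1, j-1) ---
            bs = pm[j - 1, 0]
            bm = pm[j - 1, 1]
            bc = pm[j - 1, 2]
            bi = pm[j - 1, 3]
            bj = pm[j - 1, 4]
            s2 = px[j - 1, 0]
            if s2 > bs or (
                s2 == bs
                and (px[j - 1, 1] > bm or (px[j - 1, 1] == bm and px[j - 1, 2] > bc))
            ):
                bs = s2
                bm = px[j - 1, 1]
                bc = px[j - 1, 2]
                bi = px[j - 1, 3]
                bj = px[j - 1, 4]
            s2 = py[j - 1, 0]
            if s2 > bs or (
                s2 == bs
                and (py[j - 1, 1] > bm or (py[j - 1, 1] == bm and py[j - 1, 2] > bc))
            ):
                bs = s2
                bm = py[j - 1, 1]
                bc = py[j - 1, 2]
                bi = py[j - 1, 3]
                bj = py[j - 1, 4]
            ismatch = np.int32(1) if (ai == b[j - 1] and ai < 4) else np.int32(0)
            sub = np.int32(match) if ismatch else np.int32(mismatch)
            nm_s = bs + sub
            nm_m = bm + ismatch
            nm_c = bc - np.int32(1)
            nm_i = bi
            nm_j = bj

            # --- X: gap consuming a[i-1], open from M / extend X at (i-1, j) ---
            o_s = pm[j, 0] + go
            e_s = px[j, 0] + ge
            if o_s > e_s or (
                o_s == e_s
                and (pm[j, 1] > px[j, 1] or (pm[j, 1] == px[j, 1] and pm[j, 2] > px[j, 2]))
            ):
                cx[j, 0] = o_s
                cx[j, 1] = pm[j, 1]
                cx[j, 2] = pm[j, 2] - 1
                cx[j, 3] = pm[j, 3]
                cx[j, 4] = pm[j, 4]
            else:
                cx[j, 0] = e_s
                cx[j, 1] = px[j, 1]
                cx[j, 2] = px[j, 2] - 1
                cx[j, 3] = px[j, 3]
                cx[j, 4] = px[j, 4]

            # --- Y: gap consuming b[j-1], open from M / extend Y at (i, j-1) ---
            o_s = dm_s + go
            e_s = y_s + ge
            if o_s > e_s or (
                o_s == e_s and (dm_m > y_m or (dm_m == y_m and dm_c > y_c))
            ):
                y_s = o_s
                y_m = dm_m
                y_c = dm_c - np.int32(1)
                y_i = dm_i
                y_j = dm_j
            else:
                y_s = e_s
                y_c = y_c - np.int32(1)
            cy[j, 0] = y_s
            cy[j, 1] = y_m
            cy[j, 2] = y_c
            cy[j, 3] = y_i
            cy[j, 4] = y_j

            cm[j, 0] = nm_s
            cm[j, 1] = nm_m
            cm[j, 2] = nm_c
            cm[j, 3] = nm_i
            cm[j, 4] = nm_j
            dm_s, dm_m, dm_c, dm_i, dm_j = nm_s, nm_m, nm_c, nm_i, nm_j

            # --- free trailing gap: alignment may end at any M cell on the
            # last row or column; strict improvement keeps the first
            # (lowest i, then j) co-optimal endpoint, deterministically ---
            if i == m or j == n:
                if nm_s > best_s or (
                    nm_s == best_s
                    and (nm_m > best_m or (nm_m == best_m and nm_c > best_c))
                ):
                    best_s = nm_s
                    best_m = nm_m
                    best_c = nm_c
                    best_si = nm_i
                    best_sj = nm_j
                    best_ei = i
                    best_ej = j

        pm, cm = cm, pm
        px, cx = cx, px
        py, cy = cy, py

    return (
        int(best_s),
        int(best_m),
        -int(best_c),
        int(best_si),
        best_ei,
        int(best_sj),
        best_ej,
    )
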