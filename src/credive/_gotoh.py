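"""Global affine-gap (Gotoh) alignment kernel.

Written as plain nested loops over int64 numpy arrays so that numba can
compile it when available; falls back transparently to the pure-Python
version otherwise.  Scores are integers throughout.

Conventions
-----------
* A gap run of length L scores ``gap_open + (L - 1) * gap_extend`` (the
  first gap column pays the open score), matching Biopython's
  ``PairwiseAligner`` semantics.
* Traceback ties are broken deterministically by preferring a
  match/mismatch column over a gap-in-reference column over a
  gap-in-query column, so block boundaries are reproducible.
"""

from __future__ import annotations

import numpy as np

NEG = np.int64(-(10**12))

# state codes, in tie-break priority order
_M = 0  # match/mismatch column
_Y = 1  # gap in reference (column consumes a query residue)
_X = 2  # gap in query (column consumes a reference residue)


def _fill_and_traceback(ref, qry, submat, gap_open, gap_extend):
    m = ref.shape[0]
    n = qry.shape[0]
    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    # traceback: predecessor state for each state's cell
    tb_m = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_x = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_y = np.zeros((m + 1, n + 1), dtype=np.int8)

    M[0, 0] = 0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        tb_x[i, 0] = _X
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        tb_y[0, j] = _Y

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # M: diagonal from best of the three states
            best = M[i - 1, j - 1]
            state = _M
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                state = _Y
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                state = _X
            M[i, j] = best + submat[ref[i - 1], qry[j - 1]]
            tb_m[i, j] = state

            # X: gap in query, consumes ref[i-1]
            best = M[i - 1, j] + gap_open
            state = _M
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                state = _Y
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                state = _X
            X[i, j] = best
            tb_x[i, j] = state

            # Y: gap in reference, consumes qry[j-1]
            best = M[i, j - 1] + gap_open
            state = _M
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                state = _Y
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                state = _X
            Y[i, j] = best
            tb_y[i, j] = state

    score = M[m, n]
    state = _M
    if Y[m, n] > score:
        score = Y[m, n]
        state = _Y
    if X[m, n] > score:
        score = X[m, n]
        state = _X

    # traceback, collecting per-column (ref index | -1, qry index | -1)
    ncols_max = m + n
    col_ref = np.empty(ncols_max, dtype=np.int64)
    col_qry = np.empty(ncols_max, dtype=np.int64)
    k = 0
    i = m
    j = n
    while i > 0 or j > 0:
        if state == _M:
            col_ref[k] = i - 1
            col_qry[k] = j - 1
            state = tb_m[i, j]
            i -= 1
            j -= 1
        elif state == _X:
            col_ref[k] = i - 1
            col_qry[k] = -1
            state = tb_x[i, j]
            i -= 1
        else:
            col_ref[k] = -1
            col_qry[k] = j - 1
            state = tb_y[i, j]
            j -= 1
        k += 1

    return score, col_ref[:k][::-1].copy(), col_qry[:k][::-1].copy()


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fill_and_traceback = njit(cache=False)(_fill_and_traceback)
except ImportError:  # pragma: no cover
    pass


def gotoh_align(ref_codes, qry_codes, submat, gap_open, gap_extend):
    """Align two integer-encoded sequences; return (score, col_ref, col_qry).

    ``col_ref[k]`` / ``col_qry[k]`` give the 0-based residue index placed in
    alignment column ``k``, or -1 for a gap.
    """
    ref_codes = np.ascontiguousarray(ref_codes, dtype=np.int64)
    qry_codes = np.ascontiguousarray(qry_codes, dtype=np.int64)
    submat = np.ascontiguousarray(submat, dtype=np.int64)
    score, col_ref, col_qry = _fill_and_traceback(
        ref_codes, qry_codes, submat, np.int64(gap_open), np.int64(gap_extend)
    )
    return int(score), col_ref, col_qry
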