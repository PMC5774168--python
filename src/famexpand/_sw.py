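"""Affine-gap Smith-Waterman kernels (numba) shared by the protein search and
the nucleotide isoform clustering.

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``, i.e. the
first gap residue is charged open+extend, matching the BLAST convention the
scoring parameters (11/1 for BLOSUM62) are published for.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_score(a, b, sub, go_ext, ge):
    """Best local alignment score of integer-coded sequences a, b.

    go_ext is gap_open + gap_extend (cost of the first gap residue),
    ge the per-residue extension cost. Linear memory, score only.
    """
    n = a.shape[0]
    m = b.shape[0]
    hprev = np.zeros(m + 1, np.int32)
    f = np.zeros(m + 1, np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        hdiag = np.int32(0)
        ecur = np.int32(0)
        hleft = np.int32(0)
        ai = a[i - 1]
        for j in range(1, m + 1):
            fj = hprev[j] - go_ext
            if f[j] - ge > fj:
                fj = f[j] - ge
            f[j] = fj
            ej = hleft - go_ext
            if ecur - ge > ej:
                ej = ecur - ge
            ecur = ej
            h = hdiag + sub[ai, b[j - 1]]
            if ej > h:
                h = ej
            if fj > h:
                h = fj
            if h < 0:
                h = 0
            hdiag = hprev[j]
            hprev[j] = h
            hleft = h
            if h > best:
                best = h
    return int(best)


@njit(cache=True)
def sw_matrices(a, b, sub, go_ext, ge):
    """Full H/E/F dynamic-programming matrices for traceback.

    E holds gaps in `a` (consuming b, horizontal moves); F holds gaps in `b`
    (consuming a, vertical moves).
    """
    n = a.shape[0]
    m = b.shape[0]
    big = np.int32(-10_000_000)
    h = np.zeros((n + 1, m + 1), np.int32)
    e = np.full((n + 1, m + 1), big, np.int32)
    f = np.full((n + 1, m + 1), big, np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            ev = h[i, j - 1] - go_ext
            if e[i, j - 1] - ge > ev:
                ev = e[i, j - 1] - ge
            e[i, j] = ev
            fv = h[i - 1, j] - go_ext
            if f[i - 1, j] - ge > fv:
                fv = f[i - 1, j] - ge
            f[i, j] = fv
            hv = h[i - 1, j - 1] + sub[ai, b[j - 1]]
            if ev > hv:
                hv = ev
            if fv > hv:
                hv = fv
            if hv < 0:
                hv = 0
            h[i, j] = hv
    return h, e, f


def traceback(a, b, sub, go_ext, ge, h, e, f):
    """Recover the optimal local alignment from sw_matrices output.

    Ties between equally scoring alignments are resolved by smaller start in
    `a`, then smaller start in `b`, then fewer aligned columns; within a path,
    diagonal moves are preferred over gaps.

    Returns (score, a_start, a_end, b_start, b_end, columns) with 1-based
    inclusive coordinates; columns is a list of (ai, bi) 0-based indices with
    -1 marking a gap on that side.
    """
    best = int(h.max())
    if best == 0:
        return 0, 0, 0, 0, 0, []
    ends = np.argwhere(h == best)
    candidates = []
    for i_end, j_end in ends:
        cols = []
        i, j = int(i_end), int(j_end)
        state = "H"
        while True:
            if state == "H":
                if h[i, j] == 0:
                    break
                if h[i, j] == h[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                    cols.append((i - 1, j - 1))
                    i -= 1
                    j -= 1
                elif h[i, j] == e[i, j]:
                    state = "E"
                elif h[i, j] == f[i, j]:
                    state = "F"
                else:  # pragma: no cover - defensive
                    raise AssertionError("inconsistent DP matrices")
            elif state == "E":
                cols.append((-1, j - 1))
                if e[i, j] == h[i, j - 1] - go_ext:
                    state = "H"
                else:
                    pass  # stay in E
                j -= 1
            else:  # F
                cols.append((i - 1, -1))
                if f[i, j] == h[i - 1, j] - go_ext:
                    state = "H"
                i -= 1
        cols.reverse()
        a_idx = [c[0] for c in cols if c[0] >= 0]
        b_idx = [c[1] for c in cols if c[1] >= 0]
        candidates.append(
            (a_idx[0] + 1, b_idx[0] + 1, len(cols),
             a_idx[-1] + 1, b_idx[-1] + 1, cols)
        )
    a_s, b_s, _, a_e, b_e, cols = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return best, a_s, a_e, b_s, b_e, cols
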