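"""Internal local-alignment engine for read classification.

Two-stage design suited to short reads against a small amplicon database:

1. *Screen*: each mate is located on each reference with a fast banded
   edit-distance search (edlib, infix mode) under a budget derived from
   the score floor.  Because a substitution costs 5 score units relative
   to a match (+2 vs -3), an end-to-end alignment with edit distance ``d``
   cannot score above ``2L - 5d``; references beyond the budget cannot
   reach the floor and are skipped.
2. *Refine*: for references whose screening bound is within a fixed margin
   of the best one, the exact affine-gap local (Smith-Waterman/Gotoh)
   score is computed with a numba-compiled banded kernel around the
   located window.  More distant references keep their screening bound —
   they can neither win the assignment nor pull the uniqueness score below
   its cap.

Scoring: match +2, mismatch -3, gap open -5, gap extend -2 (a gap of
length g costs 5 + 2g).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

_NEG = -(10 ** 9)

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (matches nothing)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _banded_local_score(q: np.ndarray, t: np.ndarray, diag: int,
                        band: int) -> int:
    """Best local Gotoh score of q vs t within |j - i - diag| <= band.

    Band cell w (1..width) of row i holds column j = i + diag + (w-1) - band;
    indices 0 and width+1 are sentinels.  Horizontal predecessor (i, j-1)
    is cell w-1, vertical (i-1, j) is cell w+1 of the previous row, and
    diagonal (i-1, j-1) is cell w of the previous row.
    """
    m = q.shape[0]
    n = t.shape[0]
    width = 2 * band + 1
    h_prev = np.full(width + 2, _NEG, dtype=np.int64)
    f_prev = np.full(width + 2, _NEG, dtype=np.int64)
    h_cur = np.full(width + 2, _NEG, dtype=np.int64)
    f_cur = np.full(width + 2, _NEG, dtype=np.int64)
    e_cur = np.full(width + 2, _NEG, dtype=np.int64)
    # row i = 0: local alignments may start anywhere, H = 0
    for w in range(1, width + 1):
        j = 0 + diag + (w - 1) - band
        if 0 <= j <= n:
            h_prev[w] = 0
    best = 0
    for i in range(1, m + 1):
        for w in range(width + 2):
            h_cur[w] = _NEG
            f_cur[w] = _NEG
            e_cur[w] = _NEG
        for w in range(1, width + 1):
            j = i + diag + (w - 1) - band
            if j < 0 or j > n:
                continue
            if j == 0:
                h_cur[w] = 0
                continue
            e_open = h_cur[w - 1] + GAP_OPEN + GAP_EXTEND
            e_ext = e_cur[w - 1] + GAP_EXTEND
            e = e_open if e_open > e_ext else e_ext
            f_open = h_prev[w + 1] + GAP_OPEN + GAP_EXTEND
            f_ext = f_prev[w + 1] + GAP_EXTEND
            f = f_open if f_open > f_ext else f_ext
            qa = q[i - 1]
            ta = t[j - 1]
            sub = MATCH if (qa == ta and qa < 4) else MISMATCH
            d = h_prev[w] + sub
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            h_cur[w] = h
            e_cur[w] = e
            f_cur[w] = f
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best


@njit(cache=False)
def _local_score_full(q: np.ndarray, t: np.ndarray) -> int:
    """Exact affine-gap local alignment score (full DP, no band)."""
    m = q.shape[0]
    n = t.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int64)
    f_prev = np.full(n + 1, _NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        h_cur = np.zeros(n + 1, dtype=np.int64)
        f_cur = np.full(n + 1, _NEG, dtype=np.int64)
        e = _NEG
        for j in range(1, n + 1):
            e_open = h_cur[j - 1] + GAP_OPEN + GAP_EXTEND
            e_ext = e + GAP_EXTEND
            e = e_open if e_open > e_ext else e_ext
            f_open = h_prev[j] + GAP_OPEN + GAP_EXTEND
            f_ext = f_prev[j] + GAP_EXTEND
            f = f_open if f_open > f_ext else f_ext
            qa = q[i - 1]
            ta = t[j - 1]
            sub = MATCH if (qa == ta and qa < 4) else MISMATCH
            d = h_prev[j - 1] + sub
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            h_cur[j] = h
            f_cur[j] = f
            if h > best:
                best = h
        h_prev = h_cur
        f_prev = f_cur
    return best


def local_score(query: str | np.ndarray, target: str | np.ndarray) -> int:
    """Exact affine-gap local alignment score (full-matrix reference path)."""
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    return int(_local_score_full(q, t))


def refine_score(q: np.ndarray, t: np.ndarray, loc_start: int, loc_end: int,
                 pad: int = 16, band: int = 12) -> int:
    """Exact-within-band local score around an edlib-located window.

    ``loc_start``/``loc_end`` are the inclusive target coordinates of the
    screening alignment; the kernel scores the query against the window
    extended by ``pad`` on each side, with a diagonal band wide enough to
    absorb the located span's drift plus ``band``.
    """
    lo = max(0, loc_start - pad)
    hi = min(len(t), loc_end + 1 + pad)
    window = t[lo:hi]
    span = hi - lo
    drift = abs(span - len(q))
    diag = (span - len(q)) // 2
    return int(_banded_local_score(q, window, diag, band + drift))
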