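"""Numba dynamic-programming kernels for duplex alignment and sequence identity.

Sequences are encoded as int8 arrays with A=0, C=1, G=2, U=3. The duplex
alignment is a Smith-Waterman local alignment with affine gaps in which
"match" means Watson-Crick complementarity between the miRNA (passed in
reversed, i.e. read 3'→5') and the candidate site (read 5'→3'), so the
aligned diagonal corresponds to an antiparallel duplex.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pairing classes recorded in Duplex.pairing
UNPAIRED = 0
WC = 1
WOBBLE = 2

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_NEG = -1e18


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def pair_class_table(allow_wobble: bool = True) -> np.ndarray:
    """4x4 table classifying (miRNA base, site base) pairs as WC/WOBBLE/UNPAIRED."""
    cls = np.zeros((4, 4), dtype=np.int8)
    for a, b in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
        cls[a, b] = WC
    if allow_wobble:
        cls[2, 3] = WOBBLE  # G:U
        cls[3, 2] = WOBBLE  # U:G
    return cls


def substitution_table(
    match: float, wobble: float, mismatch: float, allow_wobble: bool = True
) -> np.ndarray:
    cls = pair_class_table(allow_wobble=True)
    sub = np.full((4, 4), mismatch, dtype=np.float64)
    sub[cls == WC] = match
    sub[cls == WOBBLE] = wobble if allow_wobble else mismatch
    return sub


@njit(cache=False)
def sw_score(m, w, sub, mult, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local alignment score of reversed miRNA codes ``m`` against window
    codes ``w``. The first residue of a gap costs ``gap_open``; each further
    residue costs ``gap_extend``. ``mult`` is a per-miRNA-position score
    multiplier (seed weighting; all ones by default).
    """
    L = m.shape[0]
    n = w.shape[0]
    Hprev = np.zeros(n + 1)
    Hcur = np.zeros(n + 1)
    Fcol = np.full(n + 1, _NEG)
    best = 0.0
    for i in range(1, L + 1):
        Hcur[0] = 0.0
        e = _NEG
        for j in range(1, n + 1):
            diag = Hprev[j - 1] + sub[m[i - 1], w[j - 1]] * mult[i - 1]
            e = max(Hcur[j - 1] + gap_open, e + gap_extend)
            Fcol[j] = max(Hprev[j] + gap_open, Fcol[j] + gap_extend)
            h = diag
            if e > h:
                h = e
            if Fcol[j] > h:
                h = Fcol[j]
            if h < 0.0:
                h = 0.0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


@njit(cache=False)
def sw_scan(m, tx, win_len, sub, mult, gap_open, gap_extend):  # pragma: no cover
    """Score every length-``win_len`` window of transcript codes ``tx``."""
    n_win = tx.shape[0] - win_len + 1
    scores = np.empty(n_win)
    for s in range(n_win):
        scores[s] = sw_score(m, tx[s : s + win_len], sub, mult, gap_open, gap_extend)
    return scores


@njit(cache=False)
def sw_align(m, w, sub, mult, gap_open, gap_extend):  # pragma: no cover - numba
    """Full local alignment with traceback.

    Returns ``(score, mir_lo, mir_hi, w_lo, w_hi, pair_mi, pair_wj, n_pairs)``
    where the lo/hi bounds are 1-based inclusive positions of the aligned
    region in the (reversed) miRNA and the window, and ``pair_mi[k]``/
    ``pair_wj[k]`` list the diagonally aligned position pairs (1-based).
    Tie preference during traceback: diagonal, then horizontal gap, then
    vertical gap.
    """
    L = m.shape[0]
    n = w.shape[0]
    H = np.zeros((L + 1, n + 1))
    E = np.full((L + 1, n + 1), _NEG)
    F = np.full((L + 1, n + 1), _NEG)
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            diag = H[i - 1, j - 1] + sub[m[i - 1], w[j - 1]] * mult[i - 1]
            h = diag
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    # best cell; ties resolved to the smallest (i, j) in row-major order
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            if H[i, j] > best:
                best = H[i, j]
                bi = i
                bj = j
    pair_mi = np.zeros(L + n, dtype=np.int64)
    pair_wj = np.zeros(L + n, dtype=np.int64)
    n_pairs = 0
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, pair_mi, pair_wj, 0
    i = bi
    j = bj
    state = 0  # 0 = main, 1 = horizontal gap (E), 2 = vertical gap (F)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] <= 0.0:
                break
            diag = H[i - 1, j - 1] + sub[m[i - 1], w[j - 1]] * mult[i - 1]
            if H[i, j] == diag:
                pair_mi[n_pairs] = i
                pair_wj[n_pairs] = j
                n_pairs += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    mir_lo = i + 1
    w_lo = j + 1
    return best, mir_lo, bi, w_lo, bj, pair_mi, pair_wj, n_pairs


@njit(cache=False)
def nw_identity_counts(a, b, match, mismatch, gap):  # pragma: no cover - numba
    """Global (Needleman-Wunsch) alignment with linear gaps.

    Returns ``(score, identities)`` where ``identities`` is the maximum number
    of identical aligned positions over all optimal-score alignments
    (lexicographic DP: score first, then identity count).
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.empty((n + 1, m + 1), dtype=np.int64)
    I = np.zeros((n + 1, m + 1), dtype=np.int64)
    S[0, 0] = 0
    for i in range(1, n + 1):
        S[i, 0] = i * gap
    for j in range(1, m + 1):
        S[0, j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            sd = S[i - 1, j - 1] + (match if eq == 1 else mismatch)
            su = S[i - 1, j] + gap
            sl = S[i, j - 1] + gap
            s = sd
            if su > s:
                s = su
            if sl > s:
                s = sl
            ident = -1
            if sd == s:
                ident = I[i - 1, j - 1] + eq
            if su == s and I[i - 1, j] > ident:
                ident = I[i - 1, j]
            if sl == s and I[i, j - 1] > ident:
                ident = I[i, j - 1]
            S[i, j] = s
            I[i, j] = ident
    return S[n, m], I[n, m]
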