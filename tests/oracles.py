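"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity over speed and shares no code with the
package: plain-Python dynamic programming, exhaustive enumeration, and direct
recounting.
"""

from __future__ import annotations


NEG = float("-inf")


def sw_score_oracle(mirna: str, site: str, *, match=5.0, wobble=1.0, mismatch=-3.0,
                    gap_open=-8.0, gap_extend=-2.0, allow_wobble=True) -> float:
    """Affine-gap Smith-Waterman score of the antiparallel duplex alignment.

    The miRNA is reversed and aligned against the site 5'→3'; complementary
    bases score ``match``, G:U pairs score ``wobble``, everything else
    ``mismatch``. The first residue of a gap costs ``gap_open``, later ones
    ``gap_extend``.
    """
    comp = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    wob = {("G", "U"), ("U", "G")}

    def s(x, y):
        if (x, y) in comp:
            return match
        if allow_wobble and (x, y) in wob:
            return wobble
        return mismatch

    a = mirna[::-1]
    b = site
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def nw_identity_oracle(a: str, b: str, *, match=1, mismatch=-1, gap=-2) -> float:
    """Global-alignment identity: max identities among score-optimal alignments,
    divided by the shorter length."""
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    I = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = i * gap
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            options = [
                (S[i - 1][j - 1] + (match if eq else mismatch), I[i - 1][j - 1] + eq),
                (S[i - 1][j] + gap, I[i - 1][j]),
                (S[i][j - 1] + gap, I[i][j - 1]),
            ]
            top = max(o[0] for o in options)
            S[i][j] = top
            I[i][j] = max(ident for score, ident in options if score == top)
    return I[n][m] / min(n, m)


def longest_run_oracle(paired) -> tuple[int, int]:
    """Exhaustive enumeration of all runs of consecutive paired positions."""
    n = len(paired)
    best_len, best_pos = 0, 0
    for start in range(n):
        for end in range(start, n):
            if all(paired[start : end + 1]):
                length = end - start + 1
                if length > best_len:
                    best_len, best_pos = length, start + 1
    return best_len, best_pos


def pairing_counts_oracle(paired) -> dict:
    """Direct recount of every pairing-derived feature."""
    L = len(paired)
    seed = sum(1 for i in range(1, min(8, L)) if paired[i])  # positions 2..8
    three_p = sum(1 for i in range(12, L) if paired[i])  # positions 13..L
    run_len, run_pos = longest_run_oracle(paired)
    return {
        "n_paired": sum(bool(p) for p in paired),
        "seed_match": seed,
        "n_paired_3p": three_p,
        "seed_minus_3p": seed - three_p,
        "longest_run": run_len,
        "longest_run_pos": run_pos,
    }


def negative_site_oracle(mirna_seq, transcript_seq, pos_start, pos_end, tol, energy_fn,
                         cg_fn):
    """Exhaustively enumerate disjoint CG-matched windows; return the energy
    argmin as (start, end) 1-based, or None."""
    width = pos_end - pos_start + 1
    pos_site = transcript_seq[pos_start - 1 : pos_end]
    pos_cg = cg_fn(pos_site)
    best = None
    best_energy = float("inf")
    for s0 in range(len(transcript_seq) - width + 1):
        e0 = s0 + width  # exclusive
        if not (e0 <= pos_start - 1 or s0 >= pos_end):
            continue
        window = transcript_seq[s0:e0]
        if abs(cg_fn(window) - pos_cg) > tol:
            continue
        e = energy_fn(mirna_seq, window)
        if e < best_energy:
            best_energy = e
            best = (s0 + 1, s0 + width)
    return best


def confusion_oracle(scores, labels, threshold):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        called = s >= threshold
        if called and y == 1:
            tp += 1
        elif called and y == 0:
            fp += 1
        elif not called and y == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def pr_auc_oracle(scores, labels) -> float:
    """Enumerate every distinct threshold, integrate step-wise over recall."""
    n_pos = sum(1 for y in labels if y == 1)
    thresholds = sorted(set(scores), reverse=True)
    auc = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp, fp, _, _ = confusion_oracle(scores, labels, t)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return auc


def loo_threshold_oracle(scores, labels, precision_target=1.0):
    """Leave-one-out threshold selection by exhaustive fold enumeration.

    Folds are the n singletons; precision of a fold with no positive call is
    vacuously 1.0; the smallest observed score whose mean fold precision
    reaches the target is selected.
    """
    n = len(scores)
    grid = sorted(set(scores))
    for t in grid:
        precisions = []
        for i in range(n):
            tp, fp, _, _ = confusion_oracle([scores[i]], [labels[i]], t)
            precisions.append(tp / (tp + fp) if tp + fp else 1.0)
        if sum(precisions) / n >= precision_target:
            return t
    return max(scores)
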