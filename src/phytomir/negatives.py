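"""Matched negative-exemplar generation.

For each documented positive interaction, candidate negative sites are all
windows of the same length on the same mRNA that do not overlap the positive
site and have a similar CG dinucleotide frequency; among the survivors the
window with the lowest miRNA:window hybridisation energy becomes the negative
exemplar. Picking the energy argmin makes the negatives maximally confusable
with real sites, which is exactly what a discriminative classifier needs.

Length matching matters because site length is itself a feature: a length
difference between classes would leak the label.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .duplex_align import duplex_energy
from .io_formats import (
    NEGATIVE,
    POSITIVE,
    DataError,
    InteractionRecord,
    MiRNA,
    Transcript,
)

logger = logging.getLogger(__name__)

#: adaptive tolerance ladder for "similar CG dinucleotide frequency"
DEFAULT_TOL = 0.05
TOL_LADDER_FACTORS = (1.0, 2.0, 4.0)


def cg_dinucleotide_freq(seq: str) -> float:
    """Frequency of the CG dinucleotide: overlapping ``CG`` count / (len - 1)."""
    if len(seq) < 2:
        raise DataError("cg_dinucleotide_freq requires length >= 2")
    count = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    return count / (len(seq) - 1)


def _window_cg_freqs(seq: str, width: int) -> np.ndarray:
    """CG dinucleotide frequency of every width-``width`` window (stride 1)."""
    is_cg = np.array(
        [1 if seq[i : i + 2] == "CG" else 0 for i in range(len(seq) - 1)], dtype=int
    )
    csum = np.concatenate([[0], np.cumsum(is_cg)])
    n_win = len(seq) - width + 1
    starts = np.arange(n_win)
    counts = csum[starts + width - 1] - csum[starts]
    return counts / (width - 1)


def generate_negative(
    mirna: MiRNA,
    transcript: Transcript,
    positive: InteractionRecord,
    tol: float = DEFAULT_TOL,
    *,
    widen: bool = True,
) -> Optional[InteractionRecord]:
    """Select the negative exemplar for one positive interaction, or ``None``.

    Candidate windows have the positive site's length, stride 1, no overlap
    with the positive interval, and CG dinucleotide frequency within ``tol``
    of the positive site's. When ``widen`` is set and no window survives the
    base tolerance, the tolerance is stepped up (x2, then x4) before giving
    up. The survivor minimising the hybridisation energy with the miRNA wins;
    ties go to the smaller ``site_start``.
    """
    if positive.label != POSITIVE:
        raise DataError("generate_negative expects a positive interaction")
    if tol < 0:
        raise DataError("tol must be >= 0")
    width = positive.site_length
    T = len(transcript.seq)
    if T < width or T - width < width:  # no room for any disjoint window
        logger.info(
            "no negative for %s on %s: transcript too short",
            positive.mirna_id,
            transcript.id,
        )
        return None
    pos_cg = cg_dinucleotide_freq(positive.site_seq(transcript))
    freqs = _window_cg_freqs(transcript.seq, width)
    starts0 = np.arange(len(freqs))  # 0-based window starts
    # overlap exclusion in 0-based half-open arithmetic
    p_lo = positive.site_start - 1
    p_hi = positive.site_end  # exclusive
    disjoint = (starts0 + width <= p_lo) | (starts0 >= p_hi)
    ladder = [tol * f for f in (TOL_LADDER_FACTORS if widen else (1.0,))]
    for step_tol in ladder:
        mask = disjoint & (np.abs(freqs - pos_cg) <= step_tol)
        if not mask.any():
            continue
        best_start = -1
        best_energy = np.inf
        for s in np.nonzero(mask)[0]:
            e = duplex_energy(mirna.seq, transcript.seq[s : s + width])
            if e < best_energy:
                best_energy = e
                best_start = int(s)
        return InteractionRecord(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            site_start=best_start + 1,
            site_end=best_start + width,
            label=NEGATIVE,
        )
    logger.info(
        "no negative for %s on %s: no CG-matched disjoint window",
        positive.mirna_id,
        transcript.id,
    )
    return None


def build_negative_set(
    positives: Sequence[InteractionRecord],
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
    tol: float = DEFAULT_TOL,
    *,
    widen: bool = True,
) -> list[InteractionRecord]:
    """One negative per positive where possible; unresolvable positives are skipped."""
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}
    negatives: list[InteractionRecord] = []
    n_unresolved = 0
    for pos in positives:
        mirna = mirna_by_id.get(pos.mirna_id)
        tx = tx_by_id.get(pos.transcript_id)
        if mirna is None or tx is None:
            n_unresolved += 1
            continue
        neg = generate_negative(mirna, tx, pos, tol=tol, widen=widen)
        if neg is not None:
            negatives.append(neg)
    if n_unresolved:
        logger.info("build_negative_set: skipped %d unresolvable positives", n_unresolved)
    return negatives
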