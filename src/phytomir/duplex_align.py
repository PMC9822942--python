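"""Candidate target-site discovery and miRNA:site duplex alignment.

This is the complementarity-scanning stage of the pipeline: a Smith-Waterman
local alignment of the miRNA (5'→3') against candidate windows of the
transcript read 3'→5', scored with match/wobble/mismatch and affine gap
parameters, followed by a nearest-neighbour hybridisation energy filter.
Unlike canonical animal predictors, no seed-perfection filter is applied by
default: plant targeting involves sites with imperfect seed pairing, and the
downstream classifier, not the scanner, decides what is a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import RNA

from . import _kernels
from ._kernels import UNPAIRED, WC, WOBBLE, encode
from .io_formats import DataError, MiRNA, Transcript, normalize_rna

__all__ = [
    "ScanParams",
    "Duplex",
    "align_duplex",
    "duplex_energy",
    "scan_candidate_sites",
    "UNPAIRED",
    "WC",
    "WOBBLE",
]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the site scanner.

    The alignment scores follow miRanda-style conventions (a strong reward for
    Watson-Crick complementarity, a token reward for G:U wobbles, affine gap
    costs). ``min_score`` and ``max_energy`` jointly gate candidate sites;
    ``max_gap_slack`` bounds how much longer or shorter than the miRNA a site
    may be (bulge tolerance). ``seed_double`` doubles alignment scores at
    miRNA positions 2-8 and is off by default so that non-canonical plant
    sites are not pre-filtered away.
    """

    min_score: float = 80.0
    max_energy: float = -15.0
    allow_wobble: bool = True
    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_penalty: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    max_gap_slack: int = 4
    seed_double: bool = False

    def __post_init__(self):
        if self.match_score <= 0:
            raise ValueError("match_score must be > 0")
        for name in ("mismatch_penalty", "gap_open", "gap_extend"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0")
        if self.max_gap_slack < 0:
            raise ValueError("max_gap_slack must be >= 0")


@dataclass(frozen=True)
class Duplex:
    """A located miRNA:site duplex.

    ``pairing[i]`` gives the state of miRNA position ``i+1`` (counted 1..L
    from the 5' end): WC, WOBBLE or UNPAIRED. ``site_start``/``site_end`` are
    1-based inclusive coordinates on the transcript (or on the supplied site
    sequence when produced by :func:`align_duplex` directly).
    ``mirna_site_map[i]`` is the 1-based site/transcript position aligned
    opposite miRNA position ``i+1``, or 0 when that position sits in a gap or
    outside the local alignment; the map is monotone decreasing over aligned
    positions (antiparallel duplex).
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    pairing: np.ndarray
    energy: float
    alignment_score: float
    mirna_site_map: np.ndarray = field(default=None, repr=False)

    @property
    def n_paired(self) -> int:
        return int(np.count_nonzero(self.pairing))

    @property
    def site_length(self) -> int:
        return self.site_end - self.site_start + 1


def duplex_energy(mirna_seq: str, site_seq: str) -> float:
    """Minimum free energy (kcal/mol) of intermolecular hybridisation.

    Computed with the ViennaRNA nearest-neighbour duplex model (no
    intramolecular structure). Clamped at 0.0: a pair of sequences with no
    stable hybridisation (e.g. no complementary bases at all, or a helix too
    short to pay its initiation cost) has zero hybridisation energy rather
    than a positive one.
    """
    a = normalize_rna(mirna_seq, name="mirna_seq")
    b = normalize_rna(site_seq, name="site_seq")
    dup = RNA.duplexfold(a, b)
    e = dup.energy
    if e >= 0.0 or "(" not in dup.structure:
        return 0.0
    return float(e)


def _mult(L: int, params: ScanParams) -> np.ndarray:
    mult = np.ones(L)
    if params.seed_double:
        mult[1:8] = 2.0  # miRNA positions 2-8
    return mult


def align_duplex(
    mirna_seq: str,
    site_seq: str,
    params: Optional[ScanParams] = None,
    *,
    mirna_id: str = "",
    transcript_id: str = "",
    site_offset: int = 0,
    compute_energy: bool = True,
) -> Duplex:
    """Optimal local complementarity alignment of a miRNA against a site.

    The miRNA (5'→3') is aligned against the site read 3'→5'; equivalently,
    the reversed miRNA is aligned against the site 5'→3'. The returned
    ``site_start``/``site_end`` delimit the aligned region of the site
    (1-based, shifted by ``site_offset`` so callers can report transcript
    coordinates). When no positive-scoring alignment exists the duplex has
    an all-UNPAIRED pairing vector, score 0 and energy 0.
    """
    params = params or ScanParams()
    a = normalize_rna(mirna_seq, name="mirna_seq")
    b = normalize_rna(site_seq, name="site_seq")
    L = len(a)
    m_rev = encode(a)[::-1].copy()
    w = encode(b)
    sub = _kernels.substitution_table(
        params.match_score,
        params.wobble_score,
        params.mismatch_penalty,
        allow_wobble=params.allow_wobble,
    )
    mult = _mult(L, params)[::-1].copy()  # rows follow the reversed miRNA
    score, _, _, w_lo, w_hi, pair_mi, pair_wj, n_pairs = _kernels.sw_align(
        m_rev, w, sub, mult, params.gap_open, params.gap_extend
    )
    pairing = np.zeros(L, dtype=np.int8)
    site_map = np.zeros(L, dtype=np.int32)
    cls = _kernels.pair_class_table(allow_wobble=params.allow_wobble)
    if n_pairs == 0:
        return Duplex(
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            site_start=site_offset + 1,
            site_end=site_offset + len(b),
            pairing=pairing,
            energy=0.0,
            alignment_score=0.0,
            mirna_site_map=site_map,
        )
    for k in range(n_pairs):
        i_rev = int(pair_mi[k])  # 1-based position in the reversed miRNA
        j = int(pair_wj[k])
        pos = L - i_rev  # 0-based position in the 5'→3' miRNA
        pairing[pos] = cls[m_rev[i_rev - 1], w[j - 1]]
        site_map[pos] = site_offset + j
    site_start = site_offset + int(w_lo)
    site_end = site_offset + int(w_hi)
    if compute_energy and np.any(pairing):
        energy = duplex_energy(a, b[int(w_lo) - 1 : int(w_hi)])
    else:
        energy = 0.0
    return Duplex(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_end,
        pairing=pairing,
        energy=energy,
        alignment_score=float(score),
        mirna_site_map=site_map,
    )


def _merge_overlapping(cands: list[Duplex]) -> list[Duplex]:
    """Collapse transitively overlapping duplexes to a single best one.

    Plants typically have a single binding site per mRNA, so each cluster of
    overlapping hits is reduced to its best member: highest alignment score,
    then lowest energy, then smallest site_start.
    """
    if not cands:
        return []
    cands = sorted(cands, key=lambda d: (d.site_start, d.site_end))
    clusters: list[list[Duplex]] = [[cands[0]]]
    hi = cands[0].site_end
    for d in cands[1:]:
        if d.site_start <= hi:
            clusters[-1].append(d)
            hi = max(hi, d.site_end)
        else:
            clusters.append([d])
            hi = d.site_end
    best = [
        min(c, key=lambda d: (-d.alignment_score, d.energy, d.site_start))
        for c in clusters
    ]
    return sorted(best, key=lambda d: d.site_start)


def scan_candidate_sites(
    mirna: MiRNA, transcript: Transcript, params: Optional[ScanParams] = None
) -> list[Duplex]:
    """Find all candidate sites of ``mirna`` on ``transcript``.

    Every window of length ``len(mirna) + max_gap_slack`` is locally aligned;
    windows whose alignment score reaches ``min_score`` are trimmed to the
    aligned interval, required to have a length within ``max_gap_slack`` of
    the miRNA length, and kept only when the hybridisation energy of the
    trimmed site is at most ``max_energy``. Overlapping hits are merged to the
    best per cluster, and the result is sorted by ``site_start``. A transcript
    shorter than the miRNA yields an empty list.
    """
    params = params or ScanParams()
    L = len(mirna.seq)
    T = len(transcript.seq)
    if T < L:
        return []
    win_len = min(T, L + params.max_gap_slack)
    m_rev = encode(mirna.seq)[::-1].copy()
    tx = encode(transcript.seq)
    sub = _kernels.substitution_table(
        params.match_score,
        params.wobble_score,
        params.mismatch_penalty,
        allow_wobble=params.allow_wobble,
    )
    mult = _mult(L, params)[::-1].copy()
    scores = _kernels.sw_scan(
        m_rev, tx, win_len, sub, mult, params.gap_open, params.gap_extend
    )
    lo_len = max(1, L - params.max_gap_slack)
    hi_len = L + params.max_gap_slack
    seen_intervals: set[tuple[int, int]] = set()
    energy_cache: dict[tuple[int, int], float] = {}
    cands: list[Duplex] = []
    for s in np.nonzero(scores >= params.min_score)[0]:
        d = align_duplex(
            mirna.seq,
            transcript.seq[s : s + win_len],
            params,
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            site_offset=int(s),
            compute_energy=False,
        )
        key = (d.site_start, d.site_end)
        if key in seen_intervals or not lo_len <= d.site_length <= hi_len:
            continue
        seen_intervals.add(key)
        if key not in energy_cache:
            energy_cache[key] = duplex_energy(
                mirna.seq, transcript.seq[d.site_start - 1 : d.site_end]
            )
        energy = energy_cache[key]
        if d.alignment_score >= params.min_score and energy <= params.max_energy:
            cands.append(replace(d, energy=energy))
    return _merge_overlapping(cands)
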