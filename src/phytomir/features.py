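"""The 11-value feature vector describing a miRNA:site duplex.

Features fall into three groups: thermodynamics (hybridisation energy, site
accessibility), local sequence composition (AU content), and pairing-pattern
statistics read off the duplex pairing vector (seed match, total pairs,
longest consecutive run and its position, 3'-end pairing, and the seed/3'
difference). The seed region is miRNA positions 2-8 counted from the 5' end;
the 3' region is positions 13 to the miRNA length. G:U wobbles count as
paired throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import RNA

from .duplex_align import Duplex, ScanParams, align_duplex, duplex_energy
from .io_formats import DataError, InteractionRecord, MiRNA, Transcript

__all__ = [
    "FeatureVector",
    "LabeledExample",
    "FEATURE_NAMES",
    "longest_consecutive_pairings",
    "au_content",
    "accessibility",
    "me_motif",
    "me_reference_profile",
    "extract_features",
]

#: canonical feature order used everywhere (CSV columns, model input)
FEATURE_NAMES = [
    "folding_energy",
    "seed_match",
    "accessibility",
    "au_content",
    "me_motif",
    "n_paired",
    "site_length",
    "longest_run",
    "longest_run_pos",
    "n_paired_3p",
    "seed_minus_3p",
]

SEED_START, SEED_END = 2, 8  # 1-based inclusive miRNA positions
THREE_PRIME_START = 13

#: default flank (nt each side) over which AU content is computed
AU_FLANK_DEFAULT = 10
#: default folding context (nt each side of the site) for accessibility
ACCESSIBILITY_CONTEXT_DEFAULT = 70


@dataclass(frozen=True)
class FeatureVector:
    folding_energy: float
    seed_match: int
    accessibility: float
    au_content: float
    me_motif: float
    n_paired: int
    site_length: int
    longest_run: int
    longest_run_pos: int
    n_paired_3p: int
    seed_minus_3p: int

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def to_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


@dataclass(frozen=True)
class LabeledExample:
    """A (miRNA, site) pair with its feature vector and a class label."""

    mirna: MiRNA
    transcript_id: str
    site_start: int
    site_end: int
    label: str  # "positive" | "negative"
    features: FeatureVector

    @property
    def species(self) -> str:
        return self.mirna.species

    @property
    def y(self) -> int:
        return 1 if self.label == "positive" else 0


def longest_consecutive_pairings(pairing: np.ndarray) -> tuple[int, int]:
    """Length and 1-based start position of the longest run of paired positions.

    Ties go to the smallest start index; a vector with no paired positions
    returns ``(0, 0)``.
    """
    pairing = np.asarray(pairing)
    if pairing.size == 0:
        raise DataError("empty pairing vector")
    paired = pairing != 0
    best_len = 0
    best_pos = 0
    run = 0
    for i, p in enumerate(paired):
        if p:
            run += 1
            if run > best_len:
                best_len = run
                best_pos = i - run + 2  # 1-based start of this run
        else:
            run = 0
    return best_len, best_pos


def au_content(
    transcript_seq: str, site_start: int, site_end: int, flank: int = AU_FLANK_DEFAULT
) -> float:
    """Fraction of A/U in the site extended by ``flank`` nt each side (clipped)."""
    n = len(transcript_seq)
    if not 1 <= site_start <= site_end <= n:
        raise DataError(f"invalid site coordinates [{site_start}, {site_end}]")
    lo = max(0, site_start - 1 - flank)
    hi = min(n, site_end + flank)
    window = transcript_seq[lo:hi]
    return sum(1 for c in window if c in "AU") / len(window)


def accessibility(
    transcript_seq: str,
    site_start: int,
    site_end: int,
    context: int = ACCESSIBILITY_CONTEXT_DEFAULT,
) -> float:
    """Mean equilibrium probability that site positions are unpaired.

    The context window (site plus ``context`` nt each side, clipped at the
    transcript ends) is folded intramolecularly with the ViennaRNA partition
    function; per-position unpaired probabilities are 1 minus the row sums of
    the base-pair probability matrix. By construction the value only depends
    on sequence inside the context window.
    """
    n = len(transcript_seq)
    if not 1 <= site_start <= site_end <= n:
        raise DataError(f"invalid site coordinates [{site_start}, {site_end}]")
    lo = max(0, site_start - 1 - context)  # 0-based window start
    hi = min(n, site_end + context)
    window = transcript_seq[lo:hi]
    fc = RNA.fold_compound(window)
    fc.pf()
    bpp = np.array(fc.bpp())[1:, 1:]  # 1-indexed upper-triangular -> dense
    p_paired = bpp.sum(axis=0) + bpp.sum(axis=1)
    site_lo = site_start - 1 - lo  # site positions within the window, 0-based
    site_hi = site_end - lo
    p_unpaired = 1.0 - p_paired[site_lo:site_hi]
    return float(np.clip(p_unpaired, 0.0, 1.0).mean())


def me_reference_profile(L: int) -> np.ndarray:
    """Reference match/editing profile: paired at positions 2-8 and 13-16.

    A boolean vector of length ``L``; ``True`` where the profile expects a
    paired position. This is a fixed, documented stand-in profile capturing
    the canonical seed plus 3'-supplementary pairing blocks; it is swappable
    via the ``profile`` argument of :func:`me_motif`.
    """
    prof = np.zeros(L, dtype=bool)
    prof[SEED_START - 1 : min(SEED_END, L)] = True
    prof[THREE_PRIME_START - 1 : min(16, L)] = True
    return prof


def me_motif(pairing: np.ndarray, profile: np.ndarray | None = None) -> float:
    """Fraction of miRNA positions whose paired state matches the reference profile."""
    pairing = np.asarray(pairing)
    if pairing.size == 0:
        raise DataError("empty pairing vector")
    if profile is None:
        profile = me_reference_profile(pairing.size)
    if profile.size != pairing.size:
        raise DataError("profile length does not match pairing length")
    return float(np.mean((pairing != 0) == profile))


def pairing_features(pairing: np.ndarray) -> dict:
    """All features read directly off the pairing vector.

    Returns ``seed_match`` (paired positions among miRNA 2-8), ``n_paired``,
    ``n_paired_3p`` (positions 13..L), ``seed_minus_3p``, ``longest_run``
    and ``longest_run_pos``.
    """
    pairing = np.asarray(pairing)
    if pairing.size == 0:
        raise DataError("empty pairing vector")
    paired = pairing != 0
    seed_match = int(paired[SEED_START - 1 : SEED_END].sum())
    n_paired_3p = int(paired[THREE_PRIME_START - 1 :].sum())
    longest_run, longest_run_pos = longest_consecutive_pairings(pairing)
    return {
        "seed_match": seed_match,
        "n_paired": int(paired.sum()),
        "n_paired_3p": n_paired_3p,
        "seed_minus_3p": seed_match - n_paired_3p,
        "longest_run": longest_run,
        "longest_run_pos": longest_run_pos,
    }


def extract_features(
    duplex: Duplex,
    mirna: MiRNA,
    transcript: Transcript,
    *,
    au_flank: int = AU_FLANK_DEFAULT,
    access_context: int = ACCESSIBILITY_CONTEXT_DEFAULT,
) -> FeatureVector:
    """Compute all 11 features for a duplex located on a transcript."""
    if duplex.mirna_id and duplex.mirna_id != mirna.id:
        raise DataError(
            f"duplex miRNA id {duplex.mirna_id!r} does not match {mirna.id!r}"
        )
    if duplex.transcript_id and duplex.transcript_id != transcript.id:
        raise DataError(
            f"duplex transcript id {duplex.transcript_id!r} does not match "
            f"{transcript.id!r}"
        )
    pairing = np.asarray(duplex.pairing)
    if pairing.size != len(mirna.seq):
        raise DataError("pairing vector length does not match miRNA length")
    pf = pairing_features(pairing)
    n_paired = pf["n_paired"]
    return FeatureVector(
        folding_energy=duplex.energy if n_paired else 0.0,
        seed_match=pf["seed_match"],
        accessibility=accessibility(
            transcript.seq, duplex.site_start, duplex.site_end, context=access_context
        ),
        au_content=au_content(
            transcript.seq, duplex.site_start, duplex.site_end, flank=au_flank
        ),
        me_motif=me_motif(pairing),
        n_paired=n_paired,
        site_length=duplex.site_length,
        longest_run=pf["longest_run"],
        longest_run_pos=pf["longest_run_pos"],
        n_paired_3p=pf["n_paired_3p"],
        seed_minus_3p=pf["seed_minus_3p"],
    )


def featurize_record(
    mirna: MiRNA,
    transcript: Transcript,
    record: InteractionRecord,
    params: "ScanParams | None" = None,
    *,
    au_flank: int = AU_FLANK_DEFAULT,
    access_context: int = ACCESSIBILITY_CONTEXT_DEFAULT,
) -> LabeledExample:
    """Featurise a located interaction record (positive or negative).

    The pairing vector comes from the local duplex alignment of the miRNA
    against the recorded site; the site-anchored features (length, AU
    content, accessibility) and the hybridisation energy use the full
    recorded interval, so positives and negatives are processed identically.
    """
    from dataclasses import replace as _replace

    site_seq = record.site_seq(transcript)
    duplex = align_duplex(
        mirna.seq,
        site_seq,
        params,
        mirna_id=mirna.id,
        transcript_id=transcript.id,
        site_offset=record.site_start - 1,
        compute_energy=False,
    )
    energy = duplex_energy(mirna.seq, site_seq) if duplex.n_paired else 0.0
    duplex = _replace(
        duplex,
        site_start=record.site_start,
        site_end=record.site_end,
        energy=energy,
    )
    fv = extract_features(
        duplex, mirna, transcript, au_flank=au_flank, access_context=access_context
    )
    return LabeledExample(
        mirna=mirna,
        transcript_id=transcript.id,
        site_start=record.site_start,
        site_end=record.site_end,
        label=record.label,
        features=fv,
    )


def examples_to_matrix(examples) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled examples into ``(X, y)`` in canonical feature order."""
    X = np.array([ex.features.to_array() for ex in examples], dtype=float)
    y = np.array([ex.y for ex in examples], dtype=int)
    return X, y


def examples_to_frame(examples):
    """Serialise labelled examples to a DataFrame (metadata + the 11 features)."""
    import pandas as pd

    rows = []
    for ex in examples:
        row = {
            "mirna_id": ex.mirna.id,
            "species": ex.species,
            "transcript_id": ex.transcript_id,
            "site_start": ex.site_start,
            "site_end": ex.site_end,
            "label": ex.label,
            "mirna_seq": ex.mirna.seq,
        }
        row.update(dict(zip(FEATURE_NAMES, ex.features.to_tuple())))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_examples(df) -> list[LabeledExample]:
    """Rebuild labelled examples from a feature table written by ``examples_to_frame``."""
    examples = []
    int_fields = {
        "seed_match",
        "n_paired",
        "site_length",
        "longest_run",
        "longest_run_pos",
        "n_paired_3p",
        "seed_minus_3p",
    }
    for row in df.itertuples(index=False):
        fv = FeatureVector(
            **{
                name: (int if name in int_fields else float)(getattr(row, name))
                for name in FEATURE_NAMES
            }
        )
        examples.append(
            LabeledExample(
                mirna=MiRNA(id=row.mirna_id, seq=row.mirna_seq, species=row.species),
                transcript_id=row.transcript_id,
                site_start=int(row.site_start),
                site_end=int(row.site_end),
                label=row.label,
                features=fv,
            )
        )
    return examples
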