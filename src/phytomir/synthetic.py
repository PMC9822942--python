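"""Synthetic miRNA/transcript corpora with known planted ground truth.

Every stage of the pipeline can be exercised without downloads: the generator
emits plant-style miRNAs (20-24 nt), transcripts with exactly one planted
binding site each (plants typically have a single site per mRNA), species
labels with planted cross-species homolog families, and the true site
coordinates. Two regimes are supported:

``plant``
    The planted site is a near-perfect reverse complement of the miRNA
    (mutations sprinkled uniformly), placed anywhere on the transcript. A
    configurable fraction of sites is *non-canonical*: at least two of the
    mutations are forced into the positions pairing the miRNA seed (2-8).

``animal``
    Canonical-seed, 3'-UTR-style sites: the seed-pairing positions are kept
    perfectly complementary, the rest of the site is heavily mutated, and the
    site sits in the final third of the transcript.

The generator emulates the *structure* of curated plant interaction sets
(one located site per positive, conserved miRNA families across species); it
does not attempt to match real genome composition or any curated database's
sequence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np

from .duplex_align import ScanParams
from .features import LabeledExample, featurize_record
from .io_formats import POSITIVE, DataError, InteractionRecord, MiRNA, Transcript
from .negatives import DEFAULT_TOL, build_negative_set

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

PLANT_REGIME = "plant"
ANIMAL_REGIME = "animal"

#: mutation rate outside the seed block for animal-regime (canonical) sites
ANIMAL_NONSEED_MISMATCH_RATE = 0.40


@dataclass(frozen=True)
class CorpusSpec:
    """Conditions of a synthetic corpus; defaults are the package's study corpus."""

    n_mirna: int = 200
    n_transcript: int = 2000
    mirna_len_range: tuple[int, int] = (20, 24)
    transcript_len_range: tuple[int, int] = (300, 500)
    site_mismatch_rate: float = 0.05
    noncanonical_fraction: float = 0.10
    homolog_fraction: float = 0.30
    homolog_identity_range: tuple[float, float] = (0.80, 0.95)
    species_labels: tuple[str, ...] = ("gma", "osa", "ptc", "bdi")
    seed: int = 42
    regime: str = PLANT_REGIME
    au_rich_background: bool = False

    def __post_init__(self):
        for name in ("site_mismatch_rate", "noncanonical_fraction", "homolog_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.regime not in (PLANT_REGIME, ANIMAL_REGIME):
            raise DataError(f"unknown regime {self.regime!r}")
        if self.transcript_len_range[0] < 2 * self.mirna_len_range[1]:
            raise DataError(
                "transcripts must be at least twice the longest miRNA "
                "(room for a site and a disjoint negative window)"
            )


@dataclass
class Corpus:
    spec: CorpusSpec
    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    positives: list[InteractionRecord]

    @property
    def mirna_by_id(self) -> dict[str, MiRNA]:
        return {m.id: m for m in self.mirnas}

    @property
    def transcript_by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}


def _random_seq(rng: np.random.Generator, length: int, au_rich: bool) -> str:
    p = [0.35, 0.15, 0.15, 0.35] if au_rich else None
    return "".join(rng.choice(_BASES, size=length, p=p))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _mutate_positions(
    rng: np.random.Generator, seq: list[str], positions: np.ndarray
) -> None:
    for p in positions:
        choices = [b for b in "ACGU" if b != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]


def _plant_site(rng: np.random.Generator, mirna_seq: str, noncanonical: bool, rate: float) -> str:
    """Mutated reverse complement; non-canonical sites get >=2 seed-region hits."""
    L = len(mirna_seq)
    site = list(reverse_complement(mirna_seq))
    n_mut = int(rng.binomial(L, rate))
    # site index j (0-based) pairs miRNA position L - j (1-based)
    seed_js = np.arange(L - 8, L - 1)  # pair miRNA positions 2..8
    if noncanonical:
        n_mut = max(n_mut, 2)
        forced = rng.choice(seed_js, size=2, replace=False)
        rest = np.setdiff1d(np.arange(L), forced)
        extra = rng.choice(rest, size=n_mut - 2, replace=False) if n_mut > 2 else []
        positions = np.concatenate([forced, np.asarray(extra, dtype=int)])
    else:
        positions = rng.choice(L, size=n_mut, replace=False)
    _mutate_positions(rng, site, np.asarray(positions, dtype=int))
    return "".join(site)


def _animal_site(rng: np.random.Generator, mirna_seq: str) -> str:
    """Perfect seed complementarity, heavily mutated elsewhere."""
    L = len(mirna_seq)
    site = list(reverse_complement(mirna_seq))
    seed_js = set(range(L - 8, L - 1))
    non_seed = np.array([j for j in range(L) if j not in seed_js])
    n_mut = int(rng.binomial(len(non_seed), ANIMAL_NONSEED_MISMATCH_RATE))
    positions = rng.choice(non_seed, size=n_mut, replace=False)
    _mutate_positions(rng, site, positions)
    return "".join(site)


def _make_mirnas(rng: np.random.Generator, spec: CorpusSpec) -> list[MiRNA]:
    lo, hi = spec.mirna_len_range
    n_derived = int(round(spec.homolog_fraction * spec.n_mirna)) // 2
    n_indep = spec.n_mirna - n_derived
    mirnas: list[MiRNA] = []
    for i in range(n_indep):
        species = spec.species_labels[int(rng.integers(len(spec.species_labels)))]
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)), au_rich=False)
        mirnas.append(MiRNA(id=f"mir{i:04d}", seq=seq, species=species))
    if n_derived and len(spec.species_labels) < 2:
        raise DataError("homolog planting needs at least two species labels")
    parents = rng.choice(n_indep, size=n_derived, replace=False) if n_derived else []
    for k, pi in enumerate(parents):
        parent = mirnas[int(pi)]
        other = [s for s in spec.species_labels if s != parent.species]
        species = other[int(rng.integers(len(other)))]
        ident = rng.uniform(*spec.homolog_identity_range)
        L = len(parent.seq)
        n_mut = max(1, int(round(L * (1.0 - ident))))
        seq = list(parent.seq)
        _mutate_positions(rng, seq, rng.choice(L, size=n_mut, replace=False))
        mirnas.append(MiRNA(id=f"{parent.id}h", seq="".join(seq), species=species))
    return mirnas


def generate_corpus(spec: Optional[CorpusSpec] = None, **overrides) -> Corpus:
    """Generate a corpus with one planted site per transcript, reproducibly.

    Accepts either a :class:`CorpusSpec` or keyword overrides of its fields.
    """
    if spec is None:
        spec = CorpusSpec(**overrides)
    elif overrides:
        spec = dc_replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    mirnas = _make_mirnas(rng, spec)
    lo_t, hi_t = spec.transcript_len_range
    transcripts: list[Transcript] = []
    positives: list[InteractionRecord] = []
    for t in range(spec.n_transcript):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        T = int(rng.integers(lo_t, hi_t + 1))
        seq = list(_random_seq(rng, T, au_rich=spec.au_rich_background))
        if spec.regime == ANIMAL_REGIME:
            site = _animal_site(rng, mirna.seq)
        else:
            noncanonical = bool(rng.random() < spec.noncanonical_fraction)
            site = _plant_site(rng, mirna.seq, noncanonical, spec.site_mismatch_rate)
        w = len(site)
        if spec.regime == ANIMAL_REGIME:
            utr_start = max(0, T - T // 3 - w)
            start0 = int(rng.integers(utr_start, T - w + 1))
        else:
            start0 = int(rng.integers(0, T - w + 1))
        seq[start0 : start0 + w] = site
        tx = Transcript(id=f"tx{t:05d}", seq="".join(seq), species=mirna.species)
        transcripts.append(tx)
        positives.append(
            InteractionRecord(
                mirna_id=mirna.id,
                transcript_id=tx.id,
                site_start=start0 + 1,
                site_end=start0 + w,
                label=POSITIVE,
            )
        )
    return Corpus(spec=spec, mirnas=mirnas, transcripts=transcripts, positives=positives)


def corpus_to_examples(
    corpus: Corpus,
    tol: float = DEFAULT_TOL,
    params: Optional[ScanParams] = None,
) -> list[LabeledExample]:
    """Wire a corpus through negative generation and feature extraction.

    Returns one positive example per planted site and at most one negative
    per positive, both featurised identically from their recorded site
    interval.
    """
    negatives = build_negative_set(
        corpus.positives, corpus.mirnas, corpus.transcripts, tol=tol
    )
    mirna_by_id = corpus.mirna_by_id
    tx_by_id = corpus.transcript_by_id
    examples: list[LabeledExample] = []
    for rec in list(corpus.positives) + negatives:
        examples.append(
            featurize_record(
                mirna_by_id[rec.mirna_id], tx_by_id[rec.transcript_id], rec, params
            )
        )
    return examples
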