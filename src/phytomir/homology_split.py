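"""Homology-controlled train/test partitioning.

Training a target predictor and evaluating it on interactions whose miRNAs
are near-identical homologs of training miRNAs inflates every metric; plant
miRNA families are widely conserved across species, so this leakage is the
default, not the exception. The split logic here (i) measures pairwise miRNA
identity with an exact global alignment, (ii) clusters miRNAs greedily at an
identity threshold (CD-HIT style, with exact DP identity in place of k-mer
screening), and (iii) excludes from training every example whose miRNA
reaches the threshold against any test-species miRNA. Test examples with
duplicate feature vectors are also removed, so a family of conserved targets
cannot be counted many times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import encode
from .features import LabeledExample
from .io_formats import DataError, MiRNA

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.70

# Needleman-Wunsch parameters for identity computation. Gaps are costed at
# twice a mismatch so that shifting the alignment to manufacture matches
# between unrelated sequences does not pay; point-mutated homologs keep the
# plain diagonal alignment and an identity of (L - mutations) / L.
NW_MATCH = 1
NW_MISMATCH = -1
NW_GAP = -2


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence length.

    The alignment is a global Needleman-Wunsch; among score-optimal
    alignments the one with the most identities is used, which makes the
    value well-defined (no dependence on traceback tie-breaking). Symmetric,
    in [0, 1] for the scoring used here.
    """
    if not a or not b:
        raise DataError("pairwise_identity: empty sequence")
    _, ident = _kernels.nw_identity_counts(
        encode(a), encode(b), NW_MATCH, NW_MISMATCH, NW_GAP
    )
    return ident / min(len(a), len(b))


def cluster_mirnas(
    mirnas: Sequence[MiRNA], threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> list[list[MiRNA]]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest-first (ties broken by id for
    determinism); each joins the first existing cluster whose representative
    (its founding, longest member) reaches the threshold, otherwise it founds
    a new cluster.
    """
    if not 0 < threshold <= 1:
        raise DataError("threshold must be in (0, 1]")
    ordered = sorted(mirnas, key=lambda m: (-len(m.seq), m.id))
    clusters: list[list[MiRNA]] = []
    for m in ordered:
        for cluster in clusters:
            if pairwise_identity(m.seq, cluster[0].seq) >= threshold:
                cluster.append(m)
                break
        else:
            clusters.append([m])
    return clusters


@dataclass
class DatasetSplit:
    """A leakage-free train/test partition with per-stage bookkeeping."""

    train: list[LabeledExample]
    test: list[LabeledExample]
    test_species: str
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    n_train_removed_homology: int = 0
    n_test_removed_duplicates: int = 0
    n_test_removed_exclusion: int = 0

    def max_cross_identity(self) -> float:
        """Exhaustive all-pairs audit of miRNA identity across the split."""
        train_seqs = sorted({ex.mirna.seq for ex in self.train})
        test_seqs = sorted({ex.mirna.seq for ex in self.test})
        best = 0.0
        for a in train_seqs:
            for b in test_seqs:
                best = max(best, pairwise_identity(a, b))
        return best


def make_split(
    examples: Sequence[LabeledExample],
    test_species: str,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    exclude_like: Optional[Sequence[str]] = None,
) -> DatasetSplit:
    """Partition examples into a test species and a homology-filtered train set.

    ``test`` holds all examples of ``test_species``, minus any whose miRNA
    reaches the identity threshold against a sequence in ``exclude_like``
    (e.g. miRNAs also present in an auxiliary training source), and minus
    later duplicates at the feature-vector level (first occurrence kept).
    ``train`` holds all other examples except those whose miRNA has identity
    >= ``threshold`` with any test miRNA.
    """
    test_raw = [ex for ex in examples if ex.species == test_species]
    if not test_raw:
        raise DataError(f"no examples with species {test_species!r}")
    train_raw = [ex for ex in examples if ex.species != test_species]

    n_excluded = 0
    if exclude_like:
        kept = []
        for ex in test_raw:
            if any(pairwise_identity(ex.mirna.seq, s) >= threshold for s in exclude_like):
                n_excluded += 1
            else:
                kept.append(ex)
        test_raw = kept

    seen: set[tuple] = set()
    test: list[LabeledExample] = []
    n_dup = 0
    for ex in test_raw:
        key = ex.features.to_tuple()
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        test.append(ex)

    test_seqs = sorted({ex.mirna.seq for ex in test})
    identity_cache: dict[str, float] = {}

    def max_identity_to_test(seq: str) -> float:
        if seq not in identity_cache:
            identity_cache[seq] = max(
                (pairwise_identity(seq, t) for t in test_seqs), default=0.0
            )
        return identity_cache[seq]

    train = [ex for ex in train_raw if max_identity_to_test(ex.mirna.seq) < threshold]
    n_homology = len(train_raw) - len(train)
    logger.info(
        "make_split(%s): test %d (-%d dup, -%d excluded), train %d (-%d homologous)",
        test_species,
        len(test),
        n_dup,
        n_excluded,
        len(train),
        n_homology,
    )
    return DatasetSplit(
        train=train,
        test=test,
        test_species=test_species,
        identity_threshold=threshold,
        n_train_removed_homology=n_homology,
        n_test_removed_duplicates=n_dup,
        n_test_removed_exclusion=n_excluded,
    )
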