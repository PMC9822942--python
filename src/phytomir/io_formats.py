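"""Reading and writing external data: FASTA sequences, interaction tables, predictions.

All external coordinates are 1-based and inclusive, following the convention of
degradome/PARE-style binding-site listings. Sequences are normalised to the
uppercase RNA alphabet on input (``T`` becomes ``U``); records containing any
other character are rejected, because base pairing and hybridisation energy are
undefined on ambiguity codes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: mature miRNAs are typically 20-24 nt; lengths outside this band trigger a warning
MIRNA_LENGTH_SOFT_RANGE = (16, 30)


class DataError(ValueError):
    """Malformed or inconsistent input data (maps to CLI exit code 3)."""


def normalize_rna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase and convert DNA ``T`` to RNA ``U``; reject non-ACGU characters."""
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise DataError(f"{name}: empty sequence")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise DataError(
            f"{name}: non-ACGU characters after normalization: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: ~20-24 nt guide strand, written 5'→3'."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq, name=self.id))
        lo, hi = MIRNA_LENGTH_SOFT_RANGE
        if not lo <= len(self.seq) <= hi:
            logger.warning(
                "miRNA %s has unusual length %d nt (typical mature length 20-24)",
                self.id,
                len(self.seq),
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """An mRNA/transcript sequence, written 5'→3'."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq, name=self.id))

    def __len__(self) -> int:
        return len(self.seq)


POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class InteractionRecord:
    """A (miRNA, transcript) pair with a located binding site and a label.

    ``site_start``/``site_end`` are 1-based inclusive transcript coordinates.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    label: str = POSITIVE

    def __post_init__(self):
        if self.label not in (POSITIVE, NEGATIVE):
            raise DataError(f"label must be positive/negative, got {self.label!r}")
        if not 1 <= self.site_start <= self.site_end:
            raise DataError(
                f"invalid site coordinates [{self.site_start}, {self.site_end}]"
            )

    @property
    def site_length(self) -> int:
        return self.site_end - self.site_start + 1

    def site_seq(self, transcript: Transcript) -> str:
        if self.site_end > len(transcript.seq):
            raise DataError(
                f"site_end {self.site_end} beyond transcript "
                f"{transcript.id} length {len(transcript.seq)}"
            )
        return transcript.seq[self.site_start - 1 : self.site_end]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file into ``[(id, seq), ...]``.

    Ids are the first whitespace-delimited token of each header. Sequences are
    normalised (uppercase, T→U). Order is preserved. Empty files and duplicate
    ids are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, normalize_rna(str(rec.seq), name=rec.id)))
    if not records:
        raise DataError(f"no records in FASTA file {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [
        SeqRecord(Seq(normalize_rna(seq, name=rid)), id=rid, description="")
        for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_mirnas(path: str | Path, species: str = "") -> list[MiRNA]:
    return [MiRNA(id=r, seq=s, species=species) for r, s in read_fasta(path)]


def read_transcripts(path: str | Path, species: str = "") -> list[Transcript]:
    return [Transcript(id=r, seq=s, species=species) for r, s in read_fasta(path)]


INTERACTION_COLUMNS = ["mirna_id", "transcript_id", "site_start", "site_end", "label"]


def read_interactions(
    path: str | Path,
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
) -> tuple[list[InteractionRecord], int]:
    """Read a TSV interaction table and resolve ids against the sequence sets.

    Returns ``(records, n_skipped)``. Records whose miRNA or transcript id is
    absent from the supplied sets are skipped and counted (binding-site
    databases routinely list transcripts that have since left the annotation);
    malformed coordinates are a hard error that names the offending line.
    """
    path = Path(path)
    mirna_ids = {m.id for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}
    records: list[InteractionRecord] = []
    n_skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(INTERACTION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            if row["mirna_id"] not in mirna_ids or row["transcript_id"] not in tx_by_id:
                n_skipped += 1
                continue
            try:
                start = int(row["site_start"])
                end = int(row["site_end"])
                rec = InteractionRecord(
                    mirna_id=row["mirna_id"],
                    transcript_id=row["transcript_id"],
                    site_start=start,
                    site_end=end,
                    label=row["label"],
                )
            except (ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            tx = tx_by_id[rec.transcript_id]
            if rec.site_end > len(tx.seq):
                raise DataError(
                    f"{path}:{lineno}: site_end {rec.site_end} beyond transcript "
                    f"{tx.id} length {len(tx.seq)}"
                )
            records.append(rec)
    if n_skipped:
        logger.info("read_interactions: skipped %d unresolvable records", n_skipped)
    return records, n_skipped


def write_interactions(path: str | Path, records: Iterable[InteractionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(INTERACTION_COLUMNS)
        for r in records:
            writer.writerow([r.mirna_id, r.transcript_id, r.site_start, r.site_end, r.label])


@dataclass(frozen=True)
class PredictionRow:
    """One scored candidate site, as reported to the user."""

    mirna_id: str
    transcript_id: str
    mirna_seed_index: int
    mrna_seed_index: int
    mirna_seed_seq: str
    mrna_seed_seq: str
    site_start: int
    site_end: int
    confidence: float


PREDICTION_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "mirna_seed_index",
    "mrna_seed_index",
    "mirna_seed_seq",
    "mrna_seed_seq",
    "site_start",
    "site_end",
    "confidence",
]


def write_predictions(path: str | Path, rows: Sequence[PredictionRow]) -> None:
    """Write scored candidate sites as CSV; confidence with four decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PREDICTION_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.mirna_id,
                    r.transcript_id,
                    r.mirna_seed_index,
                    r.mrna_seed_index,
                    r.mirna_seed_seq,
                    r.mrna_seed_seq,
                    r.site_start,
                    r.site_end,
                    f"{r.confidence:.4f}",
                ]
            )
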