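"""End-to-end orchestration: configuration, prediction runs, experiments.

``run_predict`` is the deployment path (scan every miRNA against every
transcript, featurise candidates, score them with a trained forest).
``run_experiment`` is the evaluation path: it assembles a training mixture
from labelled example pools (animal-style, plant-style, or combinations),
builds a homology-controlled split against a test species, trains, and
reports PR-AUC plus threshold metrics. An embedded leakage audit re-checks
the split with an exhaustive all-pairs identity scan and aborts the run if
any train/test miRNA pair reaches the identity threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .duplex_align import Duplex, ScanParams, scan_candidate_sites
from .evaluation import metrics_at_threshold, pr_curve
from .features import (
    ACCESSIBILITY_CONTEXT_DEFAULT,
    AU_FLANK_DEFAULT,
    SEED_END,
    SEED_START,
    LabeledExample,
    examples_to_matrix,
    extract_features,
)
from .homology_split import DEFAULT_IDENTITY_THRESHOLD, make_split
from .io_formats import (
    DataError,
    MiRNA,
    PredictionRow,
    Transcript,
    write_predictions,
)
from .model import DEFAULT_CV_FOLDS, DEFAULT_N_TREES, TrainedModel, predict, train
from .negatives import DEFAULT_TOL

logger = logging.getLogger(__name__)


class InternalError(AssertionError):
    """A pipeline self-check failed (maps to CLI exit code 4)."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their paper-pinned defaults.

    Identity threshold 0.70, 13 trees, 5 CV folds and an evaluation threshold
    of 0.5 are the pinned operating points; everything else is a documented
    default of this implementation.
    """

    scan: ScanParams = field(default_factory=ScanParams)
    negative_tol: float = DEFAULT_TOL
    au_flank: int = AU_FLANK_DEFAULT
    access_context: int = ACCESSIBILITY_CONTEXT_DEFAULT
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    n_trees: int = DEFAULT_N_TREES
    cv_folds: int = DEFAULT_CV_FOLDS
    eval_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan = ScanParams(**raw.pop("scan", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"scan"}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(scan=scan, **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        scan_fields = {f.name for f in dataclasses.fields(ScanParams)}
        scan_kw = {k: v for k, v in kwargs.items() if k in scan_fields and v is not None}
        cfg_kw = {
            k: v for k, v in kwargs.items() if k not in scan_fields and v is not None
        }
        scan = dataclasses.replace(self.scan, **scan_kw) if scan_kw else self.scan
        return dataclasses.replace(self, scan=scan, **cfg_kw)


def seed_location(duplex: Duplex, mirna: MiRNA, transcript: Transcript):
    """Locate the seed-pairing region on both molecules.

    Returns ``(mirna_seed_index, mrna_seed_index, mirna_seed_seq,
    mrna_seed_seq)``; the mRNA segment is the transcript stretch aligned
    opposite miRNA positions 2-8, reported 5'→3' in transcript orientation.
    When no seed position is aligned, index 0 and an empty string are
    reported.
    """
    mirna_seed_seq = mirna.seq[SEED_START - 1 : SEED_END]
    site_map = np.asarray(duplex.mirna_site_map)
    mapped = site_map[SEED_START - 1 : SEED_END]
    mapped = mapped[mapped > 0]
    if mapped.size == 0:
        return SEED_START, 0, mirna_seed_seq, ""
    lo, hi = int(mapped.min()), int(mapped.max())
    return SEED_START, lo, mirna_seed_seq, transcript.seq[lo - 1 : hi]


def predict_targets(
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
    model: TrainedModel,
    config: Optional[PipelineConfig] = None,
) -> list[PredictionRow]:
    """Scan every (miRNA, transcript) pair, featurise and score all candidates.

    Rows are sorted by confidence descending (ties: miRNA id, transcript id,
    site start), so reruns with identical inputs are byte-identical.
    """
    config = config or PipelineConfig()
    candidates: list[tuple[Duplex, MiRNA, Transcript]] = []
    for mirna in mirnas:
        for tx in transcripts:
            for dup in scan_candidate_sites(mirna, tx, config.scan):
                candidates.append((dup, mirna, tx))
    if not candidates:
        logger.info("predict_targets: no candidate sites found")
        return []
    X = np.array(
        [
            extract_features(
                d, m, t, au_flank=config.au_flank, access_context=config.access_context
            ).to_array()
            for d, m, t in candidates
        ]
    )
    confidences = predict(model, X)
    rows = []
    for (dup, mirna, tx), conf in zip(candidates, confidences):
        mi, ti, mseq, tseq = seed_location(dup, mirna, tx)
        rows.append(
            PredictionRow(
                mirna_id=mirna.id,
                transcript_id=tx.id,
                mirna_seed_index=mi,
                mrna_seed_index=ti,
                mirna_seed_seq=mseq,
                mrna_seed_seq=tseq,
                site_start=dup.site_start,
                site_end=dup.site_end,
                confidence=float(conf),
            )
        )
    rows.sort(key=lambda r: (-r.confidence, r.mirna_id, r.transcript_id, r.site_start))
    return rows


def run_predict(
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
    model: TrainedModel,
    out_csv: str | Path,
    config: Optional[PipelineConfig] = None,
) -> list[PredictionRow]:
    rows = predict_targets(mirnas, transcripts, model, config)
    write_predictions(out_csv, rows)
    logger.info(
        "run_predict: %d miRNAs x %d transcripts -> %d scored sites",
        len(mirnas),
        len(transcripts),
        len(rows),
    )
    return rows


MIXTURES = {
    "animal_only": ("animal",),
    "animal_plus_small_plant": ("animal", "small_plant"),
    "animal_plus_plant": ("animal", "plant"),
    "plant_only": ("plant",),
}


def run_experiment(
    pools: dict[str, Sequence[LabeledExample]],
    mixture: str,
    test_species: str,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Train a mixture classifier and evaluate it on one test species.

    ``pools`` maps pool names (``animal``, ``plant``, optionally
    ``small_plant``) to labelled examples. The test set is always drawn from
    the ``plant`` pool's test-species examples; the training candidates come
    from the mixture's pools, homology-filtered against the test miRNAs.
    """
    config = config or PipelineConfig()
    if mixture not in MIXTURES:
        raise DataError(f"unknown mixture {mixture!r}; expected one of {sorted(MIXTURES)}")
    if "plant" not in pools:
        raise DataError("missing pool 'plant' (source of the test set)")
    for pool in MIXTURES[mixture]:
        if pool not in pools:
            raise DataError(f"missing pool {pool!r} for mixture {mixture!r}")
    examples = [
        ex
        for pool in MIXTURES[mixture]
        for ex in pools[pool]
        if ex.species != test_species
    ]
    examples += [ex for ex in pools["plant"] if ex.species == test_species]
    split = make_split(examples, test_species, threshold=config.identity_threshold)
    audit = split.max_cross_identity()
    if audit >= config.identity_threshold:
        raise InternalError(
            f"leakage audit failed: max train/test miRNA identity {audit:.3f} "
            f">= {config.identity_threshold}"
        )
    m = train(split.train, n_trees=config.n_trees, seed=config.seed)
    scores = predict(m, split.test)
    _, y_test = examples_to_matrix(split.test)
    curve = pr_curve(scores, y_test)
    metrics = metrics_at_threshold(scores, y_test, threshold=config.eval_threshold)
    report = {
        "mixture": mixture,
        "test_species": test_species,
        "n_train": len(split.train),
        "n_test": len(split.test),
        "auc": curve.auc,
        "recall": metrics.recall,
        "precision": metrics.precision,
        "accuracy": metrics.accuracy,
        "leakage_audit_max_identity": audit,
    }
    logger.info("run_experiment: %s", report)
    return report
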