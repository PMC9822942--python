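"""Matched vs mismatched training regimes on a plant-style test set.

Trains one forest on plant-style interactions (broad complementarity,
sites anywhere on the transcript, 10% non-canonical seeds) and one on an
equally sized canonical-seed 3'-UTR-style corpus, then evaluates both on the
same homology-controlled plant test species.
"""

import numpy as np

import phytomir as pm

plant = pm.corpus_to_examples(pm.generate_corpus(n_mirna=25, n_transcript=220, seed=31))
animal = pm.corpus_to_examples(
    pm.generate_corpus(
        n_mirna=25, n_transcript=180, seed=32,
        regime="animal", species_labels=("hsa",), homolog_fraction=0.0,
    )
)

split = pm.make_split(plant, "gma", threshold=0.70)
print(f"test species gma: {len(split.test)} examples; "
      f"max train/test miRNA identity {split.max_cross_identity():.2f}")

n = min(len(split.train), len(animal))
y = np.array([e.y for e in split.test])
for name, pool in (("plant-trained", split.train[:n]), ("animal-trained", animal[:n])):
    model = pm.train(pool, seed=3)
    scores = pm.predict(model, split.test)
    auc = pm.pr_curve(scores, y).auc
    m = pm.metrics_at_threshold(scores, y, 0.5)
    print(f"{name:<15} PR-AUC {auc:.3f}  recall {m.recall:.3f}  "
          f"precision {m.precision:.3f}  accuracy {m.accuracy:.3f}")
print(
    "\nThe regime mismatch costs the canonical-seed model on plant data — "
    "it misses non-canonical sites and misjudges plant-style negatives, so "
    "the matched (plant-trained) model dominates on PR-AUC and precision."
)
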