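"""Build a labelled training set from a synthetic corpus.

Generates a small plant-style corpus with planted binding sites, derives one
matched negative per positive (disjoint, CG-matched, lowest hybridisation
energy), extracts the 11-feature vector for every example and prints the
per-class means of a few discriminative features.
"""

import numpy as np

import phytomir as pm
from phytomir.features import FEATURE_NAMES

corpus = pm.generate_corpus(n_mirna=15, n_transcript=60, seed=5)
examples = pm.corpus_to_examples(corpus)

n_pos = sum(e.y for e in examples)
print(f"corpus: {len(corpus.positives)} planted positives -> "
      f"{n_pos} positive / {len(examples) - n_pos} negative examples")

X = np.array([e.features.to_array() for e in examples])
y = np.array([e.y for e in examples])
print(f"\n{'feature':<16}{'pos mean':>10}{'neg mean':>10}")
for name in ("folding_energy", "seed_match", "n_paired", "longest_run"):
    i = FEATURE_NAMES.index(name)
    print(f"{name:<16}{X[y == 1, i].mean():>10.2f}{X[y == 0, i].mean():>10.2f}")
print(
    "\nPlanted sites are near-perfect duplexes (low energy, ~20 paired "
    "positions); the energy-argmin negatives pair far less, which is the "
    "signal the forest learns."
)
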