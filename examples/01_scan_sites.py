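"""Scan a transcript for candidate miRNA binding sites.

Builds a 400-nt transcript with the reverse complement of a miRNA planted at
position 151, scans it, and prints each candidate's coordinates, alignment
score, hybridisation energy and pairing pattern.
"""

import numpy as np

import phytomir as pm
from phytomir.synthetic import reverse_complement

rng = np.random.default_rng(0)
mirna = pm.MiRNA(id="mir-demo", seq="UGGAGUGUGACAAUGGUGUUUG", species="gma")

background = "".join(rng.choice(list("ACGU"), size=400))
site = reverse_complement(mirna.seq)
seq = background[:150] + site + background[150 + len(site):]
tx = pm.Transcript(id="tx-demo", seq=seq, species="gma")

hits = pm.scan_candidate_sites(mirna, tx)
print(f"{len(hits)} candidate site(s) for {mirna.id} on {tx.id}:")
for h in hits:
    pairing = "".join(".WG"[p] for p in h.pairing)  # W = Watson-Crick, G = wobble
    print(
        f"  site {h.site_start}-{h.site_end}  score {h.alignment_score:.0f}  "
        f"energy {h.energy:.1f} kcal/mol  pairing(5'->3') {pairing}"
    )
print(
    "\nThe planted site at 151-172 is recovered; a score of 110 is the "
    "maximum for a perfectly complementary 22-mer (22 x 5), and the strongly "
    "negative energy marks a stable duplex."
)
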