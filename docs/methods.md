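# Methods

## Problem and overall design

Plant miRNAs silence their targets through extensive base-pairing with the
mRNA, usually at a single site in the coding region, and with more tolerance
for imperfect seed pairing than the canonical animal 3′-UTR rules allow.
Rule-based plant predictors enforce those rules up front and therefore miss
non-canonical interactions; predictors trained on animal interaction data
transfer poorly to plants. phytomir takes the learning route: an
intentionally permissive complementarity scan proposes candidate sites, each
candidate duplex is summarised by 11 features, and a small random forest
trained on located plant interactions decides what is a target. The pipeline
is deliberately symmetric between training and deployment: negatives are
manufactured from the same mRNAs as the positives, features are computed
identically for both classes, and train/test splits are controlled for miRNA
homology so that evaluation simulates an unannotated species.

## Candidate site scanning (`duplex_align`)

Candidates come from a Smith–Waterman local alignment of the miRNA (5′→3′)
against transcript windows read 3′→5′ — an antiparallel duplex alignment.
Substitution scores are complementarity scores: Watson–Crick pairs +5, G:U
wobble +1, everything else −3; gaps are affine (first residue −8, each
further −2). Every window of length `L + max_gap_slack` (miRNA length plus a
4-nt bulge allowance) is scored; windows reaching `min_score` (default 80)
are trimmed to their aligned interval and kept if the interval length stays
within the slack band and the hybridisation energy of the trimmed site is at
most `max_energy` (default −15 kcal/mol). Overlapping hits are merged to the
single best per cluster (score, then lower energy, then smaller start),
reflecting the one-site-per-mRNA pattern typical of plants. The DP kernels
are numba-compiled; traceback prefers diagonal over horizontal over vertical
moves on exact ties, and the best cell is the row-major-first maximum, so
results are bit-deterministic.

Seed weighting (doubling scores at miRNA positions 2–8) exists as a switch
but is off by default: pre-filtering on seed perfection would remove exactly
the non-canonical sites the classifier is supposed to judge.

`min_score` trades recall against candidate volume. At the default 80, a
22-nt site tolerates roughly three full mismatches (each costs 8 score
points against the 110-point perfect score); site recovery on synthetic
corpora is ≥95% at a 5% per-base site mutation rate but degrades once the
mutation rate approaches 10%, where four-mismatch sites become common.
Lower `min_score` if very divergent sites matter more than scan volume.

## Thermodynamics

Hybridisation energy is the minimum free energy of intermolecular duplex
formation under the ViennaRNA nearest-neighbour model (`duplexfold`), with
no intramolecular structure. Energies are clamped at 0.0: sequence pairs
with no stable duplex (no complementary stretch, or a helix too short to
repay the initiation penalty) are assigned zero rather than a positive
value, so "no pairing ⇒ energy 0" and "energy ≤ 0" hold everywhere.

Site accessibility is computed separately: the site plus 70 nt of context on
each side (clipped at transcript ends) is folded intramolecularly with the
ViennaRNA partition function, and the feature is the mean probability that
site positions are unpaired in the equilibrium ensemble. By construction it
ignores sequence beyond the context window. Folding energy and accessibility
are deliberately kept as two separate features rather than folded into one
opening-cost-corrected energy; the forest can combine them as the data
dictate.

## The 11 features (`features`)

In canonical order: `folding_energy` (kcal/mol, ≤0), `seed_match` (paired
positions among miRNA 2–8, 0–7), `accessibility` (mean unpaired
probability), `au_content` (A/U fraction of the site ±10 nt flank),
`me_motif`, `n_paired`, `site_length`, `longest_run` (longest consecutive
paired stretch), `longest_run_pos` (1-based miRNA position of its 5′-most
base, 0 if no pairs; ties to the smallest start), `n_paired_3p` (paired
positions among miRNA 13..L), and `seed_minus_3p` (= `seed_match` −
`n_paired_3p`, by construction).

Choices worth stating: the seed is positions 2–8 and the 3′ region is
13..L — the field's usual delimitation, since the regions are conventionally
named but not formally delimited. `seed_match` is a count rather than a
binary flag because plant sites tolerate seed mismatches and a count keeps
that information. G:U wobbles count as paired in every pairing feature
(they are thermodynamically real in plant duplexes); `allow_wobble=False`
switches this off globally. The `me_motif` feature scores the fraction of
miRNA positions whose paired/unpaired state matches a fixed reference
profile — paired at 2–8 and 13–16, unpaired elsewhere — i.e. the canonical
seed plus 3′-supplementary pairing pattern; the profile is an explicit,
swappable stand-in (`me_reference_profile`), not a claim about any
particular published motif definition.

For labelled training examples the pairing vector comes from aligning the
miRNA against the recorded site, while site-anchored quantities (length, AU
content, accessibility, energy) use the full recorded interval; positives
and negatives pass through exactly the same code path, so no feature leaks
the label procedurally.

## Negative exemplars (`negatives`)

For each positive interaction, candidate negatives are all same-length
windows on the same mRNA (stride 1) that do not overlap the positive site
and whose CG-dinucleotide frequency (overlapping `CG` count / (len−1)) is
within `tol` of the positive site's. Among survivors, the window with the
lowest hybridisation energy against the miRNA becomes the negative — the
hardest plausible decoy. "Similar CG frequency" is operationalised as an
adaptive tolerance ladder: 0.05 absolute, widened to 0.10 and then 0.20 only
if no candidate survives, so yield stays high without silently abandoning
the constraint. Length matching is strict because site length is itself a
feature. Transcripts shorter than twice the site length cannot host a
disjoint window and produce no negative (logged, not an error), which is why
negative counts run slightly below positive counts.

## Homology control (`homology_split`)

Pairwise miRNA identity is an exact global (Needleman–Wunsch) alignment
with match +1, mismatch −1, linear gap −2; the value is the number of
identical aligned positions — maximised among score-optimal alignments, so
the number is well-defined — divided by the shorter length (the convention
of greedy-clustering tools). Gaps are costed at twice a mismatch
deliberately: with cheap gaps, unrelated 21-mers frequently reach 0.70
"identity" and the leakage threshold loses its meaning; with this scoring
random miRNA pairs centre near 0.46 and point-mutated homologs score
(L−k)/L.

`cluster_mirnas` is greedy incremental clustering (longest-first, join the
first cluster whose founder reaches the threshold) with exact DP identity in
place of k-mer prescreening — exactness is affordable at desk scale.
`make_split` builds the evaluation protocol: all test-species examples form
the test set (minus feature-vector duplicates, first kept, and minus any
whose miRNA matches an optional exclusion list at the threshold); every
other example trains unless its miRNA reaches ≥0.70 identity to any test
miRNA. "Greater than 70%" is implemented as exclusion at ≥0.70 — the
conservative reading. `DatasetSplit.max_cross_identity()` re-audits the
split exhaustively, and `run_experiment` aborts (exit code 4 from the CLI)
if the audit ever reaches the threshold.

## The scorer (`model`)

A scikit-learn random forest with exactly 13 trees (unlimited depth, √11
features per split, bootstrap on, fixed seed). Only the tree count is a
pinned design point; the rest are ordinary forest defaults. Confidence is
the fraction of trees voting "target" — multiples of 1/13 — rather than
sklearn's averaged leaf probabilities, which keeps the score's meaning
simple and the threshold grid finite. Determinism: identical data and seed
give bitwise-identical predictions; models round-trip through
`TrainedModel.save`/`load`.

The operating threshold is chosen by stratified k-fold cross-validation
(k=5 default): candidate thresholds are the distinct out-of-fold scores, and
the smallest one whose mean fold precision reaches the target (1.0 default)
is selected, reported with mean ± sd (population sd) of fold recall and
precision. Edge rules: a fold with no positive calls is vacuously precise
(1.0); folds without positive examples are excluded from the recall mean;
k = n degenerates to leave-one-out with singleton folds in index order; if
no threshold reaches the target, the maximum observed score is returned
flagged `target_reached=False`. When called with examples, a forest is
retrained per fold; it can also run on precomputed scores, in which case the
folds only partition the evaluation.

## Evaluation (`evaluation`)

PR curves enumerate every distinct score as a threshold, with tied scores
flipping together; the area is the step-wise sum Σ(R_k − R_{k−1})·P_k —
average precision without interpolation, which avoids the optimism of
trapezoidal integration in PR space. The positive-call rule is `score ≥ t`
(closed), so t=0 cleanly yields recall 1. All-equal scores collapse to a
single operating point at (recall 1, precision = prevalence). Score-density
output is a pair of per-class histograms over [0,1] normalised to unit mass,
for the separation plots; `overlap_coefficient` summarises class overlap.

## Synthetic corpora (`synthetic`)

The generator emulates the structure of curated plant interaction sets: each
transcript carries exactly one planted site (the mutated reverse complement
of a randomly assigned miRNA at recorded coordinates), miRNAs are 20–24 nt,
species labels are drawn from four plant tags, and 30% of miRNAs belong to
cross-species homolog pairs at 80–95% identity — the conservation pattern
that makes homology control necessary. Default conditions, fixed once:
transcripts 300–500 nt of i.i.d. uniform ACGU (an AU-rich mode exists to
stress the AU-content feature), a 5% per-base site mutation rate, and 10%
non-canonical sites. A non-canonical site draws its mutation count as
max(binomial, 2) and forces two mutations into the seed-pairing block;
curated plant databases put atypical interactions near 1%, but 10% keeps the
non-canonical behaviour statistically visible at desk-scale sample sizes.
The animal regime (for mismatched-training contrasts) keeps the seed-pairing
block perfectly complementary, mutates the remainder at 40%, and places the
site in the final third of the transcript. The study corpus referenced by
the test suite uses the generator defaults: 200 miRNAs × 2,000 transcripts, seed 42,
yielding 2,000 positives and just under 2,000 negatives.

What passing tests on these corpora do *not* show: real transcript
composition (codon structure, UTR base bias, repeats), real miRNA family
topology, degradome-grade site annotation noise, or realistic
target-to-background ratios in genome-scale scans. The synthetic results
validate the machinery and the qualitative regime ordering, not absolute
performance on any real species.

## Problem sizes and numerical choices

The suites run on a single CPU. Featurisation is dominated by the
accessibility partition function (~tens of ms per example at the 70-nt
context) and negative generation by per-window duplex energies (~0.2 ms
each); corpus sizes in the tests and the acceptance script (hundreds to a
few thousand examples, probe corpora of ~1,200 scan pairs) were chosen so
each stage completes in minutes while keeping the statistical assertions
(recovery ≥90%, holdout accuracy ≥0.95, regime ordering strict) well away
from small-sample noise. Floating-point determinism is maintained
throughout: fixed seeds for every RNG, deterministic tie-breaks in all DPs,
and stable sort keys for report ordering.

## Known limitations

- The scanner's default `min_score` bounds recoverable site divergence
  (~3 mismatches for a 22-mer); highly divergent genuine sites need a lower
  threshold, at the cost of more candidates per transcript.
- Hybridisation energy ignores intramolecular competition beyond the
  separate accessibility feature; a coupled opening-cost model (RNAup-style)
  would be more faithful and more expensive.
- The m/e-motif reference profile is a fixed stand-in; swap it via
  `me_motif(profile=...)` if a calibrated profile is available.
- Identity is exact DP, quadratic in the number of miRNAs for the split
  audit — fine for thousands of miRNAs, not for millions.
- Thresholds selected by CV on synthetic corpora do not transfer to real
  data; rerun `select_threshold_cv` on the interactions of the deployment
  species.
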