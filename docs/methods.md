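# Methods

## Feature model

Drugs are described exclusively by their target gene sets. The gene
universe G is the sorted union of target sets over the training drug
roster; sorting makes feature positions independent of input file order.
A drug is the binary indicator vector over G, a pair the elementwise sum of
the two drug vectors, so entries lie in {0, 1, 2} and a 2 marks a shared
target. Target genes outside G (e.g. genes seen only in test-time drugs)
are discarded, which keeps train and test feature descriptors identical;
the universe is rebuilt per cross-validation fold from training-fold drugs
only, so no feature information leaks from held-out pairs. All genes are
kept without selection or weighting: target profiles are extremely sparse,
and feature subsetting would leave many pairs as null vectors.

Pair vectors are exchanged as sparse (position, value) entries and
assembled into a CSR matrix; dense vectors are materialized only on demand.

## Classifier

The base learner minimizes ½ωᵀω + C Σ log(1+exp(−yᵢωᵀxᵢ)) with labels in
{−1, +1}. The solver is L-BFGS on the primal (scikit-learn's
`LogisticRegression`, whose l2 objective is exactly this form); the dual
formulation of the same problem is background, not an implementation
requirement. The intercept is fitted but unpenalized by default and can be
disabled. Defaults: C = 1, tolerance 1e−8, max 5000 iterations — tight
enough that retrained weights are reproducible to floating-point noise and
the objective matches an independent BFGS minimization of the same loss to
better than 1e−4 relative (verified in the test suite). C is tuned, when
requested, on {2^i : −16 ≤ i ≤ 16} by mean k-fold ROC-AUC with ties broken
toward the smaller C (the more regularized model). Trained models are
persisted as plain text with a SHA-256 fingerprint of the ordered gene
list; scoring refuses feature matrices built on a different universe.

## Metrics and evaluation protocol

All threshold metrics derive from a 2×2 confusion matrix with class order
(positive, negative) and M[i][j] = count of class i predicted as class j.
Per-class precision, sensitivity and MCC use the intermediates p_l, q_l,
r_l, s_l (diagonal, complementary block, column and row leakage); the
overall MCC uses the pooled intermediates, which for two classes reduces
algebraically to 2·Acc − 1. F1 is the harmonic mean of positive-class
precision and sensitivity. Zero denominators yield an NA marker (NaN,
rendered "NA" in reports), never a silent zero — an undefined precision
must not inflate a summary. ROC-AUC is the Mann–Whitney probability
(ties = ½), computed on decision-function scores.

Cross validation: negatives are sampled **once** before folding, uniformly
over unordered non-self pairs of the drug roster excluding known positives
(and optionally an independent test set), with the same cardinality as the
positives. Folds are stratified to avoid degenerate single-class folds.
Independent-test recall verifies disjointness from the training pairs and
reports the fraction of a single-class external set recovered at the
configured threshold.

## Path statistics

"All paths" between two genes means all **simple** paths (no repeated
node): unrestricted walks are infinite in cyclic graphs. Enumeration is
depth-first with breadth-first distance pruning toward the target, bounded
by a length cap (default 8 edges, matching the observed range of longest
path lengths between target sets in curated PPI data) and a per-gene-pair
count ceiling (default 10^6) that sets an explicit `truncated` flag instead
of returning silently wrong counts. The true longest simple path is
NP-hard; L is therefore the longest *within the cap*, and all three
statistics respect the cap consistently. A shared gene (g, g) counts as one
path of length 0, which makes Avg, S and L well-defined for overlapping
target sets and gives the identities S = 0 ⇔ shared target ⇔ Jaccard > 0.
Avg divides the total path count by |G_d1|·|G_d2| cross gene pairs.

Cohort-level class comparisons (and the acceptance script) use plain BFS
shortest distances rather than full enumeration: the per-class shortest
path and overlap contrasts need no path counts, and full enumeration at cap
8 on a 400-node scale-free graph is combinatorially explosive. Full
enumeration remains available per pair and is exercised at toy scale, where
it is verified against exhaustive search.

## Pathway overlap

A drug maps to the union of gene sets containing any of its targets; a
pair's common sets are the intersection of the two unions, each with the
supporting genes of both drugs recorded. The same machinery serves
signaling pathways and GO biological-process collections (GMT input, kind
tag "pathway"/"process"). No enrichment statistics are computed — the
overlap counts themselves are the readout. An optional maximum set size can
exclude giant terms; it is off by default.

## Synthetic data generator

The generator emulates the structure of curated DDI corpora at desk scale;
its defaults are the study conditions used throughout the tests: 300 drugs,
400 genes, 1–8 targets per drug, a preferential-attachment PPI graph
(3 edges per node; switchable to Erdős–Rényi for null experiments), 60
pathway and 80 process gene sets grown with preference for PPI-adjacent
genes (so pathway overlap correlates with network proximity), and 2000
positive + 2000 negative pairs.

Positive pairs are planted to share at least one target gene with
probability 0.6 (`share_prob`) or to have targets within PPI distance ≤ 2
with probability 0.2 (`proximity_prob`); negatives are sampled uniformly
from the remaining pair space. Positive-pair *endpoints* are drawn with
Zipf-weighted per-drug propensities (`hub_exponent`, default 1.0) rather
than uniformly. This reflects the strong hub structure of real DDI networks
(a minority of drugs — e.g. CYP450 substrates — account for most known
interactions) and is what makes the planted signal visible to the linear
model: the score of a pair is additive in the two drug vectors, so purely
pairwise overlap with uniform endpoints is invisible to it by construction.
Exponent 0 recovers uniform sampling for null tests. All draws flow from
one seeded generator; a fixed seed reproduces the bundle byte-for-byte.

What passing tests on this generator do **not** show: performance at the
scale of real corpora (6066 drugs, 915,413 interactions), robustness to
curation noise and incomplete PPI coverage, or calibration of predicted
probabilities against clinical ground truth. The generator plants exactly
the mechanisms the statistics measure, so the tests demonstrate correct
recovery of a known signal, not discovery in real data.

## Numerical and degenerate-input conventions

* Unordered pairs are canonicalized lexicographically; self-pairs and
  conflicting duplicate labels are rejected at ingestion.
* Gene symbols are uppercased at every boundary (sources mix casings).
* Drugs with zero valid target genes are rejected at load; a drug whose
  targets all fall outside the universe yields an all-zero vector plus a
  warning.
* Genes absent from the PPI network are isolated nodes (zero paths,
  warning), not errors.
* Unreachable path lengths are None internally and "unreachable" in files;
  histograms carry them as a separate bucket.
* Negative sampling is rejection sampling; the pair space is checked first
  so exhaustion raises instead of looping.
* The classification threshold is boundary-inclusive (p ≥ t → positive).

## Problem sizes

The test suite runs module tests on toy fixtures and a 60-drug bundle, and
the end-to-end checks on the 300-drug default bundle (three CV sweeps plus
a shuffled-label control, ~20 model fits); the whole suite completes in
well under a minute, and `scripts/acceptance.py` in a few seconds. These
sizes were chosen so the planted-signal margins are comfortably
significant (the 5-fold null AUC standard deviation at 800-pair test folds
is ≈0.02) while keeping iteration fast.

## Known limitations

* The linear pair model cannot represent purely pairwise effects (it scores
  a pair as the sum of two per-drug scores); it succeeds on data whose
  interaction propensity concentrates on drugs and genes, as real corpora
  and the generator both exhibit.
* Longest-path values are cap-relative; raising the cap can only increase
  them.
* External identifier mapping (between drug databases) is assumed done;
  inputs must share one identifier namespace.
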