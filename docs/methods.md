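# Methods

This note documents the models, procedures and design choices behind
`subport`, the assumptions they make, and what the synthetic-world tests
do and do not demonstrate.

## Problem setting

Experimental substrate annotations exist for a small minority of transport
proteins, and databases record only positives: a transporter's known
substrates, never its confirmed non-substrates. The pipeline therefore
(1) curates positive transporter–substrate pairs from annotation sources,
(2) *constructs* a negative class by constrained random sampling, and
(3) trains discriminative models on concatenated protein/molecule feature
vectors, evaluating under explicit homology control so that reported
performance is not an artifact of near-duplicate sequences spanning the
train/test boundary.

## Curation

Positives come from two parsers. The GAF parser keeps records whose GO
term is covered by a user-supplied term→ChEBI map and whose evidence code
is experimental; the default code set is {EXP, IDA, IPI, IMP, IGI, IEP,
HTP, HDA, HMP, HGI, HEP} — the GO experimental and high-throughput
categories. The UniProt parser resolves RHEA reaction IDs to substrate
ChEBI accessions through a supplied map. Merging deduplicates on the
(transporter, molecule) key; when a pair occurs in both sources the
UniProt record wins by default (those entries are restricted to top-score
manual curation) — the choice is configurable because nothing in the data
dictates it. Quality filters drop pairs whose molecule lacks a structure
string, whose substrate is in the exclusion set (by default the proton,
CHEBI:15378/CHEBI:24636 — proton flux in sym-/antiport rarely marks the
primary cargo), or whose protein is shorter than 30 residues (fragments).
Filtering is idempotent. A TCDB reader is deliberately a stub that raises:
TCDB substrate assignments are largely not experimentally validated, and
excluding the source is a curation decision, not an omission.

Thermal-shift screens are ingested by an explicit rule: a compound is a
candidate substrate when its mean apparent-melting-temperature shift is at
least `delta_tm_threshold` (default 1 °C, inclusive).

## Sequence identity and clustering

Percent identity is computed from an optimal global (Needleman–Wunsch)
alignment with BLOSUM62, gap open 10, gap extend 0.5, as
100 × identical columns / alignment length (gap columns counted). The
cited alignment tool's parameters are conventions, not measurements; they
are stored in `AlignmentScoring` and logged. Identity between unrelated
sequences is not unique — co-optimal alignments can differ by a column or
two — so the test-suite oracle (an independent aligner) checks that our
value falls within the identity span of all co-optimal alignments rather
than asserting a single number.

Clustering is greedy and longest-first: a sequence joins the first cluster
whose representative it matches at ≥ threshold (default 60 %), else founds
a new cluster. This guarantees representatives are pairwise below the
threshold and members are within it of their representative; it does *not*
bound all cross-cluster member pairs, which is why the fold-construction
tests verify the cross-fold bound exhaustively at fixture scale. The 60 %
threshold is applied to percent *identity* throughout, although the
literature sometimes says "similarity" for the same quantity.

## Negative sampling

For each positive pair, a quota drawn uniformly from {1..4} of negative
molecules is sampled for the same transporter from the vocabulary of
molecules observed among the positives (sampling outside the observed
substrate set would produce negatives that are trivially recognizable and
biologically unlikely to be encountered). Candidates must:

1. not be a substrate of the transporter itself or of any transporter
   with identity strictly greater than 60 % (false-negative control;
   strict inequality, so exactly-60 % homologs do not exclude);
2. have Tanimoto similarity to the pair's true substrate within
   [lower, 0.95], where lower starts at 0.75 and is relaxed in 0.2 steps —
   0.75 → 0.55 → 0.35 → 0.15 → 0 — until candidates exist (the floor at 0
   guarantees termination);
3. remain under a frequency cap of 3× their positive occurrence count, so
   the negative set mirrors the substrate frequency distribution rather
   than concentrating on a few decoys.

Positives are processed in a seeded shuffled order so early pairs do not
monopolize capped molecules; shortfalls are logged, never fatal; output is
byte-reproducible for a fixed seed. The uniform quota has mean 2.5
negatives per positive. A `quota_weights` knob reweights the draw for
users who want a different regime (e.g. an achieved mean of 3); the
uniform default is the honest reading of "between 1 and 4" absent any
stated distribution. Similarity for sampling uses the same radius-3 /
1024-bit ECFPs used as model features (one fingerprint family keeps the
pipeline self-consistent); the degenerate all-zero-fingerprint case is
defined as similarity 1 for structure-identical records and 0 otherwise,
since the Tanimoto denominator vanishes there.

## Splitting and leakage control

The train/test split unit is the distinct sequence: identical sequences
are co-assigned, so no test protein occurs verbatim in training.
Near-duplicates (< 100 % identity) may span the boundary — deliberately:
the identity-binned evaluation (bins [0,40), [40,50), …, [90,100]) is the
instrument that measures how performance depends on that relatedness, and
collapsing it in the split would remove the thing being studied. CV folds
are built from identity clusters kept atomic, balanced greedily
largest-cluster-first into the smallest fold by transporter count (pair
count balancing is a configurable alternative). Test pairs are annotated
with max identity to training and with the substrate's occurrence count
among positive training pairs (bins 0, 1–10, 11–100, >100).

## Features and models

A pair's feature vector is the concatenation of a protein embedding and a
molecule representation. Backends are pluggable: full deployments use a
protein language model (1280-d mean-pooled residue states) and a SMILES
language model (767-d mean-pooled token states). The bundled mocks are
first-class deterministic backends: the protein mock projects hashed
3-mer count vectors through a seeded Gaussian matrix and L2-normalizes
(64-d default) — sequences sharing most k-mers land nearby, which gives
the locality the recovery tests rely on; the molecule mock does the same
with character 3-grams of the canonical SMILES. Molecules are always
canonicalized (RDKit) before fingerprinting or embedding, so atom order
and input format (SMILES vs InChI) cannot leak into features; whether a
learned SMILES model should see raw or canonical strings is ambiguous in
the literature, and this package canonicalizes and records that choice.

Classifiers are XGBoost tree ensembles. Hyperparameters — learning rate
(log-uniform [0.01, 0.31]), max depth ({4..13}), L2/L1 regularization
(log-uniform [1e-3, 1e2]), max delta step ({0..5}), min child weight
([0.1, 15]), boosting rounds ({50..400}), and a negative-class weight in
(0.1, 1] — are chosen by seeded random search over the identity-
constrained folds, maximizing mean MCC (accuracy for the class task), ties
to the earlier trial. The search ranges are package choices; no reference
values exist for them. A eukaryote-focused variant adds a prokaryote
down-weight in (0.1, 1] and scores validation on eukaryotic pairs only
(`selection_masks`). Early stopping is not used; the round count is a
tuned hyperparameter. Binary decisions use the fixed threshold
score > 0.5 (0.5 itself is negative); scores between 0.4 and 0.6 are
reported as low-confidence by `confidence_bins`. MCC with a vanishing
denominator is defined as 0, the standard convention. Models serialize to
the booster's native JSON plus a sidecar (recipe, hyperparameters) and
reload with bit-identical predictions.

## Substrate classes

The seven-class scheme (cations, anions, sugars, amino acids/
oligopeptides, proteins/mRNA, electrons, other) is assigned per molecule
in a fixed order: manual override table; breadth-first ChEBI ancestor
search (depth cap 30, cycle detection) against packaged per-class anchor
term sets, nearest hit winning with a fixed priority for same-depth ties;
the sugar naming rule (name ends in "-ose" and formula contains only C, H,
O); and "other" only when both name and formula are known. The packaged
anchor table is a best-effort stand-in for a manually curated assignment
and is deliberately editable; the override table is the mechanism for
manual curation. A transporter enters the class dataset only if its
positive substrates map to exactly one class. Class imbalance is handled
by inverse-frequency weights normalized to mean 1.

## Evaluation

MCC, accuracy, precision and recall come from the thresholded confusion
matrix; ROC-AUC is the normalized Mann–Whitney U with midrank tie
correction. Degenerate strata (single class, no predicted positives)
report 0 with a warning rather than raising, so stratified reports never
abort on a thin bin. The homology baseline predicts, for each test
protein, the substrate union of its k most identical training proteins
(ties by accession); scoring is set-valued — TP = predicted∩true,
FP = predicted\true, FN = true\predicted, aggregated as
precision ΣTP/(ΣTP+ΣFP), recall ΣTP/(ΣTP+ΣFN) and accuracy
ΣTP/(ΣTP+ΣFP+ΣFN). This accuracy has no true-negative term; it is one
consistent reading of a correct/incorrect scheme and is documented as
such. McNemar's test uses the exact two-sided binomial on discordant
pairs below 25, else chi-square with continuity correction. The screening
projection is the closed form E[FP] = round(fpr·(n−n_true)),
E[TP] = tpr·n_true.

## Synthetic worlds

The generator emulates the *statistical* structure the pipeline assumes,
not transporter biochemistry. Protein families: one random ancestor per
family, members mutated independently per residue (default rate 0.05,
length 150) — member–member identity therefore concentrates at
(1−r)² + r²/19 ≈ 90.3 % for r = 0.05, while cross-family identity sits at
the random-sequence baseline (< 40 %). Molecule groups are drawn from a
packaged pool of 74 real SMILES in five chemically coherent sub-pools
(sugars, amino acids, nucleosides, organic acids, ions); within-group mean
Tanimoto exceeds between-group mean over the library as a whole, though
not inside the monatomic-ion group, whose members share no fingerprint
bits. Each family is assigned a substrate group and all members are
positive for the same drawn substrates; optional label noise swaps a
fraction of molecules outside the truth set. Family metadata (domain,
location, TC class) is assigned round-robin purely to exercise stratified
reporting. Default world: 10 families × 10 members, 5 groups × 8
molecules, 5 substrates per family, no noise — 500 positives, small
enough that the full pipeline (including the all-pairs identity matrix
and model training) runs in well under a minute on one CPU, which is the
problem size the test suite and examples use.

What passing tests show: the pipeline recovers a planted
family×molecule-group interaction rule (held-out ROC-AUC ≥ 0.9,
MCC ≥ 0.6) and produces chance-level output when training labels are
shuffled. What they do not show: performance on real transporters, where
family structure is deeper, substrate promiscuity is real, annotations are
noisy, and learned embeddings replace the mocks. The high held-out
numbers on the default world partly reflect close train/test relatives —
the same effect the identity-binned evaluation exists to expose on real
data.

## Numerical and degenerate-input choices

- Tanimoto of two all-zero vectors is 1.0 at the bit-vector level (the
  vectors are indistinguishable); the similarity-matrix layer resolves the
  case by structure identity when canonical SMILES are available.
- Identity of identical sequences short-circuits to 100 without aligning.
- Clustering ties (equal lengths) break lexicographically by accession;
  fold ties break toward the lowest fold index after a seeded shuffle —
  all orderings deterministic under a fixed seed.
- One-hot encoding of an unseen substrate raises a structured error: the
  baseline is undefined outside the training vocabulary by construction.
- All random draws flow through `numpy.random.Generator` seeded from
  explicit config fields; reruns are byte-identical.

## Known limitations

- The greedy clustering bounds member–representative identity, not all
  cross-cluster pairs; exhaustive verification is only feasible at fixture
  scale.
- The packaged class-anchor table is minimal; real ChEBI deployments
  should extend it or rely on overrides.
- The quota distribution for negative sampling is uniform by default;
  regimes with a different achieved negative:positive ratio require
  `quota_weights`.
- The mock embedders preserve locality but carry no learned biochemistry;
  absolute metric values on synthetic worlds do not transfer to real data.
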