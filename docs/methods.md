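# Methods

## Model

The package treats partner prediction as binary classification of protein
pairs. The only input per protein is its amino-acid sequence; the claim the
model embodies is that sequence composition at the level of local
physicochemical patterns carries enough signal to rank plausible physical
partners.

**Featurization.** The 20 standard residues are mapped to 7 classes grouped
by dipole moment and side-chain volume: {A,G,V}, {I,L,F,P}, {Y,M,T,S},
{H,N,Q,W}, {R,K}, {D,E}, and {C} alone (cysteine's disulfide chemistry sets
it apart). A sequence of length L yields L−2 overlapping residue triples;
each is counted as one of the 7³ = 343 class triads. Counts f are min–max
normalized, d = (f − min f)/max f, which removes the linear dependence on
sequence length while preserving the relative triad spectrum. For any
sequence shorter than ~345 residues some triad has zero count, so min f = 0
and the normalized vector spans exactly [0, 1]. The class table ships as
`src/spps/data/residue_classes.tsv` and is configurable; a trained model
records a fingerprint of the table (plus ambiguity policy) and refuses to
predict under a different one.

Ambiguity codes (B, J, O, U, X, Z) carry no class. The default "skip" policy
drops every window touching one (so the counted-window total can fall below
L−2); a "strict" policy rejects such sequences. Skipping was chosen over
inventing class assignments because it degrades gracefully on real-world
FASTA without biasing the spectrum.

**Pair composition.** A pair is the ordered concatenation [v_A ‖ v_B]
(686 dims). The descriptor itself is order-dependent; order invariance is
restored at prediction time by averaging the calibrated probabilities of
both orderings. This is the simplest contract that keeps the feature space
expressive (an interaction between *different* motif contents on the two
sides is representable) while making the reported score symmetric, as a
physical interaction must be.

**Classifier.** A support-vector machine with RBF kernel on the (already
[0,1]-scaled) pair vectors. By default the penalty C is chosen from {1, 10}
by inner stratified 3-fold accuracy on the training split (ties toward the
smaller C); gamma uses the variance-scaled heuristic, which behaves well on
these sparse bounded features. The grid is deliberately small: the decision
surface needed for triad features is not hyperparameter-sensitive in our
benchmarks, and a large grid would dominate cross-validation cost. Tuning
can be disabled (`SVMParams(tune=False)`), in which case the first grid
entries are used.

**Probability calibration.** Decision values f(x) are mapped to posterior
probabilities with the two-parameter sigmoid P(interact | f) =
1/(1 + exp(A·f + B)). (A, B) minimize the negative log-likelihood of the
calibration set under the regularized targets t₊ = (N₊+1)/(N₊+2),
t₋ = 1/(N₋+2), which bound the fitted probabilities away from 0/1 at finite
sample size. The minimizer is a damped Newton iteration on the
numerically robust form of the objective (no exponential of a large
argument is ever taken), with backtracking line search, a 1e−12 Hessian
ridge for degenerate (near-constant) decision values, gradient tolerance
1e−10 and at most 100 iterations; a line-search stall at gradient norms
below 1e−6·n is treated as convergence. Calibration data are the
*out-of-sample* decision values from an internal stratified 3-fold split of
the training set — calibrating on the training fit itself yields
over-confident sigmoids because SVM training values cluster at ±1. With the
positive class on the larger decision values the fitted A is negative; a
positive A is logged as a warning since it signals anti-learning
(e.g. shuffled labels). Degenerate case: if all decision values are equal,
the fitted sigmoid reduces to the constant mean target (the class prior
under regularization).

## Search semantics

- **Single Query** scores the query against every database protein
  (symmetrized), keeps probabilities strictly above 0.5, sorts descending
  and breaks ties by accession, so output is independent of storage order.
  A database record with the query's own id is excluded.
- **Direct interaction** is the symmetrized probability of one pair;
  "interact" iff > 0.5.
- **Indirect interaction** enumerates chains A–C–B and A–C–D–B over
  database intermediates (C ≠ D, neither equal to an excluded endpoint id),
  requiring every edge > 0.5. The path score is the product of edge
  probabilities — the natural chain score if edges are treated as
  independent events — and paths sort by score, then length, then node
  order. The product rule and the endpoint-deduplication rule are package
  conventions; the score function is a plain dataclass field and easy to
  swap. Optionally, known-PPI edges between database proteins count as
  probability 1.0 (`use_known_ppi=True`); by default only predicted
  probabilities are used, keeping the two evidence types separate.
- The 50% threshold is **strict** everywhere: a probability of exactly 0.5
  is a non-call, not a positive.

## Partner network

The network around a query merges the predicted query–hit edges (weight =
probability) with known interactions among the included proteins
(weight 1.0, a convention that makes weights comparable on one scale).
Node set = query ∪ hits ∪ `depth` rings of known partners (default one
ring; 0–2 supported). An edge both predicted and known is stored once with
provenance `known+predicted` and the predicted weight retained, so the
prediction remains visible. Exports (edge-list TSV, GraphML, node table)
are sorted lexicographically — byte-identical across runs.

## Evaluation

5-fold stratified cross-validation over pairs, fold assignment seeded.
Each fold's model is trained from scratch — including hyperparameter
selection and a fresh Platt calibration — on the other folds; held-out
pairs are classified at the 0.5 probability threshold. Reported are
per-fold SE/SP/PRE/ACC, their unweighted mean (headline), and the pooled
metrics from summed confusion counts (identical to per-fold summation by
construction). Any ratio with a zero denominator is reported as missing
(NaN), never as 0, and fold means skip missing folds.

Pair-level splitting is the default, matching common practice for this
family of methods; it is optimistic when both proteins of a test pair were
seen in training pairs. A `protein_disjoint` mode partitions *proteins*
into k groups and evaluates fold i only on pairs entirely inside group i,
eliminating that leakage at the cost of evaluating fewer pairs (cross-group
pairs are trained on but never tested). On the synthetic benchmark the
protein-disjoint accuracy is at or below the pair-split accuracy, as
expected.

## Synthetic benchmark

The generator emulates a species database with a learnable interaction
rule. Sequences are i.i.d. uniform over the 20 residues (a natural-
composition mode exists for realism checks), lengths uniform on 80–160. A
random 60% of proteins carry a motif: alternately `CKCKCKCKC` (triads over
the cysteine and basic classes) or `DWDWDWDWD` (acidic and amide/aromatic
classes), overwritten at a random interior position. A pair truly
interacts iff one member carries the A-motif and the other the B-motif —
complementary binding surfaces, crudely. These motifs were chosen because
their triad signatures are essentially absent from random background, so
the planted rule is expressible in the implemented feature space and
classifier tests measure real discrimination, not luck.

The default labeled set draws 400 true positives and 400 non-interacting
pairs (the 1:1 ratio is a configuration choice, not an estimate of
interactome sparsity), randomizes the within-pair order so neither motif
side is systematically first, then flips each label independently with
probability 0.05, emulating screening error. Annotations assign tissues
from a six-word vocabulary and mark a random 25% of true-positive pairs as
"known" interactions (symmetric by construction). All generators are pure
functions of the spec and its seed.

What passing on this benchmark does **not** show: performance on real
interactomes. Real PPIs involve heterogeneous binding modes, homology
between training and test proteins, hub-dominated degree distributions and
non-uniform residue composition, none of which the generator reproduces.
The benchmark validates the machinery (featurization, learning,
calibration, search logic), not biological accuracy.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| residue classes | 7 | dipole/volume grouping; 343-dim triad space |
| triad window | 3 | conjoint triads; larger k explodes dimensionality |
| SVM kernel | RBF | smooth nonlinear boundary over bounded features |
| C grid | {1, 10} | benchmark accuracy is flat across it |
| calibration folds | 3 | enough out-of-sample values without tripling cost |
| Platt tol / max iter | 1e−10 / 100 | Newton converges in < 20 iterations |
| CV folds | 5 | standard for this method family |
| benchmark | 200 proteins, 400+/400− pairs, noise 0.05 | desk-scale set on which 5-fold CV runs in seconds while leaving clear headroom between signal and chance |
| default training seed | 20120126 | arbitrary fixed constant recorded in model metadata |

## Known limitations

- The SVM kernel is a design choice, not a reproduction of any particular
  production system; with other kernels results will differ.
- Platt calibration assumes a sigmoidal relation between decision value and
  posterior; strongly multimodal decision distributions would need
  isotonic or binned calibration.
- Indirect-path search is O(n²) model evaluations over candidate
  intermediates; it is intended for focused candidate sets, not whole
  proteomes.
- The annotation store keeps whole free-text fields; the tissue filter is a
  case-insensitive substring match, not a tokenized or ontology-aware
  search.
- No redundancy reduction beyond duplicate-id rejection is applied to the
  sequence store.
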