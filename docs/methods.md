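# Methods

## Problem setting

`mutgraph` classifies patients as case or control from per-gene germline
mutation counts, borrowing structure from two sources: a supervised
text-retrieval weighting of the counts, and the physical protein–protein
interaction (PPI) network.  Both are combined in a single heterogeneous
graph on which a graph attention network (GAT) performs transductive node
classification, and an integrated-gradients explainer ranks genes by their
influence on case predictions.

## Feature model

Treat each patient as a document and each gene as a term.  With
`tf(p, g)` the number of mutation events of gene `g` in patient `p`:

* **Saturating term frequency.**  `bm25_tf(tf) = (k+1)·tf / (k+tf)` with
  smoothing constant `k > 0` (default 1.2, the conventional BM25 k1).  The
  transform is strictly increasing, fixes `bm25_tf(1) = 1`, and is bounded
  by `k+1`, so hypermutated genes cannot dominate a feature vector.
* **Relevance frequency.**  For gene `g` and class `c`,
  `rf_c(g) = log2(2 + a_c / max(1, b_c))` where `a_c` is the gene's support
  among class-`c` patients and `b_c` its support in the other class.
  Support is by default the number of patients with at least one mutation
  (the document-frequency analogue from the retrieval literature); an
  `events` mode sums counts instead.  `rf ≥ 1`, with equality exactly when
  the gene never occurs in the class.
* **Feature value.**  `x(p, g) = bm25_tf(tf(p, g)) · rf_{class(p)}(g)`.

Because `rf` is class-conditional, featurisation needs a class for every
patient.  In the standard transductive evaluation the recorded label is
used for all patients, matching the main-experiment protocol; this is
deliberately label-dependent featurisation, and the deployment protocol
below exists precisely because an incoming patient has no label.  The
ablation feature set (`nm`) is the label-free alternative: counts
normalised by the patient's total (all-zero rows stay zero).

## Heterogeneous graph

Nodes are patients `P` and proteins `Pr` (one protein per catalog gene —
the gene↔protein map must be a bijection; ambiguous mappings are rejected,
not resolved).  Patient nodes carry their feature vectors; protein nodes
carry one-hot identity vectors of dimension `|Pr|`.  Edges:

* `E_ppi`: undirected physical PPI edges, stored once per unordered pair;
  the model materialises both directions for message passing.
* `E_mut`: directed protein→patient edges.  Under the `max` strategy a
  patient connects to the proteins of its `k_edges` (default 300) highest
  strictly-positive feature values, ties broken toward the lower gene
  index; zero features never produce an edge, so sparsely mutated patients
  get fewer edges rather than padded ones.  The `random` strategy draws
  `k_edges` proteins uniformly without replacement per patient — the
  information-free control arm.

There are no patient→protein or patient→patient edges: patients are
classified purely through incoming protein messages, and proteins are
updated by the PPI network alone.

## Classifier

Two multi-head attention layers.  Per edge type and head: source nodes
are linearly projected; the attention logit is
`LeakyReLU(a_src·W_src x_src + a_dst·W_dst x_dst)` (slope 0.2);
coefficients are softmax-normalised over each target's incoming edges of
that type.  Layer 1 concatenates heads and applies an ELU; layer 2
averages heads; a linear head yields two logits, and class probabilities
are their softmax.  The patient's own features enter the attention logits
and the input projection only — there is no self-loop on the
protein→patient edge type, which is what makes the random-edge control
collapse informative.  Per-node-type input projections reconcile the
differing input dimensions (`|genes|` for patients, `|Pr|` for proteins).

Training: full-batch Adam (learning rate 0.001), cross-entropy on
train-mask patients, early stopping on validation accuracy with patience
30 (defaults: at most 300 epochs), parameters restored from the
best-validation epoch.  When several epochs tie on validation accuracy the
one with the lower training loss is kept; only a strict validation
improvement resets the patience clock.  The reference width is 128 hidden
units per head with 8 heads; the experiment harnesses in this package run
a compact configuration (16 units, 4 heads, patience 50) selected on
full-model validation accuracy, so that repeated cross-validation
completes quickly on a single CPU.  The batched homogeneous baseline runs
at 8 units x 2 heads with a 40-epoch cap for the same reason; on the
planted cohorts it plateaus within the first dozen epochs.  The problem
sizes used by each experiment are recorded in its report descriptor, and
trained models serialize to an ``.npz`` checkpoint with a CSV training
log.

The whole stack (model, Adam, and the attention message passing) runs on
an in-package reverse-mode autodiff engine over float64 numpy arrays
(`mutgraph/_autodiff.py`).  Besides keeping the dependency surface small,
this makes every stage bit-reproducible under a fixed seed and
single-threaded execution, and gives the explainer exact gradients with
respect to arbitrary leaves such as edge masks.

## Explainer

Every protein→patient edge gets a presence mask scaled from 0 (absent) to
1 (present) that multiplies the edge's messages in both layers.  The
attribution of an edge is the integrated gradient of its target patient's
case logit with respect to the mask, along the straight path from the
zero baseline, approximated with a midpoint Riemann sum (default 50
steps; the rule is exact for mask-linear models at any step count).
Because an edge can only influence its own target patient, attributions
of edges into control patients vanish and case-patient attributions are
computed jointly in one backward pass per step.

Per-gene scores are the mean attribution over all case-patient edges
sourced at that gene's protein (mean rather than sum, so genes mutated in
many patients are not favoured merely by edge count; a sum option
exists).  The report is the top-k (default 20) genes with scores min-max
normalised inside the list; constant-score lists normalise to zero with a
warning, and a singleton list reports 1.0.

## Evaluation

Metric panel: accuracy, sensitivity, specificity, MCC, ROC AUC (rank
statistic, ties counted half), AUPRC as average precision (step
integration, not trapezoidal), and F1.  The confusion matrix thresholds
the case probability at 0.5, with exactly 0.5 counted as control —
consistent with the deployment tie rule.

Cross-validation: stratified k-fold (reference: 3 repeats × 10 folds),
each fold's validation set a stratified 1/9 hold-out of the non-test
patients, preserving the 10-fold test geometry.  Reported means and
standard deviations are over all repeat×fold runs.  Features are computed
once from recorded labels (transductive protocol); the graph is assembled
per fold with a fold-derived seed for the random-edge arm.

Baselines share the identical feature matrix: unregularised logistic
regression; a 4-weight-layer MLP with a geometric width taper (floor 16)
trained under the same optimizer and early-stopping contract; and a
homogeneous graph classifier (the common alternative design) with one
PPI-topology graph per patient, the patient's per-gene values as node
scalars, the same attention layers, mean pooling over nodes, and a
two-logit head.  Since all patient graphs share topology they are
processed as one batched tensor program.

## Deployment (dual-assumption) protocol

For an unlabeled patient: featurise the cohort twice, once assuming the
patient is a case and once a control (the rf table is recomputed from the
training labels plus the single assumed label); build the two graphs
(training patients plus the one test patient); train and predict on each;
sum the two probability pairs component-wise and decide by the larger sum,
ties resolving to control.  The two runs use distinct derived seeds.  The
patient's true label is never read before the decision, and each
patient's runs are independent of any other test patient.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
real exomes: a balanced cohort (defaults 100 cases + 100 controls), 500
genes, counts Poisson with background rate 0.2 events/gene/patient, and
25 uniformly placed planted genes whose rate in cases is multiplied by
5.0.  The PPI network grows by preferential attachment (2 edges per new
node), giving a connected scale-free graph; planting is independent of
topology so feature- and graph-borne signal can be disentangled (a
negative-binomial dispersion option models the overdispersion of real
counts).  Emitted fixture files round-trip through the readers, including
minimal sites-only VCFs.

What passing tests on these cohorts show: the pipeline recovers a planted
class-conditional rate difference end to end — features, edge selection,
attention classifier, explainer ranking, and the deployment decision rule.
What they do not show: robustness to population structure, mutational
signatures, linked genes, annotation noise, or class imbalance, none of
which the generator models.

One property of the planted regime deserves a caveat.  The class contrast
of the synthetic rf tables is far stronger than is typical for real
cohorts, and with the transductive (label-dependent) featurisation even
the random-edge control can occasionally exceed chance: the target-side
attention term lets a patient's own features modulate the softmax
temperature over its incoming edges, which a two-layer model can learn to
read.  This pathway exists in any GAT with target-dependent attention; it
only becomes visible when the features alone are nearly class-separable.
The max-vs-random contrast therefore remains qualitative (max ≫ random)
rather than an exact collapse to 0.5 in every run.

## Numerical choices and degenerate inputs

* float64 throughout; softmax and log-softmax are max-shifted.
* Segment softmax over a target's incoming edges uses presorted
  `reduceat` reductions; nodes without incoming edges of a type receive a
  zero aggregate (plus bias) rather than NaN.
* Ties: top-gene selection by ascending gene index; top-k attribution by
  gene identifier; decision ties to control; equal-validation epochs to
  the lower training loss.
* Empty PPI edge sets, all-zero count rows, and patients with fewer than
  `k_edges` positive features are all valid inputs.
* MCC is defined as 0 when its denominator vanishes.

## Known limitations

* The homogeneous baseline's batched implementation assumes shared
  topology; per-patient topologies would need the (slower) disjoint-union
  path it deliberately avoids.
* Runtime scales linearly in `E_mut`; the random strategy with the
  default `k_edges=300` is the most expensive arm.
* The reference 128×8 width is impractical for repeated CV on one CPU;
  compact widths are used by the harnesses, and single-run experiments at
  the reference width remain feasible.
* VCF reading trusts the gene annotation key; no annotation is performed.
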