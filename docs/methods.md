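# Methods

## Model

`tmenet` trains a feed-forward classifier whose architecture is a declared
tumor-microenvironment (TME) hierarchy. Layers are genes, cellular
components (surface / secreted / intracellular-transcription-factor marker
groups), cell types, immune roles (immunostimulatory, immunosuppressive),
and a single output. Connectivity between the first four layers is given by
three binary mask matrices compiled from the hierarchy declaration: a gene
connects only to the component(s) that list it as a marker, a component
belongs to exactly one cell, a cell to exactly one role. The role layer is
densely connected to the output. A gene listed by several components or
cells is one node with several edges.

With hidden activation `a` (tanh by default) and sigmoid output, the
forward pass is the usual affine chain; the predicted probability is
clamped to `[1e-7, 1 − 1e-7]` before any logarithm. The loss is mean binary
cross-entropy in natural log, `L = −mean(y log ŷ + (1−y) log(1−ŷ))`, with
`y = 1` for responders. Training is plain full-batch gradient descent with
the masked update

    W ← W ⊙ M − η (∇L ⊙ M)

applied per layer (the dense role→output block carries an all-ones mask);
biases are updated unmasked. Gradients are computed dense by analytic
backpropagation and masked only at update time, so weights on undeclared
edges are exactly zero after initialization and after every step — the
test suite asserts this invariant inside the training loop and checks all
gradients against central finite differences at relative tolerance 1e-5.

### Parameters and defaults

| parameter | default | notes |
|---|---|---|
| activation | `tanh` | sign-preserving and bounded, keeping signed weights interpretable; `relu` and `identity` available |
| output head | 1 sigmoid node | a 2-node softmax head is available via `n_out=2` masks |
| learning rate η | 0.2 | see below |
| epochs | 400 | full batch |
| optimizer | plain gradient descent | matches the printed update rule; no momentum |
| biases | on, never masked | toggleable for exact parameter-count studies |
| initialization | U(−a, a), a = 1/√(active fan-in) | fan-in counted over mask-active edges only, so sparse and dense columns start at comparable scale |
| standardization | on | gene-wise z-scoring fitted on the training set, stored in the model state |
| probability clamp ε | 1e-7 | numeric safety before logs |

Two defaults deserve explanation:

**Input standardization.** log2-TPM values sit around 3–10, far from the
near-origin regime where tanh units have useful gradients; without
rescaling, first-layer pre-activations saturate immediately and training
stalls at the ln 2 plateau. The model therefore z-scores each gene using
training-set statistics; the fitted mean/sd vectors are part of the model
state (and its checkpoint), so saved models score new samples consistently.
Note that z-scoring compresses per-gene discriminability: a balanced
two-group shift of δ with noise σ becomes δ/√(σ² + δ²/4) after scaling,
which saturates near 2 as δ grows. Relative gene importance is therefore
best probed in regimes where planted per-gene effects are ≲2σ.

**Step size.** With a symmetric near-zero initialization every output
starts at 0.5 and the cross-entropy surface is nearly flat; for a network
this small (a few dozen to a few hundred parameters) a timid step can keep
plain gradient descent on that plateau for hundreds of epochs, and whether
a run escapes within the epoch budget becomes an initialization lottery.
η = 0.2 for 400 full-batch epochs escapes reliably at this scale while
remaining stable; both knobs are ordinary `TrainConfig` fields.

### Parameter counting

`count_parameters` counts one parameter per mask-active edge plus the dense
role→output block, with biases for all non-input nodes optional and the
number of output nodes explicit. Published totals for networks of this
family are sensitive to both conventions, so neither is hard-coded; for
reference, a hierarchy with 138 single-membership genes, 27 components and
9 cells yields exactly 218 parameters under the two-output,
biases-everywhere convention (138 + 27 + 9 + 4 edges + 40 biases).

## Evaluation protocol

Cohorts are split 70/30, stratified by label (small responder fractions
otherwise produce single-class test sets; stratification is toggleable).
Run *i* of a repeated study derives both its split seed and its
initialization seed from `base_seed + i`, so any two model variants
evaluated with the same base seed see identical partitions; comparisons
across variants then use a paired t-test on per-run AUCs (pairing is
auto-detected from the stored seed sequences, with Welch's t-test as the
unpaired fallback, and the degenerate all-equal case reported as t=0, p=1
rather than 0/0). AUC is the rank-based (Mann–Whitney) statistic with ties
counted ½; accuracy uses a fixed 0.5 threshold.

The benchmark roster pairs the masked network with eight scikit-learn
classifiers (KNN, random forest, decision tree, gradient boosting,
AdaBoost, Gaussian naive Bayes, QDA, SVM) at library-default
hyperparameters — recorded verbatim in the output metadata — plus two
dense neural controls of identical layer sizes: FULL (all-ones masks) and
DropNN (FULL with inverted dropout, p = 0.2, on the gene layer only,
applied after standardization). All models consume the identical
hierarchy-aligned gene matrix. SVM scores test samples with its decision
function (monotone-equivalent to a probability for AUC) and predicts hard
labels with `predict`.

## Weight interpretation

Influence is read from the distribution of each active edge's weight over
repeated runs. For odd activations the network function is invariant under
flipping any hidden node's inbound and outbound weights together, so a raw
weight's sign is an initialization coin-flip. Signed summaries therefore
canonicalize orientations per run: component and cell nodes are oriented so
the summed inbound weight from the already-oriented previous layer is
nonnegative (a node "points with" its markers), and role nodes are oriented
to push the predicted response probability up. Under this convention a
positive cell→role weight means the cell's measured marker program pushes
toward response. Absolute values — and hence all rankings — are unaffected;
for relu the flip is not exact and canonicalization is only a reporting
convention. Rankings use mean |w| (ties broken lexicographically); signed
means are reported alongside. When a gene connects to several of one cell's
components, its per-cell importance is the sum of those edges' mean |w|
(identical to the single edge weight in the common one-membership case).
No normalization is applied across layers; comparisons are within-layer.

## Ablation studies

`run_ablation` removes one cell type, its components, and every gene
exclusive to it (shared genes survive), realigns the cohort, and retrains
over the same split-seed sequence as an all-cells baseline, so run *i* of
every condition sees the identical partition. Reported per surviving cell:
the shift of its cell→role weight (mean over runs, ablated minus baseline)
with a two-sample Welch t-test over the per-run weight samples; and for
the model as a whole, paired comparisons of the AUC and accuracy
distributions. Cross tables arrange ablated cells of one role against
surviving cells of the opposite role. Raw p-values are reported
(Benjamini–Hochberg adjustment is left to the caller, e.g.
`statsmodels.stats.multitest`). The conventional study size is 100 runs
per condition; the test suite uses 20 for desk-scale runtimes.

## Synthetic cohorts

The generator emulates a labelled ICI cohort directly on the log2-TPM
scale: expression of marker gene *g* of cell *c* in sample *i* is
`Normal(μ0 + s_c · δ_c · y_i, σ)` with `s_c = +1` for immunostimulatory
and `−1` for immunosuppressive cells — responders up-express stimulatory
programs and down-express suppressive ones — plus label-independent decoy
genes, all floored at 0 (log2(TPM+1) is nonnegative). A gene claimed by
several cells receives the sum of their shifts. Defaults: n = 400 samples,
balanced classes, μ0 = 5, σ = 1 — a cohort size and marker-shift scale
representative of pooled published ICI expression studies. This is a
deliberate Gaussian-on-log-scale model, not a count-level simulation: the
network consumes log2-TPM, so count realism, batch structure, cohort
effects and deconvolution-grade mixtures are out of scope. Consequently,
passing the recovery suites shows that the estimator identifies planted,
mask-consistent signal at realistic noise — not that any particular
biology holds in real cohorts, where marker redundancy, confounding and
cohort heterogeneity are untested here.

## Numerical and degenerate-input choices

- TPM normalization rejects all-zero samples and negative entries;
  log2 uses pseudocount 1.
- Gene matching is exact string after whitespace trimming; alias
  resolution is curation and out of scope. Missing hierarchy genes are an
  error by default, or zero-imputed with a warning under
  `missing_policy="zero"`.
- A hierarchy must keep at least one cell per role; emptying a role during
  removal requires an explicit override (the role node then keeps zero
  inbound edges).
- Non-finite training loss aborts with the epoch named.
- All index orderings (cells by declaration, categories in the fixed
  surface/secreted/TF order, genes by first appearance) are deterministic,
  so masks, weight tables and artifacts reproduce bit-for-bit from a seed.

## Known limitations

- Plain gradient descent only; no early stopping, regularization, or
  hyperparameter search.
- The shipped default hierarchy's marker genes are illustrative, not
  curated; real analyses must supply their own hierarchy document.
- Interpretation canonicalization assumes odd activations; relu readouts
  are convention-dependent.
- Real published ICI cohorts are supported as inputs but not bundled or
  tested against.
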