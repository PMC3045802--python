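# Methods

## The problem and the model

`genevote` predicts two gene phenotypes genome-wide: **morbidity** (a gene
whose mutations cause a hereditary disease) and **druggability** (a gene
whose protein product can be modulated by small molecules with phenotypic
effect).  Both are framed as positive-unlabeled binary classification over
genes of an integrated interaction network: known morbid/druggable genes
are positives, and because no curated negative class exists, every other
network gene is a provisional negative.  Per-gene evidence comes from
three systems-level sources — network topology, tissue expression, and
subcellular localization — combined into 24 learning attributes.

### Integrated network

Three interaction layers are merged over one gene-identifier space:

* **ppi** — undirected protein physical interactions; edges are
  canonicalized (source ≤ target) at parse time so symmetric duplicates
  cannot double-count.
* **regulatory** — directed transcription-factor → target edges.
* **metabolic** — directed enzyme coupling derived from a stoichiometric
  model: g1 → g2 whenever a product of a reaction catalyzed by g1 is a
  reactant of a reaction catalyzed by g2.  Before derivation, *currency
  metabolites* are removed; the default is the fixed eight-species list
  (ADP, ATP, H+, H2O, NADP+, NADPH, orthophosphate, pyrophosphate), with a
  data-driven top-k-by-reaction-participation alternative
  (`select_currency_metabolites`, ties lexicographic).

Self-loops are excluded in every layer; a gene pair may carry one edge per
layer; genes present in only one layer are kept (features from absent
layers are 0).  Identifier normalization drops (and counts) records with
unmapped endpoints rather than guessing.  Metabolite compartment suffixes
are treated as distinct species unless the input table strips them — the
package does not invent compartment-merging semantics.

### The 24 learning attributes

Twelve network topological features per gene: per-layer degree
centralities (`ppi`, `metin`/`metout`, `regin`/`regout`, counting distinct
partners), clustering coefficient `c` (neighbor-pair link density on the
undirected projection of all layers), closeness `cent` (mean shortest-path
length to genes *reachable from* the gene on the combined graph — ppi
edges traversable both ways, the other layers direction-respecting; 0 when
nothing is reachable), unnormalized betweenness on the combined graph
(`inbet`) and per layer (`inbetppi`, `inbetmet`, `inbetreg`), and
`identicalness` — the number of genes (self included) sharing the gene's
other 11 feature values after rounding reals to 9 decimals.

Betweenness uses ordered source–target pairs whenever the graph under
consideration has any directed edge, and unordered pairs on a purely
undirected graph (the per-layer ppi scope).  Per-layer betweenness is
computed over all network genes, so every gene has all 12 features.
`metin` is metabolic in-degree, per the degree-centrality definition; an
alternative reading ("metabolites catalyzed by an enzyme") exists in the
literature the feature names come from, but the degree reading keeps the
five degree features mutually consistent.  `cent` is mean distance (not
its reciprocal); smaller values therefore mean *more* central, which is
irrelevant to tree learners but matters when reading thresholds in rules.

Two expression attributes from a gene × 32-tissue tpm matrix:
`numtissuesexp`, the number of tissues with tpm ≥ 5, and `avegexptec`, the
mean tpm over those qualifying tissues ((0, 0) when none qualify).
Averaging over threshold-qualifying tissues (rather than tpm > 0 tissues)
keeps the two attributes consistent; the threshold is a parameter.

Ten binary localization flags (Cytoplasm, Endoplasmic reticulum,
Mitochondrion, Nucleus, Extracellular space, Golgi apparatus, Plasma
membrane, Cellular component, Other localization, Unknown).  Annotation is
multi-hot — a gene may carry several compartments — except Unknown, which
is exclusive and marks genes with no localization annotation.  Terms
outside the eight named compartments route to "Other localization" via a
remap table (terms the table does not cover fall back there too).

### Datasets

Each task builds 10 balanced replicate datasets: all positives plus an
equal-size uniform sample (without replacement, independent across
replicates) of non-positive genes.  Replicate randomness derives from a
master seed as `default_rng([master_seed, replicate_index])`, so any
replicate is regenerable alone.  The null condition permutes class labels
uniformly within each dataset ("shuffled"); feature ablation removes one
of the 24 columns ("without-one-feature").

### Classifier

A voting meta-classifier over seven tree-family learners, each wrapped in
bootstrap aggregating (10 bags by default); the ensemble's positive-class
probability is the arithmetic mean of its members' probabilities.  The
roster (scikit-learn realizations, functional-class fidelity rather than
bit compatibility with any particular toolkit):

1. reduced-error-style pruned tree (entropy, cost-complexity pruned),
2. randomized tree (random splits, √p features),
3. random forest (10 trees),
4. C4.5-style tree with ≥ 32 instances per leaf,
5. best-first-expanded tree with ≥ 32 instances per terminal node,
6. logistic-model tree: a depth-5 tree with a logistic regression over
   one-hot leaf membership,
7. 25 rounds of boosted decision stumps (the alternating-decision-tree
   role).

Evaluation is stratified 10-fold cross-validation per dataset (a
`--no-stratify` switch reverts to plain random partitioning); per-fold
recall, precision (probability threshold 0.5 — the natural operating point
on balanced data) and rank-based AUC (Mann–Whitney with half credit for
ties) are averaged per dataset, then summarized as median [min, max] over
the 10 replicates.

### Wilcoxon signed-rank comparisons

Condition comparisons (normal vs shuffled, normal vs ablated, and per-gene
normal vs shuffled scores) use the exact Wilcoxon signed-rank test: zero
differences are discarded (reducing N), absolute differences are ranked
with mid-ranks on ties, W = min(positive-rank sum, negative-rank sum), and
significance is the critical-value rule W ≤ W_c at two-tailed p = 0.05.
W_c comes from exhaustive enumeration of the 2^N sign patterns (dynamic
programming over the rank-sum distribution) for N ≤ 25 — giving W_c = 8 at
N = 10 and W_c = 5 at N = 9 — and a continuity-corrected normal
approximation with tie correction above.  Published critical-value tables
occasionally print slightly different values at these N (e.g. 6 at N = 9);
the package follows the enumeration, which is reproducible from first
principles and is verified in the tests against direct 2^N enumeration.
For N < 6 no outcome reaches two-tailed 0.05, so W_c is undefined and
nothing is significant.

### Genome-wide scoring and rules

The 10 normal-condition and 10 shuffled-condition fitted models are
applied to the whole feature matrix (labels withheld).  A gene's
morbidity/druggability score is the median of its 10 normal
probabilities; the per-gene Wilcoxon test over the 10 paired
normal/shuffled scores flags genes scoring above their null.  A score
histogram summarizes, per 0.2-wide score bin, the percentage of known
positives falling in the bin.

Interpretable rules come from a separate single-tree learner authored in
the package (scikit-learn trees split by information gain, not gain
ratio): top-down induction choosing the binary split with the best gain
ratio (numeric attributes at midpoints between observed values, binary
flags as flag = 0/1), followed by error-based pruning — a subtree
collapses to a leaf when the leaf's pessimistic error (binomial upper
confidence limit, Clopper–Pearson form, confidence 0.25) does not exceed
the subtree's.  Defaults: min 2 instances per branch, confidence 0.25;
both exposed.  Each leaf carries "(n/e)" counts; root-to-leaf paths are
exported as rules.  The representative tree among the 10 replicates is
the one with the modal root feature and, within those, the highest
cross-validated AUC (ties: fewer leaves, then earlier replicate) — the
modal-root rule reflects that downstream interpretation hinges on the
root feature's identity.

## Synthetic studies

The generator produces data with the statistical shape the method
assumes, not a fit to any particular organism's network: a
preferential-attachment ppi layer (heavy-tailed degrees), a regulatory
layer from TF hubs with Poisson out-degrees, a metabolic layer realized
as reaction chains run through the same currency-removal derivation as
real input, independent multi-hot localization draws at roughly
proteome-like compartment frequencies, and log-normal tpm profiles with a
beta-distributed per-gene tissue breadth (bimodal: housekeeping-like vs
tissue-specific).

Labels are planted through a logistic model **on the extracted feature
columns** (standardized), with the intercept bisected so expected
prevalence hits the target.  Planting on post-extraction columns (rather
than latent variables) makes signal and rule recovery exactly testable;
the cost is that the generator cannot model confounding between latent
biology and measured features.  Default effect directions follow the
task-specific biology the method is meant to surface: the morbidity-like
spec loads on `regin`, `inbetmet` and Extracellular space; the
druggability-like spec on Plasma membrane, `inbetreg` and `metin`
(dominant coefficient 3, secondary 1, standardized scale).  Default
prevalences are 0.14 (morbidity-like, a realistic known-disease-gene rate)
and 0.05 (druggability-like) at a 2,000-gene desk scale.

What passing on synthetic data does and does not show: null calibration,
exactness of the statistics, oracle equivalence of the graph features and
recovery of planted effects are fully probed; the difficulty of *real*
morbidity prediction — noisy labels, unknown positives inside the
negative pool, annotation bias, network incompleteness — is not, so
synthetic AUCs say nothing about attainable real-data AUCs.

## Evaluation scales and numerical choices

The packaged study setups (`genevote.studies`) mirror the published
positive-class sizes: 1,412 positives per morbidity dataset (2,824 rows)
and 257 per druggability dataset (514 rows), 10 replicates, 10 folds.
Matrices are sized so the planted prevalence yields enough positives and
negatives: 3,400 genes at prevalence 0.45 (morbidity scale) and 900 genes
at prevalence 0.35 (druggability scale), using the first 1,412 (resp.
257) planted positives.

* Betweenness and closeness run on python-igraph's C core; brute-force
  path-enumeration oracles in the test suite pin the semantics on random
  small graphs.
* Identicalness compares vectors rounded to 9 decimals and counts the
  gene itself (minimum 1).
* AUC ties get half credit; single-class folds raise rather than
  returning a silent default (stratified folds prevent them).
* Precision is defined as 0 when nothing is predicted positive.
* Degenerate inputs: empty datasets, single-class label vectors, folds
  exceeding rows, unknown feature columns, and k exceeding the metabolite
  pool all raise immediately.
* All randomness flows from explicit integer seeds; every generator and
  fit is bit-reproducible under a fixed master seed.

## Known limitations

* The negative class is unlabeled, not verified; no reliable-negative
  mining is attempted.
* The ensemble roster is a functional reconstruction; exact member
  hyperparameters of the original toolkit implementations are not
  replicated, and bag count (10) is a package default.
* Error-based pruning uses the exact binomial (Clopper–Pearson) upper
  limit rather than C4.5's normal-approximation shortcut; pruned trees
  can differ marginally from classic C4.5 implementations at the same
  confidence.
* Closeness of a gene that reaches only part of the network averages over
  reachable genes only, which can rank poorly-connected genes as
  spuriously "central"; the tree learners are insensitive to this, but
  direct numeric comparisons across components are not meaningful.
* The 24-attribute set treats localization flags as independent binary
  columns; correlations induced by the GO DAG are not modeled.
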