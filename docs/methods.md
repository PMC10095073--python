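# Methods

## Model overview

`driverprog` treats prognosis prediction as a two-stage problem: first
summarize each tumor sample by how strongly each gene *drives* the sample's
dysregulation, then classify patients on those per-gene driver summaries.
The driver summary is a network-propagation score on a patient-specific
reweighting of a shared gene network, corrected by the patient's somatic
mutations and normalized to within-patient win rates. The premise is that
patients with different prognoses harbour different driver genes, so driver
scores separate prognosis groups better than raw expression alone.

## Network substrate

Input edge lists (TSV: source, target, optional per-edge directedness flag)
are merged into one directed network. Directed edges are stored **reversed**:
the propagation asks "which regulators can explain this gene's
dysregulation", so influence must flow from targets back to regulators.
Undirected (functional-interaction) edges contribute both orientations.
Exact duplicate oriented edges collapse; self-loops are dropped with a
warning — the model never discusses them, and a self-loop would both inflate
a gene's damping factor and feed its score back to itself. Gene symbols are
matched case-sensitively with no alias resolution. Genes present in the
expression data but absent from the network are kept as isolated nodes:
their damping is 0, so propagation leaves them with their initial score and
the feature matrix keeps one consistent gene universe. Network genes without
expression are dropped when the network is aligned to a cohort: with no
expression evidence their rank difference would be undefined, and any edge
weight through them would be arbitrary.

## Patient-specific weighting

For a tumor sample t with normal-group mean expression m:

* `R_g = |rank_t(g) − rank_m(g)|` with average (mid) ranks on ties; midranks
  keep R symmetric across tied blocks and make R invariant under any
  strictly increasing within-sample transform.
* `Φ_ij = (R_i + R_j)·min(R_i, R_j)` per oriented edge. The formula is
  symmetric, so reciprocal edges carry equal weight. An edge endpoint
  missing a rank contributes R = 0 and zeroes the edge.
* `A_ij ∈ {0, 1, 2}`: 1 on network edges, doubled when either endpoint is
  somatically mutated in this patient. A is the only patient-specific part
  of the *structure*; the edge set itself is shared.
* `W = A ⊗ Φ`, then column-normalized: each source gene distributes unit
  influence across its out-edges. The model applies W inside a damped
  fixed-point iteration without stating a normalization; without one the
  iteration diverges for weights ≫ 1, and column-stochastic normalization is
  the standard choice for this family of personalized-PageRank driver
  methods. Zero columns (sources with no weighted out-edge) stay zero.

## Impact scores, penalty, win rates

`S = (1 − d)·f + d·(W_norm·S)` is iterated from `S = f` to its fixed point;
`f_g = |t_g − m_g|` on the expression scale of the input matrix, and
`d_g = Asum_g/(Asum_g + 3)` where `Asum_g` counts the gene's incoming
oriented edges. Because all `d < 1` and columns of `W_norm` sum to ≤ 1, the
iteration matrix has spectral radius < 1 and converges; we stop at a
max-abs change ≤ 1e−6 (at most 1000 sweeps — non-convergence is flagged and
logged, never fatal). The propagation is linear in f, so any per-patient
rescaling of f changes nothing downstream of the rank-based win rate; f is
therefore used unnormalized, which also keeps the "raw score" ablation
(below) on the data's own scale, exactly as the score is defined.

Non-mutated genes are penalized (`S × p`, p = 0.85), then scores become win
rates: a mutated gene's V is the fraction of all other n−1 genes it
outscores; a non-mutated gene is compared against the patient's mutated
genes only. Ties count 0.5, which keeps the all-equal case symmetric at
V = 0.5. A patient with no mutated genes has no defined comparison set; V
falls back to the all-genes win rate with a warning.

## Cohort handling

Genes with an expression value of exactly zero in more than 80% of samples
(tumor and normal pooled; configurable to tumor-only) are removed before
anything else. Prognosis labels: death before the cancer-type criterion year
is *bad*; death at/after it, or being alive with follow-up reaching it, is
*good*. Patients censored before the criterion are excluded by default —
labelling them good would inject noise — with a config flag
(`censored_policy: good`) preserving the literal "good if not died" reading.
Mutation input is a two-column (sample, gene) table; any appearance marks
the gene mutated, with no variant-class filtering.

## Selection and classification

The per-gene test is a **two-sided Welch t-test on expression** between
good- and poor-prognosis tumor samples (normals play no role here). Welch
rather than pooled-variance because prognosis groups are routinely
imbalanced. Genes with zero variance in both groups get p = 1 by
convention; there is no multiple-testing correction — selection is
deliberately against a fixed cutoff grid (0.1, 0.05, 0.01, 0.005), with the
cutoff chosen by stratified 5-fold cross-validation on the training half:
p-values are recomputed inside each fold from the fold's training part
only, so held-out labels never touch selection; the cutoff with the highest
mean fold AUC wins and ties go to the stricter cutoff. The features the
classifier sees are the *win rates* of the selected genes — the test runs
on expression, the model consumes V.

The classifier is a feed-forward network: three hidden layers (widths
n/4, n/16, n/64 of the input, floored at 64/32/16 units — depth,
activations and optimizer protocol are fixed by design, widths are free;
without the floors the taper degenerates to 1–2-unit bottleneck layers at
small feature counts, which produces dead-ReLU constant predictors), ReLU
between hidden layers, sigmoid output, binary cross-entropy, Adam at
lr 0.001, mini-batches of 2, at most 200 epochs. Training stops early once
the per-epoch mean loss has been below 1e−4 on more than 20 epochs,
counted cumulatively (a `consecutive` mode is available). All randomness
flows from one seed; a fixed seed makes the entire experiment
bit-reproducible.

One experiment = 10 repeats of {stratified 5:5 train/test split → CV cutoff
choice → train → evaluate}. Metrics: ROC AUC and PR-AUC from probabilities;
balanced accuracy, F1 and Matthews correlation from calls at 0.5. Ablation
hooks swap the network weighting (`random_weight`, `unweighted`) or the
features (`score_no_winrate` = penalized scores, `raw_score` = plain
propagated scores); splits are paired across arms by the shared seed.

## Prognostic genes

Per repeat, each gene's *final score* is its mean win rate across the
repeat's training samples (`mean_v`; a bad-minus-good variant `mean_v_diff`
is available). Genes in the top 30 in at least 3 of the 10 repeats form the
prognostic list. Connectivity is summarized as average per-gene edge
density: nonzero W entries inside the induced subgraph divided by subset
size, averaged over all patients' networks, against the same statistic on
the whole network. The units of this statistic are a package convention
(edges per gene, averaged over patients); no external numeric equivalence
is claimed.

## Synthetic cohorts

The generator produces everything the pipeline consumes, with ground truth
planted so recovery is measurable:

* **Network**: random directed edges over the gene universe with ~15% of the
  edge budget concentrated inside the planted-gene module, making the module
  denser than the background (as a real driver pathway would be); roughly
  half the background edges are marked undirected to mimic a
  functional-interaction component beside regulatory edges.
* **Expression**: per-gene log-scale baselines drawn once (planted genes kept
  moderately expressed — an unexpressed driver would be invisible to every
  downstream step); samples are log-normal around them; values below 1 floor
  to 0, so a realistic minority of genes trips the 80%-zeros filter.
  Matrices are emitted as log2(x+1), the scale expression data conventionally
  reaches this kind of pipeline on. Every sample receives a per-sample scale
  offset (log2 SD 0.4, emulating library-size/purity/batch variation):
  within-sample ranks are untouched, cross-sample magnitudes are not — the
  data property the win-rate normalization exists to absorb.
* **Signal**: all tumors displace planted genes from the normal baseline by
  `rank_shift` (default 0.25 log-SD — mild common tumor dysregulation);
  bad-prognosis tumors add `group_effect` (default 3 log-SD). The common
  displacement is deliberately small relative to the prognostic one: a gene
  already rank-saturated in every tumor cannot carry prognosis information
  through a rank-based feature.
* **Mutations**: Bernoulli background (2% per gene per sample), boosted
  ×10 on planted genes — drivers mutated in ~20% of patients, the typical
  frequency range for recurrent cancer drivers.
* **Labels/clinical**: survival times are generated consistently with the
  intended labels; optional extra samples censored before the criterion year
  exercise the exclusion rule on load.

The fixed demo spec is 300 genes / 1500 edges, 60 good + 60 bad tumors and
20 normals with 20 planted drivers (seed 42). The tumor count mirrors the
median scale of the TCGA cohorts this protocol targets; materially smaller
cohorts starve the batch-2/200-epoch classifier, whose held-out performance
then reflects sample size rather than the feature signal. Generation is a
pure function of the spec.

**What passing on synthetic data does and does not show.** The generator
reproduces rank structure, sparse mutations, censoring and per-sample scale
effects, but not batch structure, tumor-purity mixtures, correlated
co-expression modules outside the planted one, or driver heterogeneity
*between patients of the same prognosis group* — every bad tumor shifts the
same planted set. Consequently cross-patient score magnitudes stay more
comparable than in real data, and ablations that exploit magnitudes
(`raw_score`) perform unrealistically well here; on real cohorts the
win-rate correction is reported to matter far more. Passing tests
demonstrate correctness of the machinery and absence of information
leakage, not expected real-data effect sizes.

## Numerical and degenerate-case choices

* Propagation tolerance 1e−6 (max-abs), ≤ 1000 sweeps; convergence flagged.
* Rank ties: midranks everywhere (R and win rates).
* Win-rate ties: 0.5; empty comparison set: all-genes fallback + warning.
* Zero-variance genes: p = 1; empty selection at the chosen cutoff falls
  back to the 10 smallest p-values with a warning (keeps a repeat alive on
  pathological splits).
* A CV fold whose cutoff selects nothing scores an uninformative AUC 0.5.
* All-zero columns of W stay zero; isolated genes keep S = f.
* Experiment seeds: split/CV/model seeds are all derived from the single
  experiment seed, so ablation arms see identical splits (paired
  comparisons) and reruns are bit-identical.

## Known limitations

* Single-omics f (expression only); no methylation/CNV extensions.
* No gene-identifier mapping; symbol collisions across resources are the
  caller's responsibility.
* The feed-forward classifier is intentionally unregularized beyond early
  stopping, faithful to the protocol; on very small cohorts it overfits and
  alternative classifiers plugged into the same interface may behave better.
* Edge-density units are a package convention; compare only within runs.
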