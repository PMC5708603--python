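# Methods

This note documents the models and procedures implemented in `pindiff`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical and design decisions a maintainer
should know about.

## Sample-specific networks

The static input is an undirected protein interaction network with
confidence weights in (0, 1]. Duplicate undirected edges are collapsed to
the maximum weight (confidence scores aggregate evidence, so the strongest
record wins) and self-loops are dropped. Gene identifiers are plain
symbols, case-sensitive, with no mapping layer: network, expression and
annotation inputs are intersected on exact symbol match, and genes outside
the intersection are logged and ignored.

A gene is *expressed* in an RNA-seq sample when its value is ≥ 1 RPKM,
the conventional one-transcript-per-cell cut; the comparison is inclusive,
so boundary values are kept. For array intensities the cut is percentile
matched: the fraction q of reference RNA-seq entries below 1 RPKM is
computed over all (gene, sample) entries globally (per-gene or per-sample
matching would be alternatives; global is the least parameterized and is
configurable), and the array threshold is the q-quantile of the array
matrix with linear interpolation. The sample network is the induced
subgraph on expressed genes — node removal, never edge re-weighting.
Isolated expressed nodes are retained; they simply receive score 0 unless
seeded. A sample whose projection is empty is a hard error.

## Diffusion

For sample network G_s with adjacency W_s and weighted degrees D_s, the
normalized operator is S = D_s^{−1/2} W_s D_s^{−1/2} (rows and columns of
zero-degree nodes are zero). Seeding a function's annotated genes present
in the sample (Y_s over A_f ∩ V_s), the raw score solves

    F_s = (1 − α) S F_s + α Y_s  ⇔  F_s = α (I − (1 − α) S)^{−1} Y_s .

The eigenvalues of S lie in [−1, 1], so for α ∈ (0, 1] the system matrix
is symmetric positive definite and the solution unique. Defaults and
numerics:

* α = 0.2 — the restart weight balancing prior annotation against network
  smoothing; scores are robust over a broad α range, and 0.2 is the
  standard choice for this operator family.
* Single right-hand sides: conjugate gradients, relative tolerance 1e−10,
  at most 10·|V_s| iterations. The tolerance is far below the p-value
  resolution of the downstream calibration.
* Many right-hand sides (all functions of a sample; 100 null bootstraps
  per bin): one sparse LU factorization of I − (1 − α) S per sample,
  shared across solves.
* Every solve — CG or batched — is verified against the fixed-point
  residual ‖F − (1 − α)SF − αY‖_∞ < 1e−8 and hard-fails otherwise.
  Negative round-off (≈ −1e−16) is clipped to zero after the check.

At α = 1 the solution degenerates to F = Y; the implementation accepts
α ∈ (0, 1] so this limit is testable.

## Null calibration and assignment

A raw score scales with both the seed size |A_f ∩ V_s| and the topology of
G_s, so it is compared against scores from random seed sets of the same
size drawn uniformly without replacement from V_s. To keep this tractable
the functions of a sample are partitioned into seed-size bins: a greedy
sweep over functions sorted by seed size grows a bin while every member
stays within ±10 of the running median (lower median, so the bin size is
an attained integer) and opens a new bin otherwise. On small instances the
greedy sweep reproduces the exhaustive-minimum number of bins; only the
±10 constraint is contractual, the sweep is our choice of algorithm.

Each bin's null is estimated from 100 bootstrap diffusions and stored as a
per-gene normal (mean, sample sd). The null is per gene — each gene is
compared to its own score distribution — because score scales differ by
orders of magnitude with local topology; pooling across genes would
mis-rank hubs against leaves. The upper-tail normal p-value of the
observed score is taken, with sd = 0 resolved to p = 0 if the score
exceeds the null mean and p = 1 otherwise. A gene is assigned the function
in the sample when p ≤ 0.01 and its raw score is strictly positive (genes
in seedless components can never be assigned). The threshold comparison is
inclusive. Null RNG streams are derived by hashing
(global seed, sample id, bin seed size), so any sample's table can be
recomputed independently and reproducibly.

**Domain of validity of the normal approximation.** A gene's null score is
a mixture over the event "the gene itself is drawn as a seed", which
contributes an atom of height ≈ α. When seed sets are sparse relative to
the network and α is large, this atom dominates the null sd and the
distribution is strongly bimodal; a two-parameter normal then misstates
tail probabilities, and the fraction of null genes passing p ≤ 0.01 can
exceed the nominal level severalfold (e.g. a 100-node cycle with 10-gene
seeds at α = 0.2 yields ≈ 0.04). The approximation is accurate when each
gene's score aggregates many comparable contributions — denser graphs,
larger seed sets, smaller α. The calibration test fixture (circulant graph
on 400 nodes, degree 20, seed size 200, α = 0.05) sits in that regime and
reproduces the nominal level within Monte-Carlo error; the cohort pipeline
at its default scale operates far from the worst case but users applying
tiny networks with small seeds should prefer empirical nulls (the
machinery stores means/sds, and the bootstrap scores are available to
compute empirical quantiles at debug time).

## Function filters

Three filters select analyzable functions, all boundaries inclusive:

1. **Size**: 50 ≤ |A_f| ≤ 500. Smaller sets calibrate poorly; larger ones
   defy interpretation.
2. **Leave-one-out recall ≥ 0.1** on the *static* network: for each
   annotated gene, seed the remaining annotated genes, diffuse, calibrate
   with the same binned-null machinery (bins built over the leave-one-out
   seed sizes), and count the held-out gene as recovered if it would be
   assigned. Functions whose genes do not cluster in the network fail
   this filter, by design.
3. **Expression activity**: the fraction of annotated genes expressed must
   reach 0.85 in at least 20% of samples. The 0.85 value is fixed by
   default (it can be recomputed from the data at hand, but a fixed cut
   keeps runs comparable across cohorts).

## Gain/loss calls and Δ_f

For gene g and function f, over the samples where g is expressed, the
counts (case assigned, case not, control assigned, control not) form a 2×2
table. Significance is a two-sided Fisher exact test — two-sided because
either direction of enrichment is of interest, with direction taken from
the effect size. The effect size is the cross-product odds ratio
θ = (n00·n11)/(n10·n01) (a ratio-of-assigned-fractions mode is available
as an alternative); zero-cell conventions: θ = +∞ when only the
denominator vanishes, 0 when only the numerator does, undefined (no call)
when both do. A call requires significance (nominal p ≤ 0.05, or
Benjamini–Hochberg adjusted p < 0.1 across the genes tested within the
function in FDR mode) *and* θ ≥ θ_min for gain or θ ≤ 1/θ_min for loss;
the default θ_min = 10 is deliberately stringent, and 2–10 is the
reasonable range. Gain and loss are mutually exclusive for θ_min > 1.

Two bias guards precede the calls: genes whose expressed/not-expressed
status associates with condition (Fisher p ≤ 0.05) are excluded entirely,
and only expressed-in-sample observations are counted. The
differential-expression exclusion is this same expressed/not Fisher
filter — a separate magnitude-based DE test is not applied, since
assignment eligibility is what the expressed/not status controls.

Δ_f sums +1 for each un-annotated gaining gene and −1 for each
un-annotated losing gene (annotated genes are excluded so Δ_f reflects
network rewiring, not annotation expression); positive Δ_f is net gain in
the case condition. It is reported raw, normalized by |A_f|, and next to
the annotation log fold change — the natural log of the ratio of mean
per-sample expressed-annotated-gene counts between conditions (median
aggregation is used for the feature-selection control); zero aggregates
produce ±inf sentinels rather than an exception.

## Association statistics

* **Elevated-statistic labels** (Mut(f), CNV(f)): one-sided rank-sum test
  that the gained (or lost) genes' event frequencies exceed the remaining
  genes'. One-sided because the hypotheses are directional (elevated
  missense among gained genes, elevated nonsense/deletion among lost).
  Combined n ≤ 12 is evaluated by exhaustive permutation of the rank-sum
  statistic (exact under ties); larger samples use the
  normal-approximation Mann–Whitney test. Flag = 1 at p ≤ 0.05; an empty
  gene set yields a flagged (1.0, 0) record.
* **Class enrichment**: cross-product odds ratio and two-sided Fisher p
  for any 2×2 function-class table.
* **Driver AUC**: rank-based ROC-AUC (average ranks, ties get half
  credit) of per-gene gain or loss tendencies — the fraction of evaluated
  functions gained/lost by the gene — against a positive driver set,
  compared over all scored genes. The empirical p-value uses 2000 label
  shuffles with add-one smoothing, (r + 1)/(n + 1), so finite permutation
  counts never report p = 0.
* **Activity profiles**: X_{s,f} is the number of genes assigned f in
  sample s by diffusion; X′_{s,f} = |A_f ∩ V_s| is its annotation-based
  counterpart. Scaled variants standardize each function across samples,
  with zero-variance rows mapped to zeros. Feature selection takes the top
  and bottom ⌈k%⌉ functions by Δ_f (ties broken by function ID for
  determinism; the degenerate all-tied case deduplicates), or in control
  mode the same number of functions by |median-count log fold change|.
  Exported matrices are plain TSV for downstream survival or
  classification tooling, which is deliberately out of scope here.

## Synthetic studies

The generator produces a full study — network, two-condition expression,
annotations, event frequencies, ground truth — with planted signal whose
mechanism matches the pipeline's assumption: *rewiring happens through
expression only*, the static edge list never differs between conditions.

* **Network**: scale-free background (Barabási–Albert, 3 edges/node;
  random-geometric available) over 2000 genes, with each function's
  module (20 functions, 50–100 genes) densified to intra-module edge
  probability 0.25. Background weights are uniform on [0.5, 1];
  planted wiring carries weight 1.0 (maximal confidence).
* **Planted rewiring**: each planted function (6 gain + 6 loss by
  default) receives 15 un-annotated target genes connected to the module
  exclusively through 12 bridge genes (each bridge linking 15 module
  genes). Bridges are expressed in their active condition at rate 0.95
  and leak at 0.05 in the silenced condition; for gain functions the
  active condition is the case cohort, for loss functions the control
  cohort. Targets therefore sit two hops from the seeds in one condition
  and disconnected from them in the other. The bridge fan-in matters:
  with symmetric normalization a target's two-hop score is ≈
  α(1−α)²·k_b/√(d_t·d_m) for k_b bridges, so sparse bridging disappears
  into the random-seed null — the defaults were sized so planted targets
  clear the p ≤ 0.01 call in most case samples.
* **Expression**: log-normal on/off states (exp N(ln 10, 0.8) vs
  exp N(ln 0.05, 0.5)) with 1% dropout, 30 + 30 samples.
* **Event frequencies**: baseline uniform [0, 0.02]; planted-gain targets
  get elevated missense frequency and planted-loss targets elevated
  nonsense and deletion-CNV frequency (+0.15·U(0.5, 1)), mirroring the
  association hypotheses the downstream statistics test.

What the generator does *not* emulate: realistic cancer genome structure
(no subtype heterogeneity, no survival times, no mutational signatures,
no correlated CNV segments), annotation incompleteness, network false
edges/ascertainment bias, or batch effects. Passing the recovery tests
shows the pipeline detects expression-mediated rewiring under its own
model assumptions at realistic size and noise; it does not certify
performance on real cohorts, where identifier mismatch, annotation bias
and confounding dominate.

With the default configuration (seed 7), the full pipeline recovers the
planted direction for 12/12 planted functions, keeps |Δ_f| ≤ 2 for all 8
no-signal functions, and permuting condition labels collapses the median
planted |Δ_f| to 0 — the computation behind these numbers runs in
`tests/test_acceptance.py` and `scripts/acceptance.py`.

## Problem sizes

The shipped tests and the acceptance script use desk-scale instances: the
synthetic cohort at 2000 genes × 60 samples × 20 functions (about a
minute of single-CPU time for the full assignment tensor thanks to the
shared per-sample factorization), the calibration study at 400 nodes × 50
replicates × 100 bootstraps, and enumeration oracles at n ≤ 30. These
sizes were chosen so every result recomputes from scratch in minutes
while keeping each statistical check adequately powered.

## Known limitations

* The normal null approximation degrades in the sparse-seed/large-α
  regime (see above); empirical nulls are the fallback.
* Uniform random seed sampling ignores degree bias; degree-aware seed
  sampling would refine the nulls but is not implemented.
* Node removal is a blunt instrument for expression context; edge
  re-weighting schemes are out of scope by design.
* Flat gene sets: no ontology-graph propagation of annotations before
  filtering.
* The Fisher gain/loss test treats samples as exchangeable within
  condition; cohort structure (batches, subtypes) is not modelled.
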