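# Methods

`recovnet` implements a compatibility analysis for a two-component drug
combination: does the combination restore a disease-perturbed system better
than either component alone?  The question is asked at three levels — gene
expression over a disease network, a functional plate assay, and the gut
metabolome/microbiome — and each level has its own statistic.  Because no
machine-readable data accompany the study design this package emulates, every
stage runs on synthetic tables with planted ground truth; this note records
the models, the defaults, and exactly what the synthetic studies do and do
not demonstrate.

## Disease network

The network's node set is the intersection of the measured transcriptome
with a curated disease reference gene list (exact identifier match after
uppercasing and whitespace stripping — no alias or ortholog mapping).  Edges
come from a PPI table and are kept when both endpoints are in the shared set
and the confidence is at least `min_confidence` (default 0.4, the STRING
"medium confidence" convention).  **Genes left without a single qualifying
edge are dropped.**  This is a deliberate, visible choice: an isolated node
carries no network information, and dropping such genes is what makes a
shared-gene set larger than the final node count.

Node importance uses an NTRA-style score

    score(g) = z(|log2FC_disease(g)|) + z(log(degree(g) + 1))

z-scored over network nodes, rank 1 = highest score, ties broken by gene id.
This is a **declared stand-in**: the originally published NTRA ranking is
cited without a formula anywhere we can reimplement from, so this additive
z-score heuristic — perturbation magnitude plus log-degree centrality —
should not be read as the published method.  A zero-variance component
contributes 0 with a warning rather than an undefined z-score.

## Efficiency of recovery (EoR)

Per gene and treatment arm, with linear fold changes of group means:

    EoR = 100 − |100 − 100 · FC(arm/model) / FC(sham/model)|

EoR = 100 iff the arm reproduces the sham/model contrast exactly; the score
is symmetric about a fold-change ratio of 1 and unbounded below.  Negative
values are kept (they distinguish over-correction from inaction); only the
recovery threshold is configurable (default: recovered iff EoR > 0,
strictly).  Recovery percentages are rounded half-up to two decimals.

Fold changes are plain ratios of arithmetic group means with a configurable
pseudo-count (library default 0.5; the bundled demo uses 0 so planted values
are recovered exactly).  No DESeq2-style shrinkage or dispersion modelling
is applied — this is a documented divergence from typical RNA-seq practice,
chosen because the recovery score is defined on plain ratios and shrinkage
would make the planted-truth accounting opaque.

Gene selections relative to the combination arm:

* **specific** — EoR > 0 in the combination and EoR ≤ 0 in *every* mono arm;
* **differential** — combination EoR exceeds each mono arm's EoR by more
  than `delta`.  `delta` defaults to 0.2 **on the fraction scale**, i.e. a
  margin of 20 EoR percentage points; a `delta_scale="percent"` switch reads
  it as 0.2 points instead, since the source analysis is ambiguous about the
  scale.  `mono_mode="any"` relaxes "every mono arm" to "at least one";
* **union** — specific ∪ differential (sizes obey inclusion–exclusion).

## Bliss synergy

Readouts are normalized on the control/model window,
E = (mean_arm − mean_model)/(mean_control − mean_model), and clamped to
[0, 1] (the Bliss formula requires it; the raw value is retained because an
arm can genuinely score worse than the model group).  Bliss independence
gives the expected additive effect E_a + E_b − E_a·E_b, and the combination
index CI = E_expected / E_observed classifies the pair: synergistic below 1,
antagonistic above, with |CI − 1| ≤ 0.05 labelled additive by default (the
strict CI < 1 rule is recovered with `additive_tol=0`).  An inhibition rate,
100·(model − treatment)/(model − control), covers assays whose readout
decreases with treatment.

A percentile bootstrap (resampling wells within groups) supplies an optional
CI interval.  Caveat: at very small replicate counts (n ≈ 3–6 per group) the
percentile bootstrap undercovers — measured ≈ 88% at n = 6 for a nominal
95% interval in our calibration — so intervals from three-replicate plates
should be read as rough uncertainty indicators, not exact coverage
statements.  The calibration test uses 10 replicates per group, where the
nominal level is approximately attained.

## Metabolite screening and association

The differential screen applies three independent gates per feature: a Welch
(unequal-variance) two-sample t-test at p < 0.05, |log2 fold change| > 0.2
(ratio of group means with a pseudo-count of half the smallest non-zero
abundance), and a compound annotation score ≥ 38.1.  "T test" alone does not
fix a variant; Welch is chosen as the safer default for unequal variances.
Features constant in both groups get p = 1 when the means agree and p = 0
otherwise, flagged `degenerate`.  Disabling a gate can only grow the passing
set.

A feature is **restored** when it passes the screen in both the disease
contrast (model vs sham) and the treatment contrast (treatment vs model)
with opposite fold-change signs.  Requiring significance in both contrasts
is the default; `require_significance=False` keeps direction-only calls, and
a `toward_baseline` mode instead demands that the cumulative log2 fold
change moves closer to zero (which also rejects overshoot past sham).

Taxon–metabolite association is tie-corrected Spearman correlation over
shared samples (≥ 4 required), with Benjamini–Hochberg adjustment across all
pairs by default.  Constant features yield missing correlations with a
warning.

## Synthetic studies: what is planted and what is emulated

All generators draw from child streams derived from one seed plus a stage
label (CRC-32 into a `SeedSequence`), so identical seeds give bit-identical
tables and single stages can be re-run reproducibly.

**Expression**: per-gene lognormal baselines; the model group mean is
baseline / FC_disease; each arm's mean realises a planted EoR target by
inverting the EoR formula.  The inversion is two-valued (EoR is symmetric
about ratio 1): positive targets use the branch between model and sham
("under"), non-positive targets force the overshoot branch, which is the
only positive-fold-change solution; the branch used is recorded in the
ground truth.  Noise is mean-preserving multiplicative lognormal with a
given CV, so fold changes stay well-defined without pseudo-count distortion
— at CV = 0 every downstream estimator returns the planted value to
floating-point precision.  Real RNA-seq features that are *not* emulated:
counts, library-size effects, gene-length/GC bias, dispersion–mean
relationships.  Passing tests therefore demonstrate correctness of the
scoring arithmetic and its estimators, not robustness to RNA-seq artefacts.

**PPI**: Erdős–Rényi wiring at a requested expected mean degree with
confidences uniform on [0, 1].  Degree-distribution realism (hubs,
scale-freeness) is a non-goal.

**Assay**: group means placed on a linear readout scale so that the planted
effects are exactly recovered by normalization at zero noise; Gaussian well
noise on top.

**Metabolites**: three planted classes — restored (disease shift of ±1.5
log2 units, reversed by the combination, partially by the mono arms),
disease-only, and null.  Restored features draw annotation scores from a
high range (45–95) and the fillers from a low range (5–35), emulating that
the compounds of interest are the confidently identified ones; this makes
the planted restored count robust to t-test false positives among fillers.

**Paired omics**: a Gaussian copula plants Spearman correlations exactly in
expectation (latent Pearson r = 2·sin(π·ρ/6)); strictly monotone per-feature
maps then produce positive abundances.  A true compositional closure
(dividing by per-sample totals) is deliberately *not* applied because it is
not rank-preserving; taxa are fraction-like but not compositional, and
zero-inflation is not modelled.  Cross-correlation matrices whose joint
latent covariance is not PSD are projected to the nearest PSD matrix with a
warning — the bundled demo matrix is chosen feasible (cross-block spectral
norm < 1) so its planted values are realisable exactly.

## The bundled demo study

The default `RunConfig` (mirrored in `configs/demo.yaml`) plants a study at
the scale of the analysis it emulates: a 32,545-gene universe, a 1641-gene
disease reference with 1539 shared genes, 92 of them left unwired so the
network has 1447 nodes, and Erdős–Rényi wiring at mean degree 62.03
(≈ 44,879 expected edges).  The planted per-arm EoR block structure
(`RECOVERY_BLOCKS`) yields recovery counts of 902 / 804 / 437 genes for the
combination / CF / BBP arms (62.34% / 55.56% / 30.20% of 1447), a
250-gene combination-specific set, a 492-gene differential set overlapping
it in 205 genes, and hence a 537-gene union.  The assay plants effects
(0.3, 0.4, 0.8), giving CI = 0.725 (synergistic); the metabolite study
plants 70 restored features among 200; the association block plants
moderate rho values (±0.2–0.45) for four genera against four metabolites.
Expression noise is 0 in the demo — the fixture's purpose is exact planted
accounting — while the assay (SD 0.02) and metabolite (lognormal σ 0.2,
n = 6 per group at ≈ 2.8-fold shifts, detection power ≈ 1) stages carry
noise their planted outcomes tolerate.  The demo network's *node* memberships
and counts are deterministic; the edge count varies by ~0.5% across seeds.

The full demo runs in well under a minute on one CPU.  Problem sizes in the
test suite are smaller (hundreds of genes/features, 20-seed calibrations) —
enough for the binomial and type-I calibration bands they assert.

## Known limitations

* The NTRA ranking is a placeholder heuristic (above).
* Fold changes are unshrunk ratios; genes with near-zero model-group means
  need a pseudo-count and their EoR is sensitive to it.
* The Bliss analysis covers one two-drug pair per run; dose–response
  surface models (Loewe, ZIP, median-effect) are out of scope.
* The screen applies no multiple-testing correction by default (matching
  its stated thresholds); BH is default only for the association matrix.
* Synthetic realism is deliberately limited to what the estimators consume
  (means, ranks, group structure); see the per-generator caveats above.
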