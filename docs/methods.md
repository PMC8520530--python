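# Methods

This note records the modelling choices behind `cernet`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer should know about.

## Data model and scales

All statistics operate on `log2(x + 1)` of normalized expression (TPM for
mRNA/lncRNA, RPM for miRNA). Read counts appear only in the prevalence
filter: a gene is retained iff it reaches the class minimum (mRNA 5 reads,
miRNA and lncRNA 1 read) in *strictly* more than 50% of all samples,
pooled across groups. Normalization and alignment are upstream of this
package; differential statistics can either come from the built-in Welch
test on log values or be imported from a count-model tool. The three
expression matrices must be sample-matched (identical sample ids in
identical order); missing values are rejected rather than imputed, because
a sample-matched design has no principled unit of imputation here.

## Triplet discovery

Candidate lncRNA–mRNA pairs are those sharing at least one expressed miRNA
interactor; this keeps the search quadratic only over connected pairs and
avoids evaluating the hypergeometric test at zero overlap, where it is
powerless by construction. The hypergeometric universe is the set of
expressed miRNAs with at least one curated interaction — the sampling
frame from which both interactor sets are drawn. Every shared miRNA that
passes the correlation filters yields its own triplet, so one lncRNA–mRNA
pair can contribute several triplets. Correlation significance is the
two-sided t-based p; sidedness is not needed because the sign thresholds
(+0.7 / −0.7) already impose direction. Sample correlations of exactly ±1
(possible in deterministic fixtures) are clipped to ±0.999999 before the
t transform and the Fisher transform.

With fewer than four control samples the Pearson p-value is undefined and
discovery refuses to run.

## Dysregulation score

**Node (dot) score.** The score is the CDF of
`z = (−log10 p)·|log2FC|` under the null product model
`Z = E·|N|`, `E ~ Exp(ln 10)` (the −log10 of a uniform p-value),
`N ~ Normal(0, σ²)`. σ² is the empirical variance (ddof = 1) of log2FC over
all filtered genes of the member's RNA class in the same comparison —
classes differ grossly in fold-change spread, so pooling across classes
would mis-calibrate miRNAs against mRNAs. If a class has fewer than two
genes or zero variance the node scores of that class are set to 0 (no
distributional evidence). The defining integral is reduced by `x = σt` to
the one-parameter kernel

    G(w) = √(2/π) ∫₀^∞ exp(−t²/2 − w/t) dt,   DotScore = 1 − G(z·ln10/σ).

The public scalar `dot_score` evaluates G by adaptive quadrature
(abs tol 1e−10, so `F_Z(0) = 0` to quadrature tolerance). The vectorised
engine uses a monotone PCHIP interpolant of G on a 1500-point log grid over
w ∈ [1e−8, 400] (G < 1e−30 beyond); the interpolant deviates from
quadrature by ~1e−8, far below the Monte-Carlo tolerance any test uses,
and both paths are cross-checked in the suite.

**Edge score.** The statistic is the Fisher-z difference
`d = Y·[F(r_case) − F(r_control)]` with `Y = +1` if `r_control < 0`, `−1`
if `r_control > 0`, and `Y := +1` at exactly 0 (a measure-zero tie; the
choice is arbitrary and documented). The score is `Φ(d/σ_d)` under the
null of equal population correlations, with the standard asymptotic
`σ_d² = 1/(n₁−3) + 1/(n₂−3)`. Treating the null mean as anything other
than zero would fix the score at 0.5 identically, so the null-calibrated
reading is the only usable one. Identical case and control correlations
give exactly 0.5; groups of three or fewer samples are refused.

**Influence score.** For each member, the 2×2 Fisher exact (upper-tail
hypergeometric) enrichment of its background-network neighbours in SDE
genes (p < 0.01 and |log2FC| > 1.2, both strict), returning 1 − p. The
lncRNA and mRNA components use miRNA neighbours with the network's miRNA
nodes as universe; the miRNA component uses mRNA *and* lncRNA neighbours
with the combined universe. A member with no neighbours of the relevant
class contributes 0. SDE calls, like everything else, are recomputed per
permutation.

**Permutation p.** One shuffle of the pooled case+control sample labels is
shared by all three RNA classes per permutation (group sizes preserved);
this preserves inter-gene correlation under the null and lets the SDE calls
and class variances be recomputed once per permutation for all triplets.
An alternative per-class shuffle is available (`shuffle_mode="per_rna"`)
for the reading in which each RNA type is relabelled independently.
`emp_p` counts strictly greater permuted scores; the null is per-triplet,
not pooled. Default 1000 permutations (the analysis scale is 10 000; the
default keeps desk-scale runs interactive and is a config field).
External DE tables apply to the observed score only — permuted scores
always use the internal Welch test, since an external tool cannot be
re-invoked per shuffle.

## Time-ordered network

Initial nodes are the genes with the smallest mean triplet score inside
the intersection of both conditions' bottom decile (ties lexicographic;
with one condition, its bottom decile alone). An empty intersection is an
error suggesting a larger decile — on networks of a few hundred genes the
10% intersection is frequently empty, which at transcriptome scale it is
not. Levels come from one multi-source BFS (all seeds at level 1
simultaneously); a triplet takes the minimum level of its members and is
removed from all later levels, so level counts partition the triplet set.
Genes unreachable from the seeds (impossible when the background network
is one component, possible for user-supplied graphs) are placed one level
past the deepest reachable level and reported. The stability procedure
re-seeds the BFS with two random genes drawn from the level-1 triplets'
genes (excluding the original seeds) and tabulates per-triplet level
changes (new − original): unchanged, |Δ| = 1, |Δ| = 2, |Δ| > 2, with mean
and population SD.

## Progression comparison

Per-level overlap uses the union denominator |A∩B|/|A∪B|; per-condition
denominators are a flag away. Level activity is the per-sample mean of
z-scored (across samples) log2 expression over the level's member mRNAs —
a deliberately transparent per-sample set-activity score; the output is
tagged `mean_zscore` so downstream consumers know which activity method
produced it. Constant member genes are dropped from the z-score (a fully
constant level is an error). Levels are compared by Pearson correlation of
their activity vectors and clustered by complete linkage on Euclidean
distances between correlation rows; the dendrogram is exported as Newick
with merge heights as depths.

## Patient scores

`Exp_mRNA = a₁·Exp_miRNA + a₂·Exp_miRNA·Exp_lncRNA + c` is fitted by OLS
on control samples (log2 scale). The constant c is an intercept: a pure
"error" term would not be computable for a new patient, and only the
intercept reading yields a per-patient prediction. DS = estimated −
observed, so over-expressed mRNA gives negative DS, DS is linear in the
observation with slope −1, and the control-sample mean DS is exactly zero.
Rank-deficient designs (constant miRNA, or miRNA·lncRNA collinear with
miRNA) are refused rather than pseudo-inverted. Cross-triplet interactions
are deliberately ignored; each triplet is fitted independently.

## Biomarker selection

Elimination uses out-of-bag permutation importance: each tree is fitted on
a bootstrap sample and importance is the mean drop in OOB accuracy when a
feature's OOB values are permuted. Importance measured on the training
points themselves is uninformative at cohort scale (the forest
interpolates 16 samples and every permutation importance is zero), which
is why the OOB form is implemented here. Each round drops the lowest third
(floor, at least one) until at most 10 survive (the paper-scale search
must stay exhaustive: 10 survivors cap the combination search at 385
panels of size ≤ 4). Ties in importance are broken randomly under the
stage seed.

The SVM is RBF, C = 1, scale-heuristic gamma (linear kernel by flag);
features are standardised with training-fold statistics only. LOOCV
accuracy is the fraction of held-out samples predicted correctly; AUC
pools held-out decision values, each oriented so that larger means the
second class on its training fold. Panel choice maximises accuracy, then
prefers fewer features, then higher AUC, then lexicographic order.

Two calibration facts worth knowing. First, LOOCV accuracy on
label-independent data is *pessimistically* biased (the held-out sample's
class is always the training-fold minority, and an underfitting SVM then
votes against it); null means sit near 0.4, not 0.5, and individual runs
can reach 0. Second, the *selected* panel's accuracy is the maximum over
hundreds of correlated LOOCV estimates and is strongly optimistic on null
data (measured 0.8–1.0 on pure noise). Both are properties of the
selection procedure itself, not of an implementation defect; any claimed
panel should therefore be validated on data not used for selection. The
suite checks calibration the sound way: a *fixed* panel re-evaluated under
label permutations averages to chance within binomial noise.

## Synthetic data

The generator emulates a sample-matched three-class cohort: one control
and two case groups of 8 samples each (the scale of a small myocardial
biopsy study), log-normal expression (Gaussian log2 values, mean 8,
SD 1, exponentiated), 200 mRNAs / 200 miRNAs / 60 lncRNAs with 30 planted
triplets. Planted members load ±√r on one latent per-group factor, giving
exact pairwise population correlations ±r (default r = 0.9) and the dense
cross-triplet crosstalk real ceRNA networks show. The curated interaction
set gives each planted pair its own miRNA plus five decoy shared miRNAs
(hypergeometric signal), adds cyclic "bridge" shared-miRNA profiles
between neighbouring triplets so the emitted network stays one component
even when individual bridge correlations miss the 0.7 cut-off at n = 8,
and sprinkles random background edges (density 0.005). Dysregulation in a
case redraws the triplet's members independently of the factor (breaking
all three correlations) and shifts lncRNA/mRNA up and miRNA down by
2 log2 units, so node, edge and influence components all receive signal;
both mechanisms can be toggled to isolate components. Case B's dysregulated
set overlaps case A's by about half, giving the progression comparison
partial common structure.

What the generator does **not** emulate: library-size and batch effects,
count noise (mean–variance coupling), hub-degree heterogeneity of real
interaction databases, indirect (partial-correlation) confounding, and
group sizes beyond a few dozen. Passing tests therefore demonstrate
correctness of the statistics and the pipeline's behaviour under its own
model, not robustness to real-data artefacts.

The 11-gene worked example is small enough to verify by hand: its
shared-miRNA p is 1/35 exactly, one planted triplet is a deterministic
function of the latent factor so the interaction regression recovers
(−1.0, −0.05, 16.0) with zero residual, and a BFS from the shared miRNA
puts every other gene at level 2.

## Problem sizes and defaults used in checks

Self-checks run at the generator's cohort scale: 8/8/8 samples,
30 planted triplets (~460 genes), 500 permutations for empirical p-values,
200-triplet null calibrations, 200-replicate detection studies at
|r| = 0.95, and 10-replicate stability analyses — sizes chosen so the full
verification cycle stays interactive on a laptop while keeping every
statistic in its intended regime (n − 3 Fisher variances at n = 8, exact
hypergeometric tails, LOOCV at n = 16).

## Known limitations

* The Welch-on-log DE stand-in ignores count dispersion; import a
  count-model table for real data.
* Empirical p-values are not multiplicity-corrected (raw 0.05, by design).
* The selected biomarker panel's LOOCV accuracy is optimistically biased
  (see above) and needs external validation.
* `emp_p` resolution is 1/n_perm; at the default 1000 permutations the
  smallest non-zero p is 0.001.
* The TO-BCeN initial-decile intersection assumes a large network; small
  networks need a wider decile.
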