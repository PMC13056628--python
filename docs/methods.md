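# Methods

This note documents the models, conventions and design choices behind
`mmconn`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Parcellation and data model

All stages share a unified 104-node parcellation: 68 cortical nodes (the 34
Desikan–Killiany regions per hemisphere) plus 36 subcortical/cerebellar
nodes (thalamus, caudate, putamen, pallidum, hippocampus, amygdala,
accumbens and ventral diencephalon per side, and ten cerebellar lobule
nodes per side). Node order is fixed (left cortical, right cortical,
subcortical, cerebellar) and every matrix is re-aligned to it by node name
on read, so cross-modal edge vectors correspond element-wise.

Each node carries one of five network affiliations — Motor, Sensory,
Premotor, Frontotemporal, Subcortical/Cerebellar — matching the
conventional five-colour connectogram palette (red, blue, orange, purple,
green). No standard enumeration of this five-class map exists, so the
region→class assignment ships as an editable TSV (`mmconn/data/nodes_104.tsv`):
Motor = precentral + paracentral; Premotor = caudal middle frontal +
superior frontal; Sensory = the somatosensory and early visual/auditory
strip (postcentral, superior parietal, supramarginal, transverse temporal,
pericalcarine, cuneus, lateral occipital, lingual); Frontotemporal = the
remaining cortex; all 36 non-cortical nodes form the fifth class.

Connectivity matrices are dense TSV with a node-name header, symmetric
within 1e-9, zero diagonal, finite everywhere; violations raise distinct
error types. Values are written with 13 significant digits so a
write/read round-trip is lossless to ≤1e-12 relative error.

The packaged clinical fixture (`table1_cohort.tsv`) transcribes the
published per-subject ages, grip strengths and ALSFRS-R scores, including
a duplicated patient row which the reader drops (first occurrence kept,
with a warning). Per-subject sex and handedness are not published; those
two columns are synthetic, assigned to reproduce the published group
counts, and marked as such in the file header. The published summary table
prints ALSFRS-R 40.7 ± 2.4 for patients, but the per-subject column gives
37.3 ± 2.9; the two cannot both be right, and this package follows the
per-subject values everywhere.

## Synthetic cohort generator

The generator produces a full multimodal cohort from one seed; `(config,
seed)` determines every output byte-for-byte. Its defaults are the study
conditions, not tuning knobs.

**Demographics.** Ages are truncated normals (18–100 y) at 64.7 ± 6.5
(patients) and 63.7 ± 3.9 (controls); grips at 15.2/12.0 ± 6.6 kg
(patients, dominant/non-dominant) and 32.2 ± 1.8 / 31.7 ± 1.7 kg
(controls), truncated at 0; patient ALSFRS-R at 37.3 ± 2.9 rounded and
clipped to [0, 48]; controls score the ceiling 48. Sex and handedness are
Bernoulli draws at the published group proportions.

**Structural connectomes.** A deterministic base matrix assigns
within-affiliation-module weight 60 and between-module weight 12
(arbitrary streamline-count-like units; only ratios matter). Because
homotopic cortical pairs share an affiliation, left–right mirror edges are
always present. For patients, every interhemispheric edge whose two
endpoints are both Motor or Premotor is scaled by (1 − δ); the default
δ = 0.15 plants a mild deficit of the kind described qualitatively for
interhemispheric motor pathways. Subject heterogeneity is log-normal
multiplicative noise (σ = 0.35, mean-one), giving count-like positive
skew. The 2:1 within/between contrast wins comfortably at the top-5%
threshold: single-subject Louvain modularity of the thresholded network is
≈0.5.

**Functional time series.** For each subject a target correlation matrix
is built as C* = a·(ρ_sf·S + √(1−ρ_sf²)·G) off the diagonal, where S is
the standardized structural weight matrix, G standardized symmetric
Gaussian noise, ρ_sf the planted structure–function coupling (default
0.25, the magnitude scale of published rest-coupling values), and
a = 0.2 the correlation amplitude. The ρ/√(1−ρ²) weighting makes the
expected edge-wise Pearson correlation between structural weights and the
planted correlations exactly ρ_sf; finite scan length attenuates the
measured value slightly (≈4% at T = 300), which is why the recovery
tolerance is ±0.07 rather than tighter. C* is projected to the nearest
valid correlation matrix by eigenvalue clipping at 1e-6 and diagonal
renormalization — simple, deterministic and adequate at N = 104. Series
are zero-mean Gaussians with covariance C*: 300 volumes at rest, 600
under task, TR = 2.5 s.

Task runs add an activation term: boxcars for the alternating 30-s
right-hand / rest / left-hand / rest blocks, convolved with the canonical
double-gamma HRF (response gamma peaking near 6 s, undershoot near 16 s at
1/6 amplitude — the conventional default, since no HRF is prescribed by
the design), unit-peak scaled, applied to Motor/Premotor/Sensory nodes
contralateral to the moving hand. Background connectivity is identical
across conditions, so block regression of the task series should (and
does) restore the rest-level coupling.

**Morphometry.** Regional value = base (2.5) + β_age·age (−0.01/y) +
β_sex·sex (0.10) + β_TIV·TIV (5e-7/mm³, TIV ~ N(1.5e6, 1.5e5) mm³) + a
per-subject latent factor shared within each affiliation module (SD 0.2)
+ independent noise (SD 0.1). The 2:1 factor/noise ratio is what the
covariance-network stage recovers as block structure. No group difference
is planted in morphometry.

**Clinical link.** Patient grips and ALSFRS-R are rewritten as
monotone-noisy transforms of a chosen network metric through a Gaussian
copula: the metric's normal scores are mixed with independent noise at
latent Pearson r = 2·sin(π·ρ/6), the value at which a bivariate normal
copula has Spearman correlation ρ (default planted ρ = −0.70). ALSFRS-R
rounding to integers introduces ties that can attenuate the realized rank
correlation slightly; the continuous grip variables carry the exact
target.

**What the generator does not emulate.** No image-level simulation, no
physiological noise or motion, no spatial autocorrelation beyond the
module structure, no tractography biases (distance dependence, gyral
bias), no real covariance geometry of cortical thickness. Passing
recovery tests therefore demonstrates that the *pipeline arithmetic* is
faithful — planted parameters come back out within tolerance — not that
the methods would behave identically on real MRI-derived data. One
visible consequence: because all synthetic modalities share the same
module skeleton, group-averaged matrices are strongly correlated across
modalities (coupling r ≈ 0.5–0.9), unlike real cortical-covariance
networks whose coupling to function is near zero.

## Structural covariance networks

Morphometry is residualized by OLS on [intercept, age, sex, TIV] per
region (residuals exactly orthogonal to each covariate), then each group's
network is the cross-subject Pearson correlation of every region pair,
clipped to |r| ≤ 1 − 1e-7 (finite Fisher z under exact collinearity) and
z-transformed. At the default group sizes (15/14) these correlations are
extremely noisy — a known property of covariance networks at small n, not
a defect of the implementation.

Because each group yields a single network, group inference uses label
permutation: group assignments are shuffled (default 1000 times), both
SCNs and their fixed-density metrics recomputed, and the two-tailed
p = (1 + #{|perm diff| ≥ |observed|}) / (n_perm + 1) reported. The source
study reports SCN p-values without naming a method; permutation is the
standard choice for one-network-per-group designs and is documented here
as this package's decision. SCN (and FC) thresholding considers positive
edges only; DTI weights are nonnegative counts and use all nonzero edges.

## Fixed-density graph analysis

Every network is reduced to K = round(ρ·N(N−1)/2) edges (round-half-up) by
descending weight, ties broken by ascending (i, j) index pair for
determinism. At N = 104, ρ = 0.05 this gives exactly K = 268, density
0.05004 and mean nodal degree 2K/N = 5.154 — the rounding convention is
pinned by that printed degree (K = 267 would give 5.135). Metrics are
computed on the binarized thresholded graph; mean nodal strength uses the
retained pre-binarization weights (a degree SD of exactly zero in the
published tables implies fixed-K binary analysis).

Conventions for disconnected structure, stated per metric because sparse
5%-density graphs are routinely fragmented: global efficiency counts
disconnected pairs as zero contribution; characteristic path length
averages over connected pairs only and reports the excluded-pair count;
assortativity returns an undefined flag when endpoint-degree variance is
zero; per-node clustering is zero for degree < 2.

Null models are Maslov–Sneppen degree-preserving rewirings: 10 successful
double-edge swaps per edge (self-loops and multi-edges rejected), 100
nulls by default, one shared ensemble for both normalized metrics.
Small-worldness σ = (C/C_rand)/(L/L_rand). The rich-club curve
φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1)) is normalized level-wise by the null
mean; the scalar summary is the mean of φ_norm(k) for k from ⌈mean
degree⌉ up to the last level with ≥5 surviving nodes — the published
tables print a single rich-club number without defining k, so the window
is this package's documented choice. Louvain modularity uses a seeded
node ordering; betweenness is Brandes, normalized by (N−1)(N−2)/2.
Weighted-distance path metrics and local efficiency are deliberately out
of scope.

## Functional connectivity and task regression

FC is the pairwise Pearson correlation of ROI series, clipped and Fisher
z-transformed like the SCN edges. Task connectivity is computed after
residualizing each node's series on [intercept + HRF-convolved block
regressors, one per movement condition], leaving intrinsic (background)
connectivity. The source describes "beta-series" task regression without
detail; block-regressor residualization is the minimal procedure achieving
the stated goal and is this package's documented interpretation —
trial-wise single-trial GLMs would be an alternative reading. No band-pass
filtering, scrubbing or nuisance regression: denoising belongs to the
(out-of-scope) preprocessing stage.

Streamline-count matrices are normalized by ROI size as
w_ij = c_ij / ((v_i + v_j)/2); the mean-endpoint-volume formula is a
documented choice (only "normalized by ROI size" is specified upstream).

## Cross-modal coupling and clinical statistics

Coupling between two matrices is the Pearson correlation of their strict
upper-triangle edge vectors — raw weights over all 5356 unique pairs by
default (a thresholded-union mask is available but off by default), with
the p-value from the t transform at n_edges − 2 df. Two couplings are
compared with Fisher's z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
The published cross-modal r/p values and the task-coupling z = 2.80 are
not reproducible from the text alone (the edge count n behind them is
unstated, and recomputing with n = 5356 does not reproduce the printed
z); these formulas are therefore verified against closed-form oracles
rather than against the printed numbers.

Group comparisons follow a Shapiro–Wilk gate at α = 0.05: Welch's t-test
with Cohen's d (n−1 pooling) when both groups pass, otherwise
Mann–Whitney U with rank-biserial r = 1 − 2U/(n₁n₂). Welch rather than
pooled Student is a robustness choice; with the packaged ages both round
to the same printed p = 0.61, so the published value does not
disambiguate. Mann–Whitney p-values are exact permutation probabilities
(all C(n₁+n₂, n₁) labelings, valid under ties) for n₁+n₂ ≤ 10 and
tie-corrected normal approximations above. Sex/handedness use Pearson's
chi-square without Yates correction (with the published counts this gives
p ≈ 0.91 where 0.92 is printed — documented, not treated as a target).
Multiple comparisons within a metric table use Benjamini–Hochberg FDR at
q = 0.05. Clinical correlations are tie-aware Spearman (Pearson on
mid-ranks), exact-permutation p for n ≤ 10 and the t approximation above,
with the conventional star marking (*p < 0.05, **p < 0.01).

## Pipeline orchestration and reproducibility

A master seed spawns one `numpy` SeedSequence child per stage (cohort,
structural matrices, time series, morphometry, clinical link, metric
nulls, SCN permutations) in a fixed order, so a full run — including
permutation tests and null ensembles — is reproducible, and the numbered
analysis scripts can re-run stages in isolation with identical results.
The clinical link is planted on per-patient structural global efficiency
after the metric stage, closing the loop the clinical table then
recovers.

Problem sizes used by the default run and the reproduction script: 29
subjects, 104 nodes, 300/600 volumes, 100 nulls per network, 1000 label
permutations; parameter-recovery checks use 10 seeds (coupling), 5
replicates at n = 200 patients (clinical link), and 20 replicates at
δ = 0.5 with 50 subjects per group (deficit power). Calibration checks
use 500 replicates (test type-I error) and 1000 replicates of m = 20
(FDR). These sizes were chosen so each check's Monte-Carlo error is well
inside its stated tolerance.

## Known limitations

* The five-class affiliation map and the subcortical/cerebellar node list
  are best-effort defaults; both are editable data, not code.
* Group-level SCNs at n ≈ 15 are dominated by sampling noise; permutation
  p-values are calibrated but have little power at these sizes.
* The generator's modular geometry makes cross-modal couplings uniformly
  positive at group level; absolute coupling values on synthetic data are
  not comparable to real-data values (the subject-level planted ρ_sf is
  the meaningful recovery target).
* Exact Spearman permutation at n = 10 enumerates 3.6M orderings and takes
  a few seconds; beyond n = 10 the t approximation is used.
* Mean clustering is not monotone under edge addition (connecting an
  isolated node to a triangle lowers the mean), so no such property is
  asserted; global efficiency is strictly monotone and is.
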