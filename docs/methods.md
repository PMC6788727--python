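# Methods

`voxgene` implements a multi-scale imaging-genetics analysis for a
case–control structural-MRI study design: a voxel-wise SNP association
screen on grey-matter volume (GMV), validation of the resulting candidate
genes by their co-expression interconnectedness in spatio-temporally
stratified brain developmental expression, extraction of "hot clusters"
(HCs) of voxels collectively associated with candidate genes, and
subtyping of patients by their HC GMV profiles with symptom (PANSS)
characterization.  Because cohort-level clinical data of this kind is not
generally shareable, the package is organized around a synthetic-data
generator with planted, recoverable ground truth; every downstream stage
is validated by recovering what was planted and by calibration against
nulls.

## Genotype QC

Subjects with a genotyping call rate strictly below 97% are removed;
markers are removed when missingness exceeds 5%, when the minor-allele
frequency (computed over all retained subjects, cases and controls
pooled) is ≤ 0.05, or when the Hardy–Weinberg exact test gives P ≤ 1e-6.
The HWE test enumerates all heterozygote counts compatible with the
observed allele counts in log space (the exact conditional distribution),
rather than the χ² approximation, because the 1e-6 decision threshold
sits deep in the tail where χ² is unreliable; a χ² variant is available
via `hwe_method="chi2"`.

## Voxel-wise association screen

For SNP *s* and voxel *v* the model is

    GMV_v = β0 + β1·g_s + β2·age + β3·sex + β4·edu + ε,

fit by OLS over the subjects with a non-missing call at *s* (per-test
complete cases; no imputation).  β1's two-sided t-test uses n_used − 5
degrees of freedom.  The implementation residualizes both GMV and
genotype on the covariate block (Frisch–Waugh), which reproduces the full
OLS slope, standard error and t exactly while vectorizing over all voxels
and all complete-call SNPs; the test suite verifies agreement with an
explicit normal-equations oracle and with statsmodels to 1e-8 relative
tolerance.  A gene becomes a candidate when any of its SNP × voxel tests
falls strictly below 1e-6 (configurable); no multiple-testing correction
is applied at this stage, matching the fixed-screen design.  Tests with a
constant genotype or non-positive degrees of freedom return missing
p-values.

At the default desk scale (1000 SNPs × 13 824 voxels ≈ 1.4e7 tests) a
1e-6 screen is expected to admit ~14 chance SNP–voxel pairs, so the
candidate set contains the planted genes plus a handful of false
positives — exactly as a fixed threshold behaves at scale.  Recovery
checks that assert *exact* gene sets therefore run at a smaller scale
(e.g. 40 SNPs × 8 000 voxels, expected chance discoveries ≈ 0.3), chosen
so that the probability of any contaminating false positive is small.

## Spatio-temporal co-expression networks

Expression samples are stratified by 4 brain regions (FC, SC, SM, TP) × 3
developmental stages (fetal; infancy–childhood; adolescence–adulthood).
Within a stratum, the network weight between two genes is |Pearson r| of
their expression, kept only when strictly above the threshold (0.8
default); unweighted mode binarizes surviving edges, and the merged
network pools all samples.  Zero-variance genes keep their node but carry
no edges, preserving the resampling universe.  The interconnectedness of
a gene set is the sum of surviving edge weights over its unordered pairs.

Significance is assessed by drawing `n_resamples` (default 10 000)
uniform same-size subsets from the risk-gene pool without replacement;
p = (#{null ≥ observed} + 1)/(n + 1).  The add-one correction keeps p
strictly positive and the ≥ convention counts ties toward the tail
(conservative); the plain strictly-greater fraction is available via
`strict_greater=True`.  The stability suite repeats the test across all
strata, the merged network, thresholds and both weighting modes.

## Hot clusters

Each voxel is weighted by the number of distinct SNPs significantly
associated with it.  The count is corrected for linkage disequilibrium:
within each chromosome, a voxel's significant SNPs contribute the Li–Ji
effective number of independent tests, m_eff = Σ f(λᵢ) with
f(λ) = 1[λ ≥ 1] + (λ − ⌊λ⌋), computed from the eigenvalues of their
genotype correlation matrix; chromosomes contribute additively.  This
estimator is this package's documented choice of LD correction — it
satisfies the required boundary behaviour (a perfectly correlated block
counts once, independent SNPs count fully) — and is swappable.
Eigenvalues within 1e-9 of an integer are snapped before flooring, since
f is discontinuous at integers and rank-deficient blocks land epsilon
below them.

The corrected map is smoothed with an isotropic Gaussian kernel with
σ_voxels = FWHM/(2√(2 ln 2))/voxel_size (FWHM 8 mm and 1.5 mm voxels give
σ ≈ 2.2649), zero-padded boundaries, truncated at 4σ, unit-sum kernel.
Voxels strictly above the cluster-forming threshold (default 0.2304,
treated as data-dependent; a percentile alternative is provided) are
merged into connected components.  "Sharing at least one edge or side" is
read as face-plus-edge adjacency, i.e. 18-connectivity (corner-only
contact excluded); 6 and 26 are configurable.  Clusters are ranked HC1,
HC2, … by decreasing maximum voxel weight, annotated with the genes whose
significant voxels intersect them, and labelled with the modal atlas
region (full label fractions retained).

## Subtyping and symptom characterization

Patients are represented by their mean GMV over each HC and clustered by
K-means under d(x,y) = 1 − Pearson r.  Rows are standardized to zero mean
and unit norm, making d half the squared Euclidean distance, so Lloyd
iterations with mean centroids minimize the within-group cost; 1000
random restarts are run and the minimum-cost solution kept.  Empty
clusters re-seed from the farthest point; constant feature rows are
rejected by name.  `CorrelationKMeans` follows the scikit-learn estimator
API (`fit`, `predict`, `labels_`, `inertia_`) and composes with sklearn
model selection.

The number of groups is chosen over K = 2..10 by maximizing the mean
in-group proportion (IGP): per group, the fraction of members whose
nearest other patient (under d, ties to the lowest index) shares their
label.  Ties in mean IGP resolve to the smallest K.  Two properties of
this index matter for interpretation and for test design.  First, when
groups are tightly separated, any K ≤ K_true yields IGP exactly 1 (a
merged pair of tight groups has no nearest-neighbour crossings), so the
smallest-K tie rule returns K = 2: the index cannot over-rule
under-clustering on ideally separated data.  Second, IGP distinguishes
the true K only when forcing fewer groups makes K-means split a real
group, which requires continuous within-group spread positioned so that
the 2-means boundary crosses a populated region.  The generator's
subtyping condition is designed accordingly: three group profiles on a
120° arc (span 120°, gaps 60°) in a zero-sum two-dimensional profile
subspace, with within-group noise about 0.175 of the shift magnitude and
70 patients per group.  Under that condition the IGP curve peaks at K = 3
and label agreement with truth is essentially perfect, which is what the
acceptance checks assert.

PANSS subscales are derived from the 30 items as P (7 items), N (7), G
(16), TT = P+N+G and the composite PN = P − N, with range validation and
a consistency check against any recorded subscale columns.  Group
differences per subscale are tested by permuting group labels (sizes
fixed, default 10 000 permutations): per-group means, all pairwise mean
differences, and an omnibus max-|difference| statistic are reported.  The
default p is the doubled smaller tail with add-one correction, capped at
1 — on the discrete PANSS statistics this is conservative and not exactly
uniform under the null; the one-tailed percentile mode (`tails="one"`),
which is the plain percentile of the observed value in the null, is
exactly uniform and is what the calibration tests check.  Per-HC GMV
differences (each group vs the rest) use two-sided Wilcoxon rank-sum
tests (exact for small tie-free groups) with Bonferroni correction over
the number of HCs (α/16 = 0.003125 for a 16-HC family).

## Synthetic-data generator

The generator emulates the study design end to end with defaults of 72
cases + 73 controls, 200 genes × 5 SNPs, a 24×24×24 grid at 1.5 mm (a
desk-scale stand-in for a ~4.3e5-voxel brain), and 30 expression samples
per (region, stage) stratum.

* **Genotypes** — latent-Gaussian threshold copula: per gene block, both
  haplotypes of a subject share a latent factor with loading
  √ld_block_rho (default 0.3); thresholding each SNP's latent value at
  Φ⁻¹(MAF) yields Hardy–Weinberg marginals at a MAF drawn uniformly from
  (0.1, 0.4), correlated within the block, independent across genes.
  There is no recombination map or ancestry structure — the LD knob
  exists solely to exercise the correction.
* **Covariates** — age ~ U(16, 45) years, sex ~ Bernoulli(½), education
  ~ U(6, 18) years, identically distributed in cases and controls
  (matched design).  Default covariate effects on GMV: −0.003/year age,
  +0.05 sex, 0 education.
* **GMV** — baseline 1.0 + planted sphere effects (β per minor allele;
  spheres must be disjoint so truth masks partition) + covariate terms +
  per-group shifts inside the spheres (cases only) + N(0, noise_sd²)
  voxel noise (default 0.2), floored at 0.
* **Expression** — background genes iid standard normal; a planted
  module's genes load on a shared per-sample factor with loading √ρ
  inside its stratum only.
* **PANSS** — items are 1 + round(|N(0, 2)|) + per-block group shift,
  clipped to the instrument's 1–7 range; an all-ceiling shift warns.

What the generator does **not** emulate: realistic population genetics,
spatial autocorrelation of anatomical noise, registration/segmentation
artefacts, non-Gaussian GMV distributions, covariate–genotype
confounding, or item-level PANSS correlation structure.  Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under its stated model, not robustness to those real-data
complications.

One consequence at desk scale: within planted spheres the only
case-to-case GMV variation is the discrete allele count plus small noise,
so HC features form genotype-lattice micro-clusters.  The IGP curve then
ties at 1.0 over small K and the smallest-K rule returns K = 2 for the
full end-to-end default study; subtyping recovery is therefore
demonstrated (and reported by `scripts/acceptance.py`) under the
dedicated arc-profile condition described above, where within-group
variation is continuous.

## Reproducibility and numerics

Every stage derives its random stream from the global seed through a
fixed per-stage counter (`SeedSequence([seed, stage_index])`), so
re-running one stage never shifts another's randomness; pipeline re-runs
with the same seed are bit-identical (checked on output hashes).  All
thresholds live in `PipelineConfig` and round-trip through YAML.  Strict
inequalities follow the quoted rules everywhere: call rate < 0.97
removes, MAF ≤ 0.05 removes, HWE P ≤ 1e-6 removes, screen p < 1e-6
selects, |PCC| > 0.8 keeps an edge, cluster weight > threshold survives.
Problem sizes in the test suite (e.g. 1e5 null tests for type-I
calibration, 500 replicates for uniformity checks, 20 000 resamples
against exhaustive enumeration) were chosen as the smallest sizes at
which the Monte-Carlo error bands in the assertions are meaningful.

## Known limitations

* The LD correction and the 0.2304 cluster-forming threshold are
  documented package choices for under-specified steps; both are
  configurable and should be revisited against any authoritative
  derivation.
* The IGP-maximization rule for K cannot detect under-clustering on
  perfectly separated groups (ties resolve to the smallest K by design).
* The regression screen assumes pooled cases and controls by default;
  pass a subject subset to analyse cases only.
* No population-stratification correction and no mixed models; the
  screen is plain OLS per SNP × voxel.
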