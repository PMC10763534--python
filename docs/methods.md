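# Methods

## Scope and data model

The pipeline operates on three artifacts, all aligned to one region table
whose ordered `region_id`s define matrix row order everywhere (asserted by a
fingerprint embedded in every output file):

1. per-subject regional BOLD matrices (`N_node × N_T`), grouped into the
   cohorts HC / MCI / AD;
2. a region × gene expression map per gene set;
3. optionally, a 4-D volume plus an integer label volume from which regional
   signals are extracted by label-wise voxel averaging (label 0 =
   background; regions without voxels are reported and surface downstream as
   zero-variance regions).

Time series are stored regions-in-rows, expression maps
regions-in-rows/genes-in-columns; fixing the orientation removes a silent
transpose bug class. Missing expression values drop the *gene*, never the
region, because the region set must stay aligned with the network nodes.

## Sliding windows

Windows have even length Δt and half overlap: window m starts at mΔt/2, and
only windows with t_m + Δt ≤ N_T exist — trailing samples that cannot fill a
window are not covered, and no partial windows are formed. The window count
is therefore ⌊(N_T − Δt)/(Δt/2)⌋ + 1; for the default N_T = 197, Δt = 20
(one minute of scan time at TR = 3 s) that is 18 windows. This bound is the
only reading consistent with 18 windows at those sizes; an index bound of
the form m < N_T/Δt would give 10.

## Network thresholding

The full-signal network keeps links whose two-sided Pearson p-value (t-test,
df = N_T − 2) is below α = 0.01 ("99% significance"); the critical |r| at
the defaults is 0.183. No multiple-testing correction is applied across
links — the thresholding is per-link by construction and configurable.
Networks are weighted and signed; the diagonal is excluded, masked entries
are stored as exact zeros.

Window networks inherit the full-signal mask (a link never significant
overall is never analysed in a window) and additionally require the window
correlation to reach the full-signal value. The comparison uses **absolute
values** by default (|ρ_tΔ| ≥ |ρ|): the networks carry positive and negative
weights, and a signed ≥ would discard strong negative links asymmetrically.
A signed mode is available (`threshold_mode="signed"`). The discarded
fraction is the count of reference-retained link-window slots that failed
the window rule, divided by all off-diagonal link-window slots of the
subject; it is reported per subject and averaged per group.

A region whose signal is constant *within one window* has its links zeroed
for that window (logged, not fatal); a region constant over the whole scan
is an error, since Pearson correlation is undefined for it.

## Centrality

Node strength is the signed sum of retained link weights (diagonal
excluded; the self-correlation of 1 would only add a constant). Eigenvector
centrality is the principal eigenpair of the signed weight matrix: the
largest *algebraic* eigenvalue and its unit-norm eigenvector. Because
weights can be negative, Perron–Frobenius positivity is not available, so
determinism is imposed by (a) a fixed internal pseudo-random start vector
and (b) a sign convention (sum of entries ≥ 0, first non-zero entry
positive on exact cancellation).

The solver is a shifted power iteration (shift = Frobenius norm, which
bounds the spectral radius, making the target eigenvalue dominant in the
shifted matrix). Convergence is declared when the residual ‖Wv − λv‖ falls
below 1e-12·max(‖W‖_F, 1), so the returned pair satisfies the fixed-point
equation to well below the 1e-8 contract. Degenerate spectra are detected
by deflating the converged pair and taking the Rayleigh quotient of the
remainder over a short second iteration: the Rayleigh quotient of a
symmetric matrix never exceeds its largest eigenvalue, so the estimated gap
only overestimates — an exact tie is caught immediately and raised as an
error (centrality is undefined there), while a slow-to-separate but genuine
gap never raises spuriously.

Window metrics are computed on the thresholded window matrices for both
measures; windows where a metric is undefined (empty network, tied
spectrum) are skipped with a warning, and a subject whose windows all fail
is an error. Subject profiles are window means; group profiles are subject
means.

## Gene PCA

Gene columns are z-scored across regions before decomposition
(correlation-matrix PCA) because microarray platform units differ wildly
between genes; a centering-only mode exists (`pca_scale="center"`).
Standardisation uses the sample standard deviation (ddof = 1) and is
idempotent; zero-variance genes are dropped with a warning.

The decomposition treats genes as variables and regions as observations —
a dimensional necessity, since the downstream correlation needs one value
per region. Scores and loadings come from a full SVD (scikit-learn PCA,
`svd_solver="full"`); `region_scores @ gene_loadings.T` reconstructs the
standardized map exactly at full rank, and the variance-fraction vector
always covers the full spectrum (non-increasing, summing to 1) even when
only k components are returned. Requests beyond the matrix rank are
truncated with a warning.

PCA signs are arbitrary; to make rankings reproducible, PC-1 is oriented so
its region scores correlate non-negatively with the map's per-region mean
expression, and higher components orient their largest-magnitude gene
loading positive. Region ranking sorts by signed PC-1 score, takes
⌈top_fraction · N⌉ regions per tail (13 for the default decile of 121
regions) and breaks ties by `region_id`.

## Association

The default contrast z-scores each group's regional vector across regions
and subtracts (`zdiff`): the contrast is unit-free, invariant to affine
rescaling of either profile, and exactly antisymmetric in the group order.
Z-scoring the raw difference (`diffz`) is available behind a flag. The
contrast is Pearson-correlated with z-scored PC-1 scores; p-values are
two-sided from the t-distribution with n − 2 degrees of freedom. Brain
regions are spatially autocorrelated, so the analytic df is optimistic; a
region-permutation p-value can be requested as a check, but the analytic
value is what the table reports. The full table covers
{AD/MCI, AD/HC, MCI/HC} × {strength, eigenvector} × gene sets, 6 cells per
gene set, each starred (\*\*\*\* p<1e-5, \*\*\* p<1e-4, \*\* p<0.01,
\* p<0.05); no correction is applied across cells. Cells whose contrast has
zero variance are flagged rather than dropped, keeping the table shape
stable.

Whether group profiles should be subject means or medians is not uniquely
determined by the analysis; means are used, consistent with computing
metrics "on the group's average".

## Synthetic generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline's recovery properties are demonstrated.

**BOLD.** Each subject runs an independent two-state symmetric Markov chain
(stationary start; per-step switch probability = switching_rate/(N_T − 1)).
State 0 uses the group's base covariance — equicorrelated with r₀ = 0.15 and
unit variances by default. State 1 adds the planted perturbation
Δ = ccᵀ with zeroed diagonal, where c is the group's contrast profile
(default: amplitude 0.7 on 10 targeted regions for AD, half for MCI, zero
for HC). Zeroing the diagonal leaves variances untouched so correlations
shift directly, keeps the planted difference exactly on the targeted set
(pairs with a zero entry are unperturbed), and is PSD-safe up to
max cᵢ² ≈ the smallest base eigenvalue; positive semidefiniteness is
nevertheless checked and a violation rejected with the minimum eigenvalue
in the diagnostic. Implementing the two states as {base, base + Δ} rather
than a symmetric base ± Δ pair is deliberate: with equal state occupancy a
± pair makes the group-mean covariance identical across groups, leaving the
planted difference only second-order and defeating the ground-truth
purpose. Innovations are Gaussian and serially independent within a state —
the Pearson pipeline is distribution-light, so the generator stays minimal;
no haemodynamic model, voxel-level structure or motion/physiological
artefacts are simulated.

**Genes.** Gene g's column is a_g·loading + ε with a_g ~ Uniform(0.5, 1.5)
(positive, so genes agree on the loading's sign) and ε iid Gaussian
(noise_sd = 0.1 by default). With noise 0 the map is exactly rank 1. In the
bundled cohorts the loading is the z-scored planted contrast profile
(`loading_mode="contrast"`), making the end-to-end contrast–PC association
positive by construction; `loading_mode="random"` gives the null
configuration.

All randomness flows from one explicit integer seed through numpy
`SeedSequence` spawning; identical seeds give bit-identical outputs, and
the planted vectors plus all parameters are stored in `truth.json`.

**Calibration.** The distribution of window-to-window correlation
fluctuation in real cohorts is not characterised, so the defaults are
chosen for testability rather than realism: they were fixed once, by a
pre-build Monte-Carlo sweep, such that at 30 subjects/group the planted
strength difference concentrates its 10 largest magnitudes on the 10
targeted regions and the end-to-end association is recovered in ≳ 90% of
seeds, while the null configuration stays uniform. A baseline correlation
much above ~0.2 injects a global strength fluctuation shared across regions
that swamps the planted profile at these sample sizes — worth keeping in
mind when replacing the generator's inputs with real data, where global
signal regression plays the analogous role.

## Problem sizes

Single-run demonstrations and PCA checks use the full study scale
(121 regions, 197 timepoints, Δt = 20, α = 0.01, 30 subjects/group; 71- and
13-gene maps). The repeated Monte-Carlo experiments use 60 regions
(recovery/null, 100/200 seeds) and 40 regions (strength-concentration, 50
seeds) — region count is the one dimension the recovery conditions do not
pin down, and these sizes keep the full suite fast while leaving the
per-seed effects far from threshold (recovery r ≈ 0.6–0.7 at 60 regions).

## What passing tests do and do not show

The generator's covariance-switching mechanism produces genuine
window-wise fluctuation, but real BOLD has autocorrelated noise,
heavy-tailed motion artefacts, spatially smooth parcellation-induced
dependence, and gene maps with donor structure and spatial autocorrelation.
Passing recovery and calibration tests therefore demonstrate the pipeline's
*internal* correctness — the transforms do what they claim, planted signal
of realistic magnitude survives the full chain, and the null is calibrated
under exchangeability — not that analytic p-values are calibrated on real,
spatially autocorrelated brain maps (the permutation option exists for
exactly that concern, and spatial-autocorrelation-preserving nulls are out
of scope).

## Numerical conventions

- Pearson matrices are symmetrised (0.5·(R + Rᵀ)) and clipped to [−1, 1];
  diagonals zeroed before any thresholding.
- Retention uses strict `p < α`; the boundary case p = α is masked out.
- Z-scores use ddof = 1 throughout.
- Eigen ties raise at an estimated gap below 1e-9·max(‖W‖_F, 1).
- TSV/CSV round-trips write 17 significant digits, reproducing values to
  1e-12 relative tolerance.
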