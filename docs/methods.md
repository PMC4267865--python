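# Methods

This note documents the models, estimators and numerical choices behind
`phyloinv`, and what the synthetic data do and do not emulate.

## Dated trees and distances

Trees are rooted, with branch lengths in millions of years (My), stored
as parent-pointer arrays in topological order.  Patristic distances use
`d(a, b) = depth(a) + depth(b) − 2·depth(mrca(a, b))`; the full matrix is
assembled in one post-order traversal (tip pairs straddling two child
subtrees of a node have that node as MRCA), O(n²) overall and
polytomy-safe.  Zero-length branches are permitted (they arise from rate
smoothing in dated trees); the pairwise walk therefore climbs by
topological index rather than metric depth, which is exact even when an
ancestor and its descendant sit at the same depth.  Ultrametricity is
checked as max minus min root-to-tip depth relative to the maximum
depth (default tolerance 1e−6).  Tip labels are matched to species
tables after one documented normalization (trim whitespace, spaces ↔
underscores); unmatched names are reported, never dropped silently.

## Relatedness metrics

PNND is the minimum and MPD the mean patristic distance from a focal
alien to a native set, so PNND ≤ MPD always.  MPD is deliberately
focal-species-vs-set — not the community-wide all-pairs MPD — because
the question is how far *each alien* sits from the natives.  At the plot
scale the native set is the natives co-occurring in the plot; whether
plot MPD should instead use the country pool is ambiguous in general,
and the co-occurring-natives reading is implemented and stated here.
Nearest-native ties are broken to the lexicographically smallest label
and flagged.  Plots that do not retain ≥ 1 native and ≥ 1 alien after
tree matching are excluded and tallied in a filter report, along with
occurrences of species absent from the tree.  No abundance weighting and
no null-model standardization (NRI/NTI): groups are compared on raw
distances.

## D statistic

The contrast sum `d` codes tips 0/1 and runs the branch-length-weighted
down-pass of the independent-contrasts algorithm: an internal node's
value is the 1/v-weighted average of its two daughters (daughter branch
lengths v inflated exactly as in Felsenstein's pruning), and `d` is the
sum over internal nodes of |difference between daughter values|.
Polytomies are resolved to zero-length bifurcations in deterministic
(stored-child) order first; zero-length daughter branches receive
epsilon = 1e−8 × mean positive branch length so weights stay finite.
The down-pass is linear in tip values, so null replicates are processed
as columns of one matrix in a single traversal.

The permutation null shuffles the observed labels (prevalence preserved
exactly); the Brownian-threshold null simulates unit-rate Brownian
liabilities on the tree and assigns state 1 to the k top-ranked tips
(rank thresholding, prevalence again exact).  D scales `d_obs` between
the two null means; since both anchors are estimated with the same
contrast sum, E[D] ≈ 1 under random labels and ≈ 0 under Brownian
labels *by construction*, whatever the ancestral-value estimator — this
calibration is asserted by simulation (500 replicates on a 200-tip
tree, both anchors recovered within ±0.1).  P-value orientation:
`p_random = P(d_perm ≤ d_obs)` (small when the trait is more clustered
than random) and `p_brownian = P(d_BM ≥ d_obs)` (small when less
clustered than Brownian).  A degenerate denominator (null means equal
within 1e−9 relative, e.g. on a 2-tip tree) yields a flagged NaN result
rather than an exception.  Group-wise D (all naturalized aliens,
neophytes, archaeophytes) prunes the tree to the group's tips before
computing, so tips outside the group cannot influence the result.

## Dutilleul's modified correlation test

Moran's I of each (centered) variable is computed per distance class —
13 equal-width classes on the pairwise-distance range by default, empty
classes merged downward with a warning — giving estimated spatial
correlation matrices S with unit diagonal.  With the centering matrix
B = I − 11′/n and R = B S B, the sampling variance of r is
`tr(Rx Ry) / (tr(Rx) tr(Ry))`, the effective sample size is
M = 1 + 1/var, and r is tested with F = r²(M−2)/(1−r²) on (1, M−2) df.
In the white-noise limit S → I and M → n, recovering the nominal n − 2
df (asserted within 10% by simulation); under an autocorrelated null
(independent Gaussian fields, exponential covariance with range 20 on a
100×100 domain, n = 100) the corrected test holds its 5% level within
[0.03, 0.07] while the naive Spearman test rejects at ≈ 40%.  Because
the headline correlation is Spearman-type, the correction is applied to
mid-ranks by default; raw Pearson is available by flag.  The choice of
13 classes follows common correlogram practice; both the class count and
the rank/raw choice are exposed as options since neither is canonical.

## Loess and residual hot spots

One-dimensional local regression: at each point, a weighted polynomial
of degree 2 is fitted to the ⌈span·n⌉ nearest x-neighbours with tricube
weights scaled to the neighbourhood radius (no robustness iterations;
span 0.75 by default).  Exactly quadratic data are reproduced to
machine precision at any span because the quadratic lies in the local
model space.  Integer covariates can make the neighbourhood radius
zero (all neighbours tied); weights then fall back to uniform, and the
boundary point receives a tiny positive weight so the local design
keeps full rank.  Residuals of invasive on non-invasive richness are
signed so that positive = more invasive richness than predicted.
Doubly-empty grid cells are removed (and counted) before the spatial
analyses; cells with one zero are retained.

## Trait models

Continuous trait differences are native − alien (the literal reading of
the contrast definition; the convention is stamped into the design
matrix metadata because only coefficient signs, not significance,
depend on it).  Height is log-transformed before differencing.
Categorical contrasts are 0/1 mismatch.  Life-form enters as
reference-coded dummies (most frequent class as reference) and the
block enters/leaves candidate models as a unit, counting as one
variable toward the ≤ 5 cap — splitting the factor would break its
meaning, and the cap is about model complexity.

GLMs are maximum-likelihood logistic fits (statsmodels IRLS) with
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`; AICc is the default criterion
because candidate sets reach ~20 parameters at n of a few hundred
(plain AIC by flag).  Fits showing separation (non-convergence,
|coef| > 20, or SE > 100) are excluded from averaging with a warning.
Averaging is "full": a model omitting a variable contributes a zero
coefficient with zero variance (conditional averaging by flag); the
unconditional SE is `sqrt(Σ wᵢ [varᵢ + (βᵢ − β̄)²])`, CIs use ±1.96·SE,
and relative importance is the summed Akaike weight of models containing
the variable.  Single-candidate averaging reproduces the single fit
exactly.

Country-scale group comparisons are pooled-variance two-group linear
models (t on n₁+n₂−2 df).  Plot-scale models are REML linear mixed
models with a random intercept per species and a variance component for
square nested within species, fitted with statsmodels MixedLM (lbfgs,
default tolerance) and cross-checked against lme4 in the test suite;
the fixed effect uses cell-means coding so per-group means ± SE are read
off directly.  Non-convergence is reported on the result object, never
silently replaced.  The Wilcoxon rank-sum test uses exact enumeration
when the smaller sample has ≤ 8 tie-free observations, otherwise the
normal approximation with tie correction.

## Synthetic data

The generators fix the study conditions once: a Yule (pure-birth) tree
conditioned on the tip count and rescaled to depth 450 My — the
simplest ultrametric generator, adequate because the analyses consume
only branch lengths; status counts by largest-remainder rounding of the
prevalences 1249:274:89 (so the exact study counts are reproducible),
aliens split 135:228 into archaeophytes:neophytes; invasiveness either
an exchangeable permutation (`random`, D ≈ 1) or rank-thresholded
Brownian liabilities (`brownian_threshold`, D ≈ 0, the default);
Ellenberg indicators as Brownian values discretized by rank-quantile
binning (preserving phylogenetic signal in the ordinal trait; salt
tolerance gets a zero-heavy marginal), lognormal height around a
Brownian component, an equal-rates Markov life-form, thresholded
Brownian clonality, and a change index shifted +0.7 for invasive
aliens.  A trait-driven alternative draws invasiveness from
`logit⁻¹(β·x)` with default β mirroring the moisture/fertility effect
sizes the trait analysis is built to detect (F = 0.30, N = 0.26).

Survey plots draw species by inclusion odds with species- and
square-level random intercepts (sd 0.5 on the log-odds scale, so the
mixed-model stage has real variance components to estimate); plots
failing the ≥1 native & ≥1 alien filter are resampled rather than
dropped, so requested plot counts are met exactly, and the alien base
rate is solved from λ/(1−e^{−λ}) = 1.53 so the *conditional* mean
aliens per retained plot matches the survey regime (max clipped at 12).
The hectad grid drives log-Poisson richness of both alien groups from a
shared Gaussian random field (exponential covariance, range 100 km on
10 km cells) plus independent noise; shared weight 0.98 and log-field
sd 1.0 were chosen once so realized rank congruence sits in the ~0.9
regime of national atlas data.  All generators are pure functions of
(inputs, seed); per-stage generators derive from
`SeedSequence([root_seed, stage_index])` with a fixed stage table, so
stages re-run independently and byte-identically.

What the synthetic data do *not* emulate: real floras are not Yule
trees (no rate variation, no extinction); traits are not exactly
Brownian and Ellenberg marginals are not exactly quantile-uniform;
occurrence (not abundance) is simulated, since cover data are typically
too sparse to define local invasiveness; richness is Poisson around a
log-Gaussian field rather than an accumulation of species ranges; and
there is no recording-effort bias.  Passing tests therefore demonstrate
that the estimators are correct and calibrated under their assumed
generating processes — not that any ecological conclusion about a real
flora is correct.

## Problem sizes and tolerances

Distance algebra is checked exactly (≤ 1e−9) against a brute-force
path-sum oracle on 200 random trees of ≤ 20 tips.  D calibration uses a
200-tip tree, 50 state-1 tips, 500 trait replicates per mode and 1000
randomizations per replicate; the permutation-null mean is checked
against exhaustive enumeration on 5 tips within 2%.  Dutilleul
calibration uses n = 100 locations (500 white-noise and 1000
autocorrelated-null replicates).  Model-averaging recovery uses 2 true
(|β| = 0.35–0.4) and 6 null predictors at n = 2000 over 100 replicates;
mixed-model recovery uses 100 surveys of 3000 records (75 species × 10
squares × 4 plots) with variance components 100/25/50, requiring ≤ 30%
median relative error.  The acceptance script runs the full pipeline at
study scale (1612 species, 3600 plots, 2809 grid cells) and reduced-
replicate versions of the calibrations; its problem sizes are recorded
in its output JSON.

## Known limitations

The Dutilleul correction treats correlogram estimates as plug-in truth;
with very strong autocorrelation the effective df estimate is noisy
(the test remains approximately level but conservative in the rank
variant).  The ancestral estimator in the contrast sum has known
implementation variants across the literature; the statistic is
anchored by its calibration (E[D] under the two nulls), not by matching
any one implementation's internals.  Separation-affected GLM candidates
are dropped rather than penalized, which can bias averages when
separation is common (rare at the sample sizes here).  MixedLM
occasionally reports boundary fits when a variance component is near
zero; the convergence flag is propagated.
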