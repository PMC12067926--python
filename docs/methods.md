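# Methods

This note records the models implemented in `phylotox`, the defaults and why
they were chosen, the numerical decisions, and what the simulation-based
tests do and do not establish about real data.

## Growth quantification

A well's growth curve is hourly A600 over 0–72 h. Rather than fitting a
mechanistic growth model (lag/rate/capacity parameters are ill-defined for
the non-sigmoidal curves stressed cultures produce), overall fitness is the
area under the curve. `fit_auc` fits a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) and integrates its
piecewise-polynomial form exactly over the observed span; the default
smoothing parameter is chosen per curve by generalised cross-validation, so
no per-dataset hand tuning is needed, and an explicit value can be passed
for reproducibility-sensitive batch work. Curves with exactly four points
(the validity minimum) fall back to the interpolating cubic, and exactly
constant curves integrate in closed form, since GCV is ill-posed for both.

Blank handling: readings are integrated as given by default. A per-well
baseline option (`baseline="min3"`) subtracts the minimum of the first three
readings and clips negatives at zero before fitting — useful for plate
exports that include media absorbance — but it is off by default because the
relative-growth ratio cancels any common offset-free scaling, and because
AUC of an unblanked constant-OD well should be its literal integral.

Relative growth is dAUC = mean(AUC, chemical replicates) / mean(AUC, DMSO
replicates), computed per culture × chemical; dAUC = 1 is no effect, < 1
inhibition, and log10(dAUC) = −1 corresponds to tenfold less growth than
control. Three biological replicates are expected but not enforced; fewer
trigger a logged warning, since real plates have dropouts.

Significance screening uses Dunnett's many-to-one comparison of each
chemical's AUCs against the control wells of the same culture, two-sided at
α = 0.05, with the error variance pooled across all of that culture's
groups. p-values come from the equicorrelated multivariate-*t* distribution
via `scipy.stats.dunnett` (quasi-Monte Carlo, seeded). Both directions are
tested because growth increases, though rare, occur.

## Phylogenetic signal

Trees are rooted with branch lengths; ultrametricity is not required. The
Brownian trait covariance V has V[i,j] = root-to-MRCA shared path length,
and the patristic distance satisfies d(i,j) = V[i,i] + V[j,j] − 2V[i,j]
(property-tested). A stem edge on the root is ignored; the crown defines
time zero.

**Blomberg's K** = (MSE0/MSE) / E_BM[MSE0/MSE], with MSE0 the ordinary and
MSE the V⁻¹-weighted mean squared deviation from the GLS phylogenetic mean,
and E_BM[MSE0/MSE] = (tr V − n/ΣᵢⱼV⁻¹ᵢⱼ)/(n−1). K ≈ 1 under Brownian
evolution; K → 0 for star-like traits; binary clade-aligned traits can give
K ≫ 1. The permutation test shuffles trait values across tips (999 by
default, seeded) and ranks the observed MSE — lower MSE means stronger
signal — giving p = (1 + #{MSE_perm ≤ MSE_obs})/(n_perm + 1).

**Pagel's λ** multiplies the off-diagonal entries of V; the likelihood
profile over λ ∈ [0, λ_max] (λ_max the largest value keeping V(λ) positive
definite, capped at 1.2 to detect boundary solutions) is maximised by
bounded scalar search with the mean and rate profiled out analytically.

The λ = 0 null sits on the boundary of the parameter space, and on
ultrametric trees the null MLE lands exactly on the boundary far more often
than the asymptotic half of the time (measured ≈ 80% at n = 50–400). Both
analytic LRT references — χ²₁ and the ½χ²₀+½χ²₁ boundary mixture — are
therefore strongly conservative here (realised type-I ≈ 0.005–0.02 at
nominal 0.05). Because i.i.d. tip values are exchangeable under λ = 0, the
package instead defaults to an **exact permutation reference for the LRT
statistic**: the profile likelihood is evaluated on a shared λ grid for the
observed trait and 999 tip-permutations simultaneously (one Cholesky per
grid point serves all permutations), and p is the rank of the observed
grid-LRT. This is exactly calibrated by construction (measured 0.056 at
nominal 0.05) at negligible extra cost; `p_method="chisq1"` / `"boundary"`
reproduce the analytic conventions of the comparative-methods R packages.
The reported λ̂ always comes from the continuous optimiser.

**Mantel test.** Phenotype distance is the Euclidean distance between
cultures' raw dAUC profiles across all chemicals (a log10 switch exists,
since heatmaps are usually drawn on that scale). The statistic is Kendall's
τ-b on the corresponding lower-triangle entries — rank-based because
pairwise phenotype distances are far from normal, τ-b because rounded dAUC
values can tie. The permutation test jointly permutes row/column labels of
one matrix; one-sided (greater), 9999 permutations by default, matching the
directional hypothesis of positive phylogeny–phenotype association.

**Correlogram.** Moran's I with binary weights restricted to a patristic
distance window, for 20 equal-width windows overlapping by half a window
across the observed range; the null expectation is −1/(n−1). 95% bands per
window come from 199 bootstrap resamples of tips; windows with fewer than 3
pairs are flagged and their bands suppressed. For a multi-chemical response
matrix the scalar trait is the first principal coordinate of the phenotype
distance matrix — the response suite's dominant axis — with a per-chemical
mode available by passing single columns.

**Multiple testing** is Benjamini–Hochberg step-up (via statsmodels),
applied across chemicals separately for the K family and the λ family.
Underflowed p = 0 values are clipped to the smallest positive float before
adjustment.

## Community structure

Abundance tables are samples × taxa, counts or relative; rows are
renormalised to sum to one where a metric requires it. Taxa at relative
abundance ≤ 1e-4 count as absent (configurable): species-level profilers
emit many spurious near-zero abundances, and richness, MPD and entropy are
only meaningful above a detection floor.

Bray-Curtis uses `scipy.spatial.distance`. Weighted UniFrac is computed
in-package by postorder accumulation of per-branch descendant abundances —
raw WU = Σ_b ℓ_b |A_b − B_b| — because the installed microbiome library's
diversity API floors abundances to integer counts, which is incompatible
with relative-abundance input; the normalised variant divides by the maximum
attainable value Σᵢ dᵢ(aᵢ + bᵢ) (root-to-tip depth dᵢ), bounding distances
to [0, 1]. An independent brute-force branch-enumeration oracle checks both
variants to 1e-10 in the test suite.

PCoA double-centres −½JD²J and eigendecomposes; coordinates are
eigenvectors scaled by √eigenvalue for positive eigenvalues only, while the
full spectrum (negatives included) is reported without Cailliez/Lingoes
correction. Richness is the count of detected taxa; Shannon entropy is in
nats over the renormalised detected taxa.

SES.MPD: observed MPD is the mean pairwise patristic distance among a
sample's detected taxa (optionally abundance-weighted by pᵢpⱼ; unweighted is
the default, matching the common community-phylogenetics default). The null
shuffles taxon labels on the distance matrix — equivalently draws the same
number of taxa at random from the pool — 999 times, holding richness (and
the abundance multiset, when weighted) fixed. ses = (obs − null mean)/null
sd, with a lower-tail rank p. A sample containing every pool taxon makes the
shuffle a no-op; such samples are flagged degenerate rather than given a
NaN-propagating score.

## Structure–function linkage

Community growth curves are processed by the same AUC/dAUC machinery as
isolates. Diversity metrics are averaged over the replicates of each
treatment before ordinary least-squares regression of community dAUC on the
metric (slope, r², two-sided slope p; for a single predictor r² equals the
squared Pearson correlation, property-tested). Genus fold change sums the
genus's species-level relative abundances per sample, averages over
treatment replicates, and divides by the control average, with a
pseudo-abundance ε = 1e-4 added to numerator and denominator so
compositional zeros give finite ratios; fold changes are compared on the raw
ratio scale. Monoculture-vs-community correlations are Pearson (linear) and
Spearman (monotonic), two-sided, BH-adjusted across genera separately within
each family, so adjusting one family can never alter the other.

## The simulator

The generator realises the environmental-filtering model end to end.
Defaults are the emulated study conditions: a 26-isolate panel, 23 chemical
treatments plus DMSO control of which 8 are impactful, 3 growth replicates
of hourly 72-h curves, 2 sequenced community replicates at 1e5 reads.

* **Trees**: Yule (pure birth, rate 1/time unit), stopped at the n-th
  speciation and extended by the Exp(n·rate) waiting time to the next
  event, so trees are ultrametric with no zero-length terminal branches and
  E[crown depth] = Σ_{k=2..n} 1/(rate·k) (tested against this formula).
* **Effects** live on a log-relative-growth scale; 0 = no effect. Conserved
  chemicals use clade-structured susceptibility: one monophyletic clade
  (20–50% of tips) is resistant, every other tip is inhibited at magnitude
  −2. Filtering out whole clades leaves a monophyletic set of survivors —
  the configuration in which surviving communities are phylogenetically
  clustered. (Inhibiting a small clade and sparing the rest, available as
  `mode="susceptible_clade"`, leaves survivors over-dispersed instead.) The
  remaining chemicals are inactive, mirroring a screening panel that mixes
  impactful compounds with deliberate no-impact controls; their measured
  responses are pure assay noise and should never be flagged.
* **Growth**: logistic curves (capacity 1 OD, rate 0.3/h, midpoint 24 h,
  observation noise SD 0.01) with carrying capacity multiplied by
  2·expit(effect) — equal to 1 at effect 0, approaching 0 under strong
  inhibition, and allowing rare growth increases up to 2. Community curves
  use the base-abundance-weighted mean multiplier of member taxa, so
  community yield falls exactly when abundant members are inhibited.
* **Communities**: taxon base abundances are lognormal (log-SD 1 — a
  realistic spread that still keeps most taxa above the detection floor in
  controls); under a treatment each abundance is multiplied by
  exp(strength·effect) with strength 5, renormalised, and sampled as
  multinomial reads. Strength 5 with magnitude −2 drives filtered taxa to
  ~e⁻¹⁰ of their base abundance — effectively eliminated at 1e5 reads,
  matching the observed loss of whole genera under impactful chemicals.
  The `scenario` switch applies effects as given ("conserved"),
  tip-permuted per chemical ("random" — the same filtering pressure with no
  phylogenetic structure), or not at all ("none").
* Genera are monophyletic groups obtained by repeatedly splitting the
  largest clade; every dataset ships its ground truth (effect vectors,
  filtered tips, scenario permutations, base abundances).

Simulation sizes in the test-suite studies (500 null datasets for each
calibration, 200 recovery fits at 100 tips, 100 filtering simulations at 26
tips, 20 end-to-end runs at 50 tips × 20 chemicals) were chosen to give
Monte-Carlo standard errors comfortably inside the tested bands on a single
core. Batch response-matrix construction inside the large simulation studies
passes an explicit spline smoothing parameter instead of per-curve GCV;
those studies probe signal recovery, not smoothing selection, and at noise
SD 0.01 the two choices give indistinguishable dAUC.

## What the synthetic tests do and do not show

The simulator establishes internal validity: the estimators are calibrated
under their nulls, recover known parameters, and jointly detect the
filtering mechanism through the full pipeline. It deliberately omits several
features of real data: no sequencing-error or taxonomic-misassignment model
(read counts are exact multinomials), no rare-biosphere tail flickering
around the detection threshold, no biotic interactions (effects act
independently per taxon), binary rather than graded potency, and a single
community rather than site-to-site variation. One visible consequence:
simulated richness is nearly noise-free and predicts community growth
essentially perfectly, whereas in real profiles richness is the noisiest of
the three diversity metrics and the phylogenetic metric (SES.MPD) tends to
be the strongest predictor of functional loss. The suite therefore asserts
the direction and strength of all three diversity–growth relationships and
the clustering signature, not the relative ordering of their r² values.

## Numerical notes and degenerate inputs

* Seeds: every stochastic routine takes a seed; fixed seeds are
  bit-reproducible. Quasi-Monte Carlo Dunnett p-values are seeded and stable
  to ~1e-4.
* λ optimisation: bounded scalar search, tolerance 1e-6, with endpoints
  checked explicitly so boundary optima are never missed; the permutation
  reference uses a 41-point shared λ grid (the grid is shared by observed
  and permuted traits, so exchangeability — hence exactness — is preserved
  regardless of grid resolution).
* Singular covariances (duplicate zero-length tips) raise errors carrying
  the condition number rather than returning garbage; the trait simulator
  adds 1e-12 jitter to tolerate semi-definite covariances from zero-length
  branches.
* Constant traits, all-zero samples, samples with fewer than two detected
  taxa, zero-variance predictors and absent control groups all raise typed
  errors naming the offending input; degenerate SES.MPD nulls are flagged,
  not NaN-propagated.
* Permutation p-values are (1 + r)/(n_perm + 1) and can never be zero;
  analytic p-values that underflow to zero are clipped to the smallest
  positive float before BH adjustment.
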