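# Methods

`naiveomics` implements the statistical pipeline for a time-resolved
multi-omics comparison of two chemical routes to naïve pluripotency in mouse
embryonic stem cells: dual Mek1/2 + Gsk3 inhibition (2i) and Cdk8/19
inhibition (Cdk8/19i), both measured against the serum/LIF (S/L) metastable
reference.  Four layers are modelled: an isobaric-label proteome time course
(days 0–14), an early phosphoproteome time course (hours 0–6), an endpoint
metabolome, and matched mRNA log2 ratios.  This note records the models,
their assumptions, the parameters that matter, and the design decisions
taken where the procedure was genuinely open.

## Study design assumptions

Each cell line is one labelled multiplex ("plex"), so plex and biological
replicate coincide for the proteome; the S/L reference channels live in the
same plex as the treated channels they normalise.  Treated channels are
expressed as log2 ratios against the mean of their plex's S/L channels,
which cancels any per-(feature, plex) additive batch effect exactly.  Cell
lines (n = 4) are the replication unit: every differential test is a
one-sample test of per-cell-line ratios against zero, separately per
(treatment, timepoint).  A consequence worth noting: all ratios within a
(feature, cell line) share the reference-channel noise, so borderline false
discoveries are *correlated across timepoints* — see the integration rules
below.

## Normalization

**Cyclic loess (within plex).**  For every sample pair, the trend of
M = x_i − x_j against A = (x_i + x_j)/2 is smoothed with local regression
(span 0.7) and half the fitted trend is moved from one member to the other;
all pairs are visited for 3 passes.  The pair-sum is preserved exactly, so
each plex's grand mean is invariant.  Span and pass count are package
defaults; the method is named in the upstream workflow without parameters.
Missing values are ignored pairwise; a single-sample plex is returned
unchanged with a warning.

**Empirical-Bayes batch adjustment (across plexes).**  The standard
location/scale construction: standardize features under a model holding the
treatment × timepoint covariates, estimate per-batch per-feature locations
(normal prior) and scales (inverse-gamma prior), shrink, remove, restore.
Two refinements to the usual method-of-moments hyperpriors:

* the location-prior spread τ² subtracts the sampling contribution
  mean(δ̂)/n_b from var(γ̂); when nothing is left, locations collapse to the
  common batch mean — re-running the adjustment on its own output is then a
  near no-op (the stated idempotency property);
* per-feature scale adjustment is only engaged when the dispersion of
  log δ̂ exceeds what χ² sampling alone produces; batch scales are measured
  relative to their cross-batch geometric mean so the pooled-variance
  degrees-of-freedom convention cancels instead of rescaling the data on
  every run.

Batches with fewer than 3 samples fall back to location-only adjustment.  A
batch confounded 1:1 with a covariate level is an error naming the confound.

## Moderated differential testing

Per-feature sample variances are modelled as scaled χ² draws around a prior
(d₀, s₀²) fitted by matching the mean and variance of log s² to the
theoretical scaled-F distribution (trigamma inversion by Newton iteration;
non-positive excess dispersion gives d₀ = ∞ and a z-test against s₀).  The
moderated statistic uses the posterior variance
s̃² = (d₀ s₀² + d s²)/(d₀ + d) on d₀ + d degrees of freedom.  Each
(treatment, timepoint) family is corrected by Benjamini–Hochberg
(statsmodels), and a feature is *regulated* when q < 0.05 and
|log2FC| ≥ 0.1 — the fold-change gate and FDR level of the source workflow.
The same operation, with the same gates, serves proteome, phosphopeptidoform,
metabolite (on per-cell-line ratios of imputed, centred values) and mRNA
layers; whether the 0.1 gate should apply to metabolites is not documented
upstream, so it is applied uniformly and is configurable.

## Overlap statistics

Treatment overlaps are scored with the upper-tail hypergeometric probability
P(X ≥ k) for an overlap k between a K-set and an n-set in a universe of N
quantified features, accumulated in log space (stable past p = 1e-300), plus
the representation factor rf = k·N/(K·n).  The universe is the features
quantified in both compared analyses.  The test is one-sided (enrichment) —
the use case is always "is the common set larger than chance".

## Trend clustering

Trajectories are replicate means per treatment × timepoint, z-scored per
feature with the sample (n−1) standard deviation; constant rows map to
all-zero.  By default the z-score spans the concatenated 2i + Cdk8/19i
vector, so a feature moving in only one treatment keeps that asymmetry; a
per-treatment mode is available, and the per-treatment invariant (row mean
0, sd 1) is what the tests assert.  The day-0 point (a ratio of the
reference to itself) is excluded by default.  Cluster number is chosen by
the gap statistic — W_k from k-means inertia, B = 50 uniform reference sets
over each dimension's observed range, Gap(k) = mean_b log W*_kb − log W_k,
s_k with the √(1+1/B) factor, smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1} —
and membership by seeded k-means (Lloyd, best of 25 restarts).  Per-cluster
centroids of the two treatments are compared by the two-tailed Pearson
t-transform; clusters with a constant centroid are flagged undefined rather
than scored.

## Preranked enrichment

Classic weighted (p = 1) running-sum enrichment: hits add |score|^p
normalised over the set, misses subtract 1/(N − N_hits), ES is the signed
maximum deviation.  The null is gene-set (member) permutation — the only
option for preranked input — with 1000 permutations; NES divides ES by the
mean |null ES| of matching sign, the nominal p uses the (1+r)/(1+B) form so
null p-values are uniform, and FDR is the standard pooled normalised-NES
ratio clipped to [0, 1].  Ties in scores keep stable input order (ES depends
on order, so this is documented behaviour).  Set-size window 5–500.

## Phosphoproteome: class-I sites and Gsk3 priming pairs

Sites with localization probability ≥ 0.75 (inclusive) are class I — the
conventional threshold behind the term.  The Gsk3 consensus is read on the
15-mer window: S/T at the center with S/T four residues C-terminal (the
priming position; Myc T58 → S62 fixes the direction).  A substrate call
needs the di-phosphorylated peptidoform (target + priming) to drop in 2i
(log2FC ≤ −0.5, q < 0.05 at ≥ 1 early timepoint) while the priming-only
mono form is non-decreasing or non-significant at *every* timepoint where
the di form is down.  The universal quantifier is deliberate: a parallel
loss of both forms is whole-site dephosphorylation or degradation, not
Gsk3-specific inhibition, and the existential reading admits exactly those
decoys at half-effect timepoints.  Missing mono forms yield `motif_only`
("unpaired") rather than a guess.  The fraction of motif sites whose priming
position is itself observed phosphorylated is computed on both the class-I
and the all-site universe, since the field convention is ambiguous.

## Metabolome

Features must be observed in ≥ 75 % of the samples of at least one treatment.
Missing cells are MEC (entire treatment block missing — left-censored) or
MAR (anything else).  MAR cells draw from the feature's observed
Normal(mean, sd) within the same treatment (all-treatment fallback; sd = 0
gives the deterministic mean).  MEC cells draw uniformly from
(q − 0.5, q], where q is the 2.5th percentile of the receiving sample's
observed values, so left-censored imputations never exceed the bound; the
0.5 log2 draw width is a package choice.  "2.5" is read as a percentile of
the receiving sample — the upstream tool names the bound without defining
its semantics, and this reading reproduces deterministic left-censored
behaviour; it is documented here as our interpretation, not as the original
authors' intent.  After imputation, sample medians are equalised to the
grand median of the pre-centering medians.  One whole sample may be dropped
before analysis when over half its values are missing (logged).  MAR
statistics condition on treatment rather than treatment × cell line for
sample-size robustness.

## Protein–mRNA integration

A feature diverges post-transcriptionally when the protein is regulated but
the cognate mRNA shows no change.  "No change" requires both non-significance
(q ≥ 0.05) and a magnitude below max(0.1, 3 × se(mRNA log2FC)): with 3 mRNA
replicates at realistic noise the standard error of the fold change exceeds
the 0.1 gate, so a fixed gate would reject truly-zero mRNAs about half the
time on point-estimate wobble alone.  Divergence verdicts additionally
require sustained protein regulation — at least 2 regulated timepoints and
|moderated t| ≥ 4 at the judged timepoint (the one with the largest |log2FC|)
— because shared-reference noise correlates borderline false discoveries
across timepoints and a cross-layer claim compounds two error rates.  Where
the mRNA grid is coarser, nearest-earlier timepoint mapping is used and
logged.  Subset shift reports (e.g. a mitochondrial subset) use the paired
two-sample t-test on matched per-feature (protein, mRNA) ratios, with Tukey
box summaries (whiskers at 1.5 × IQR).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's structure — 4 cell lines × one plex,
proteome days {0,1,2,4,7,10,14}, phospho hours {0,0.5,1,2,6} in 11-channel
plexes, a 3 × 4 × 4 metabolome — with baseline log2 abundances
~ Normal(25, 2), per-(feature, plex) batch offsets ~ Normal(0, 0.5),
channel noise ~ Normal(0, 0.25), and all effects additive in log2.  Planted
truth: shared-up/shared-down/treatment-specific differential fractions
(0.08 each), four trajectory shapes (monotone, transient pulse, late
plateau, early saturation; the planted direction supplies the sign, so the
canonical monotone fall is direction −1 on the monotone shape), peak
amplitudes of at least 4 × noise sd, 200 post-transcriptional features
whose mRNA effect is exactly zero, 50 Gsk3 substrate pairs (di form falling
to −1.4 log2 by 2 h in 2i, mono priming form rising), whole-site-loss and
motif-only decoys, and MAR (5 %) plus entire-condition (5 %) metabolite
missingness.  Layer sizes default to 4000 proteins, 5000 phosphosite rows
and 440 metabolites, mirroring the study's scale.  One PCG64 stream per
layer is split from the master seed in fixed order, so outputs are
bit-reproducible and layers are mutually independent.

Deliberate simplifications: no reporter-ion ratio compression or channel
interference, no intensity-dependent missingness in the proteome (it is
complete, as the study's quantified-in-all-samples matrix is), Gaussian
noise without heavy tails, planted substrate sites are always
well-localized (the configurable low-localization fraction applies to decoy
rows), and effects are time-profile-deterministic rather than stochastic
per cell line.  Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under the declared model —
not that real spectra would yield the study's exact counts, which depend on
the deposited raw data.

## Numerical choices and degenerate inputs

Hypergeometric tails via log-beta + logsumexp; trigamma inversion by Newton
from the 1/x asymptote; PCA sign fixed by making each component's
largest-magnitude loading positive; Pearson r snapped to ±1 within 1e-12;
constant-difference paired tests report p = 0 with a warning; zero-variance
vectors are errors for correlation, skips for trend screening, and
undefined flags for centroids; k-means ties and empty clusters follow
scikit-learn's Lloyd implementation; BH is statsmodels' step-up.  Round
trips through TSV are value-exact (17 significant digits on write,
round-trip float parsing on read).

## Problem sizes in the validation suite

The test suite and pipeline defaults keep full statistical faithfulness at
reduced feature counts where the check does not depend on scale: recovery
tests use 1000–5000 features per layer, calibration tests use 5000 null
features × 20 seeds and 50-seed FDR runs, and the gap-statistic check uses
200 trajectories × 20 seeds with B = 50 references.  The one-command
synthetic run executes the full default scale (4000/5000/440) end to end.

## Known limitations

The batch model is additive location/scale only; the loess normalization
assumes most features are unchanged between any sample pair and can inject
small biases when a large, locally asymmetric fraction is regulated; the
substrate caller requires the priming mono form to be quantified and makes
no call from di-form evidence alone; FDR control is per
(treatment, timepoint) family, so unions of regulated sets across many
families carry a higher aggregate error rate — the integration stage's
sustained-regulation gate exists precisely because of this.
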