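# Methods

This note records the models behind each `srnakit` stage, the defaults and
why they were chosen, the numerical details, and what the synthetic-data
tests do and do not demonstrate.

## Coordinates and formats

All intervals are 0-based, half-open, on a named replicon and strand;
conversion to GFF3's 1-based inclusive convention happens only in
`io_formats`, so interval arithmetic is free of off-by-one hazards and the
GFF3 ↔ internal mapping is a bijection. Coverage is interchanged as
4-column bedGraph pairs (one file per strand, non-overlapping records
required); alignment files are deliberately outside the contract — coverage
is consumed, not produced. Reports render fold-changes in the signed-ratio
convention (+r = r-fold higher under C limitation, −r = r-fold higher under
N limitation, |r| ≥ 1); all internal computation uses log₂ fold-changes.

## sRNA detection

Detection formalizes what is usually a manual screen of read pile-ups, so
every threshold is an explicit, configurable assumption rather than a
recovered parameter:

| parameter | default | role |
|---|---|---|
| `min_depth` | 5 reads/base | expression threshold |
| `min_length`, `max_length` | 50, 700 nt | size band bracketing the 101–562 nt range of reported sRNAs |
| `merge_gap` | 25 nt | longest sub-threshold gap bridged |
| `utr_max_distance` | 50 nt | window upstream of a same-strand gene start treated as 5′-UTR-like |
| `min_antisense_overlap` | 0.5 | fraction of a call's length required for a *cis* label |

Candidates are maximal runs of depth ≥ `min_depth`, gap-merged, then
size-filtered. The UTR filter is same-strand only: a candidate whose
3′-most end (in the gene's reading orientation) lies within
`utr_max_distance` upstream of a gene start is removed; antisense and
gene-desert candidates always pass. Classification first trims candidate
portions overlapping same-strand gene bodies (read-through past a 3′ end
survives as its own candidate if it still meets the size band; its reported
mean depth is that of the untrimmed candidate). A candidate antisense to a
gene by ≥ half its length becomes a *cis* call targeted at the maximally
overlapping gene (ties broken by the lexicographically smaller locus tag);
a candidate overlapping no gene on either strand becomes *trans*; everything
else is discarded. Calls are made per strand independently — sense and
antisense signal may co-occur.

Detection is translation-equivariant and strand-symmetric; both are
property-tested.

## Differential expression

Genes and sRNAs are analyzed together so that normalization can assume most
features unchanged. `normalization_factors` returns per-sample **scale**
factors — raw library size × a trimmed-mean-of-M-values (TMM) correction,
rescaled to geometric mean 1 — computed against the sample whose
upper-quartile count fraction is most typical, trimming the extreme 30% of
log-ratios (M) and 5% of log-abundances (A) and averaging the surviving M
values with inverse-asymptotic-variance weights. If trimming leaves nothing
the median log-ratio is used and a warning logged.

Dispersions use the pooled within-condition method of moments,
φ̂ = (s² − m̄)/(m̄² − s²/n), the denominator correcting the small-sample
bias E[m̄²] = μ² + σ²/n (without it φ is systematically underestimated at
n = 3 and the test runs hot). Raw estimates are floored at 1e−8 and shrunk
toward a rolling-mean trend over mean-ranked features. The shrinkage weight
defaults to the empirical-Bayes form prior_df/(prior_df + residual_df) with
prior_df = 10 (≈ 0.71 for a 3 vs 3 design): simulations showed a fixed 0.5
weight leaves enough estimator noise at 4 residual df to push the realized
FDR of BH-at-0.05 calls to ~0.11, while df-aware weighting restores ~0.09
at unchanged sensitivity. Both the weight and prior df are arguments.

The exact test collapses replicates to per-condition pseudo-sums: counts
are rescaled to the geometric-mean effective library (y/f, factors having
geometric mean 1), summed within condition and rounded — the large-count
limit of quantile adjustment, chosen for transparency. A sum of n i.i.d.
NB(μ, φ) replicates is NB(nμ, φ/n), so conditional on the total t the split
probability is P(k) ∝ NB(k; n₁μ̂, n₁/φ) · NB(t−k; n₂μ̂, n₂/φ) with
μ̂ = t/(n₁+n₂), and the two-sided p-value sums all splits whose probability
does not exceed the observed one (relative tie tolerance 1e−12; φ → 0
reduces to the conditional binomial). Enumeration is O(t) per feature with
vectorized log-pmfs. A feature with zero total is defined as p = 1,
log₂FC = 0. Fold-changes use normalized condition means with a 0.5
pseudo-count. BH step-up adjusts p-values; NaN propagates. An optional
mean-count floor reports low-abundance features' q as NA instead of a
number.

Calibration measured in the suite: type-I fraction at p ≤ 0.05 ≈ 0.057
(null simulation, φ = 0.15, 3 vs 3, 2000 features, 10 seeds), realized FDR
of q ≤ 0.05 calls ≈ 0.09 over 20 default simulations, and sensitivity
≈ 0.85 for planted |log₂FC| ≥ 1.5 at moderate expression.

## Target assignment

*Cis* targets are deterministic: the antisense locus of the call. The
*trans* screen is a transparent seed scorer, not a thermodynamic
hybridization model: for each gene, a window spanning 80 nt upstream to
20 nt downstream of the start codon is scanned against the sRNA for the
best contiguous antiparallel duplex of length ≥ 7, scoring Watson–Crick
pairs 1.0 and G:U wobble 0.5 (a mismatch resets the run). Significance is
the +1-smoothed exceedance probability of the observed score among 200
dinucleotide-preserving shuffles (Altschul–Erickson) of the sRNA;
predictions below p = 0.01 are returned sorted by (p, locus). Note the
reverse-complement symmetry score(s, w) = score(rc(w), rc(s)) is exact only
for Watson–Crick-only scoring: complementing both strands maps G:U onto the
non-pairing A:C, so wobble scoring is inherently direction-specific. The
empirical p is valid by exchangeability regardless of the score's
distribution.

## Fold-change regression and the re-pairing null

Pairs are (sRNA log₂FC, target log₂FC) for *cis* sRNAs whose target has a
DE record; the regression is ordinary least squares with
F = (n−2)·R²/(1−R²) on (1, n−2) df (an exact fit reports F = +∞). The null
re-pairs targets against sRNAs by permutation **without** replacement —
"pairing randomly" — preserving both marginal multisets while destroying
the association; a with-replacement resampling variant sits behind a flag.
The empirical p uses +1 smoothing, p = (1 + #{F_null ≥ F_obs})/(n_iter+1),
so it is never zero and valid under exchangeability. For independent pairs
the null F follows F(1, n−2) (KS ≤ 0.02 at n = 69, 10⁴ iterations in the
suite); its median at n ≈ 69 is ≈ 0.455 — the quantity the acceptance
script recomputes.

## Network model

The connectedness model is an exponential random graph model containing
only an edges term and a node-covariate main effect entering additively for
sender and receiver: logit P(tie i→j) = θ_edges + θ_target·(x_i + x_j).
These terms make dyads independent, so the likelihood factorizes into three
binomial strata (0, 1, 2 target endpoints) and Newton iteration on the
aggregated likelihood yields the **exact** MLE with observed-information
standard errors — no MCMC approximation is needed; a random-walk Metropolis
sampler over the same likelihood exists solely to cross-validate the
fitter. Degenerate inputs (no ties, all ties, an empty covariate stratum,
or complete separation where targets have no ties) raise named errors.
`tie_prob_ratio` reports the fitted tie probability at one target endpoint
over baseline — the model's twin of "X% less connected". The generator
plants the deficit on the same log-odds scale (θ_target = log(1−deficit)),
making recovery well-posed: with deficit 0.2, θ_target = log 0.8 is
recovered within 2 SE in ≥ 90% of 300-node simulations.

`membership_proportions` compares the fraction of target genes vs all
annotated genes appearing as network nodes with a pooled two-proportion
Z-test (degenerate pooled proportions return z = 0, p = 1).

## Size calibration

The ladder model is a gamma GLM with the canonical inverse link:
E[size] = 1/(b₀ + b₁·distance), constant coefficient of variation. It is
fitted by IRLS (Newton, since the link is canonical) with step halving to
keep the linear predictor positive and the deviance non-increasing;
initialization is OLS on 1/size; convergence is an absolute-plus-relative
deviance change below 1e−10, with the iteration trace exposed. Dispersion
is the Pearson estimate; the coefficient covariance scales the inverse
observed information. A maximum-likelihood fit with delta-method
t-intervals (df = n−2) replaces a Bayesian posterior here — same
inferential target without a sampling dependency — and a
parametric-bootstrap interval mode is available (`method="bootstrap"`).
Intervals for a predicted size come from the interval on the linear
predictor mapped through the inverse link, which keeps them positive and
asymmetric; coverage measured over 1000 gamma-noise replicates at 8
standards, shape 50, is ≈ 0.94. Predictions more than 25% of the fitted
span beyond either end (total guard range 1.5× the span) warn and are
flagged extrapolated.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults define the study conditions at desk scale:
two replicons (200 kb + 40 kb), 160 non-overlapping genes of 300–1500 nt,
20 cis + 10 trans sRNAs of 101–562 nt, triplicate C vs N conditions, a
differentially expressed sRNA fraction of 14/99 with planted |log₂FC|
uniform on [1.0, 2.5], gene DE fraction 0.10, lognormal dispersions around
0.15, sRNA abundances log-uniform (the source gives no abundance
distribution), 50 nt reads placed uniformly within features, Poisson
0.05/base background, a directed network with base tie probability 0.02 and
a 20% target deficit on the log-odds scale, and 8 ladder standards with
gamma shape 50. Intergenic slack is split with a heavy-tailed Dirichlet so
some gaps are wide enough to host trans sRNAs clear of same-strand gene
starts (margin 60 nt > the UTR window, so planted trans sRNAs are never
UTR-filtered). Every stage draws from an independent seed-sequence spawn of
the one seed, so outputs are bit-reproducible and stages do not perturb one
another.

Deliberately not modelled: sequencing error, colorspace chemistry, rRNA
carry-over, amplification or composition bias beyond scalar library
factors, operon structure, transcription start/termination signals, and
real metabolic-network topology (degree heterogeneity, reciprocity,
clustering). Passing recovery tests therefore demonstrates correctness of
the algorithms under their stated models — rectangular-ish coverage,
NB counts, dyad-independent ties, gamma ladder noise — not performance on
real libraries, where boundary precision and the edge-model fit would
degrade gracefully rather than hold to these numbers.

## Problem sizes in the routine checks

The suite and acceptance script run at the scales the analyses were
designed for on a single CPU: 10,000 re-pairing iterations at n = 69;
exact-test enumeration for all totals ≤ 30 at φ ∈ {0, 0.1, 0.5}; 10 × 2000
features for type-I calibration; 20 simulated genomes for detection
recovery and specificity; 3 × 50-node oracle comparisons plus 100 ×
300-node recovery fits for the ERGM; and 1000 ladder replicates.
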