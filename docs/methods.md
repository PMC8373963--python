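# Methods

This note documents the models and procedures `aphidweb` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The system and the analysis chain

The package targets tri-trophic data from aphid biological control:
a herbivorous host (the cotton aphid *Aphis gossypii*), primary
parasitoid wasps that parasitize it (the ecosystem-service providers),
and hyperparasitoids that attack the primary parasitoids (the
disservice providers). The observational unit is the *site-year*: one
focal field and its surrounding 1500-m landscape sector in one season.
Three kinds of inputs are joined per site-year:

1. **Detection records** — one row per mummified aphid, carrying the
   primary parasitoid identified from the mummy's DNA and zero or more
   hyperparasitoid detections.
2. **Plot surveys** — live-aphid and mummy counts per plot and sampling
   round.
3. **Landscape composition** — proportions of cotton, maize, secondary
   crops, non-crop habitat and urban cover.

## Rates

The parasitism rate (ES) is the pooled proportion of mummies among all
aphids: counts are summed over plots, points and the three sampling
rounds before dividing. Pooling (rather than averaging per-plot ratios)
is the maximum-likelihood estimate of a common binomial proportion and
keeps plots with more aphids appropriately influential. The
hyperparasitism rate (EDS) is the mean over sampled mummies of a 0/1
indicator that at least one hyperparasitoid was detected; multiple
hyperparasitoid species in one mummy do not raise its indicator. A
site-year with no aphids observed gets a missing rate (serialized as
`NA`), never a zero.

Mummies with a hyperparasitoid detection but no identified primary
parasitoid are retained as records (they inform the hyperparasitism
rate and hyperparasitoid community counts) but are excluded from the
interaction matrix, where the resource is unknown; the exclusion count
is reported in the web diagnostics.

## Weighted web metrics

The interaction matrix `b` has resources (primary parasitoids) as rows
and consumers (hyperparasitoids) as columns; `b_ik` counts individuals
of resource *i* attacked by consumer *k*. For each consumer, the Shannon
entropy (base 2) of its column distribution gives an effective number of
host species `n_N = 2^H`; analogously per resource over its row. Taxa
with a zero margin get effective number 0 and do not act in the web.
Generality `Gq` is the interaction-weighted mean of consumer effective
host numbers, vulnerability `Vq` the weighted mean of resource effective
consumer numbers, and connectance `Cq = ½(Gq + Vq)/s`, where `s` counts
species from *both* levels with at least one interaction. Two log
conventions coexist deliberately: community Shannon diversity `H'` uses
the natural log, the web entropies use log₂ with `2^H` reciprocals;
mixing them changes values.

Consequences verified by the test suite: transposing the matrix swaps
`Gq` and `Vq`; scaling all counts leaves the metrics unchanged;
`1 ≤ Gq ≤` number of acting resources (and dually for `Vq`); and the
vectorized implementation agrees with a loop-level literal transcription
of the definitions on an exhaustive sweep of small webs.

## AICc multimodel inference

Responses are modeled on the identity scale with Gaussian errors, as is
conventional for these site-level rates; an optional logit transform of
rates is deliberately not applied by default. Without a random effect
the fit is OLS; with one (typically `year`) a random-intercept mixed
model fitted by full maximum likelihood, because models with different
fixed effects are compared on likelihoods (REML likelihoods would not be
comparable). The parameter count `k` includes the intercept, slopes, the
residual variance and, for mixed models, the random-intercept variance.

`AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)`. All predictor subsets are
enumerated (pool capped at 12); candidates are models with ΔAICc < 4;
weights are `exp(-Δ/2)` normalized over candidates. Conditional model
averaging averages each coefficient over the candidate models containing
it with renormalized weights; importance is the summed weight of those
models. AICc ties are broken by fewer parameters, then lexicographic
predictor names, making reports deterministic. VIFs
(`1/(1-R²_j)` from regressing each predictor on the rest) are reported
with a warning threshold of 2 — a screen, not an exclusion rule.

## Piecewise SEM

A path model is an acyclic diagram over observed variables. All columns
are standardized (mean 0, SD 1, `n-1` denominator) and each endogenous
node is fitted by OLS on its parents, so single-parent slopes equal
Pearson correlations and all coefficients are standardized path
coefficients. No mixed structure is used inside the SEM: the data are
site-level aggregates and year effects belong upstream.

The directed-separation basis set contains one claim per non-adjacent
unordered pair with at least one endogenous member, conditioned on the
union of both nodes' parents; the claim is tested by regressing the node
later in topological order on the other plus the conditioning set.
Fisher's `C = -2 Σ ln p` is referred to χ² with `2k` degrees of freedom;
an empty basis set means the model is saturated (C = 0, not rejectable).

Pruning removes, one per round and largest p first, nonsignificant
(p ≥ α, default 0.05) edges into the ultimate response, plus the
outgoing edges of exogenous nodes that have no significant outgoing path
left; the model is refitted after every removal and each step is logged.
Pruning stops rather than disconnect the response from all predictors,
and a second pass removes nothing (idempotence is tested).

Effects toward the ultimate response are decomposed by exhaustive
directed-path enumeration: direct = the edge coefficient (0 if absent),
indirect = the sum over paths of length ≥ 2 of the product of edge
coefficients, total = direct + indirect. Enumeration is exact for the
small diagrams used here (≤ 8 nodes) and mirrors the hand arithmetic
used to report such tables (reports round to 3 decimals; full precision
is kept internally).

The package ships two reference diagrams
(`aphidweb.datasets`): the pruned ES model
(diversity → generality → richness → parasitism with β = 0.899, 0.693,
−0.524) and the pruned EDS model (richness → diversity → vulnerability ←
secondary crops; vulnerability → hyperparasitism with β = 0.778, 0.824,
−0.449, 0.514), estimated from a three-year cotton-aphid survey in
northern China. Their decomposition reproduces the published totals
(−0.524, −0.363, −0.326; 0.514, 0.424, −0.231) within ±0.001. One
footnote: the richness-on-hyperparasitism total printed in that study,
0.329, is the product of a *rounded* intermediate; the full-precision
product 0.778 × 0.824 × 0.514 = 0.3295 rounds to 0.330, which is what
this package reports.

## The synthetic-data generator

The generator's defaults emulate the study conditions end to end: 25
site-years over 2014–2016, 3 primary parasitoids with the dominant
species at 91% of individuals, 7 hyperparasitoids with ~40% on the top
species, 86 mummies per site-year, plot surveys of 3 plots × 3 rounds
with ~800 aphids per plot-visit, and five-class Dirichlet landscapes
(concentration (3.0, 4.2, 1.8, 1.2, 1.8): a cotton–maize mosaic with
moderate between-site variation).

Site-level latent variables follow the two reference diagrams as the
structural ground truth. Exogenous nodes are standard normal, except
secondary-crop cover, which is the standardized simulated cover, so the
landscape genuinely enters the causal chain. Each endogenous node is the
coefficient-weighted sum of its parents plus a Gaussian disturbance
scaled to keep unit variance (`noise_sd` rescales disturbances; at its
default of 1 the configured coefficients are exactly standardized path
coefficients). The two rate indices map to (0, 1) through logistic
links: parasitism with baseline 0.15 and logit-scale 0.4 (a moderate,
realistic biological-control level — the emulated study prints no mean
parasitism rate), hyperparasitism with baseline 0.43 (the
hyperparasitoid share of detections in that system, 934/2153) and
logit-scale 1.0, giving between-site spreads large relative to counting
noise. Observed rates then arise through the package's own estimators:
binomial mummy counts in the surveys, Bernoulli per-mummy indicators in
the records.

By default the generator produces **exact sample moments** (`empirical
= True`, the convention of covariance-SEM simulators such as lavaan's
`simulateData(..., empirical = TRUE)`): exogenous draws are standardized
within-sample and each disturbance is orthogonalized against its node's
parents, so the sample path coefficients equal the configured truth
exactly. Recovery checks therefore measure the correctness of the
standardization/fitting/decomposition machinery plus the observation
layers, not Monte-Carlo luck; the residual recovery error (~0.01–0.03 on
the two rate coefficients at 500 sites) is the documented attenuation
from the logistic link and finite counts. `empirical = False` gives
fully stochastic draws. Directed-separation p-values remain honestly
random in empirical mode (orthogonalization touches only parent–child
correlations), and the Fisher's C calibration check additionally uses an
independent, fully stochastic simulator. The disturbance variance is
floored at 1% of the node variance so that generation stays defined at
very small site counts, where the sample variance of a linear predictor
can transiently exceed 1.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: spatially explicit landscapes and spatial
autocorrelation; within-season population dynamics; year effects (sites
are exchangeable across years); detection error in the molecular assay;
and a mechanistic link from the latent community variables to the
*realized* per-record species composition. The realized web's entropy is
qualitatively tied to the latent diversities (multinomial weights are
tempered by them), but realized richness/diversity/web metrics are noisy
reflections of the latents, not calibrated equal to them. Recovery
tests therefore fit the structural model on the latent covariates
together with the *observed* rates; the fully realized site table is
exercised by the end-to-end pipeline checks, whose claims are
structural (invariants, determinism), not parameter recovery.

## Numerical and degenerate-input choices

- `0·log 0 := 0` throughout; all-zero communities and empty webs raise
  errors rather than returning 0 metrics.
- CSV round trips are exact: floats are written with `repr` and read
  with round-trip float parsing; missing values use the token `NA`.
- Zero-variance columns abort standardization with the column named;
  the pipeline drops such nodes from a path diagram with a logged
  warning (with only three primary species, realized richness can be
  constant across 25 sites).
- Perfect collinearity yields infinite VIF (reported, not masked) and a
  rank-deficiency error naming the aliased predictors in model fits.
- A claim p-value of exactly 0 makes Fisher's C infinite — a decisive
  rejection, not an error.
- All generators draw from named substreams spawned from the master
  seed (per-site substreams inside the record and survey generators),
  so enlarging a study leaves earlier sites' draws unchanged and every
  artifact is byte-reproducible under a fixed config.

## Problem sizes used in the checks

Routine suites run at the emulated study size (25 site-years). The
parameter-recovery oracle uses 500 site-years, where estimator noise is
small against the ±0.05 reporting band; the Fisher's C calibration uses
200 replicates of 200 observations; the web-metric oracle sweeps every
matrix shape up to 9 cells with entries in {0, 1, 2} exhaustively
(~35,000 webs) and samples the 12- and 16-cell shapes randomly, since
the 4×4 shape alone has 3¹⁶ ≈ 43M configurations.
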