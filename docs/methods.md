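# Methods

This note records the models, estimators, and numerical choices behind
`ppiseq`, and what the synthetic-data generator does and does not emulate.

## Growth model and count noise

A pooled competition is modelled as deterministic exponential selection on
lineage frequencies: over `t` generations a lineage with per-generation
log-fitness `s_i` moves from frequency `x_i` to
`x_i·exp(s_i t) / Σ_j x_j·exp(s_j t)`. Sequencing counts at each timepoint
are drawn per lineage from a negative binomial with mean `depth·x_i` and
variance `κ` times the mean; `κ = 1` degenerates to Poisson. The single
dispersion knob `κ` (default 2.5) stands in for the combined stochasticity
of growth bottlenecks, PCR, and sequencing — bottlenecks are not simulated
as explicit 1:8 dilutions because downstream inference only ever sees
counts. No published per-stage noise decomposition exists for this assay
type, so κ is a calibration choice: 2.5 produces the qualitative pattern
seen in real pooled screens (precise fitness estimates for high-fitness
lineages, noisy ones near the detection floor) without overwhelming a
desk-scale pool.

PCR chimeras are injected with per-pair expectation
`rate·T1·T2` (T1, T2 = pool-wide totals of the constituent single
barcodes), realised by drawing a Poisson total `rate·(ΣT1)(ΣT2)` and
assigning each chimeric read's constituents independently in proportion to
their totals — an exact multinomial thinning of the per-pair Poisson law
that can also create novel double barcodes, as real chimeras do.

### Truth-network composition

Study-condition defaults: five timepoints at 0/3/6/9/12 cumulative
generations, depth 10⁶ reads per timepoint, four replicate double barcodes
per protein pair, nine environments. Positive PPIs draw a per-pair
strength uniformly from [0.2, 0.8] per generation, held constant across
their active environments up to N(0, 0.02) environment jitter; negatives
and inactive environments draw from N(0, 0.01). Immutable pairs are active
in 8–9 of 9 environments, mutable pairs in 1–3; default composition is 5%
immutable, 15% mutable, 80% negative — mutable PPIs dominate the positive
set, as multi-condition screens observe. Spiked controls: DHFR(+) strains
at fitness 0.8 (full-length reporter), DHFR(−) at exactly the baseline 0,
ORF×untethered-fragment and random-reference pairs as negatives, and a
positive reference set drawn from the positive fitness range. Control
strains carry two barcodes each.

What the generator does **not** emulate: methotrexate pharmacology,
within-cycle growth-phase structure, diauxie, batch effects between
sequencing runs, barcode-specific PCR bias, or promiscuous proteins
(promiscuity filtering is exercised on constructed fixtures instead).
Passing tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to every artefact of real pools.

## Barcode processing

Reads are rejected if the mean Phred quality of either barcode region is
not strictly greater than 30 or if either region fails its structural
regular expression (configurable; defaults target the double-barcode
amplicon design). Surviving regions are matched against the known barcode
list at Levenshtein distance ≤ 1 via `edlib`; ties (two known barcodes at
equal minimal distance) are left unassigned rather than guessed, because a
false merge corrupts two fitness trajectories at once. Direct matching
replaces de-novo clustering: the barcode set is known by design, so
clustering would only re-derive it. Molecule counts are the number of
distinct (UMI1, UMI2) combinations per double barcode.

Chimera correction is re-fit per sample (one environment × timepoint):
ordinary least squares of observed counts against `T1·T2` over the
barcode pairs known to exist in the designed pool, whose true counts are
uncorrelated with `T1·T2`. The fitted `slope·T1·T2` is subtracted and
counts clamped at zero; the intercept (which absorbs the mean true count
of designed pairs) is estimated but not subtracted, and a negative slope
is treated as zero so correction never increases a count. The fit needs
at least 10 designed pairs. The correction is applied to UMI counts — the
same de-duplicated currency the rest of the pipeline consumes — rather
than raw read counts; chimeric molecules carry UMIs like any others, so
the linear model applies unchanged.

## Fitness estimation

Per interval `[t, t+Δ]` the expected frequency of lineage `i` is
`x_i(t)·exp((s_i − s̄(t))Δ)` with the population mean fitness
`s̄(t) = log(Σ_j x_j(t)·exp(s_j Δ))/Δ` chosen so predictions stay on the
simplex. Estimation alternates: update `s̄` from the current `{s_i}` and
the observed frequencies, then re-minimise each lineage's objective

    Σ_t (x_obs(t+Δ) − x̂_i(t+Δ))² / x̂_i(t+Δ)

over `s_i ∈ [−2, 2]` by vectorised golden-section search (60 iterations,
bracket ~10⁻¹² wide), predictions always one step ahead from the observed
counts. This is the κ-dispersed Gaussian count likelihood reduced to a
quasi-likelihood on frequencies: working on frequencies makes estimates
exactly invariant to rescaling all counts at any one timepoint (sequencing
depth is an arbitrary scale), and a constant dispersion factor then drops
out of the argmax — κ is retained for uncertainty bookkeeping only.
A uniform shift of all `s_i` is a flat direction of the model (it cancels
in `s̄`), so each iteration re-centres on the initial-frequency-weighted
mean; convergence is `max|Δs| < 10⁻⁴` (warning and best iterate on
non-convergence, which in practice occurs within ~10–20 iterations).
Initialisation is log-linear regression of pseudocounted log-frequency on
generations. After convergence, fitnesses are anchored so the DHFR(−)
control mean is zero; with no neutral set the gauge from initialisation is
kept and the omission logged.

Before estimation, lineages with fewer than three positive timepoints, no
timepoint above four reads, or fewer than 10 total reads are merged into
one aggregate trajectory that participates in estimation (it carries real
mass) but yields no per-lineage fitness. After estimation the deviation
`d = Σ_i ((pred_i − obs_i)/obs_i)²` over timepoints with positive observed
counts flags poor fits; `d ≥ 19` excludes a lineage downstream. Timepoints
with zero observed count are skipped in `d` (the merging rules make
all-zero tails rare).

## PPI calling

Per pair and environment: `f` is the mean of ≥ 2 kept replicate
fitnesses, `p` a one-sided Welch t-test of the replicates against the
pooled negative-control fitnesses (ORF×fragment and random-reference
lineages; configurable). Thresholds `(f_min, p_max)` are chosen per
environment by exhaustive grid search — `f_min` over 50 observed-`f`
quantiles, `p_max` over a 25-point log grid from 10⁻¹² to 1 — maximising
either F1 on the positive/negative reference sets (default) or recall
subject to a false-positive-rate bound (e.g. ≤ 0.1% of negative reference
pairs called). Ties break toward larger `f_min`, then smaller `p_max`.
p-values are not multiplicity-adjusted at this stage; calibrating the
threshold against negative controls plays that role. Any protein whose
pairing with an untethered fragment control is itself called positive is
blacklisted — globally by default (a protein sticky in one environment is
suspect everywhere), per-environment optionally.

## Validation-rate model

Clonal re-tests are summarised by the AUC — the sum of OD readings at or
after saturation, 40 h with methotrexate and 25 h without. A pair
validates when its replicate (AUC_MTX+ − AUC_MTX−) values beat the
negative-control wells in a one-sided Welch test at BH Q ≤ 0.05. Binary
outcomes are binned twice — on `f` (default width 0.01, ~50 observations
per bin at the ~500-retest scale) and on integer `n` — and the linear
model `v = a + b·f + c·n` is fit by OLS on the f-binned table (the
n-binned table is held out and scored by Spearman rank correlation; which
side trains is configurable). Predictions are clamped to [0, 1] because
the richness stage consumes them as retention probabilities; an unclamped
linear model can leave the unit interval.

## Mutability

Fitnesses are rescaled per environment to the span between the DHFR(−)
mean (0) and DHFR(+) mean (1), replicates averaged per tag orientation,
orientations averaged, and negative pair means clamped to zero
(measurement noise on non-interactors). A PPI's CV is the sample (n−1)
standard deviation over the mean of its normalised fitness across all
environments — zeros from measured-negative environments included,
environments where the pair was unmeasured omitted (and counted in the
log). The sample standard deviation follows the default of the standard
statistical packages. A protein's mutability score is the mean CV of its
PPIs; its neighbour score averages, over network neighbours, the
neighbour's score recomputed with the shared edge removed (neighbours
whose only PPI is the shared edge are excluded). With nine environments a
one-hot fitness vector attains the maximal CV of 3.

## Network analysis

Interaction density for an unordered GO-term pair is called PPIs over
assayed protein pairs spanning the two terms; a protein pair spanning
several term pairs counts once in each (no down-weighting — the density
is defined per term pair). Significance comes from degree-preserving
randomisation: network nodes are relabelled by proteins drawn without
replacement from the screen's universe, which preserves the degree
multiset exactly and, being injective, cannot create duplicate edges; the
one-sided Monte-Carlo p-value is `(1 + #{random ≥ observed})/(n + 1)` over
(by default) 1000 randomisations, the permutation realisation of a
one-way Fisher–Pitman test with the density itself as statistic.
Communities come from igraph's fast-greedy, walktrap, or infomap
algorithms, seeded for determinism. Gene-feature associations are Spearman
correlations between protein mutability and a feature within PPI-degree
bins (hub threshold: degree > 15), with standard deviations from 1000
bootstrap resamples of proteins drawn before binning.

## Mass-action model

If dimer abundance follows mass action, `[AB] = k_f^AB·[A][B]`, and strain
fitness is linear in the abundance of the complementary-tagged dimer, then
with homodimer fitness as an abundance proxy
`S_AB ≈ β·√(S_AA·S_BB) + α`, where β absorbs the functional-affinity
ratio, reporter proportionality, and heterozygosity. Each heterodimer with
both homodimers measured, at least four shared environments, and at least
one positive call is fit by plain OLS (heteroscedasticity deliberately
ignored); negative fitnesses are clamped to zero before the geometric mean
(the square root of a negative product is undefined, and the clamp matches
the normalisation stage). Tag orientations are pooled as extra
observations. "Explained by abundance" requires a BH-adjusted slope
q < 0.05 across heterodimers and a single-test intercept p > 0.05. A
logistic model of the explained flag on protein features (two observations
per heterodimer, one per constituent) identifies predictors of
explainability; features are fit on raw scales with standardised
coefficients reported alongside, constant features are dropped as
non-identifiable, and perfect separation falls back to an L2-regularised
fit with p-values reported as NaN.

## Richness estimation

Treating PPIs as species and environments as sites: each called cell of
the PPI×environment matrix is retained with its modeled validation rate
(de-inflating false positives), then per trial the exact accumulation
curve `value(k) = Σ_p [1 − C(E−E_p, k)/C(E, k)]` — the closed-form average
over all k-subsets of environments — and the bootstrap richness
`S_boot = S_obs + Σ_p (1 − E_p/E)^E` are computed. Defaults follow the
procedure's published shape: 32 subsampling trials, 10,000 permuted
environment orders for the empirical accumulation curves (sampled with
replacement over orderings; the exact curve is the headline statistic and
the permutation mean agrees with it up to Monte-Carlo error). Both the
mean and the median of `S_boot` over trials are reported, since either is
a defensible point summary. The estimator inherits the bootstrap's known
conservatism-in-reverse: with many single-environment species it
extrapolates ~10–15% beyond the observed count, which is exactly its
purpose.

## Orchestration and problem sizes

All stages read and write TSV/YAML contracts; `run_stage` writes a
manifest of input hashes and parameters next to each output, and all
randomness flows from configured seeds — no stage touches the wall clock
or global RNG state. Defaults encode the analysis constants: d_max 19,
validation Q ≤ 0.05, mass-action FDR 0.05, FPR bound 0.1%, 1000
randomisations, 32 richness trials, 10,000 permutations.

Tests and the acceptance script run the chain at desk scale — tens of
proteins, hundreds of pairs, depth 10⁶, nine environments — sizes chosen
so every stage (including the full end-to-end chain) re-runs from scratch
in seconds while keeping per-lineage counts in the regime the estimators
assume (hundreds to thousands of reads per lineage). The chimera-recovery
analysis uses a dedicated design — 30×30 barcodes with degrees 5–30 and
equal lineage frequencies — because slope identifiability requires the
single-barcode totals to spread widely while per-pair counts stay
uncorrelated with them; at desk-scale depth a single sample's OLS slope is
noise-limited, so recovery is assessed on the mean over 16 independent
samples, which measures the estimator's bias at depth 10⁶.

## Known limitations

- The fitness estimator assumes one-step-ahead transitions are
  conditionally independent given the previous counts; long-range
  autocorrelation from shared bottlenecks is folded into κ.
- The dynamic threshold optimises on spiked reference sets; if reference
  fitnesses are not representative of true PPIs, the operating point
  shifts.
- `S_boot` is downward-biased for richness when many species are
  moderately rare and upward-sensitive to residual false positives; the
  confidence-weighted subsampling mitigates only the latter.
- The mass-action test inherits OLS small-sample behaviour at 4–9
  environments; an insignificant slope is evidence of absence only in the
  power-limited sense.
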