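# Methods

## Robustness statistic

Robustness of strain *S* for phenotype *i* across the perturbation set
*P* is

R(S, i, P) = −(σ²/x̄) · (1/m),

the negative Fano factor of the phenotype across perturbations,
normalized by the phenotype's grand mean *m* over all strains. The
Fano factor (variance over mean) makes the statistic insensitive to a
common rescaling of the phenotype once the 1/m normalization is
applied: scaling every value of a phenotype by c > 0 scales σ² by c²
and x̄·m by c², leaving R unchanged. R is 0 exactly when the series is
constant and strictly negative otherwise.

Numerical conventions:

* **Variance** is the n−1 sample variance. The condition sets are
  small (tens of conditions), where the distinction matters; the n−1
  convention is also the default of the mainstream statistical stacks
  this kind of analysis is run in.
* **Replicates**: R is computed per replicate condition-series, then
  summarized as mean ± SEM across replicates (SEM with n−1 SD; 0 for a
  single replicate). This keeps the replicate-to-replicate spread of
  the statistic visible instead of pooling it into the condition
  variance.
* **Grand mean m** is computed once on the QC'd table (trimmed values
  gone, flagged outliers retained) and **reused unchanged** in
  group-exclusion runs, so the influence ratio R_excl/R_all reflects
  only the change in the strain's dispersion, not a shifting
  normalization.
* **Missing values** inside a condition series are dropped pairwise;
  `n_conditions_used` records how many entered each series, and series
  with fewer than 2 values are reported missing with a reason rather
  than raising.
* **Lag phase** enters R as-is. R measures consistency, not
  desirability, so no inversion is applied even though a shorter lag is
  "better".

The group-influence ratio classifies an excluded group as
`negative_impact` when the ratio is < 1 (robustness improves once the
group is removed — the group was degrading it) and
`neutral_or_positive` at ≥ 1; it is undefined when R over all
conditions is exactly 0. Excluding a group with no matching conditions
reproduces the identical computation and returns a ratio of exactly 1.

## Growth-curve phenotyping

μmax is the maximum slope of ln(signal) over sliding windows (default
5 points) fitted by ordinary least squares, keeping only windows with
r² ≥ 0.98 and positive slope; if none qualifies the well is scored
μmax = 0 with a `no_growth` flag. Windows with zero signal variance
are non-qualifying (a constant curve is "no growth", not a perfect
fit).

Blank handling: the `blank` background is an explicit parameter
defaulting to 0, i.e., the signal is treated as already
background-corrected. Subtracting an estimated blank (such as the
minimum of the early points) inflates the log-slope — d/dt ln(y−b) >
d/dt ln(y) for any b > 0 — and for curves whose early signal sits at
the blank level it destroys the exponential-phase fit entirely. Users
with a known instrument background pass it explicitly.

Lag is the tangent-intercept construction: the tangent at the steepest
window, y = a + μmax·t in ln space, intersected with the initial
ln-signal baseline and clipped at 0. The baseline is ln(inoculum
signal) when the inoculum level is known — in screens every well
starts at a fixed OD, so it usually is — and otherwise the minimum of
the first three observed points. The distinction matters for slow
growers: the Zwietering–Gompertz curve approaches its lower asymptote
slowly, so the first observed points can sit Δ above the true baseline
and bias the heuristic lag by Δ/μmax. For a well that never grew, the
convention is lag = total cultivation time, flagged `no_growth`.

Yields are endpoint quantities: ethanol yield = ethanol produced /
total sugars consumed (summed over all sugars in the medium, since
media mix hexoses and pentoses); biomass yield = ΔCDW / consumed,
where ΔCDW is final minus initial cell dry weight through the
per-strain linear OD calibration. The reported `cdw` phenotype itself
is the final CDW, matching how screens report end-of-cultivation
biomass. Residuals exceeding the initial concentration by more than
0.5 g/L (beyond assay noise) are rejected; smaller excesses are
clamped to zero consumption, and zero total consumption yields missing
values flagged `no_consumption`.

## QC rules

Trimming is value-level (a bad ethanol yield does not discard the
well's growth rate): values outside [0, upper] are removed, with upper
bounds 0.61 g/g for both yields (theoretical maximum ethanol yield on
glucose 0.51 plus a 0.1 experimental margin) and 39.6 g/L for CDW (the
maximum biomass concentration attainable from the richest medium of
such screens); growth rate and lag are unbounded above. Bounds are
inclusive — a value exactly at the theoretical maximum is admissible.
Ethanol yields measured under the ethanol perturbation group are
excluded wholesale (production and consumption cannot be separated).
Outliers beyond the per-phenotype 0.1%/99.9% quantiles (linear
interpolation between order statistics) are flagged and **retained**.
The Shapiro–Wilk check is advisory only; phenotype distributions from
such screens are skewed and multimodal, which is why every downstream
test is rank-based.

## Trade-off and group statistics

"Performance" of a strain for a phenotype is the mean over all
retained conditions and replicates. Trade-offs are Spearman
correlations (average ranks for ties, two-sided p) between per-strain
performance and per-strain R, per phenotype, plus the full 5×5
performance × robustness matrix. No multiple-testing correction is
applied; raw p-values are reported. The attached standard error is
the sample-size-based se = (1 − r²)/√(n − 1): 0 at |r| = 1,
decreasing in both n and |r|, ≈ 0.1 at |r| = 0.7 with 24 strains and
≈ 0.2 for weak correlations at similar n. Group-vs-reference
comparisons pool records across strains and use the unpaired
two-sided Mann–Whitney test with hexoses as the default reference.

The %P transfer statistic substitutes infinite values (growth only in
the second cultivation) with the dataset-wide maximum finite %P,
keeping transfer-only growers at the top of the ranking without an
undefined ratio dominating summaries; 0/0 wells are left missing
(`no_growth_both`) because they carry no improvement information.
Per-strain summaries report the mean %P across perturbations with the
SD over replicate-level means.

## Synthetic-data generator

The generator emulates the statistical structure of a microtiter
robustness screen; defaults are the study design of 24 strains × 29
conditions (groups: acids 8, hexoses 6, aldehydes 6, pentoses 5, NaCl
2, ethanol 2) × 3 replicates × 5 phenotypes = 10,440 values. The
unperturbed 20 g/L glucose comparator is included in the condition
count by default (a flag removes it); baseline phenotype levels are
μmax 0.35 1/h, lag 4 h, CDW 5 g/L, Yx 0.12 g/g, Yp 0.40 g/g — an
unstressed lab yeast.

A value is baseline(strain, phenotype) × condition effect ×
replicate noise. Replicate noise is multiplicative lognormal with
unit mean, parameterized by a CV (default 0.2 for plain tables, 0.1 in
the trade-off construction — triplicate-level technical noise), which
keeps phenotypes positive and right-skewed like real yield/rate data.
Condition effects are multiplicative and **fixed across replicates**,
as real condition responses are.

`embed_tradeoff` couples per-strain mean performance (lognormal around
the phenotype-typical level, log-sd 0.3) with the magnitude of the
analytic robustness (uniform copula marginal over 0.1–0.9, the
magnitude range robustness screens report) through a Gaussian copula
whose latent correlation 2·sin(πρ/6) gives population Spearman ρ. The
across-condition variance is realized by strain-specific sensitivities
γ to fixed standardized condition scores (right-skewed, exactly zero
mean and unit variance over the condition set), solved as
γ² = (q·m/b − cv²)/(1 + cv²) so that the analytic robustness of each
strain is exactly −q once replicate noise is included. An early
version realized the variance as iid per-value noise instead; that
couples the performance and robustness estimators through the same
skewed finite sample and biases the recovered null correlation
negative, so the fixed-score construction is the one shipped.

Growth curves are Zwietering-parameterized Gompertz in ln-signal
space: ln(y/y₀) = A_ln·exp(−exp(μe/A_ln·(λ−t)+1)) with
A_ln = ln(A/baseline), so the maximum slope of ln(y) is exactly μ and
the tangent at that point crosses the baseline at exactly t = λ —
giving analytic oracles for the estimators. Additive Gaussian reader
noise is floored at a small positive signal.

What the generator does **not** emulate: plate-geometry effects (edge
wells, evaporation), systematic batch effects, condition–phenotype
interaction structure beyond multiplicative effects, non-lognormal
heavy tails, or mechanistic inhibitor kinetics. Passing tests
demonstrate the statistical machinery recovers known structure under
these idealized conditions; they do not certify performance on data
violating them.

## Problem sizes used in the test suite

Simulation-backed checks run at the study design (24 strains, 29
conditions, 3 replicates) with 200 Monte-Carlo repetitions for
recovery experiments (500 for the group-influence neutrality check)
and 1,000 random small tables for the brute-force equivalence check —
sizes at which the Monte-Carlo standard errors are comfortably below
the tested tolerances.

## Known limitations

* The μmax/lag estimator is a sliding-window method; it underestimates
  rates when reader noise is large relative to the window length, and
  there is no model-based (nonlinear least-squares) refinement.
* The heuristic lag baseline (minimum of early points) is biased high
  for slow growers; pass the inoculum signal when it is known.
* Eq.-level robustness requires a strictly positive condition mean;
  phenotypes that can be legitimately zero across a whole series
  (e.g., no growth anywhere) are reported missing rather than scored.
* The Shapiro–Wilk p-value is approximate for n > 5000; it is used
  only as a qualitative normal/non-normal call.
* Group-vs-reference tests pool records across strains (unpaired);
  strain-stratified or paired designs are out of scope.
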