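# Methods

## Pipeline model and assumptions

The screen's measurement model is multiplicative: the raw densitometry
intensity of strain *g* on membrane *m* is treated as
`I = S_m · θ_g · (1 + ε)`, where `S_m` is a day-to-day blotting scale shared
by all 96 wells of a membrane, `θ_g` the strain's true relative vesiculation
level, and `ε` mean-zero multiplicative noise. Dividing each well by its
membrane mean cancels `S_m` exactly (the normalization is invariant to any
positive per-membrane rescaling), leaving an estimate of `θ_g` up to the
plate-composition factor, which is common to all strains when plates carry
a representative mix. Replicates — always on different membranes — are
averaged on the linear scale and analysed as `log10` scores. Averaging
before the log is the default because the replicate noise is modelled on
the linear intensity; a `log_average` switch averages per-replicate logs
instead, which is more robust to single outlier replicates but estimates
the geometric mean. Wells with nonpositive intensity (background
subtraction artifacts) are excluded from the membrane mean and treated as
missing replicates rather than producing −∞ logs; strains left with fewer
than 2 usable replicates are rejected with an audit record, not scored.

The replicate CV is `sd/mean` with the sample (n−1) sd, computed on the
unlogged normalized replicates. With mostly duplicate measurements this
statistic is biased low (E[sd] ≈ 0.80·σ at n = 2), so a collection whose
generating noise CV is 27.8% shows a mean sample CV near 22–24%; the test
suite asserts the band [0.22, 0.30] derived from the generative model.

## Growth QC

The modified Gompertz form is fit per trial on raw OD600 by bounded
nonlinear least squares (`scipy.optimize.least_squares`, trf, tolerances
1e−12), initialized from the data: `y0 = min(od)`, `A = max − min`,
`μmax = ` steepest finite-difference slope, `λ = t(steepest) − A/(2·μmax)`
clipped at 0. One restart from perturbed initials follows an optimizer
failure; persistent failure is recorded as `converged = False` and treated
as data (the trial is simply unusable), not as an exception. Raw-OD
fitting is the default because an 18-h LB plate-reader curve spans too
little dynamic range to need (or reward) log fitting; a `log_od` flag fits
ln(OD) with the same form. A flat curve has zero total sum of squares, no
definable R², and is marked unusable.

Filtering is two-stage. R² ≤ `r2_min` (default 0.7 — the boundary value
itself is filtered, matching the strict inequality of the rule) discards
trials; a strain with no usable trial is excluded as `poor_fit_all_trials`.
Then the per-strain mean rate over usable trials is compared with the
collection: strains strictly more than `n_sd` (default 1) sample standard
deviations from the mean are excluded as `rate_outlier`. The rule is
two-sided: slow growers dilute their supernatant signal, fast-looking
lysing strains inflate it. The "1 sd over the collection" band is
interpreted on per-strain mean rates; a `pooled` flag uses all per-trial
rates instead, since the phrasing of such rules is ambiguous between the
two. Note the rule only behaves like a small-percentage filter when the
empirical rate distribution is heavy-centered (a tight mode plus a far-out
defective tail); on exactly normal rates it would flag ~31.7%.

## Phenotype calling

Cutoffs are `m ± n_sd·σ` (default `n_sd = 2`) with `m`, `σ` the mean and
sample sd of log10 scores of the growth-passing collection (a flag computes
them on the full collection instead). Calls use strict inequalities; a
score exactly on a cutoff is normal. No multiple-testing correction is
applied at this stage — the rule is a plain z-cutoff — and no per-gene
variance weighting is used: one collection-wide σ, which is what makes the
cutoffs comparable across strains with different replicate counts.

## Enrichment and concordance

The hypergeometric upper tail is computed from log-gamma binomial
coefficients accumulated with a reverse cumulative `logaddexp`, exact to
~1e−13 relative against big-integer enumeration (tested exhaustively for
all universes N ≤ 60). Below the support floor the tail is set to exactly
1. Enrichment uses raw p ≤ α (default 0.05) on flat category sets: no GO
graph propagation, no correction by default (Bonferroni/BH and a
Jaccard-redundancy filter are available but never silently applied, since
published category tables are often computed against service-specific
universes that a reanalysis cannot reconstruct). The enrichment universe
in the pipeline is the tested strain list.

FCOP values are `mean_r(FM4-64/CFU)` per strain divided by the wild-type
mean ratio (≥ 3 wild-type replicates required), making wild type exactly
1. Concordance is Pearson on (log10 HTP score, log10 FCOP value) with a
one-sided p for positive association from the t distribution on n−2 df
(one-sided because the validation hypothesis is directional); Spearman is a
flag. Direction agreement counts sign matches of the two log scores, an
exact zero agreeing with either sign (measured zeros have probability ~0;
the choice only matters for constructed data).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the screen's structure: 3,905 strains (default)
arrayed row-major on 96-well membranes; lognormal membrane scale
(σ = 0.3); truncated-normal multiplicative well noise with CV 0.278
(truncated at −1 so intensities stay positive — at CV 0.278 the truncation
point is 3.6σ out and negligible); 2 replicates per strain with random
disjoint subsets of 272/138/76 strains (scaled for smaller libraries) run
3/4/5 times, each replicate on its own membrane batch; planted log10
effects of ±0.6 on 2% (over) and 2.5% (under) of genes; a 2.69%
growth-defective subpopulation assigned independently of vesiculation
effects; Gompertz growth at y0 ≈ 0.05, A ≈ 1.0, μmax ≈ 0.5 ± 0.015 OD/h,
λ ≈ 2 h, with defective strains' rates displaced by 20× the 0.015 OD/h
spread (default slow; a flag makes them fast). The 20× displacement makes
the defective subpopulation well-separated, so the 1-sd filter flags
essentially that ~2.7% — the regime a real screen's filter operates in.
FCOP replicates get CV 0.15 (a flask assay is less noisy than the
high-throughput blot) with CFU lognormal around 1e9.

Deliberately not emulated: image formation and densitometry segmentation;
spatial within-plate effects (edge evaporation, row/column gradients);
per-gene biological variance heterogeneity (one noise CV for all strains);
correlated replicate failures; annotation noise. Passing recovery tests
therefore show the statistical machinery is correct under the stated noise
model — they do not show robustness to spatial artifacts or heteroscedastic
strains, which real screens must assess with their own replicate structure.

## Problem sizes and determinism

Unit and property tests run on 96–384-strain libraries; the end-to-end
recomputation test uses 960 strains (2,880 curve fits); null-rate and
recovery checks use ten 3,800–3,905-strain collections (scoring and calling
only, no curve fitting, which keeps them fast); `scripts/acceptance.py`
runs the full 3,905-strain screen including all 11,715 fits, about a minute
on one CPU. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds reproduce identical datasets
byte-for-byte, and the pipeline itself is deterministic given its inputs.

## Known limitations

- The per-membrane normalization assumes each membrane's strain set is a
  representative sample of the collection; membranes dominated by true
  hits would bias their neighbours' normalized values. With ≤ 5% planted
  effect genes spread across plates the bias is < 1% of the mean.
- Growth rates are in OD600/h (the fitted slope on raw OD), not 1/h
  specific growth rates; they are internally consistent for the 1-sd
  filter but not unit-comparable to specific-rate tables without
  conversion.
- The 2-sd rule's false-positive rate rides on approximate normality of
  the score distribution; the null simulations land near the 4.55%
  two-sided expectation, but heavy-tailed real collections will exceed it.
- Enrichment p-values are raw; with 40 categories, ~2 false enrichments
  per screen at α = 0.05 are expected under the null, which is why the
  correction flags exist.
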