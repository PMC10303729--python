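# Methods

## Problem setting

Bulk blood or marrow DNA is a mixture of cell types, each with a
characteristic methylome. At a CpG that is (say) methylated in HSPCs and
unmethylated in every mature leukocyte lineage, the bulk β value is, to
first order, linear in the HSPC fraction. The package exploits this in two
complementary ways: a regression calibrated on mixtures of known
composition (total HSPC fraction), and a reference-based decomposition over
several cell types at once (HSC / LMPP / CMP / leukocytes). Both operate on
a handful of targeted CpGs rather than genome-wide signatures, the regime
of pyrosequencing or droplet-PCR assays.

All methylation values are held internally as β ∈ [0, 1]; targeted-assay
percentages are divided by 100 on ingest and multiplied back only for
reporting. CpG identifiers are opaque strings; no genomic coordinates are
used.

## Marker selection

For a target group T against a comparison group R (all remaining groups by
default), each CpG gets per-group means and sample standard deviations
(n − 1 denominator) and Δ = mean_T − mean_R. Candidates are ranked by

    score = |Δ| − w · max(sd_T, sd_R),     w ≥ 0, default 1.

Design choices, all configurable:

- **Worst-case spread.** The variation axis is the *larger* of the two
  group sds, not their sum or pool: a marker is unusable if either group is
  noisy.
- **Scalarization weight** w trades separation against stability; w = 1
  treats 0.01 of β-difference as worth 0.01 of spread. A Pareto-front
  report over (|Δ| ↑, max sd ↓) is available when no single weight should
  decide.
- **Ties** break by larger |Δ|, then lexicographic CpG id, making rankings
  deterministic and order-invariant.
- **Missing values**: CpGs missing in more than 20 % of either group are
  dropped (`max_missing_frac`, set 0 for strict complete-case); retained
  CpGs use available values only.

Subset-specific selection (one call per HSPC subset against the union of
the other subsets and all leukocyte groups) enforces cross-subset
uniqueness greedily: a CpG is claimed by the subset where its score is
highest, then each subset takes its top n per direction (default 3 hypo- +
3 hypermethylated → an 18-CpG design over three subsets).

Direction is defined from the sign of Δ (hyper ⇔ Δ > 0), so Δ = 0 falls to
hypo; such CpGs never rank in practice since their score is non-positive
whenever any spread exists.

## Calibration

The dilution model is ordinary least squares with intercept of the known
CD34⁺ fraction (percent, flow cytometry) on the panel β values. Nothing
fancier is warranted by the data sizes involved (a handful of dilution
points per donor source). Key decisions:

- **Separate models per source.** CD34⁺ cells from mobilized peripheral
  blood and cord blood differ in panel methylation (adult vs fetal
  hematopoiesis), so mPB and CB models are first-class and never mixed; the
  `source` label travels with the model.
- **Clamping with raw retention.** Reported predictions are clamped to
  [0, 100]; the unclamped value is always carried so a systematic offset
  (overestimation of HSPC numbers is the known failure mode) remains
  measurable.
- **Rank checking.** A rank-deficient design (constant or collinear CpGs)
  raises an error naming the culprit columns. One degenerate case is
  meaningful: a *noise-free* two-type dilution series makes every panel CpG
  an exact affine function of the mixing fraction, so any multi-CpG design
  is collinear by construction. `allow_rank_deficient=True` opts into the
  minimum-norm OLS solution for such data; fitted values are still the
  least-squares optimum, only the split of weight across CpGs is
  unidentified.
- Equal weight per dilution point; no error model on the flow-cytometry
  fractions.

Diagnostics stored on the fitted model: R², residual sd (n − p − 1), n.
Models serialize to a small JSON document (panel, intercept, per-CpG
coefficients, diagnostics).

## Deconvolution

The reference atlas A (CpG × cell type) holds mean β per type; the
"leukocytes" pseudo-type is the mean of per-group means over the mature
lineages — equal weight per group, so arbitrary reference-cohort group
sizes do not bias the column. A sample's composition is the non-negative
least-squares solution

    x* = argmin_{x ≥ 0} ‖Ax − b‖₂

computed with the Lawson–Hanson active-set algorithm (scipy). There is no
sum-to-one constraint: coefficients are reported raw, and normalization to
proportions is an explicit reporting option with the raw vector always
retained (an all-zero fit is flagged degenerate rather than divided by
zero). Solutions satisfy the KKT conditions — zero gradient on the support,
non-negative gradient off it — which the test suite checks directly, and
the objective is verified against a brute-force grid search over the
probability simplex (step 0.01) on small instances.

## Synthetic data

The generator produces the statistical structure the analysis assumes, and
only that:

- **Background CpGs** draw a baseline from a bimodal distribution (normal
  modes at 0.1 and 0.9, sd 0.04, equal weight, clamped), shared across cell
  types — background between-group differences come from sampling noise
  alone.
- **Planted markers** put the off-target baseline near the opposite mode
  and offset the target type by ±`marker_delta` (default 0.6); offsets that
  would leave [0, 1] are shrunk to fit and flagged in the truth map.
- **Replicates** jitter around type means with `within_type_sd` (default
  0.02); **measurement noise** is additive Gaussian on β (default 0.02),
  clamped to [0, 1].
- **Dilution series** mix a two-type (CD34⁺/CD34⁻) atlas along a fraction
  grid (default 0, 1, 2.5, 5, 10, 25, 50, 100 % — a generator default, not
  a measured protocol); the **leukemia cohort** (default n = 39, noise sd
  0.03) interpolates between an HSPC-like and a leukocyte reference with a
  uniformly drawn blast fraction stored as covariate.

Defaults are the study conditions used throughout the tests and the
acceptance script. Everything is driven by one integer seed through
`numpy.random.default_rng` and is bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: pyrosequencing overdispersion beyond a single
Gaussian noise knob, bisulfite-conversion failure, SNPs under probes, batch
effects, correlated biological variation between CpGs, and the epigenetic
heterogeneity of real leukemias (the simulated cohort is a clean two-state
interpolation, which is why its blast correlations sit near the top of the
plausible range).

## Evaluation

Pearson's r is the only correlation measure. Zero-variance input yields an
explicit *undefined* result (`CorrelationResult.r is None`), never a silent
NaN and never an exception, so degenerate cohorts are visible in reports.
Covariate correlations pair complete cases only and optionally report the
leave-one-out r range as a leverage-point diagnostic. The recovery report
gives RMSE, mean signed error (bias), and r on the percent scale; the
consistency check compares calibrated total-HSPC estimates against summed
NNLS subset fractions per sample (subset fractions ×100 when given on the
unit scale).

## Numerical choices

- OLS via `numpy.linalg.lstsq`; the test oracle is explicit normal
  equations, agreement to 1e−8 is enforced.
- NNLS via `scipy.optimize.nnls`; KKT tolerance 1e−8 in tests, grid-search
  oracle step 0.01.
- Normalized deconvolution fractions sum to 1 within 1e−9.
- Pearson r on constant input is undefined by decision, not by exception.
- All file I/O round-trips at full stored precision; delimiter
  auto-detected between tab and comma with an override.

## Problem sizes

The test suite and acceptance script use deliberately small instances —
200-CpG backgrounds for selection fixtures (1000 for the recovery-rate
check over 50 replicates), 40-sample cohorts for the consistency
correlation, 39 samples for the leukemia regime, 100–200 random instances
for the solver oracles — chosen as the smallest sizes at which the
measured properties are stable across seeds.

## Known limitations

- Low-abundance populations: when the cell type of interest is a small
  fraction of bulk DNA, even a perfectly specific marker moves bulk β only
  slightly, so precision is bounded by assay noise; the package reports
  unclamped values precisely so such borderline estimates are not silently
  floored.
- The selection score is one defensible scalarization of a two-criterion
  choice; rankings under other readings of the "variation" axis (pooled
  variance, sd sums) can differ, which is why the Pareto report exists.
- No cross-source transfer: an mPB-calibrated model applied to CB samples
  is out of contract.
- The NNLS atlas treats reference means as noise-free; uncertainty in the
  atlas itself is not propagated.
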