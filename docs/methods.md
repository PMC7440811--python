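# Methods

## The generative model

A DTE experiment is modeled as `n` i.i.d. wells. For one taxon with
relative abundance `r` and viability `V` in an inoculum with Poisson mean
`λ` cells/well:

1. `total_cells ~ Poisson(λ)` — serial dilution randomizes the number of
   cells pipetted into a well;
2. `taxon_cells ~ Binomial(total_cells, r)` — each cell belongs to the
   taxon independently with probability equal to its community fraction
   (no clumping: cells are assumed planktonic and independent);
3. a well is *positive* if it holds ≥1 taxon cell and *pure* if it is
   non-empty and holds only taxon cells;
4. for pure wells, `viable_cells ~ Binomial(taxon_cells, V)`; the well is
   *observed pure* (yields an isolate) if ≥1 cell is viable.

Viability here means "presently able to grow in the medium used", not
aliveness in general. Step 4 applies to pure wells only: a mixed well never
yields a pure culture even if only the focal taxon's cells grow. That is a
deliberate fidelity choice — the detection step in the lab (growth above
10⁴ cells·ml⁻¹, then 16S identification of transfers) is collapsed into
"≥1 viable cell"; no lag or detection-threshold model is included.

Because wells are i.i.d., each tally over `n` wells is exactly
`Binomial(n, q)` with

| tally          | per-well probability `q`              |
|----------------|---------------------------------------|
| positive       | `1 − e^(−λr)`                         |
| pure           | `e^(−λ)(e^(λr) − 1)`                  |
| observed pure  | `e^(−λ)(e^(λr) − e^(λr(1−V)))`        |
| singleton      | `λe^(−λ)`                             |

`bootstrap_summary` replays the well-level model per replicate;
`fast_bootstrap_summary` draws replicate counts directly from
`Binomial(n, q)`. The two are distributionally identical (KS-tested in the
suite); grid scans and campaign-wide reports use the fast path by default,
single-design summaries the generative path.

Setting `r = 1` recovers the whole-community view: "observed pure" then
means "≥1 viable cell in the well", with `q = 1 − e^(−λV)`, which is how
whole-community viability ranges are scanned.

## Randomness and reproducibility

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` substreams: generative bootstraps key each
replicate as `(seed, *context, replicate)`, grid scans key each grid point
by its index, and campaign reports key each (experiment, taxon) pair by its
sorted position. Results are therefore independent of execution order and
byte-identical across runs.

## Bootstrap summaries

Defaults follow the study conditions: B = 9,999 bootstrap replicates for
simulations and viability scans, B = 999 for design scans, 95% CIs. The CI
uses empirical order statistics at 1-indexed ranks `ceil(0.025(B+1))` and
`floor(0.975(B+1))` without interpolation — the statistic is an integer
count, and at B = 9,999 this reproduces published intervals within one
count. Fewer than 40 replicates with a 95% CI triggers a warning.

## Viability inference

`compare_actual_vs_expected` classifies an observation against the CI
simulated at V = 100% (bounds inclusive), with a deviance score
(observed − simulated median) reported only outside the CI.

`estimate_viability_range` scans V over a 0.1% grid (0.001…0.999) and
returns the smallest and largest grid points whose CI contains the
observation. Both endpoints are reported, with flags when the range touches
the grid floor (the data only cap viability from above, reported like
"0.1–15") or ceiling (full viability is consistent). Observations that no
grid V explains — over-cultivated taxa, plausibly due to cell clumping —
are flagged `inconsistent` rather than assigned V > 1.

By default each grid point uses an independent bootstrap substream; with
`common_random_numbers=True` all points share one stream, which makes the
pass/fail indicator cross the boundary once instead of flickering. The scan
boundary is a stochastic quantity either way: at B = 9,999 its standard
deviation is roughly 1–3 grid steps depending on how slowly the CI moves
with V (widest for shallow boundaries such as a single observed isolate at
moderate abundance). It is also sensitive to the third decimal of `r` —
e.g. at n = 460, λ = 2, zero observed, the exact-binomial ceiling moves
from 14.9% to 15.5% as `r` goes from 0.150 to 0.145 — so published ranges
computed from unrounded abundance tables are only reproducible to a few
grid steps from their rounded prints.

## The closed-form estimator

`button_viability` implements V = −ln(1−p)/λ with p = z/n. The standard
error is the delta-method propagation of the binomial error of p:
ASE = sqrt(p/(n(1−p)))/λ, which reproduces published ASEs to printed
precision; CV = ASE/V. Estimates above 1 are returned with an
`exceeds_unity` flag, never clamped, and p = 1 raises — these are the
documented failure modes that motivate the Monte Carlo route.

## Experiment design

"A zero is informative" is operationalized as: the bootstrapped 2.5%
quantile of the observed-pure count at V = 100% is ≥ 1, so an observation
of zero falls below the 95% CI. `wells_required` scans whole 92-well plates
(96 minus four corner controls) up to 9,200 wells; `min_informative_abundance`
scans `r` on the 0.1% grid. Both share one bootstrap substream across scan
points so the first passage is a single crossing; at the default B = 999
the answers still carry Monte Carlo noise of about ±1–2 plates / ±2 grid
steps around the exact binomial solution, matching the precision of the
procedure they emulate. Unreachable targets return `None` rather than
raising.

## Subpopulation growth model

`simulate_growth` evaluates N(t) = N₀[(1−f) + f·e^(μt)]: a fraction `f` of
cells divides at continuous per-cell rate μ (= ln2 / generation time;
a conversion helper is provided) while nondividers persist without dying.
`apparent_rate` is the least-squares slope of ln N vs t over a window — the
conventional whole-culture estimate — and is strictly below μ whenever
f < 1, converging to μ once the dividing subpopulation dominates. An
optional carrying capacity K applies the saturation
N ↦ K·N/(K + N − N₀), preserving N(0) and early exponential behaviour. The
mapping from a whole-culture rate plus a viability range back to per-cell
rates is left as a configurable fit (choose the window and invert), not a
pinned computation.

## Synthetic campaigns

`generate_campaign` emulates a multi-experiment cultivation study:
communities are symmetric Dirichlet(0.1) draws (matching the observed
rank-abundance skew — a few taxa above 5%, a long rare tail), true
viability is assigned per taxon by a rule (all-viable, or a dormant
mixture), and observed pure-well counts come from the generative model.
Defaults mirror the study scale: 17 experiments × 460 wells, λ drawn from
{1.27, 1.5, 1.56, 1.8, 1.96, 2}. Whole-community positive wells are drawn
once per experiment from Binomial(n, 1 − e^(−λV̄)) with V̄ the
abundance-weighted mean viability, since taxa are otherwise simulated one
at a time ("taxon vs rest").

What the generator does *not* emulate: sequencing (reads, primer bias, ASV
calling), abundance-estimation error, cell clumping, salinity or other
covariate effects on viability, and between-replicate compositional
variation. Passing parameter-recovery tests therefore show that the
inference is correct *under the model's assumptions*; on real data,
abundance mis-estimation and clumping shift expectations in ways the model
attributes to viability.

## Test and validation sizes

The suite validates well-level frequencies on 10⁶ simulated wells,
generative-vs-fast equivalence on 3,000–4,000 replicate pairs (two-sample
KS), CI coverage on a 480-pair synthetic campaign, and parameter recovery
on 100 forward-simulated experiments (true V = 0.5, r = 0.12, λ = 2,
n = 460; coverage ≥ 90%). Published-value checks run at the full study
conditions (B = 9,999; 0.1% grid).

## Known limitations

- Relative abundances are treated as exact; no propagation of amplicon
  sampling error into the viability CI.
- No multiple-testing adjustment across campaign-wide comparisons.
- The viability scan reports a range, not a posterior; boundary values
  inherit 1–3 grid steps of Monte Carlo noise (above).
- Design answers at B = 999 inherit ±1–2 plates of noise; the exact
  binomial solution is available in closed form and used as the test
  oracle.
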