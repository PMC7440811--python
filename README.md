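# dtecult

Modeling dilution-to-extinction (DTE) cultivation: how many axenic cultures
should a high-throughput culturing experiment yield, and what does the
shortfall say about the viability of the cells you failed to grow?

DTE cultivation dilutes a water sample until each well of a plate receives
roughly 1–3 cells, pre-isolating taxa before growth. Given the mean inoculum
size λ (cells/well, Poisson-distributed) and a taxon's relative abundance
*r* in the source community (from 16S rRNA amplicon profiles), this package
predicts the number of **positive** wells (≥1 cell of the taxon), **pure**
wells (all cells from the taxon) and **observed pure** wells (pure, with ≥1
cell *viable*, i.e. presently able to grow in the medium) — and inverts the
model to estimate viability from observed cultivation outcomes.

## The models

**Closed-form whole-community viability.** With *z* positive wells of *n*
(*p* = *z*/*n*):

    V = −ln(1 − p) / λ,     ASE = sqrt(p / (n(1 − p))) / λ

This estimator is undefined at *p* = 1 and can exceed 100% at high *p*;
both pathologies are surfaced, not hidden.

**Monte Carlo well-occupancy model.** Per well: cells ~ Poisson(λ); taxon
cells ~ Binomial(cells, *r*); for pure wells, viable cells ~
Binomial(taxon cells, *V*). Bootstrapped over 9,999 replicates, this gives
medians and 95% CIs for any tally, is valid at *p* ∈ {0, 1}, and extends to
single taxa. Because wells are i.i.d., each tally is exactly
Binomial(*n*, *q*) with a closed-form *q* (e.g. observed-pure:
*q* = e^(−λ)(e^(λr) − e^(λr(1−V)))) — an equivalent fast path used for grid
scans.

**Viability inference.** A taxon whose observed pure-well count falls below
the 95% CI simulated at *V* = 100% is cultured less often than its abundance
predicts. Scanning *V* over a 0.1% grid yields the range of viabilities
whose CI contains the observation — for example, an abundant taxon with
zero isolates gets a viability *ceiling*.

**Experiment design.** The same machinery sizes future experiments: the
minimum abundance at which zero isolates is statistically informative, and
the number of 92-well plates needed to expect at least one isolate.

**Subpopulation growth.** A deterministic model
N(t) = N₀[(1−f) + f·e^(μt)] showing that a culture where only a fraction
*f* of cells divides still yields log-linear growth curves whose apparent
rate understates the per-cell rate μ of the dividing subpopulation.

## Worked example

A 460-well experiment at λ = 1.27 cells/well returned 15 positive wells;
one taxon comprised 15% of the inoculum community yet yielded zero isolates:

```python
import dtecult as d

cfg = d.RunConfig(rng_seed=42)           # 9,999 bootstraps, 95% CI, 0.1% grid

est = d.button_viability(15, 460, 1.27)  # closed-form whole-community V
# V = 2.6%  ASE = 0.67%  CV = 0.258

s = d.bootstrap_summary(d.WellPlateDesign(460, 2.0), 0.145, 1.0, cfg)
# expected isolates at V=100%: median 21, 95% CI [13, 30]

tax = d.TaxonRecord("ARD2c", "ASV7629", 0.15, 0)   # observed: 0 pure wells
vr = d.estimate_viability_range(d.WellPlateDesign(460, 2.0), tax, cfg,
                                common_random_numbers=True)
# viability range consistent with 0 isolates: 0.1% - 14.7% (floor=True)

ps = d.predicted_isolates(800, 2.0, 0.10, 0.15, cfg)
# 800 wells at r=10%, V=15%: median 4 isolates, 95% CI [1, 8]
```

Reading: although 13–30 isolates were expected if every cell could grow,
zero were observed — that observation is only explainable if at most ~15%
of the taxon's cells were viable. Planning a re-isolation attempt at 10%
abundance and 15% viability, 800 wells should yield about 4 isolates.

The same operations are available from the shell:

```sh
dte button --n 460 --z 15 --lambda 1.27
dte simulate --wells 460 --lambda 2 --abundance 0.145 --viability 1 --seed 42
dte estimate-viability --experiments exp.tsv --taxa taxa.tsv --seed 42
dte design-wells --abundance 0.01 --lambda 2 --viability 1
dte make-fixtures --experiments 17 --wells 460 --taxa 100 --seed 11 --out-dir fixtures/
```

All tables are plain TSV (fractional abundances in [0, 1]; percent inputs
are rejected). `dte make-fixtures` writes synthetic campaigns with known
ground-truth viability for estimator validation.

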