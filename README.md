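# fishwarm

Do riverine fish populations increase with warming near the poleward
(cool) edge of their species' range and decline near the equatorward
(warm) edge?  `fishwarm` packages that question as a reusable analysis
pipeline for community abundance time series: it cleans and zero-fills
survey records, converts monthly air temperatures to stream temperatures,
derives species range limits from occurrence points, reduces every
population to a binary temperature response, and fits binomial mixed
models relating that response to the population's position in the species
range.  A synthetic-data generator with known ground truth stands in for
the survey, climate, occurrence and trait databases, so the entire chain
is verifiable by parameter recovery.

It is aimed at ecologists and biostatisticians who want the method — and
its estimators — as importable, tested Python rather than a one-off
analysis script.

## The model

Each population (one species in one community time series) is classified
by the sign of the least-squares slope of its z-scored abundance on
same-year water temperature: response = 1 if abundance rises with warming,
0 otherwise.  Water temperature comes from monthly maximum air temperature
via the logistic transfer

```
T_water = 32 / (1 + exp(−0.13 · T_air + 1.94))        (°C, bounded by 32)
```

applied month-wise before computing the annual mean (`t_avg`) and maximum
(`t_max`) of the monthly values.  The population's location in its species
range is

```
position = (|latitude| − equatorward limit) / (poleward limit − equatorward limit)
```

with limits taken as the 1st/99th percentiles of the species' occurrence
latitudes.  The headline model is then a binomial GLMM with logit link,

```
logit P(response = 1) = β0 + β_pos · position + u_species,   u_species ~ N(0, σ²)
```

fitted per temperature variable and per duration subset (series spanning
10+/20+/30+ years); β_pos > 0 means poleward populations are more likely
to benefit from warming.  The marginal likelihood is maximised with a
Laplace approximation (optional adaptive Gauss–Hermite refinement) written
against a numerically verifiable likelihood; companion models add
elevation, trait × position interactions, a hemisphere contrast, a
continuous-slope sensitivity analysis, and the site-level warming-trend
LMM `temperature ~ year + (1 | site)`.

## Worked example

`examples/simulate_and_recover.py` generates one synthetic study (150
species, 3,000 series, β0 = −0.3, β_pos = 0.6, σ = 0.8) and refits the
position model to the realized response signs:

```
     term  estimate       se         z            p
intercept -0.406229 0.104189 -3.898980 9.659871e-05
 position  0.839180 0.149190  5.624897 1.856191e-08
random-intercept SD: 0.757  (truth 0.8)
log-likelihood: -1979.9  over 3000 series, 150 species
```

The position estimate (0.84 ± 0.15) and intercept (−0.41 ± 0.10) sit
within two standard errors of the generating values for this seed, and the
species-level SD is recovered at 0.757.  The predicted population-level
probability of a positive response rises from 0.40 at the equatorward edge
to 0.61 at the poleward edge — the sign-switching pattern the model is
built to detect.

Other narrative examples: `examples/transfer_function.py` (the air-to-water
curve and why conversion precedes aggregation), `examples/range_positions.py`
(tail-trimmed range limits and site positions), and
`examples/full_pipeline.py` (the end-to-end run on a ~500-series study,
writing the variable × duration effect table).

A thin CLI wraps the same code:

```
fishwarm simulate --preset small --seed 2 --out data/
fishwarm run --input-dir data/ --out run/ --models position --temperature-variable t_avg
fishwarm report run/
```

## Layout

```
src/fishwarm/
  synthetic.py     generator: five input tables + ground truth
  ingest.py        readers, averaging, zero-fill, inclusion rules
  climate.py       air-to-water transfer, annual aggregation, warming trend
  ranges.py        occurrence trimming, range limits, positions
  response.py      z-scoring, slope classification, modeling table
  mixedmodels.py   binomial GLMM (Laplace/AGQ), LMMs, predictions
  pipeline.py      orchestration, artifacts, provenance
  cli.py           typer entry points
docs/methods.md    models, generator, numerics, limitations
```
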