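# habvalue

Valuing breeding habitats for itinerant colonial breeders — birds (or other
taxa) that form dense breeding colonies but do not reuse the same sites every
year. For such species, comparing habitats by reproductive success alone is
misleading: a substrate whose colonies fledge many chicks but that stands
empty most years may contribute less to the regional population than a
modestly productive substrate that is occupied almost always. `habvalue`
computes a **time-averaged reproductive output** per habitat substrate from
three routinely collected data streams: site-by-year presence/absence
surveys, colony sizes, and per-colony reproductive success. The motivating
system is the Tricolored Blackbird (*Agelaius tricolor*), a Californian
songbird of conservation concern that breeds itinerantly in cattail marshes,
Himalayan blackberry, stinging nettles, thistles, triticale grain fields and
other substrates.

## What it computes

**Occupancy and turnover.** Sites are scored annually as occupied,
unoccupied, or unknown (not surveyed). A *cessation of use* is a site
occupied in year *t*−1 and surveyed but unoccupied in year *t*; a
*colonization* is a known-vacant site that hosts a colony in year *t*.
Denominators count only *possible* events (both endpoints known), which
avoids censoring bias from unmonitored years. Per-substrate rates carry
exact (Clopper–Pearson) binomial confidence intervals, and differences are
tested with a logit-link binomial mixed model (random year intercept)
fitted by Gauss–Hermite marginal maximum likelihood, with ANOVA-style sums
of squares and partial eta-squared h² = SS_effect/(SS_effect+SS_error).

**Colony longevity.** Runs of consecutive occupied years form censored
spells analysed with a Weibull accelerated-failure-time model,

    log T = μ_substrate + σ·W,    S(t) = exp(−(t/e^{μ})^{1/σ}),

fitted by explicit censored maximum likelihood (density terms for observed
cessations, survivor terms for censored spells). σ < 1 means the hazard of
a colony ceasing use declines with colony age. Nested models are compared
with likelihood-ratio tests.

**Reproduction.** RS is chicks per nest including failures; RSS is chicks
per *successful* nest; the two satisfy RS = RSS · prop_successful exactly.
Colony sizes in birds convert to nests by ×2/3 (each two nests have three
birds, as one male breeds with two females on average), and back by ×1.5.
Substrate effects are fitted with a linear mixed model (colony random
intercept), screening observer and year terms by AICc.

**The habitat-value index.** For each substrate, predicted chicks per
average colony is x = RS · (2/3) · birds, with delta-method standard
deviation x·√(s₁² + s₂²) from the proportional SDs of colony size (s₁) and
RS (s₂). Multiplying by occupancy gives chicks per site per year — the
quantity that ranks substrates by conservation value.

**Synthetic surveys.** A metapopulation generator drives each site through
a two-state Markov chain (cessation probability e, colonization probability
c; long-run occupancy c/(c+e)), draws lognormal colony sizes and
zero-inflated nest outcomes, and hides site-years at random to emulate
incomplete monitoring. Ground truth is retained, so every pipeline stage is
testable by parameter recovery.

## Worked example

```python
import pandas as pd
import habvalue as hv
from habvalue.habitat_value import decadal_summary, habitat_value_frame
from habvalue.synthetic_data import SimulationConfig, simulate_metapopulation

cfg = SimulationConfig(n_sites=120, seed=1)          # default study conditions
truth, survey, repro = simulate_metapopulation(cfg)

series = hv.build_occupancy_series(survey)
rates = hv.substrate_turnover_rates(hv.score_transitions(series), series)
aft = hv.fit_weibull_aft(hv.extract_spells(series))
print(aft.summary())
```

```
Weibull AFT (censored maximum likelihood)
events = 218, censored = 592, logLik = -499.466
scale sigma = 0.5421 (shape 1/sigma = 1.845)

                  term  estimate     se       z      p
             Intercept    1.3209 0.0881 14.9890 0.0000
 substrate[blackberry]   -0.0968 0.1213 -0.7982 0.4248
substrate[grain-field]   -0.7149 0.1123 -6.3672 0.0000
     substrate[nettle]    1.3329 0.2278  5.8516 0.0000
    substrate[thistle]   -0.4552 0.1169 -3.8945 0.0001
     substrate[willow]    0.6046 0.1395  4.3330 0.0000
```

σ ≈ 0.54 < 1: colonies that survive their first year become less likely to
leave. The intercept is the log-scale longevity of the reference substrate
(cattail marsh); grain-field colonies are markedly shorter-lived
(−0.71 on log duration), nettle colonies far longer-lived. Composing the
index:

```python
rs_sum = hv.substrate_rs_summaries(repro)
sizes = decadal_summary(pd.DataFrame({
    "substrate": [r.substrate for r in repro],
    "year": [r.year for r in repro],
    "n_birds": [r.n_breeding_birds for r in repro]}))[1]
values, skipped = hv.habitat_value_table(rs_sum, sizes, rates)
print(habitat_value_frame(values).round(2).to_string(index=False))
```

```
    substrate  rs_mean  mean_colony_birds  occupancy  chicks_per_colony  chicks_per_site_year
       nettle     1.65             231.57       0.50             254.42                127.95
   blackberry     1.76             283.67       0.29             333.04                 96.68
  grain-field     0.46            1000.82       0.21             307.91                 63.47
cattail-marsh     0.65             222.54       0.30              95.89                 28.78
      thistle     0.60             300.24       0.23             120.80                 27.19
       willow     0.59             121.95       0.44              47.67                 21.10
```

Grain-field colonies are by far the largest (~1000 birds) and third in raw
chick production per colony, yet occupancy-adjustment drops them well below
nettles: big colonies in an ephemeral, frequently harvested substrate
contribute less per site over time than small, persistent nettle colonies.

A command-line interface mirrors the library:

```sh
habvalue simulate --seed 1 --out-dir fixtures/
habvalue run-all --survey fixtures/survey.csv --out-dir results/
```

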