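# otochron

Growth analysis for otolith-increment biochronologies: crossed
random-effects mixed models, sliding-window climate signal selection, and
individual thermal plasticity, with a synthetic-data generator that carries
known truth through every stage.

## The problem

Annual increments in fish otoliths record each individual's growth history.
Pooling thousands of archived otoliths yields a biochronology — a
century-scale growth series — but the interesting biology is hierarchical:
growth is dominated by age, shaped by who the fish is (persistent
individual quality), when it grew (shared year anomalies), and when it was
born (cohort effects), and only then by environment.  With repeated
measurements per fish one can go further and split a temperature covariate
into *within-individual* effects (one fish's plastic response across its
own warmer and colder years) and *among-individual* effects (do fish that
lived in warmer water grow differently?), and ask whether individuals
differ in their thermal reaction-norm slopes — individual plasticity — and
whether the spread of those slopes changes between cohorts.

## The model

For log increment width $y_{ijkl}$ of fish $i$ at age $j$ in year $k$ from
cohort $l$:

$$
y_{ijkl} = \alpha_0 + \alpha_i^F + \alpha_k^Y + \alpha_l^C
 + (\beta_1 + b_{1i}^F + b_{1k}^Y + b_{1l}^C)\,x_j
 + (\beta_w + b_{wi}^F)(x_{ik} - \bar x_{i})
 + \beta_A \bar x_{i} + f(\cdot) + \varepsilon_{ijkl}
$$

with $x_j$ centred log age, $x_{ik}$ the windowed temperature, $\bar x_i$
the fish's lifetime mean, correlated (intercept, age-slope) pairs per
grouping factor, an independent fish-level thermal slope
$b_{wi}^F \sim N(0,\sigma_F^2)$, and Gaussian residuals.  Estimation is
REML/ML over a profiled deviance with the relative covariance factors in
log-Cholesky form; the fish block of the mixed-model equations is
eliminated analytically (one small block per fish), so fits with thousands
of fish take seconds.  A dense brute-force likelihood doubles as an
independent oracle in the tests.

Around the model sit the protocol stages: AICc-based selection of random
and fixed structure, a 24-month sliding-window scan for the climate signal
with a permutation (randomization) null, within-group centering, BLUP
extraction of the year/cohort chronology, percent-change back-
transformation of effects, and Pearson correlations of per-cohort
plasticity variance against the cohort's mean environment.

## Worked example

```sh
python examples/01_simulate_and_fit.py
```

prints (abridged):

```
1511 increments from 200 fish

age slope: -0.633 (generated at -0.645) CI [-0.671, -0.595]
residual variance: 0.0559 (generated at 0.056)
  fish_id  intercept variance 0.0059
  year     intercept variance 0.0008
  cohort   intercept variance 0.0005
```

The fitted age slope recovers the generating ontogenetic decline and its
95% CI covers the truth; the variance components separate individual,
year, and cohort contributions to log-width variance.  The other examples
cover the window scan (`02`, finds the planted April window, 8 months back
from December, with randomization percentile at its 1/100 floor), the
within/among decomposition and individual reaction norms (`03`), and the
full config-driven pipeline (`04`).  The same pipeline is available from
the shell:

```sh
otochron run config.yaml --out results/
```

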