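# mistkit

A psychometrics toolkit for misinformation-susceptibility testing: building,
scoring, and evaluating balanced true/false news-judgment tests, built around
the Misinformation Susceptibility Test (MIST) and its *Verification done*
scoring framework.

## Who this is for

Researchers and practitioners who measure how well people distinguish real
from fake news headlines: running the packaged MIST scales, interpreting
scores against population norms, evaluating media-literacy interventions, or
developing new scales of the same design from their own item pools.

## The measurement model

A respondent labels each of *k* headlines (half real, half fake) as real or
fake. Five quantities summarize the response vector:

- **V** (veracity discernment) — total correct, 0..k;
- **r** / **f** — real-news and fake-news items correct;
- **d** (distrust) = max(0, #"fake" labels − k_fake) — excess skepticism;
- **n** (naïvité) = max(0, #"real" labels − k_real) — excess gullibility.

Identities: V = r + f, d·n = 0, and on balanced banks d − n = f − r. The
latent model behind the scales is a higher-order factor structure: real-news
and fake-news detection abilities θ_r, θ_f load on a general discernment
ability θ_V, and each item follows a three-parameter logistic (3PL) response
curve

    P(correct | θ) = c + (1 − c) / (1 + exp(−a(θ − b)))

with the guessing floor fixed at c = 0.5 (binary judgment). Scale development
is supported twice over: the classical route (tetrachoric correlations,
parallel analysis, EFA filters, Cronbach's-α pruning, DIF screen, 3PL-based
final selection) and the network route (EBIC-selected graphical-lasso partial
correlation network, Walktrap dimensions, network loadings, weighted
topological overlap for redundancy, parametric bootstrap stability, and the
total entropy fit index).

## Worked example

Score a simulated cohort and read it against the US norms
(`examples/score_cohort.py`):

```
cohort means: {'V': 15.68, 'r': 7.63, 'f': 8.05, 'd': 1.03, 'n': 0.61}
respondent R00000: V=19/20 -> 95th US percentile (r=10, f=9, d=0, n=1)
V quartiles sample Q1=14 vs population Q1=11
flags: ['V: above-norm baseline (sample Q1 13.75 > population Q1 11)']
```

The cohort answers about 15.7 of 20 headlines correctly on average, split
nearly evenly between real (7.6/10) and fake (8.1/10) detection. The first
respondent sits at the 95th percentile of the US general population; the
cohort as a whole starts above the population baseline (sample first quartile
14 vs 11), the kind of check run before attributing change to an
intervention.

Evaluating a simulated intervention that trains only fake-news detection
(`examples/evaluate_intervention.py`):

```
dim   M_diff       t        p     d_z
V      0.177    2.49   0.0130   0.125
r     -0.007   -0.14   0.8850  -0.007
f      0.185    3.70   0.0002   0.185
d      0.055    1.06   0.2893   0.053
n     -0.138   -3.30   0.0011  -0.165
```

Fake-news detection improves (f: +0.19 items, p < .001) while real-news
detection stays flat — the dissociation a single total score would hide.

Other examples: `calibrate_items.py` (3PL EM calibration + EAP ability
scoring), `run_ega.py` (network dimensionality, redundancy, bootstrap
stability), `select_items.py` (the staged item-selection pipeline on a
planted pool).

A thin CLI wraps the shell-friendly pieces:

```bash
mist bank show MIST-8
mist simulate --bank MIST-20 --n 500 --seed 7 -o responses.csv
mist score responses.csv --bank MIST-20 --norms US -o scores.csv
mist calibrate responses.csv --bank MIST-20 -o params.json
```

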