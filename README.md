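# klkbarrier

Feedback regulation of kallikrein-5 activity in the skin barrier: ODE
bistability analysis of inflammation outbreak and persistence, global
sensitivity analysis, and a bootstrap-PCA inflammation score for
expression data.

## The problem

In healthy skin, the serine protease KLK5 drives desquamation (shedding
of corneocytes) under tight control: active KLK5 (KLK5\*) activates its
own precursor, the inhibitor LEKTI (gene *SPINK5*) sequesters KLK5\*
into an inert complex, and KLK5\* cleaves the receptor PAR2, whose
activated level \[PAR2\*\] triggers inflammatory signalling and feeds
back on KLK5 and LEKTI production.  Atopic dermatitis (AD) is associated
with roughly halved LEKTI expression and elevated skin-surface pH
(≈6.5 vs ≈4.5), both of which tip this balance toward uncontrolled
protease activity.  This package implements a six-species ODE model of
the circuit

```
dL/dt    = f_L(mu, Pact) − kon·L·Kact + koff·C − deltaL·L
dK/dt    = f_K(mu, Pact) − kA·Kact·K/(mK+K) − deltaK·K
dKact/dt = kA·Kact·K/(mK+K) − kon·L·Kact + koff·C − deltaKact·Kact
dC/dt    = kon·L·Kact − koff·C − deltaC·C
dP/dt    = bP − kP·Kact·P/(mP+P) − deltaP·P
dPact/dt = kP·Kact·P/(mP+P) − deltaPact·Pact
```

with stimulus-driven production inputs `f_K = bK + kappaK·mu + alphaK·Pact`
and `f_L = rhoL·(bL + kappaL·mu + alphaL·Pact)` (variant 1, positive
LEKTI feedback) or `f_L = rhoL·(bL + kappaL·mu)·kI/(kI + Pact)`
(variant 2, negative feedback), and asks: at what external stimulus
`mu_on` does inflammation ignite, how far must the stimulus fall
(`mu_off`) for it to cease, and how do LEKTI deficit and high pH change
those thresholds?  It is written for systems-biology modellers and
dermatology-adjacent computational researchers.

Four analyses are provided as a library (`import klkbarrier`), a thin
CLI (`klkbarrier`), and narrative scripts under `examples/`:

1. **Steady states & stability** — multi-start enumeration with
   Routh–Hurwitz classification (eigenvalue cross-check built in).
2. **Bifurcation patterns** — μ-scans classified as reversible/
   irreversible bistability or continuous/discontinuous monostability,
   with threshold extraction and feedback-strength sweeps.
3. **eFAST sensitivity** — variance-based first/total-order indices of
   steady-state \[PAR2\*\], validated on the Ishigami benchmark.
4. **PAR2 score** — a bootstrap-stabilised PCA score over a fixed
   13-probe inflammatory-gene panel, with a synthetic-cohort generator
   providing ground truth.

## Worked example

```python
import numpy as np
from klkbarrier import build_parameters, scan_mu, classify_pattern

params = build_parameters("HC", variant=1, overrides={"alphaK": 0.5, "alphaL": 0.0})
summary = classify_pattern(scan_mu(params, np.linspace(0, 60, 121)))
print(summary.pattern, summary.mu_on, summary.mu_off)
```

prints (also `python examples/01_bifurcation_diagram.py`):

```
pattern:  reversible_bistable
mu_on  =  50.00   (stimulus where inflammation ignites)
mu_off =  13.96   (stimulus below which it ceases)
delta  =  36.03   (hysteresis width: persistence)

at mu ~ 32.0 the model holds 3 steady states:
  [PAR2*] =   0.000  (stable)
  [PAR2*] =   1.685  (unstable)
  [PAR2*] =  17.114  (stable)
```

Healthy skin at these feedback strengths is a switch with wide
hysteresis: between `mu_off` and `mu_on` the zero-inflammation state
and a high-inflammation state coexist, so a transient flare persists
until the stimulus falls below 14.  Under AD conditions the ignition
threshold collapses (`examples/02_ad_thresholds.py`):

```
condition         mu_on
HC                50.00
AD-LEKTI          20.00
AD-pH              2.07
AD-LEKTI/pH        2.05
```

— stimuli innocuous to healthy skin ignite inflammation in AD skin, and
with strong KLK5 feedback the pattern becomes irreversible (inflammation
outlasts any stimulus reduction).  The score stage
(`examples/05_par2_score.py`) recovers a synthetic cohort's latent
inflammation level with rank correlation 0.986, places lesional-AD
samples far above every healthy control, and reproduces the negative
*SPINK5* / positive *KLK7* association signs.

The CLI mirrors the library:

```bash
klkbarrier bifurcate --out out/ --mu-max 60
klkbarrier sweep --out out/ --resolution 21
klkbarrier sensitivity --out out/ --n-total 2000 --seed 0
klkbarrier synth --out cohort/ --seed 0
klkbarrier score --expression cohort/expression.tsv --labels cohort/labels.csv --out scores/
```

Each command writes CSV outputs, an advisory PNG and a `manifest.json`
that reproduces the run byte-identically.

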