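# Methods

## The model

`klkbarrier` models the protease circuit that maintains the skin barrier
at the interface of the granular and cornified layers.  Six species are
tracked (nondimensional concentrations): LEKTI (`L`), inactive KLK5
(`K`), active KLK5 (`Kact`), the inert LEKTI–KLK5\* complex (`C`),
inactive PAR2 (`P`) and activated PAR2 (`Pact`).  `Pact` — the level of
cleaved, internalised PAR2 driving inflammatory gene expression — is the
model's inflammation readout.

```
dL/dt    = f_L(mu, Pact) - kon·L·Kact + koff·C - deltaL·L
dK/dt    = f_K(mu, Pact) - kA·Kact·K/(mK + K) - deltaK·K
dKact/dt = kA·Kact·K/(mK + K) - kon·L·Kact + koff·C - deltaKact·Kact
dC/dt    = kon·L·Kact - koff·C - deltaC·C
dP/dt    = bP - kP·Kact·P/(mP + P) - deltaP·P
dPact/dt = kP·Kact·P/(mP + P) - deltaPact·Pact
```

Four mechanisms: KLK5 self-activation and PAR2 cleavage by active KLK5
are saturating (Michaelis–Menten) because they are bounded by substrate
availability; LEKTI sequesters active KLK5 into a reversible, inactive
complex; every species degrades first-order.  PAR2 production is
constant (`bP`).  The external stimulus `mu` — the integrated
mechanical/chemical load on the skin — drives protein production:

```
f_K = bK + kappaK·mu + alphaK·Pact                      (both variants)
f_L = rhoL·(bL + kappaL·mu + alphaL·Pact)               (variant 1, positive feedback)
f_L = rhoL·(bL + kappaL·mu)·kI/(kI + Pact)              (variant 2, negative feedback)
```

The two variants encode the two biological hypotheses for how activated
PAR2 regulates LEKTI production: co-induction with KLK5 (homeostatic
balancing, variant 1) or suppression (self-amplifying, variant 2).

Because `Kact` only grows autocatalytically, the zero-activation state
`Kact = C = Pact = 0` (with `K`, `L`, `P` at their linear
production/degradation balances) is a fixed point at **every** stimulus
level and is the only analytically tractable one.  Inflammation
"outbreaks" when this branch loses stability; because `Pact = 0` on the
branch, the outbreak threshold `mu_on` is independent of both feedback
strengths — it is a property of the condition (LEKTI capacity and pH)
alone.  The complex-recycling flux `koff·C` matters here: it returns
sequestered KLK5\* and weakens LEKTI's hold in proportion to
`deltaC/(koff + deltaC)`.

### Units and parameters

Rates are nondimensionalised with the pH-4.5 LEKTI–KLK5\* association
and dissociation rates set to 1.  The half-life calibration (degradation
rate 1.0 ↔ 15 min) implies one time unit ≈ 21.6 min; the constant is
stored for documentation only and never used in computation.  Defaults
(see `klkbarrier.model`): `kA = kP = 10` (pH 4.5) / `50` (pH 6.5);
`kon = 1/3`, `koff = 1/250` at pH 4.5/6.5 — the pH-6.5 dissociation rate
of `2.5×10²` encodes the ~80-fold weaker complex at AD-like surface pH;
`deltaK = deltaKact = 1`, `deltaL = deltaP = deltaPact = deltaC = 0.5`;
`mK = mP = 50`; `bP = 10`, `bL = 1`, `bK = 0`; `kappaK = 0.5`,
`kappaL = 0.05` (variant 1) / `0` (variant 2); `kI = 5`.  The equality
ties `kP = kA`, `mP = mK`, `deltaKact = deltaK`, `deltaPact = deltaP`
reflect that KLK5\* performs both activations and that active/inactive
turnover is not separately known; `build_parameters` applies them last
so a tie follows an overridden source unless the dependent name itself
is overridden.  The four condition presets are HC (`rhoL = 1`, pH 4.5),
AD-LEKTI (`rhoL = 0.5`), AD-pH (pH 6.5) and AD-LEKTI/pH (both).

The complex degradation rate `deltaC` and the feedback baselines are
genuinely open values.  `deltaC = 0.5` (the LEKTI/PAR2 turnover class)
keeps every qualitative behaviour below; `deltaC ≥ 1` abolishes
healthy-control bistability altogether, so the complex must be
relatively long-lived for the circuit to switch.  Feedback strengths
default to mid-range (`alphaK = 0.5`; `alphaL = 0.25` for variant 1,
`5` for variant 2); their documented ranges are `alphaK ∈ [0, 1]`,
`alphaL ∈ [0, 0.5]` (variant 1) or `[0, 10]` (variant 2).

## Steady states and stability

`find_steady_states` runs damped-Newton (MINPACK hybrid) root searches
from a deterministic start set — the analytic zero-activation state, a
high-activation heuristic, 32 unscrambled Sobol' points mapped
log-uniformly onto per-species scales, plus caller warm starts — then a
few exact-Newton polishing steps, a non-negativity filter, a residual
gate (`max|rhs| < 1e-9`) and relative-1e-6 deduplication.  Stability
comes from the Routh–Hurwitz table of the characteristic polynomial of
the analytic Jacobian (zero pivots continued with a scaled epsilon and
reported as `marginal`, never silently coerced); the leading eigenvalue
real part is kept as an independent diagnostic, and the test suite
checks the two verdicts agree on thousands of random matrices and every
enumerated fixed point.

## Bifurcation analysis

The stimulus is scanned on `[0, mu_max]`, default `mu_max = 60`: the
nominal thresholds sit at `mu_on ≈ 50` (HC), `20` (AD-LEKTI) and `2.1`
(AD-pH/combined), and above `mu ≈ 100` rising LEKTI production
restabilises the zero branch — a regime outside the analysis' scope.
Diagrams are classified into four patterns: *reversible bistable*
(hysteresis with the deactivation threshold `mu_off > 0`), *irreversible
bistable* (the ignited branch survives at `mu = 0`), *continuous
monostable*, and *discontinuous monostable* (a stimulus window with no
stable state between two monostable regimes, which arises when the
ignited branch's fold sits above `mu_on`).  Two classification routes
share their refinement helpers and are cross-checked in tests:

* `scan_mu` + `classify_pattern` — full multi-start enumeration per grid
  point (warm-started from the previous point), window edges read from
  the grid and bisected grid-free to relative precision `1e-4`.
* `summarize_cell` — the fast path used by `sweep_feedback_grid`:
  `mu_on` by bisecting the Routh–Hurwitz verdict of the *analytic* zero
  branch, `mu_off` by warm-started continuation of the ignited branch
  down to its fold.  A 21×21 sweep takes ~15 s on one core.

Feedback sweeps over the documented `(alphaK, alphaL)` ranges reproduce
the severity ordering — monostable → reversible → irreversible with
stronger KLK5 feedback, the bistability range `delta_mu` non-decreasing
in `alphaK` at fixed `alphaL` — and the AD orderings (`mu_on` lower for
AD-LEKTI and AD-pH than HC wherever both are bistable; here exactly,
since `mu_on` is feedback-independent).

**Known deviation from the source analysis:** in a stimulus sliver just
above threshold at strong variant-1 LEKTI feedback (`alphaL ≳ 0.35`,
`mu ≈ 50–54` for HC) the model holds **four** steady states — the
destabilised zero branch, a mildly ignited stable "homeostatic" state
created by the balancing feedback, a saddle, and the high-inflammation
state — where the original analysis reports one to three.  The extra
branch is numerically solid (residuals < 1e-14, consistent verdicts) and
traces to the reconstructed linear form of `f_L` and the open `deltaC`;
no reading of the open values removes it without also destroying
healthy-control bistability.  The acceptance suite reports this honestly
rather than masking it.

## Global sensitivity (eFAST)

`efast_design`/`efast_indices` implement the extended Fourier Amplitude
Sensitivity Test: per factor block, the factor of interest follows the
sinusoidal search curve at the highest resolvable frequency
`omega_max = (NS-1)/(2M)` (harmonics `M = 4`; Nyquist demands
`omega_max ≥ 2M`, i.e. `NS ≥ 4M²+1`) while the complementary set moves
at low frequencies; first-order `Si` is the spectral mass at the
assigned frequency and its `M` harmonics over total variance, total
`STi` is one minus the complementary (low-frequency) share, averaged
over phase-shift resamples.  The estimator is validated against the
closed-form Ishigami decomposition (`S ≈ 0.314 / 0.442 / 0`) and an
additive two-factor model, to 0.05 at ~2000 samples.

For the applied analysis each positive rate parameter is perturbed
log-uniformly over one order of magnitude total span centred
geometrically on its baseline (equality ties are deliberately broken so
the tied rates can be compared).  The output is the steady-state
`[PAR2*]` reached by relaxation from a KLK5\*-seeded state (the
"ignited-start" convention): the zero branch has `Pact = 0` identically,
so an output defined on it would be blind to the whole KLK5 module — the
ignited attractor is the inflammation level the analysis targets.  The
baseline stimulus is `mu = 45`, inside the nominal healthy-control
bistable window, where both attractors coexist.  Samples whose
trajectories diverge (runaway positive feedback at extreme corners) are
excluded as failures and counted.  Because the ignited attractor's
existence makes the response discontinuous, single-phase total-order
estimates are noisy at the 2000-evaluation scale; the packaged checks
average 5 phase resamples (10 000 evaluations, ~2.5 min).  With that
precision the sensitive set (`STi ≥ 0.05`, the estimator tolerance) is
seed-stable: all six degradation rates, both half-saturations, the
activation rates and `alphaK`, plus `rhoL` and `alphaL` for variant 1
only — variant 2's `alphaL`-insensitivity mirrors its
pattern-independence from that feedback.

## The inflammation score

`bootstrap_par2_score` turns an expression matrix (samples × probes,
groups HC / lesional AD / non-lesional AD) into a per-sample
inflammation indicator.  Per repetition `b = 1..B`: draw `n_background`
non-panel probes uniformly **without** replacement (duplicated columns
would degenerate the PCA), run PCA on the column-centred submatrix of
drawn-plus-panel probes, select among the leading components (≥ 95 %
cumulative variance, capped at 10) the axis with the largest
standardised AD-vs-HC score difference, orient it so AD scores higher,
and project the 13 panel columns onto the axis's panel-restricted
weights.  The score is the mean over repetitions; per-probe weight
medians and quartiles summarise each probe's contribution.  The
separation-statistic axis rule is a transparent substitute for an
unpublished selection procedure; `n_background = 200` and `B = 200`
defaults are desk-scale (the full-study setting is `B = 10 000`, and at
`B = 200` vs `400` per-sample scores already agree to well under 5 % of
the HC–LAD gap).  `scale_to_model` centres scores on the HC median, the
model's zero-inflammation baseline; `score_gene_association` reports
Spearman correlations with marker genes.

## Synthetic cohorts

`generate_cohort` emulates the statistical skeleton the scoring stage
assumes, not any real dataset: a one-dimensional latent inflammation
level per sample (HC ~ N(0, 0.3), lesional AD ~ N(3, 0.8), non-lesional
AD ~ N(1, 1.0) — HC lowest, NLAD straddling), linear probe loadings for
the 13-probe panel (CCL17 largest at 1.4; the two IL8 probes jointly
comparable), marker genes SPINK5 (loading −0.8), KLK7 (+0.8) and KLK5
(mild positive slope 0.3 minus a steeper 1.2 suppression above latent
2.0 — low expression at high inflammation without a global negative
correlation), homoscedastic Gaussian probe noise (SD 0.5), and 2000
pure-noise background probes.  Group sizes default to 10/10/8.  Marker
probe IDs carry a `_syn_at` suffix to flag them as synthetic; only the
13 panel IDs are real platform identifiers.  What passing tests show:
the score pipeline recovers a linear latent factor under Gaussian noise
(rank correlation > 0.9) and the designed association signs.  What they
do not show: robustness to platform effects, probe-level distribution
shapes, batch structure or cohort sizes of real microarray data.

## Numerical choices

Integration uses LSODA with `rtol 1e-8`, `atol 1e-10` and the analytic
Jacobian (steady-state verification needs tight residuals).  Threshold
bisection refines to relative `1e-4`; dedup tolerance relative `1e-6`;
residual gate `1e-9`; Routh marginal band `1e-9` relative to row scale.
The multi-start set is fully deterministic (no RNG in the core scan);
all stochastic stages (eFAST phases, probe bootstrap, cohorts) are
driven by explicit integer seeds and reproduce bitwise.

## Limitations

Only KLK5 is modelled (KLK7 appears solely as a data column); pH enters
through two preset rate triples, not as a continuous variable; no
limit-cycle/Hopf continuation is attempted — stimulus windows without
stable fixed points are labelled from steady-state absence only; the
printed source values for `deltaC` and the pH-6.5 dissociation rate were
not machine-readable and are reconstructed (documented above and
config-exposed); and the exact published bootstrap background size and
axis-selection rule of the score method are declared, configurable
substitutes.
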