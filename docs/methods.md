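# Methods

Statistical model, estimation choices, and limitations of `isobolo`.

## 1. Quantal log-probit model

Each dose group is `k` protected of `n` animals at dose `d` (mg/kg). The
latent model is

```
P(protected | d) = Phi( b · (log10 d − log10 ED50) )
```

with `Phi` the standard normal CDF. Working on the classical probit scale
(`probit(p) = Phi^{-1}(p) + 5`), the group proportions fall on the line

```
y = a + b · log10 d,        ED50 = 10^((5 − a) / b).
```

**Extreme groups.** Proportions of 0 or 1 have no finite probit. The
Litchfield–Wilcoxon correction replaces `0/n → 0.25/n` and
`n/n → (n − 0.25)/n` (`adjust_extreme_proportion`, correction constant
configurable).

**Estimation.** Duplicate-dose groups are pooled by summing counts; the
line is then fitted by unweighted least squares on the adjusted-probit
group points. This is the classical graphical-method estimate: it is
exact for symmetric designs (the trivial two-dose oracle 2/8 at 10 and
6/8 at 40 mg/kg gives ED50 = 20.0 exactly) and is what printed study
tables are built from. A maximum-likelihood probit fit (Nelder–Mead on
the binomial log-likelihood) runs as a cross-check by default and is
recorded in `fit_diagnostics`; the LS estimate is always the reported
one.

**Standard errors.** The default (`se_method="binomial"`) is a sandwich
covariance of the LS line using the delta-method binomial variance of
each group's probit, `v_i = p̂(1−p̂) / (n_i · φ(ẑ_i)²)`, evaluated at the
fitted line. `SE(log10 ED50)` follows by the delta method at the 5-probit
crossing, and

```
sem_ED50 = ED50 · ln(10) · SE(log10 ED50),
ci95     = ED50 · 10^(±1.96 · SE(log10 ED50)).
```

This choice (a) is defined even for two-dose designs, where
residual-based SEs have zero degrees of freedom, and (b) gave ~97–98%
empirical CI coverage at the bundled design sizes — conservative but
inside the accepted 90–99% band. `se_method="residual"` provides the
textbook residual-variance alternative (NaN at two doses).

**Slope function and effective n.** `S = 10^(1/b)` for a straight probit
line (equivalently `(ED84/ED50 + ED50/ED16)/2` up to the conventional
4/6-probit anchors). `n_effective` counts animals in groups whose
*fitted* effect lies in the 16–84% window — the animals that actually
constrain the line — and drives the parallelism factor and downstream
degrees of freedom.

**Parallelism (Litchfield–Wilcoxon).** With `S.R. = max(S_a,S_b) /
min(S_a,S_b)` and per-line factors `f_Si = S_i^(2.77/√n_eff,i)`, the
critical factor is `f S.R. = 10^√(log10 f_Sa² + log10 f_Sb²)`; lines are
non-parallel iff `S.R. > f S.R.`.

## 2. Additive predictions (type I, fixed-ratio)

For a mixture in which drug A contributes fraction `f` of the additive
effect (the 1:1 design is `f = 0.5`):

- **Parallel lines:** `ED50_add = f·A + (1−f)·B`,
  `sem_add = √(f²·sem_A² + (1−f)²·sem_B²)`,
  `n_add = n_A + n_B − 4`.
- **Non-parallel lines:** dose equivalence gives two bounding isoboles in
  reduced coordinates `u = d_A/A`, `v = d_B/B`:
  `u + v^ρ = 1` and `u^(1/ρ) + v = 1` with `ρ = b_B/b_A`. Each is
  intersected with the fixed-ratio ray (`u = f·s`, `v = (1−f)·s`) by
  bracketed Brent root finding (relative tolerance 1e-10; the bracket
  `(0, 1/f]` is guaranteed because the first term alone reaches 1
  there). The smaller intersection is the lower additive ED50, the
  larger the upper. At `f = 0.5` the bounds are exactly symmetric about
  the parallel value (if `t + t^ρ = 1` then `1 − t` solves the mirror
  equation), which the suite verifies to 0.01 mg/kg. SEMs propagate from
  the single-drug SEMs by a central-difference delta method with slopes
  held fixed. Equal slopes make both bounds collapse onto the parallel
  value.

**Comparison and classification.** The mixture dataset is fitted exactly
like a single agent (doses are totals along the ray). The test statistic
is

```
t = |ED50_ref − ED50_exp| / √(sem_ref² + sem_exp²)
```

with Welch–Satterthwaite degrees of freedom using `n_exp − 1` and
`n_add − 1` denominators, two-sided p. The reference is `ED50_add`
(parallel) or the **lower** bound (non-parallel — a conservative
convention: an interaction index below even the lower bound is required
before synergy can be declared). `p < α` with `ED50_exp < ref` is
synergy, with `ED50_exp > ref` antagonism; otherwise additivity. The
interaction index `I = ED50_exp/ED50_ref` is descriptive; classification
comes only from the test.

**Compromise power analysis.** Group SDs are reconstructed as
`SD_i = sem_i·√n_i`, pooled into Cohen's d; with
`ncp = d·√(n₁n₂/(n₁+n₂))` and `df = n₁+n₂−2`, the critical t solves
`β/α = q` by Brent bracketing, where `α = 2·P(T > t_c)` and
`β = P(−t_c < T' ≤ t_c)` under the noncentral t. scipy's
boost-backed `nct.cdf` can return NaN deep in the lower tail at large
noncentrality; a chi-mixture quadrature fallback
(`E_χ[Φ(t_c·χ/√df − ncp) − Φ(−t_c·χ/√df − ncp)]`) covers those cases.

**Other quantities.** Therapeutic index `TI = TD50/ED50`; grip-strength
neurotoxicity screen is a one-way ANOVA on raw per-animal forces (an
all-equal degenerate input returns F = 0, p = 1 instead of NaN).

## 3. Synthetic data generator

`simulate_single` / `simulate_combination` draw independent binomial
counts from the latent probit curve. A mixture's latent ED50 is
`κ · (f·A + (1−f)·B)` — `κ < 1` synergy, `κ = 1` additivity, `κ > 1`
antagonism, the same scale as the interaction index — and its slope
defaults to the effect-weighted mean of the component slopes.

`make_study_fixture` generates the bundled five-drug reference layout:
published single-drug ED50s (GBP 72.12, LCM 4.56, LEV 14.42, PGB 31.66,
RTG 29.04 mg/kg) on their dose grids (17 single-drug groups), all ten
1:1 pairs with κ set to the published interaction indices (35 mixture
groups), 8 animals/group (416 total), plus null grip-strength forces
(N(0.9 N, 0.15 N)). Slopes are not published; the fixture uses 6.0 for
GBP/LEV/RTG, 3.5 for PGB and 1.8 for LCM so that LCM-containing pairs
reproduce the study's non-parallel pattern while PGB+LCM can pass the LW
test. These defaults are study conditions, fixed independently of any
test outcome.

**Out of scope for the generator:** litter effects, between-day drift,
tolerance/kindling dynamics, pharmacokinetic interaction between mixture
components — every animal is an independent Bernoulli draw.

## 4. Numerical choices

- Exponents `10^x` in ED50/CI computation are clipped to ±300 to avoid
  overflow on degenerate near-flat fits; such fits are flagged in
  `fit_diagnostics` rather than raised, and the `estimable()` screen
  (positive slope, ED50 within 4× of the tested dose range) is provided
  for simulation harnesses.
- All root finding is bracketed Brent (no derivative, guaranteed
  convergence inside the bracket).
- Reports serialize with sorted keys and no timestamps, so a rerun of the
  same seed and inputs is byte-identical; the CLI manifest (which does
  carry a timestamp) lives outside the report.

## 5. Limitations

- The LS-on-probits estimator is the classical tabular method, not full
  ML; for very asymmetric designs the two can differ by a few percent
  (the ML cross-check flags this in `fit_diagnostics`).
- Welch comparison treats the two ED50 estimates as approximately normal
  on the dose scale; for very steep or poorly bracketed fits a log-scale
  comparison would be more faithful.
- The non-parallel SEM propagation holds the slopes fixed (slope
  uncertainty is not propagated into the bound SEMs).
- No multiple-testing correction is applied across the ten pairs; each
  combination is reported with its own per-pair test, matching standard
  practice in this assay literature.
- From printed per-pair summaries (ED50 ± SEM and n only), the Welch
  comparison reproduces eight of the ten published classifications; two
  printed "synergy" rows sit at p ≈ 0.054 and p ≈ 0.11 under any degrees
  of freedom convention and classify as additivity here. The package
  reports what the stated test actually yields.
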