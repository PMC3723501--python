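# Methods

## Model structure and assumptions

All three models share one abstraction: a developing thymocyte makes at most
n encounters with antigen-presenting cells, each encounter delivers a scalar
signal strength, and the strength falls into one of four half-open zones
separated by thresholds a ≤ b ≤ c — sub-positive [0, a), conventional
[a, b), regulatory [b, c), deletion [c, ∞). A boundary value belongs to the
higher zone (a measure-zero convention fixed for determinism; it matters
only for the agonist point mass). Deletion is absorbing at any encounter; a
regulatory-zone signal marks the cell and the mark persists unless the cell
is later deleted; a cell that never clears the positive-selection threshold
dies by neglect. Because deletion is absorbing and the mark is order-free,
fate probabilities are differences of n-th powers of cumulative zone
probabilities; the per-cell simulator (`cohort_simulator`) re-derives the
same fates by brute force and serves as the oracle for every closed form.

Signal strengths are relative, not absolute: only the zone probabilities
enter the fates, so the endogenous single-contact distribution is
normalised to a lognormal with log-mean 0 (median 1). The log-sd
`sigma_log` defaults to 1 and is exposed because the fitted encounter size
should not depend on it — the thresholds are calibrated as quantiles, so
rescaling the distribution moves thresholds and agonist strength together.
A single contact is: the agonist with probability g (strength `s_tim`,
parameterised as a percentile of productive endogenous contacts), a null
peptide with probability f·(1−g) (strength 0), a productive endogenous
peptide otherwise. Agonist replacement is assumed uniform over endogenous
peptides, null or not; the alternative (replacing only productive peptides)
would rescale f slightly and none of the qualitative results depend on it.

The models differ in what an encounter is:

* one-hit: one contact, static thresholds (the rejected baseline);
* N-sum: the sum of N proximal contacts, static thresholds;
* two-phase: one contact, but two developmental phases A and B with budgets
  nA and nB and separate zone probabilities, so the same ligand can be
  regulatory-committing early and deleting late. The fate law factorises
  over phases and is exactly order-invariant, so "early" and "late" are
  interchangeable labels.

## Numerics: the lognormal-sum distribution

The N-sum encounter CDF is a binomial mixture over (k agonist contacts,
j null contacts) of m-fold lognormal convolutions, m = N−k−j. No closed
form exists for the m-fold convolution. The default evaluator builds, per
log-sd, a table of log-survival values on a log-strength grid by recursive
numerical convolution: S_m(x) = S_1(x) + ∫₀¹ φ((ln x + ln v)/σ)
S_{m−1}(x(1−v)) dv/(σv), integrating on a shared v-grid refined at both
endpoints, with monotone (PCHIP) interpolation in between. Working on the
survival side keeps relative accuracy deep into the upper tail, which
matters because calibrated thresholds sit at quantiles like 0.85^(1/n) with
n up to 10⁴. Validated against Monte Carlo (2×10⁶ draws), the absolute CDF
error is ≲1.3×10⁻³ for m ≤ 10 at σ = 1, with relative tail accuracy of a
few percent at survival 10⁻⁴. Beyond the table depth (m = 25) a
three-moment shifted-lognormal match takes over (absolute error < 0.008 at
m ≥ 30, improving with m). The classical two-moment Fenton–Wilkinson match
is retained as a selectable method but is not the default: its body error
reaches ~0.02 at σ = 1, outside the package's own oracle tolerance.
Monte-Carlo evaluation of the encounter CDF (fixed seed and sample size) is
exposed as `method="mc"` and is the independent oracle in the tests. Tables
are cached per (σ, depth); quantiles invert the CDF by bracketed
root-finding to 10⁻⁹.

Mixture terms with k agonist contacts already exceeding a threshold
contribute exactly zero to the CDF there and are skipped; for large-N fits
(the null-peptide extension) the binomial support is additionally truncated
at mass 10⁻¹³.

## Calibration

Controls pin the non-identifiable pieces. For the N-sum model the
positive-selection threshold is −∞ (the strongly selecting regime: the
probability of an encounter below positive selection is negligible, and
over hundreds of encounters neglect is vanishing), so b and c are
encounter-distribution quantiles of frac_conv^(1/n) and
(frac_conv+frac_reg)^(1/n). For the two-phase model the identifiable
parameterization fixes the phase-A endogenous regulatory probability to 0
(in the low-sensitivity phase only the agonist can deliver a reg-zone
signal) and a per-encounter endogenous deletion probability d_A; the
phase-B probabilities are then solved exactly from the control fractions,
feasible iff (1−d_A)^nA > frac_conv + frac_reg. Both calibrations
round-trip the control fractions to 10⁻⁹ by construction, which the tests
verify over random feasible inputs.

## Fitting and model comparison

Counts are K × fate probability with K = control T_conv count / frac_conv.
Residuals are taken on log10 counts (the data span orders of magnitude and
the emulated noise is multiplicative); observed and predicted counts are
floored at 0.5 cells so that residuals saturate below the detection floor
instead of diverging. AIC uses the Gaussian-ML form n ln(RSS/n) + 2k and is
only ever interpreted through differences; k counts the optimised
parameters (N-sum: encounter size and agonist percentile; two-phase: the
two budgets; +1 if the scaling constant is freed). ΔAIC ≤ 2 of the minimum
defines the approximate 95% confidence set, read off a grid trace with one
row per grid cell.

The discrete inputs (budget n ∈ {100, 1000, 10000}, null fraction f,
phase-A deletion rate d_A) are explored on grids. The RNA→g mapping is a
nuisance: its parameters are sampled log-uniformly with a fixed seed
(g_max ∈ [10⁻³, 0.5], ρ50 ∈ [1, 10³], steepness ∈ [0.5, 2]) and — this is a
deliberate design choice — the top samples per grid cell are then polished
jointly with the model parameters by deterministic Nelder–Mead within the
prior ranges. Without the polish, cross-cell AIC comparisons are dominated
by which cell happened to draw the luckiest mapping sample (mapping
mismatch exceeds measurement noise), and the generating parameters can be
excluded from the confidence set on their own data. With it, every
shape-capable cell reaches the noise floor and the comparison reflects
model shape. A final cross-seeding pass re-profiles each cell under the
global best cell's mapping with g_max rescaled by the agonist-dose aliasing
factor (the dose enters roughly through N·g), removing residual unevenness.
The agonist percentile is profiled on a dense 241-point grid in
−log10(1−pct) before local refinement because its RSS valley is extremely
narrow — fate probabilities are n-th powers of encounter probabilities, so
small strength changes move predictions by orders of magnitude.

What is identified, and what is not. The encounter size N is identified
from below — N = 1 is strongly rejected — but only weakly from above, since
N and g_max trade off through the mean agonist dose N·g; confidence sets
therefore contain the generating N plus larger values, and recovery is
asserted as set containment. In the two-phase model the budgets (nA, nB)
scale inversely with the assumed g_max, so the free fit identifies the
phase-A share nA/(nA+nB) and the dose-response shape, not the absolute
budgets; absolute budgets are recovered by conditioning on a known mapping.
Likewise d_A trades off against the total budget along a ridge (higher
endogenous phase-A deletion is compensated by fewer encounters), which the
fits reproduce as a negative rank correlation across the d_A grid.
Between models the comparison is one-sided: signal-integration data prefer
the N-sum model decisively, but two-phase data are fitted by the N-sum
model to the same noise floor, so AIC cannot separate the mechanisms in
that direction — the two models are equivalent descriptions of a
rise-then-fall dose response unless the data carry extra structure.

## Synthetic data

The generator emulates the agonist-titration design: 24 induced animals
with relative RNA levels log-uniform over [1, 1000], 4 controls at g = 0,
counts = round(K · P_fate(g(RNA)) · 10^ε) with ε ~ N(0, 0.15) per lineage
and animal, K = 10⁵ precursors. The noise level, animal number and RNA span
were fixed once to match the visual density and log-scale scatter of the
emulated experiment; the generator's defaults otherwise are the models'
canonical parameterizations — N-sum truth: N = 3, n = 1000, agonist at the
99.9th contact percentile, controls (0.85, 0.03), mapping (g_max 0.2,
ρ50 30, steepness 1) chosen so the titration crosses the regulatory-lineage
turnover; two-phase truth: nA = 20, nB = 980, d_A = 10⁻³, controls
(0.85, 0.01), mapping (g_max 0.01, ρ50 100, steepness 1). The two-phase
control regulatory fraction is 1% because the rise-then-fall requires the
phase-A commit gain (≈ nA·frac_conv per unit g) to exceed the agonist
deletion of the baseline regulatory mass (≈ nB·frac_reg per unit g); at a
2% phase-A share this needs frac_reg ≲ 2% — itself a modelling observation:
the two-phase mechanism produces a regulatory boost only when baseline
regulatory output is a small fraction of conventional output, as it is in
real thymi.

What the generator does not emulate: animal-to-animal variability in K or
in the control fractions, counting error structure beyond multiplicative
lognormal noise, finite-precision RNA measurements, or any competition
between thymocytes. Passing recovery tests therefore demonstrates that the
inference machinery is correct and adequately powered under the stated
noise model, not that the real experiment identifies these parameters.

## Qualitative scan conventions

The one-hit rejection argument is evaluated over parameterizations
calibrated to strongly selecting controls (conv fraction 0.5–0.95,
regulatory fraction 0.5–10%), where reg(g) is provably monotone for every
agonist-zone placement (sufficient condition
p3/(p2+p3) ≤ ((p0+p1)/(1−p3))^(n−1), satisfied throughout the sampled
regime). For arbitrary zone probabilities — e.g. baselines dominated by
deletion — a conv-zone agonist can produce an interior reg maximum even at
N = 1, so the rejection argument, like the experiment, conditions on the
observed control phenotype. The N-sum shape demonstration uses n = 100,
where the turnover falls inside the g ∈ [0, 0.05] window (at n = 1000 the
same shape appears with the peak near g ≈ 0.07). The partial/full agonist
sweep draws static N-sum parameterizations with two agonist strengths
(weak/partial and strong/full) across percentiles 0.95–0.99999 and checks
that no draw yields both the partial pattern (deletion up, no regulatory
increase) and the full pattern (interior regulatory maximum) — the
discrimination argument for time-varying sensitivity.

## Known limitations

* The two-phase endogenous parameterization (reg probability 0 in phase A)
  is one identifiable choice among several; alternatives that allow small
  endogenous commitment in phase A would change fitted d_A slightly but not
  the share or the qualitative conclusions.
* Real-valued phase budgets are used during optimisation (powers are well
  defined); the simulator rounds them to integers.
* The continuous-sensitivity generalisation of the two-phase model and
  N > 1 two-phase hybrids are out of scope (qualitative sweep only).
* Fenton–Wilkinson remains available but is inaccurate at σ ≈ 1 for small
  sums; use the default convolution evaluator unless speed at high m
  matters more than body accuracy.
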