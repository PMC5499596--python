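# Methods

This note records the models implemented in `eptlig`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Duplex thermodynamics (`eptlig.thermo`)

Probe/template hybridization is modelled as two-state (all-or-none): a
duplex either exists or it does not, with formation enthalpy ΔH (kcal/mol)
and entropy ΔS (cal/(mol·K)), both negative. The association constant is
K(T) = exp(−(ΔH − TΔS)/RT) with R = 1.9872 × 10⁻³ kcal/(mol·K);
temperatures are kelvin internally and °C at every interface.

Two routes to (ΔH, ΔS) are provided:

* **Nearest-neighbor prediction** using the unified DNA/DNA dinucleotide
  parameter set (SantaLucia-type), shipped as editable delimited text
  (`data/nn_dna.csv`: 16 steps plus the two terminal-pair initiation
  terms). Only DNA/DNA is shipped; RNA/RNA and 2′-O-methyl steps are not,
  so for RNA systems users supply ΔH/ΔS or K directly. No salt correction
  is applied — the working buffer (10 mM Mg²⁺) has no universally agreed
  correction — but `DuplexThermo.with_dS_correction` provides an additive
  ΔS hook.
* **Melting-curve fitting** under the non-self-complementary equal-totals
  convention, θ defined on the limiting strand, K = θ/((1−θ)²·C) with C
  the per-strand total. Fitting is bounded least squares on (ΔH, ΔS)
  (both < 0), initialized from a linearized van't Hoff regression of
  points with θ ∈ [0.15, 0.85], parameter tolerance 1e-10. Curves that
  never melt (all θ > 0.8) or never form duplex (all θ < 0.2) raise a
  non-identifiability error rather than returning an extrapolation.

Tm is defined by θ(Tm) = 0.5, i.e. K(Tm)·C = 2, solved by bracketed root
finding on (0, 120) °C; no root raises a range error.

Note the strong leverage in back-extrapolating K to 25 °C from a melt
transition centred tens of degrees higher: with 0.01 additive noise on θ,
K(25 °C) from a fit carries roughly 5–15% error even with dense sampling.
This is an information limit of the data, not an estimator defect.

## Speciation and protonation (`eptlig.equilibria`)

The three-strand system T (template), A (EPT donor), B (amino acceptor)
forms TA, TB and the reactive ternary complex TAB with
[TAB] = ω·K_A·K_B·[T][A][B]. The cooperativity ω defaults to 1
(independent sites): nothing in the available data constrains
donor–acceptor coaxial-stacking cooperativity, so the simplest model is
the default and ω is an explicit parameter.

The solver bisects on free template in [0, T_total] — the template balance
is monotone in [T], so bracketing is guaranteed and no starting guess is
needed — eliminating free A and B in closed form at each step (the
acceptor balance reduces to a quadratic; the cancellation-free root form
is used, which matters in the weak-binding regime). Termination is at
relative bracket width 1e-12 (≤ 200 iterations, relative to the bracket
location so that very strong binding with tiny free template still
resolves); solutions are verified against a 1e-9 relative mass-balance
residual and a convergence error is raised otherwise.

**Occupancy framings.** A single "percent ternary complex" number is
ambiguous when strand totals differ: the percentage can be referenced to
template, donor, acceptor, or the limiting strand. At the standard 4/2/4 µM
composition at most half of the template can ever be ternary, so the
package's headline number is the **limiting-strand** fraction, and
`ternary_occupancy_report` prints all four framings with their reference
explicitly labelled.

**Limits worth knowing.** As K → ∞ the limiting strand's ternary fraction
tends to 1 only when the donor is at least stoichiometric with the
template; a sub-stoichiometric donor distributes randomly over the
template pool (independent sites carry no co-localization preference), so
the acceptor's ternary share tends to the donor-site occupancy instead
(e.g. 3/4 at 3 µM donor vs 4 µM template).

Amine protonation is Henderson–Hasselbalch: unprotonated fraction
1/(1 + 10^(pKa−pH)). The registry ships pKa 7.8 for 5′-amino nucleosides,
7.7 for 3′-amino DNA and 7.0 for 3′-amino RNA, all overridable. Percent
comparisons against published integer values use half-up rounding.

## Kinetics (`eptlig.kinetics`)

Hybridization is treated as quasi-equilibrium — with ternary occupancies
≥ 98% and hybridization much faster than the hours-scale chemistry, the
bound-state population tracks the instantaneous totals. The acceptor then
obeys dB/dt = −k_chem · f(pKa, pH) · occ(t) · B, with occ(t) re-solved from
the speciation model as the active-EPT pool decays (first order, k_hyd).
Hydrolysis is applied equally to free and template-bound EPT by default
(no bound-state protection data exist); `ept_protection` scales the bound
rate if desired. Integration is adaptive explicit Runge-Kutta (rtol 1e-9,
atol 1e-12) evaluated on the user grid; the curves are smooth and
non-stiff at these rates.

In the pseudo-first-order regime (gates constant, k_app(t) = k₀e^(−k_hyd·t))
the closed form is B/B₀ = exp((k₀/k_hyd)·expm1(−k_hyd·t)), plateau yield
1 − exp(−k₀/k_hyd); `expm1` keeps the k_hyd → 0 limit accurate to ~1e-9.

Observed plateaus below the hydrolysis-predicted yield (e.g. ~75% where an
8-h EPT half-life and a 10⁻² min⁻¹ rate predict near-complete conversion)
have no established mechanism; the simulator exposes `inactive_fraction`
(a never-reactive acceptor subpopulation) as a purely phenomenological
knob, default 0, and asserts nothing about its cause.

## Rate estimation (`eptlig.inference`)

k_app is the negated slope of ln(C/C₀) regressed on time **through the
origin** — C/C₀ = 1 at t = 0 by construction of the normalization, so a
free intercept only adds variance (available behind `free_intercept` for
diagnostics). The default analysis window is the initial-velocity regime,
points with product ≤ 50%: progress curves plateau below 100%, and
fitting the plateau as first order biases k̂ downward. On true first-order
data the window choice is irrelevant (verified to 1e-9). Points with
C/C₀ ≤ 0 are excluded with a warning; an entirely flat curve returns
k = 0 with an infinite-half-life flag rather than an error. Reported
standard errors are the usual through-origin OLS form; rate-ratio errors
are propagated in quadrature. Rates are conventionally echoed in units of
10⁻² min⁻¹ at two significant digits.

## Synthetic data (`eptlig.synthetic`)

The generators emulate the study conditions end to end:

* **Strand trios**: a 10-mer 3′-EPT donor and 13-mer 5′-amino acceptor
  (FAM-labelled) tiling a 23-mer template with a central nick; sequences
  drawn uniformly per seed (the real probe sequences target a
  leukemia-associated fusion junction but are not required for any
  computation here).
* **Ligation time courses**: plateau_cap × (1 − closed-form remaining),
  defaults in the measured regime (k₀ of order 10⁻² min⁻¹, hydrolysis
  half-life ≈ 8.1 h ⇒ k_hyd ≈ 1.43 × 10⁻³ min⁻¹), sampled every 5 min
  over 2 h as in the gel assays.
* **EPT decay**: exponential with half-lives drawn from the observed
  6.4–8.9 h stability range.
* **Melting curves**: two-state θ(T) sampled at 0.25 °C from 10–90 °C —
  the acquisition density of a UV-melting instrument (typically one
  reading per 0.1–0.5 °C) — for duplexes with K ≈ 10⁹–10¹⁰ M⁻¹ at 25 °C.
* **Gel lanes**: (i_remaining, i_product) pairs whose ratio encodes the
  true yield, with per-band multiplicative noise modelling integration
  error.

Noise defaults to additive Gaussian, sd 0.02 on fractions — chosen as a
realistic but recoverable magnitude for gel densitometry; the true scatter
of the original quantitation is unknowable from the published figures.
Generated fractions are clipped to [0, 1] and the number of clipped points
is counted and reported on the `NoiseSpec`. All generators are
bit-reproducible for a fixed seed.

**What passing tests do not show.** The generators produce exactly the
statistical structure the estimators assume (exponential kinetics,
Gaussian noise, two-state melts). Real gels add baseline drift, lane-to-
lane loading variation, band overlap and saturation; real melts add
baseline slopes and non-two-state intermediates. Parameter recovery here
validates the estimators' correctness, not their robustness to those
artefacts.

## Problem sizes and numerical choices

The randomized solver-vs-oracle suite uses 100 parameter draws
(K ∈ [10³, 10¹¹] M⁻¹, totals 0.1–10 µM) against a brute-force
grid-scan/bisection oracle; the stochastic-recovery suites use 200
replicate time courses (7 points over 2 h) and 100 gel lanes. Percentages
for comparison with published integer values are rounded half-up.
Equilibrium solutions are accepted only below a 1e-9 relative mass-balance
residual; ODE-vs-closed-form agreement is held to 1e-6 absolute.

## Known limitations

* No hybridization kinetics (quasi-equilibrium only), no Gillespie engine,
  no temperature-dependent rate laws.
* No mismatch, dangling-end or loop thermodynamics; no RNA
  nearest-neighbor tables; no salt model beyond the additive ΔS hook.
* The intramolecular 2′,3′-cyclization side channel of 3′-EPT RNA is not
  modelled.
* Joint nonlinear fitting of (k_chem, k_hyd, pKa) across conditions is out
  of scope; fits are per-course.
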