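# eptlig

Quantitative modelling of template-directed chemical ligation of
oligonucleotides via an electrophilic phosphorothioester (EPT) donor and an
amino-terminated acceptor.

In this chemistry a phosphorothioate end is activated with Sanger's reagent
(1-fluoro-2,4-dinitrobenzene) into an EPT group; when the EPT strand and an
amino strand hybridize adjacently on a complementary template (a nicked
duplex), the amine attacks the electrophilic phosphorus and forms a
phosphoramidate backbone bond. The reaction is pH-gated (only the
unprotonated amine is nucleophilic), occupancy-gated (only the ternary
complex reacts), and competes with hydrolysis of the EPT group, whose
half-life is on the scale of hours.

`eptlig` is for chemists and modellers who want to analyse or simulate such
reactions: predict duplex stabilities, compute ternary-complex occupancies,
simulate time courses, and estimate rate constants from gel-quantified
progress curves.

## The model

**Hybridization.** Each probe/template duplex is treated as two-state with
parameters ΔH (kcal/mol) and ΔS (cal/(mol·K)), either predicted from
unified DNA/DNA nearest-neighbor parameters or fitted from a melting curve.
The association constant is the van't Hoff expression
K(T) = exp(−(ΔH − TΔS)/RT), with R = 1.9872 × 10⁻³ kcal/(mol·K).

**Speciation.** With template T, EPT donor A and amino acceptor B, the
species {T, A, B, TA, TB, TAB} obey [TA] = K_A[T][A], [TB] = K_B[T][B],
[TAB] = ωK_AK_B[T][A][B] (ω = cooperativity, default 1 — independent
sites). Mass balance is solved by guaranteed-bracketing bisection on free
template with closed-form elimination of free A and B.

**Protonation.** The nucleophilic fraction of the acceptor's amine is the
Henderson–Hasselbalch form f = 1/(1 + 10^(pKa − pH)), with registered pKa
values 7.8 (5′-amino), 7.7 (3′-amino DNA) and 7.0 (3′-amino RNA).

**Kinetics.** Acceptor consumption follows dB/dt = −k_app(t)·B with
k_app = k_chem · f(pKa, pH) · occ(t), where occ(t) is the acceptor's
ternary occupancy re-solved as the active EPT pool decays
(d[EPT]/dt = −k_hyd·[EPT]). In the pseudo-first-order limit this has the
closed form B/B₀ = exp(−(k₀/k_hyd)(1 − e^(−k_hyd·t))) with plateau yield
1 − exp(−k₀/k_hyd).

**Inference.** k_app is estimated by regressing ln(C/C₀) on time through
the origin over the initial-velocity window (product ≤ 50% by default);
half-lives are ln2/k. Gel yields are i_product/(i_remaining + i_product).

## Worked example

Speciation at the standard composition (4 µM EPT donor, 2 µM amino
acceptor, 4 µM template, 25 °C) with duplex constants 8.82 × 10⁹ and
10.19 × 10⁹ M⁻¹:

```bash
$ eptlig speciate --ka 8.82e9 --kb 10.19e9
{
  "free_template_M": 1.0620156835404514e-08,
  "free_amino_M": 9.812579774448983e-11,
  "ternary_TAB_M": 1.989282759427086e-06,
  "ternary_fraction_limiting": 0.9946413797135429,
  "occupancy_by_reference": {
    "template": 49.732068985677145,
    "ept": 49.732068985677145,
    "amino": 99.46413797135429,
    "limiting": 99.46413797135429
  },
  ...
}
```

99.46% of the limiting amino strand sits in the reactive ternary complex —
the basis for treating the ligation as first order. (The template and
donor, in two-fold excess, top out near 50% by arithmetic necessity; the
report prints every framing.)

Generate a synthetic time course at the fast-DNA regime
(k₀ = 5.6 × 10⁻² min⁻¹, EPT half-life 8.1 h) and fit it back:

```bash
$ eptlig synth timecourse --seed 3 --out tc.csv
$ eptlig fit --in tc.csv
{
  "k_app_per_min": 0.05564219852368171,
  "stderr": 5.6074711114681224e-05,
  "half_life_min": 12.457221298776268,
  "r_squared": 0.9999949147434165,
  "n_points_used": 3,
  "window_min": [0.0, 10.0]
}
```

The estimator recovers 5.56 × 10⁻² min⁻¹ on the initial-velocity window —
within 1% of the generating constant; the small deficit is the expected
signature of concurrent EPT hydrolysis. `eptlig reproduce` recomputes all
of the package's built-in desk-scale reference checks (protonation
percentages, ternary occupancies, the 5′/3′-amino RNA rate ratio of 3.6)
and reports pass/fail.

Other subcommands: `thermo` (nearest-neighbor ΔH/ΔS, K(T), Tm), `simulate`
(ODE time course from a JSON system config), `fit-decay` (EPT stability
half-life), `yields` (gel lane quantitation), `synth trio|decay|melt|gel`.

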