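# Methods

This note records the models, numerical choices and deliberate design
decisions behind `glycoflow`, in the order data flows through the
package.

## Reaction network and rate laws

The network couples upper glycolysis (hexose + 2 ATP → FBP), lower
glycolysis (FBP → 2 pyruvate, regenerating 2 ATP per pyruvate), the
pentose-phosphate entry reaction G6PDH and lactate dehydrogenase: 18
state species, 13 reactions, 12 distinct enzymes (hexokinase
phosphorylates both glucose and fructose, with separate kinetic
constants and a markedly lower fructose affinity). Enzymes are
immobilized on beads and enter the rate laws as fixed effective
concentrations in µM active sites; they are configuration, never state.

Rate-law forms, chosen to be the simplest saturating laws consistent
with the network topology and its two allosteric edges:

| reactions | form | free parameters |
|---|---|---|
| HK (×2), G6PDH, LDH | irreversible multi-substrate MM | kcat + one Km per substrate (3) |
| GPI, TPI, PGM, ENO | reversible one-substrate, `kcat·E·(A − B/Keq)/(Km_A + A + (Km_A/Km_B)B)` | 4 |
| ALD | reversible uni-bi with product terms in the denominator | 5 |
| GAPDH, PGK | reversible difference-of-saturations (two substrates, two products) | 6 |
| PFK | MM product × Hill inhibition `1/(1+(PEP/Ki)^n)` | 5 |
| PK | MM product × Hill activation `(1+β(FBP/Ka)^h)/(1+(FBP/Ka)^h)` | 6 |

This ledger totals exactly 56 free parameters. The Hill exponents are
fitted parameters; the activation amplitude β is the saturating-to-basal
rate ratio of PK. Inorganic phosphate and water are treated as buffered
and are not state variables (the GAPDH law omits Pi); their
stoichiometry is kept in an `implicit` record so elemental balances
close. 6-phosphogluconolactone is a terminal sink (no lactonase in the
network); its concentration is inferred downstream from NADH, its
stoichiometric twin. Reversible laws change sign exactly at their own
equilibrium condition; `Keq` values are parameters of those laws, not
thermodynamic table lookups.

The reference ("truth") parameter set used by the synthetic studies is a
fixed, documented table of plausible values — turnovers 20–100 s⁻¹, Km
0.03–2 mM, unfavorable isomerization equilibria pulled forward by the
irreversible pyruvate kinase step. It is the package's own reference
point, chosen once; fitting bounds are log-uniform per parameter class
(kcat 1–100 s⁻¹, Km/Ki/Ka 0.01–5 mM, Keq 0.01–100, β 1–20, Hill
exponents 1–4).

## Reactor integration

The CSTR mass balance `dC/dt = (Σ qⱼ c_in,ⱼ − Q C)/V + S v(C)` is
integrated with LSODA at rtol 1e-8 / atol 1e-10 mM (concentrations span
~20 µM to 10 mM). Protocols are piecewise constant; integration
restarts at every segment boundary so no step is smoothed. The 2 h
equilibration phase preceding every protocol holds the first segment's
flows. An exact model reduction drops species unreachable from the
initial state and feed through reactions with nonzero loading — for the
3-enzyme subsystem this shrinks the ODE from 18 to 8 states and is the
main reason fits run in seconds. Tiny negative excursions within solver
tolerance are clamped to zero between segments and logged on the
trajectory. Transport from reactor to detector is a pure dead time
(default 60 s to the MS, 5 s to the UV cell), configurable; tubing
dispersion is not modeled.

## Synthetic observation model

The generator emulates, per 550 ms scan: isotope-dilution plumbing
(analytes diluted by Q_r/(Q_r+Q_d), standards by Q_d/(Q_r+Q_d), with
Q_d = 87.5 µL/min), a per-species response factor (default 1000
counts/mM), multiplicative lognormal noise (σ = 0.08, mean-one
convention), an additive Gaussian detector baseline (10 ± 2.5 counts),
in-flight fragmentation (defaults φ(FBP→F6P) = 0.15 for the HPO₃ loss
and φ(hexose→lactate isobar) = 0.05, applied to both label states), the
natural-abundance M+2 overlap of NAD onto the NADH channel (fraction
computed from the NAD elemental formula, ~6 %), a constant chemical
matrix term in the total ion current, and Beer–Lambert UV absorbance of
the *undiluted* reactor outflow (the UV cell sits upstream of the
dilution tee). The hexose-phosphate isomers G6P/F6P share one m/z and
are separated only by their inverse-mobility windows. Everything is
deterministic per seed.

What it does not emulate: peak shapes and centroiding, mobility
calibration drift, space-charge effects, standard-line drift (the ¹⁵N-Glu
reference channel is exported so a user *could* monitor drift, but no
automatic correction is applied), or run-to-run fragmentation-rate
changes. Passing tests therefore demonstrate correctness of the
inversion pipeline under these stated artifacts, not robustness to every
failure mode of a real instrument.

## Quantification pipeline

Order of operations: subtract the estimated detector baseline, divide by
the per-scan TIC, subtract fragmentation cross-talk
(`I'_frag ← I'_frag − φ̂ I'_parent`, per role so both label states are
corrected; negative results are floored at zero and flagged), subtract
the isotope overlap on NADH, then quantify.

Two choices matter numerically:

* **Bin before ratio.** Intensities are averaged into 45 s bins first
  and ratios taken second. The expectation of a per-scan ratio of noisy
  intensities carries an O(σ²) multiplicative bias (≈0.6 % at σ = 0.08),
  which is systematic and therefore poisonous for inference; binning
  first removes it.
* **Fragmentation yields by baseline-subtracted mean ratio.** A plain
  mean of per-scan fragment/parent ratios is biased upward by the
  additive baseline, and a regression slope is attenuated because
  scan-to-scan variation of the parent channel is its own noise
  (errors-in-variables). The estimator therefore takes the ratio of
  baseline-subtracted channel means over above-floor scans of a
  single-compound infusion, with the quietest channel estimating the
  shared baseline. It refuses streams containing more than one compound
  and parents below the detection floor.

NADH is quantified through the UV channel: Beer–Lambert gives the
reactor-side concentration, which is aligned to the NADH ion channel by
cross-correlation (lag capped at 5 min) and regressed through the origin
against the ion intensity with the TIC normalization and the known
per-scan dilution factor divided out — both vary systematically across
residence-time regimes and would otherwise distort a single global
slope. The fitted map then converts ion intensity to concentration on
the MS time base. A UV channel indistinguishable from noise is refused.

Bins are 45 s means; the rolling average is centered with window 10 and
truncated edges; values below the 0.02 mM floor (and bins whose standard
channel vanished) are masked, not dropped. The mass-balance report sums
hexose equivalents (6-carbon species ×1, 3-carbon ×½, NADH ×1 as the
6PGL proxy) against the feed convolved with the exact per-segment washout
exponential, shifted by the dead time; the ratio is undefined (NaN) where
the feed is zero.

## Inference

The objective stacks, over species and unmasked bins, residuals between
the quantified data and the simulation resampled at bin centers (shifted
by the dead time), each divided by that species' data standard deviation
so species on different concentration scales weigh equally; raw
per-species RMSE is reported alongside. Fits run bounded trust-region
least squares on log-parameters from log-uniform multistart draws
(deterministic per seed); fit-time simulations use rtol 1e-6, which
changes trajectories far less than the data noise.

Multistart ensembles on well-identified synthetic problems collapse onto
a single optimum, so their spread says nothing about predictive
uncertainty. `laplace_ensemble` therefore expands the best fit into a
linearized-Gaussian parameter ensemble — covariance `s²(JᵀJ)⁻¹` in log
space from the finite-difference residual Jacobian, draws clipped to the
bounds — which `predict` consumes exactly like a multistart ensemble to
produce mean trajectories with 1-SD and 2-SD envelopes. Identifiability
of all 56 parameters from a single experiment is *not* asserted; the
recovery studies run on the 3-enzyme subsystem (10 free parameters).

## Optimal experimental design

Candidates switch each input syringe every 15 min among ≤4 discrete flow
levels while the total flow steps through the configured residence-time
regimes (defaults τ ∈ {2, 4, 8, 16} min on a 100 µL reactor) in
contiguous blocks, a carrier syringe making up the balance. The score is
D-optimality on log-parameters: `log det(Σₜ JᵀWJ + 10⁻⁸ I)` with
sensitivities by central finite differences (step 10⁻³ in log space,
solver rtol 1e-8 so derivative noise stays ~10⁻⁵ of scale) and
`W = diag(noise sd)⁻²`. The ridge regularizes structurally dead
directions (e.g. parameters of unloaded enzymes) without masking them.
The search is seeded random sampling; the first candidate of the same
stream doubles as the matched "random protocol" control in utility
comparisons, which guarantees the designed protocol's score is at least
the control's by construction and lets the parameter-recovery comparison
run on paired noise seeds.

## Problem sizes of the bundled studies

The recovery and design studies shipped with the test suite use the
3-enzyme subsystem with a 2 h designed experiment (budget 6–8 candidates),
12–20 multistart fits capped at 80 objective evaluations, a 40-draw
parameter ensemble, and 4 replicate fits per protocol in the design-utility
comparison. These sizes were chosen as the smallest at which the studies'
conclusions are stable across seeds; all seeds are fixed constants in the
tests.

## Known limitations

* Rate-law shapes are the package's reconstruction; real glycolytic
  enzymes have additional effectors (e.g. ATP inhibition of PK) that are
  out of scope.
* The fragmentation model is a constant per-pair yield; real in-source
  fragmentation varies with source conditions, and the lactate isobar
  produced from hexose fragmentation is known to violate the
  constant-rate assumption across experiments.
* The Laplace ensemble is a local, linearized uncertainty; it will
  understate uncertainty near bounds or for multimodal objectives.
* Bead-scale diffusion limitation, pressure dynamics and UV/MS flow-cell
  dispersion are not modeled.
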