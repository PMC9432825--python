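# Methods

## Kinetic schemes

Both models describe a well-mixed solution of actin species `A_i`
(oligomer of `i` subunits, concentration in µM) exchanging single
subunits; there is no fragmentation, annealing, or spatial structure.

**Scheme 1 (single state).** A linear assembly chain with step-specific
rates: dimerization `k1/k−1` (with the stoichiometric factor 2 on the
monomer equation), trimer `k2/k−2`, tetramer `k3/k−3`, and a common
elongation pair `k4/k−4` for every step from the tetramer upward.  The
largest simulated species `A_n` is absorbing (no flux to `n+1`).

**Scheme 2 (two state).** The unprimed pathway uses `k1/k−1`, `k2/k−2`
and `k3/k−3` for *all* steps above the trimer.  Species with `i ≥ 3`
transition irreversibly at rate `k_trans` into a primed state `A'_i`
which elongates with its own pair `k4/k−4`; the primed trimer dissociates
into `A_2 + A` at `k−4`.  There is no reverse route from `A_2` into the
primed pathway — the equations are implemented exactly as this asymmetric
scheme states.  At `t = 0` all species are unprimed.

With `k_trans = 0` and matched stepwise rates, scheme 2 reduces exactly
to scheme 1; this is enforced by a regression test.

## Parameter choices

| parameter | default | unit | origin |
|---|---|---|---|
| `k1=k2=k3` (ATP model) | 12.9 | µM⁻¹s⁻¹ | sum of barbed (11.6) and pointed (1.3) end association rates of Mg-ATP-actin |
| `k−2=k−3` (ATP model) | 2.2 | s⁻¹ | sum of barbed (1.4) and pointed (0.8) end dissociation rates |
| `k4/k−4` (ATP model) | 11.6 / 1.4 | µM⁻¹s⁻¹ / s⁻¹ | barbed-end pair only: hydrolysis at the pointed-end terminal subunit stabilizes that end, so the primed state grows essentially from the barbed end.  This choice also reproduces the observed critical concentration, k−b/k_b = 1.4/11.6 µM ≈ 120 nM |
| `k_trans` (ATP model) | 0.3 | s⁻¹ | filament ATP-hydrolysis rate from the literature; config field with provenance string |
| `k1..k3 / k−2,k−3` (cation model) | 10.6 / 5.0 | — | end-summed rates of Ca-ATP-actin |
| `k4/k−4` (cation model) | 12.9 / 2.2 | — | end-summed rates of Mg-ATP-actin |
| `k_trans` (cation model) | 0.05 | s⁻¹ | Ca²⁺→Mg²⁺ activation; placeholder order of magnitude, flagged unverified |
| `k−1` | 1e6 | s⁻¹ | *manually adjusted* (see below) |
| `D_monomer` | 7.9e−7 | cm²s⁻¹ | literature monomer diffusion coefficient |
| monomer detection efficiency | 0.876 | — | semisynthetic-movie calibration of the MP analysis |
| mass-peak SD | 8 | kDa | assumption; the experimental per-peak SDs are not tabulated |
| BLS noise variance | 1740 | a.u.² | the value the marginal noise parameter settles at |
| scattering scale `s` | 100 | a.u./(µM·subunit²) | arbitrary; puts trace amplitudes at 10⁴–10⁵ a.u., comparable to photodetector counts |
| detection floor `sds` | 30 | subunits | an optimization parameter in fits; exposed to MCMC |

**Dimer dissociation `k−1`.** No independent measurement exists; it is
the one manually adjusted constant of the two-state models.  `k−1 = 1e6
s⁻¹` (dimer K_d ≈ 0.08 M, consistent with free-energy estimates of
extreme dimer instability) reproduces the observed phenomenology in one
pass: essentially no growth at 120 nM, strong >140-kDa mass accumulation
at 900 nM within 15 min, monotone concentration dependence across
120–2000 nM, and suppression of >150-mer formation at 2 µM when the
transition is switched off.  Values around 10 s⁻¹ (a stable dimer)
abolish the nucleation barrier entirely and none of these contrasts
survives; values ≥1e7 leave too few filaments.  `k−1` is also the prime
target of the parameter-recovery experiments.

## Observables

**Mass photometry.** Detected-particle counts are binned per species:
Gaussian mixture areas for the resolved species 1..m (m ≤ 4), half-open
42-kDa bins `[42i−21, 42i+21)` above (boundary events go up; the bin
edges themselves are not stated by the protocol, only the spacing).
Counts convert to concentrations through subunit-share bookkeeping with
round-half-even in `N_i = round(N_subunits,i/i)`.  Landing rates scale
with the species diffusion coefficient — spheres (`D_1 i^{−1/3}`) up to
`i = 4`, Tirado rods (d = 7 nm, rise 2.7 nm/subunit, 20 °C, η = 1 mPa·s)
above, with the sphere/rod discontinuity at i = 4→5 kept, not smoothed —
and the monomer is additionally corrected by the 0.876 detection
efficiency.  Upscale (detected → solution) and downscale are exact
inverses guarded by flags.

The mixture fit weights residuals by the Poisson scale of the *fitted*
model (two-pass Pearson weighting).  Unweighted least squares lets a
5·10⁵-count monomer peak swamp a 10²-count dimer peak; weighting by the
*observed* counts overweights downward-fluctuating bins and biases small
peak areas low (the classic Neyman effect) — measured at −8% on a
50-event dimer peak, enough to shift joint-fit posteriors by ~2σ.  The
Pearson scheme is unbiased within Monte Carlo error.

Synthetic event masses are the per-species Gaussian mean plus zero-mean
Gaussian noise with the fitted SD.  The original protocol calls this
noise Poissonian while simultaneously giving it the fitted Gaussian SD —
an internally contradictory description; since the resulting histograms
are Gaussian peaks, Gaussian noise is implemented and the divergence is
documented here rather than silently resolved.  Species beyond the
fitted range use `i·42` kDa and the SD of the largest fitted component.

**Bulk light scattering.** `signal = s·Σ_{i=sds}^{n} i²([A_i]+[A'_i])`.
Simulated traces are mapped onto experimental ones by an affine transform
matching the mean start and end levels over a 10-point edge window
(window length and the affine-vs-pure-scale choice are not prescribed;
pure scale is available as an option).

## Inference

Joint Gaussian likelihood over the BLS and MP channels with fixed
per-channel noise scales (σ²_BLS = 1740 a.u.², MP counts with Neyman-χ²
per-bin variance `max(count, 1)`); the constant terms `2N lnσ + N ln2π`
are kept so AIC/BIC are comparable across models.  A failed or
non-finite forward evaluation maps to −∞ log-posterior and is counted in
the diagnostics.  Priors are uniform on `[0, 1e5 × reference]` per rate
constant.  Sampling uses the affine-invariant ensemble sampler with 80%
differential-evolution and 20% snooker moves; walkers start in a 1%
Gaussian ball around the reference values, never outside the prior.
Convergence is judged by the integrated autocorrelation time (automated
windowing, window constant c = 5, averaged over walkers), flagged
unreliable when the chain is shorter than 50τ; zero-variance chains are
flagged rather than assigned a τ.  AIC = 2k − 2lnL̂ and
BIC = k lnN − 2lnL̂ use the maximum sampled log-likelihood.

Desk-scale defaults are 10–32 walkers and a few hundred to a few
thousand steps with ODE forward models of n_max ≈ 40; production-scale
settings (100 walkers, ~250 000 samples, n_max 400–2000) are plain
configuration changes but need cluster time.  One ODE solve per θ is
cached and shared between the two data channels.

## What the synthetic data do and do not emulate

The generators reproduce the statistical structure the analysis assumes:
multinomial event counts at a target total with landing/detection
thinning, Gaussian mass-peak noise, i.i.d. Gaussian scattering noise of
fixed variance, and known ground truth.  They do **not** emulate raw
landing videos, ratiometric contrast, mass-calibration error, the
dilution step before MP acquisition (shown experimentally to be
negligible), false-positive events (5.6% monomer-scale contaminants can
be switched on), or day-to-day variation in event totals.  Passing the
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under its own assumptions, not robustness to
instrument systematics.

## Numerical choices

* Integrator LSODA with analytic dense Jacobians, rtol 1e−8, atol 1e−12
  µM; rates span >6 orders of magnitude (k−1 ≫ k_trans), which a
  non-stiff method handles poorly.
* Truncation at `n_max` uses an absorbing top species exactly as the
  equations state; a warning fires when >0.1% of mass reaches it.  The
  burst regime of the ATP model intentionally runs mass into the top
  species at desk scale; fits remain self-consistent because data and
  model share the same truncation.
* Integrator output in (−1e−12, 0) µM is clipped to zero on export;
  anything below −1e−12 is treated as an integration failure.
* The detailed-balance equilibrium root-find works in log space so
  super-critical geometric tails (ratio > 1 over 400 species) do not
  overflow.
* The SSA oracle uses exact propensities (`k1/Ω·m(m−1)` for the
  self-reaction) and refuses instances above 10⁷ molecules.

## Known limitations

* Joint-fit posteriors at desk scale show a residual upward shift of
  ~1σ on (k_trans, k−1), traceable to the remaining count-histogram
  approximations (Neyman variances, finite mixture-fit error); credible
  intervals still cover the generating values in the seeded replicate
  sets.
* The two-state model's primed pathway is terminal: no reverse
  transition, no ADP→ATP recycling, no nucleotide-state gradient along a
  filament.
* Mean-field ODEs ignore number fluctuations; the SSA oracle covers only
  small instances.
* The Sept/McCammon preset ships as a citation-only template; its rate
  tables must be transcribed by the user.
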