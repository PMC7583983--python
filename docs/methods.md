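# Methods

## Scope and data model

`hydroshell` analyses single-particle translational dynamics in cubic
periodic boxes. A trajectory is a time-ordered stack of coordinate frames
(nm, ps) with per-atom class labels (`protein`, `water-oxygen`, `other`),
stored wrapped into `[0, L)`. All correlators operate on *continuous*
coordinates: inter-frame displacements are unwrapped by accumulating
minimum-image steps, which is unambiguous as long as no particle moves more
than half a box edge between frames (checked; violations raise with advice
to sample frames more densely). The synthetic generators additionally carry
their exact continuous coordinates so tests can isolate unwrapping errors;
unwrap-then-rewrap round trips are verified to 1e-9 nm (bit-exactness is not
attainable because the cumulative sum of minimum-image steps rounds).

The hydration shell is the set of water oxygens whose minimum-image distance
to the nearest protein atom is at most a cutoff, 0.6 nm by default — the
conventional shell thickness for protein hydration water. Distances use a
periodic KD-tree, cross-checked in the tests against an exhaustive 27-image
oracle. Which correlation pairs a shell water contributes is governed by an
explicit membership convention: **origin** (in shell at the time origin of
the pair; the default, and the weakest assumption consistent with
nanosecond-scale shell correlations), **both_ends**, or **continuous**
(every frame of the lag window, computed with cumulative sums). The
convention is recorded in every output. Whether the distance should be
measured to heavy atoms only cannot be decided from first principles here;
the class labels make the definition configurable.

## Correlators

All lag-dependent estimators average over sliding time origins on a
logarithmically spaced lag grid (~12 points per decade, snapped to frame
multiples), with a configurable origin stride and a cap on the number of
origins (default 10^4). Lags with zero admitted pairs are reported as gaps
(NaN with zero count), never as zeros.

- **SISF.** The defining average `⟨e^{−iQ·Δr}⟩` for a scalar wavenumber is
  evaluated with the exact isotropic kernel `sin(Q|Δr|)/(Q|Δr|)` (1 at
  `Δr = 0`), the standard choice for liquids; it avoids picking arbitrary
  Q-vectors and makes the SVHF↔SISF Fourier-pair identity hold exactly on
  identical admitted pairs (verified to <1e-3; the residual is pure binning
  error). Default Q = 22.5 nm⁻¹.
- **SVHF.** Histogram of displacement magnitudes at one lag, normalized to
  a probability density over `[0, r_max]`; mass beyond `r_max` is excluded
  from the normalization and reported as an overflow fraction (warning above
  1%). The quantity is the probability density of the displacement
  *magnitude* (`∫ dr = 1`), i.e. the r²-weighted radial part of the van
  Hove function — the only normalization under which the density statements
  in the outputs are dimensionally consistent. Default bin width 0.005 nm
  (ten bins across the ~0.05 nm cage scale) and r_max = 4 nm (protein-driven
  hops reach ~3 nm). Alongside the mean density the estimator stores
  densities over disjoint *particle* blocks (default 8): particles are the
  independent sampling units (time origins of one particle are strongly
  correlated), so the cross-block scatter is an honest standard error, used
  by the feature detector below. A refined mode estimate fits a local
  quadratic to log density around the maximal bin, which beats the raw
  argmax when the density is flat near its mode.
- **MSD** uses the squared-displacement kernel on the same machinery, and
  **g(r)** is the standard pair-distance histogram normalized by ideal-gas
  shell counts in the periodic box (r_max ≤ L/2 enforced).

## Relaxation model and fits

The hydration-water SISF is modelled as a ballistic Gaussian plus two
Kohlrausch (stretched-exponential) terms — the α relaxation and the slower
protein-coupled long relaxation; amplitudes sum to 1 at t = 0. Bulk-like
water uses the two-term variant (f_long pinned to 0). Fits are
least-squares with uniform weights on the log-spaced grid (equal weight per
decade; per-point weighting by counts is available), via lmfit. Numerical
choices:

- the amplitude simplex `f_α + f_long ≤ 1` is built in by fitting
  `f_long = (1 − f_α)·g` with `g ∈ [0, 1]`, which keeps the residual smooth;
- deterministic initialization from the curve shape: τ_s from the earliest
  decay, τ_α from the lag where the curve crosses midway between its early
  plateau and tail, τ_long two decades above, β = 0.8;
- the model is symmetric under exchange of the two stretched terms, so
  labels are canonicalized: if the α amplitude collapses (<5% of the total
  stretched amplitude) the dominant term is relabelled α; otherwise
  τ_α ≤ τ_long is enforced by a label swap (warned and flagged);
- degenerate inputs (e.g. a constant curve) push a *material* relaxation
  time to its upper bound; such fits are flagged not-converged and report no
  parameters.

Under the study conditions of the recovery tests (three-term curves sampled
at 12 points/decade over the full decay, 1% multiplicative noise, τ_α and
τ_long separated by ≥1.2 decades) all seven parameters come back with
median relative errors ~1–2%.

## Temperature laws and crossovers

Arrhenius fits are linear regressions of ln τ on 1/T with
E_A = slope · k_B (k_B = 0.0083145 kJ/(mol·K); E_A in kJ/mol); they are
exact on noiseless data. Power-law fits profile T_C: an outer bounded
scalar minimization of the SSR over T_C with an inner linear regression of
ln τ on ln(T − T_C); T_C uncertainty comes from the curvature of the
profiled SSR. Crossover detection scans every interior breakpoint with at
least 3 points per branch, fits each branch with its candidate law, and
keeps the breakpoint minimizing the total SSR in ln τ — accepted only if it
improves on the best single-law fit by ≥5% (configurable), and never when
the single law already fits to numerical precision. The crossover
temperature is the intersection of the two fitted laws in ln τ (bisection
on a dense grid), with the spread of the intersection over adjacent
breakpoints as its uncertainty. Both the breakpoint and the intersection
are reported, since either convention is defensible.

## Caging and hopping detectors

- **Peaks and shoulders.** The SVHF density is smoothed with a 5-bin moving
  quadratic (Savitzky–Golay). The main peak is the global maximum;
  secondary peaks are further local maxima with prominence above 2% of the
  main height *and* above 8 cross-block standard errors of the smoothed
  density. Shoulders are pockets of negative curvature — local maxima of
  −ρ″ after double smoothing — with curvature prominence above 5% of the
  strongest curvature *and* above 15 cross-block standard errors of the
  curvature, excluding bins within a window of a detected peak. The two
  signal-to-noise gates were calibrated once on the free-diffusion null
  (unimodal density, realistic counting noise): across 60 seeded runs the
  detector reports exactly one feature, while the hop scenarios retain all
  planted features. Without block information the gate falls back to white
  per-bin noise propagated through the exact filter coefficients, which is
  only appropriate for analytic (noise-free or uncorrelated) densities.
- **Plateaus.** The local slope d(log v)/d(log t) is estimated by linear
  regression in a sliding 5-point window; maximal runs with |slope| < 0.1
  spanning ≥ 0.5 decades are plateaus, with the median value as level. The
  0.1 threshold separates true plateaus from sub-diffusive segments with
  exponents ~0.66 with margin.
- **Localization lengths.** From an MSD plateau, `√level`; from a SISF
  plateau φ, the Gaussian-confinement (Debye–Waller) inversion
  `a = √(−3 ln φ)/Q`. For an ideal Gaussian cage of per-coordinate width σ
  these two definitions give `√6 σ` and `√3 σ` respectively — the same
  ~0.05 nm scale but an exact factor √2 apart, because the MSD plateau is a
  *two-time displacement* variance while the Debye–Waller amplitude is a
  one-time excursion. The tests assert this factor; measured estimates on
  real data tend to sit closer together because plateau heights are read
  off imperfectly flat curves.
- **Sub-diffusion exponent** by log-log linear regression inside a window of
  at least half a decade.

## Synthetic study conditions

The generators emulate the statistical structure the analysis assumes, not
molecular detail: point particles, overdamped cage rattling (position
resampled from an isotropic Gaussian each frame — no inertial memory; the
t² ballistic regime is exercised with a constant-velocity fixture instead),
Poisson hop events thinned to at most one per frame (valid for
rate·dt ≪ 1), and hop distances drawn uniformly from a discrete set. No
hydrogen bonding, no electrostatics, no real protein structure: passing
tests demonstrate estimator correctness on processes with known truth, not
force-field realism. Default conditions follow the phenomenology the
package targets: cage σ = 0.0224 nm (MSD plateau 6σ² ≈ 0.003 nm²), hop
distances at the water-shell positions 0.29/0.45/0.67 nm, protein-trap
plateau ≈ 0.6 nm², escape jumps of ~2.5 nm, and τ(T) plants with
T_C = 199 K, γ = 2.68, E_A = 61.9 kJ/mol (α) and 26.6/39.3 kJ/mol (long),
joined continuously at 215 K and 240 K.

The two-scale trap deserves its timescale budget spelled out. The outer-hop
contribution to the MSD is ~λ₂ t L²; a clean second plateau needs this to
stay ≲10% of the plateau level throughout the plateau window, which with
L = 2.5 nm caps the escaped population at long lags at a few percent — too
few to populate a detectable hop feature in the same run. The demonstration
therefore uses two configurations of the same generator: a slow-escape one
(σ = 0.05 nm, inner hops of 0.6 nm at 4·10⁻³/ps inside a 0.75 nm trap,
λ₂ = 0; 24 ns at dt = 0.2 ps) whose MSD shows both plateaus, the second
matching a brute-force Monte-Carlo simulation of the identical process run
at a coarser time step (legitimate because every ingredient of the process
is time-step invariant); and a fast-escape one (λ₂ = 5·10⁻⁴/ps, L = 2.5 nm;
6 ns at dt = 1 ps) whose long-lag van Hove develops the beyond-shell
feature near L. The trap radius 0.75 nm was set from the oracle so the
second plateau sits at 0.6 nm². Inner cage-centre proposals leaving the
trap sphere are radially reflected about its surface (r → 2R − r, clipped
to [0, R]).

Problem sizes throughout the suite are desk-scale by design: the
closed-form Brownian checks run 2000 particles × 10⁴ frames; recovery
studies use 50 parameter draws; feature-null calibration uses
300-particle runs. Determinism is end to end: every random draw flows
through `numpy.random.default_rng(seed)` and identical configs give
bit-identical trajectories.

## Pipeline

Stages communicate only through files; the manifest records the config
snapshot, package version and SHA-256 checksums of every output, so a rerun
under the same seed reproduces identical checksums and partially complete
runs are diagnosable (failures leave a `FAILED` marker naming the stage).
The temperature scan assembles τ_α(T) and τ_long(T) from converged
per-temperature fits (≥3 required; non-converged temperatures are dropped
with a warning) and applies the law fits and crossover scan to each.

## Known limitations

- Cubic boxes only; no triclinic cells, velocities or constraints, and the
  only trajectory format is the package's extended-XYZ contract.
- Origin-overlapping averages make naive per-sample error bars invalid;
  where uncertainty matters (feature detection, closed-form tests) the
  package uses particle-level resampling instead, but the correlator TSVs
  themselves carry counts, not error bars.
- The shoulder detector's noise gates are calibrated for histogram noise of
  the kind the generators produce; densities with strongly structured
  artefacts (e.g. aliasing from too-coarse frame spacing) can still fool
  the curvature test.
- The crossover scan assumes a single breakpoint; series with more than two
  regimes will report the dominant one.
- `fit_relaxation` needs the curve to cover the full decay of whichever
  terms carry material amplitude; curves truncated mid-decay are flagged
  not-converged rather than extrapolated.
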