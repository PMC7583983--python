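# hydroshell

Translational dynamics of protein hydration water from particle
trajectories: shell-restricted density correlators, multi-term relaxation
fits, temperature-law crossover analysis, and quantitative detection of the
caging and hopping signatures of supercooled liquids.

Water within ~6 Å of a protein surface relaxes through **two** slow
processes rather than the single structural (α) relaxation of bulk water: a
bulk-like α relaxation out of the nearest-neighbour cage, and a slower
"long" relaxation coupled to the protein's internal motion. `hydroshell`
implements the estimators and models needed to measure both from
coordinate trajectories, and ships stochastic trajectory generators with
known ground truth so every stage of the analysis is testable at desk
scale. It is aimed at people analysing MD trajectories of hydrated
biomolecules or supercooled liquids, and at method developers who need
trustworthy reference implementations of these estimators.

## What it computes

For water oxygens inside the hydration shell (minimum-image distance to the
nearest protein atom ≤ 0.6 nm, with the membership convention — at the time
origin, at both ends, or continuously — an explicit recorded parameter):

- **SISF** — self intermediate scattering function at wavenumber Q,
  `F_self(Q,t) = ⟨ sin(Q|Δr|)/(Q|Δr|) ⟩` over time origins and particles
  (exact isotropic average; default Q = 22.5 nm⁻¹, the principal maximum of
  the structure factor of water);
- **SVHF** — radial self van Hove function: the probability density of a
  displacement magnitude r after lag t (`∫ dr = 1`), plus the lag
  dependence of its main-maximum height;
- **MSD** — mean square displacement `⟨|Δr|²⟩`, and the radial distribution
  function g(r) used as the hop-distance reference.

The SISF is fitted with the three-term relaxation model

    F(Q,t) = (1 − f_α − f_long) e^{−(t/τ_s)²}
             + f_α e^{−(t/τ_α)^{β_α}}
             + f_long e^{−(t/τ_long)^{β_long}}

(ballistic Gaussian + two Kohlrausch stretched exponentials; bulk water uses
only the first two terms with amplitudes normalized to 1). Relaxation-time
series τ(T) are analysed with the mode-coupling power law
`τ ∼ (T − T_C)^{−γ}` (fragile) and the Arrhenius law `τ ∼ e^{E_A/k_B T}`
(strong); a breakpoint scan in ln τ locates fragile-to-strong and
strong-to-strong crossovers. Feature detectors turn the qualitative
signatures of glassy dynamics into numbers: plateaus of the MSD and of the
SVHF peak-height curve (caging; localization length `√plateau`, or
`√(−3 ln φ)/Q` from the SISF plateau φ), multimodality of the SVHF
(activated hopping; shoulders aligned with g(r) shells are neighbour-cage
hops, features at 0.8–3 nm mark protein-driven displacements), and the
sub-diffusion exponent δ of `MSD ∝ t^δ`.

Because deposited trajectories do not exist for this problem at testing
scale, the `synthetic` module generates them with known dynamics: free
diffusion, harmonic-cage rattling with Poisson hops onto discrete shell
distances, a hierarchical two-scale trap (neighbour cage inside a larger
transiently-trapping sphere with rare long escape jumps), a rigid
protein-plus-water scene, and τ(T) tables following either temperature law.

## Worked example

Run the analysis scripts in order (outputs under `results/`, bulky
regenerable inputs under `scratch/`):

```
cd analysis
python 01_simulate_trajectories.py
python 02_select_hydration_shell.py
python 03_compute_correlators.py
python 04_fit_relaxations.py
python 05_detect_caging_hopping.py
```

Step 04 prints, for the synthetic suite:

```
free_diffusion (bulk_two_term): tau_alpha = 0.198 ps (beta_alpha = 0.99, f_long = 0.000)
hopping (hydration_three_term): tau_alpha = 479 ps (beta_alpha = 1.00, f_long = 0.002)
caged SISF plateau 0.776 -> cage radius 0.039 nm
tau_alpha: fragile_to_strong at T = 215.0 K (planted at 215 K)
  high-T branch: TC = 199.0 K, gamma = 2.68; low-T branch: EA = 61.9 kJ/mol
tau_long: strong_to_strong at T = 240.0 K (planted at 240 K)
  EA = 26.6 (high T) / 39.3 (low T) kJ/mol
```

The free-diffusion fit recovers the Brownian closed form
τ = 1/(Q²D) = 0.1975 ps; the caged scenario's SISF plateau
exp(−Q²σ²) = 0.776 converts back to a cage radius of σ√3 ≈ 0.039 nm; and
the two planted temperature laws are recovered with their crossovers at the
planted temperatures. Step 05 then reports the caging/hopping picture:

```
caged: 1 MSD plateau(s): [0.1-149.9 ps] level 0.00301 nm^2 -> 0.055 nm
two_scale_trap: 2 MSD plateau(s): [0.2-1.6 ps] level 0.0159 nm^2 -> 0.126 nm,
                [2176.4-11999.8 ps] level 0.609 nm^2 -> 0.780 nm
free diffusion: MSD ~ t^1.001 (diffusive limit, delta = 1)
hopping SVHF at 350 ps: main_peak@0.04 nm, secondary_peak@0.68 nm
  -> 1 shell-scale feature(s), 0 beyond-shell (protein-type) feature(s)
two_scale_trap_escaping SVHF at 2500 ps: main_peak@0.68 nm, secondary_peak@2.58 nm
  -> 0 shell-scale feature(s), 1 beyond-shell (protein-type) feature(s)
```

The two-scale trap shows the two caging regimes in a single MSD — the
neighbour cage (plateau 6σ², localization 0.126 nm here) and the
protein-scale trap (0.61 nm², localization 0.78 nm) — and, once escape
jumps are switched on, a van Hove feature near the 2.5 nm jump length, far
beyond any water shell.

A `hydroshell` command-line tool exposes the same stages
(`generate`, `shell`, `sisf`, `svhf`, `msd`, `rdf`, `fit`, `features`,
`scan`, `run`); `hydroshell run --config run.toml` executes the full
pipeline and writes a manifest with per-file checksums.

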