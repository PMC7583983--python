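#!/usr/bin/env python
"""Define the synthetic study conditions and generate the shared inputs.

Writes, under scratch/data/ (bulky and fully regenerable):
  protein_scene.xyz      -- rigid protein cluster + waters (shell fixture),
                            small enough to keep as an extended-XYZ artifact
  generator_configs.json -- seeded configurations of every scenario; the
                            generators are bit-reproducible, so the config
                            file is the trajectory artifact for the large
                            scenarios and later stages regenerate them
  tau_alpha.tsv          -- fragile-to-strong tau_alpha(T) plant (join 215 K)
  tau_long.tsv           -- strong-to-strong tau_long(T) plant (join 240 K)

Scenarios (all lengths nm, times ps, rates 1/ps):
  free_diffusion          Brownian walkers, D = 0.01 (diffusive oracle)
  caged                   frozen neighbour cage, sigma = 0.0224
  hopping                 cage + Poisson hops onto the 0.29/0.45/0.67 shells
  two_scale_trap          neighbour cage inside a 0.75 nm transient trap,
                          no escape: two caging regimes in one MSD
  two_scale_trap_escaping same trap with 2.5 nm escape jumps: long-lag
                          displacement features far beyond the water shells
"""

import json

import numpy as np

from hydroshell import GeneratorConfig, TemperatureSeries, generate, write_trajectory
from hydroshell.synthetic import KB_KJ_PER_MOL_K, tau_arrhenius
from _paths import DATA_DIR

SEED = 2026

CONFIGS = {
    "free_diffusion": GeneratorConfig(
        500, 0.1, 4000, 5.0, SEED, "free_diffusion", {"D": 0.01}
    ),
    "caged": GeneratorConfig(
        500, 0.1, 3000, 5.0, SEED + 1, "caged_hopping", {"sigma": 0.0224}
    ),
    "hopping": GeneratorConfig(
        800, 0.1, 4000, 5.0, SEED + 2, "caged_hopping",
        {"sigma": 0.0224, "hop_rate": 2e-3, "hop_distances": [0.29, 0.45, 0.67]},
    ),
    "protein_scene": GeneratorConfig(
        400, 0.1, 100, 6.0, SEED + 3, "protein_scene", {"n_protein": 30, "D": 0.005}
    ),
    "two_scale_trap": GeneratorConfig(
        150, 0.2, 120_000, 10.0, SEED + 4, "two_scale_trap",
        {"sigma": 0.05, "hop_rate": 4e-3, "hop_distances": [0.6],
         "trap_radius": 0.75, "escape_rate": 0.0, "jump_length": 0.0},
    ),
    "two_scale_trap_escaping": GeneratorConfig(
        400, 1.0, 6000, 10.0, SEED + 5, "two_scale_trap",
        {"sigma": 0.05, "hop_rate": 5e-3, "hop_distances": [0.6],
         "trap_radius": 0.75, "escape_rate": 5e-4, "jump_length": 2.5},
    ),
}


def tau_plants():
    T = np.arange(200.0, 301.0, 5.0)
    # alpha relaxation: fragile (power law, TC=199 K, gamma=2.68) above the
    # join, strong (Arrhenius, EA=61.9 kJ/mol) below, continuous at 215 K
    tau0_pl = 4.7e5  # puts tau_alpha(300 K) near 2 ps
    tau_join = tau0_pl * (215.0 - 199.0) ** -2.68
    tau0 = tau_join / np.exp(61.9 / (KB_KJ_PER_MOL_K * 215.0))
    tau_a = np.where(T >= 215.0, tau0_pl * (T - 199.0) ** -2.68,
                     tau_arrhenius(T, 61.9, tau0))
    # long relaxation: two Arrhenius branches (26.6 / 39.3 kJ/mol), join 240 K
    tau_join = tau_arrhenius(240.0, 26.6, 1e-3)
    tau0_lo = tau_join / np.exp(39.3 / (KB_KJ_PER_MOL_K * 240.0))
    tau_l = np.where(T >= 240.0, tau_arrhenius(T, 26.6, 1e-3),
                     tau_arrhenius(T, 39.3, tau0_lo))
    return (TemperatureSeries(T, tau_a, "tau_alpha"),
            TemperatureSeries(T, tau_l, "tau_long"))


def load_config(name) -> GeneratorConfig:
    """Used by the later stages to regenerate a scenario from its record."""
    records = json.loads((DATA_DIR / "generator_configs.json").read_text())
    return GeneratorConfig(**records[name])


def main():
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    records = {name: cfg.sidecar() for name, cfg in CONFIGS.items()}
    (DATA_DIR / "generator_configs.json").write_text(json.dumps(records, indent=1))
    for name, cfg in CONFIGS.items():
        span = cfg.n_frames * cfg.dt
        print(f"{name}: {cfg.n_particles} particles x {cfg.n_frames} frames "
              f"({span:g} ps), model={cfg.model}")
    scene = generate(CONFIGS["protein_scene"])
    path = DATA_DIR / "protein_scene.xyz"
    write_trajectory(scene, path, sidecar=CONFIGS["protein_scene"].sidecar())
    print(f"wrote {path.name} ({scene.n_frames} frames x {scene.n_atoms} atoms)")
    for series in tau_plants():
        series.write_tsv(DATA_DIR / f"{series.label}.tsv")
        print(f"{series.label}: {series.temperatures.size} temperatures, "
              f"tau {series.tau_values.min():.3g}-{series.tau_values.max():.3g} ps")


if __name__ == "__main__":
    main()
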