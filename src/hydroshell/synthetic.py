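"""Synthetic trajectories and relaxation-time tables with known ground truth.

These generators emulate the statistical structure of protein hydration-water
dynamics so every downstream estimator can be tested against closed forms or
brute-force oracles:

``free_diffusion``
    Independent Gaussian random walks (per-step coordinate variance
    ``2 D dt``): the diffusive limit, MSD = 6 D t and SISF = exp(-Q^2 D t).
``caged_hopping``
    Overdamped rattling in a harmonic cage (isotropic Gaussian of standard
    deviation ``sigma`` per coordinate about a cage centre) with Poissonian
    hops of the centre to discrete neighbour-shell distances.  This is the
    low-temperature picture of supercooled water: a frozen nearest-neighbour
    cage relaxed by activated jumps onto the surrounding water shells.
``two_scale_trap``
    The caged-hopping walk confined, in addition, to a larger reflecting
    sphere of radius ``R`` (the transient "protein cage"), which itself
    escapes by rare Poisson jumps of length ``L_jump``.  Produces a mean
    square displacement with two plateaus and, at long lags, displacement
    distributions with features at nanometre distances.
``protein_scene``
    A rigid cluster of ``protein`` atoms plus free-diffusing ``water-oxygen``
    particles, some seeded inside the hydration shell -- a fixture for shell
    selection.

Relaxation-time tables tau(T) follow either an Arrhenius law
``tau0 * exp(EA / (kB T))`` (strong liquid) or a mode-coupling power law
``tau0 * (T - TC)**(-gamma)`` (fragile liquid), optionally with multiplicative
log-normal noise.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .trajectory import PROTEIN_CLASS, WATER_CLASS, Trajectory

KB_KJ_PER_MOL_K = 0.0083145  # Boltzmann constant in kJ/(mol K)

MODELS = ("free_diffusion", "caged_hopping", "two_scale_trap", "protein_scene")


class GeneratorError(ValueError):
    """Raised for invalid generator configurations."""


@dataclasses.dataclass
class GeneratorConfig:
    """Configuration of a synthetic trajectory.

    ``model_params`` holds the named physical parameters of the chosen model:
    diffusion coefficient ``D`` (nm^2/ps), cage standard deviation ``sigma``
    (nm, per coordinate), hop rate ``hop_rate`` (1/ps), hop-distance set
    ``hop_distances`` (nm), outer trap radius ``trap_radius`` (nm), outer
    escape rate ``escape_rate`` (1/ps), outer jump length ``jump_length``
    (nm), number of protein atoms ``n_protein`` and cluster radius
    ``cluster_radius`` (protein_scene only).
    """

    n_particles: int
    dt: float  # ps
    n_frames: int
    box_edge: float  # nm
    seed: int
    model: str
    model_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise GeneratorError("dt must be positive")
        if self.n_frames < 2:
            raise GeneratorError("n_frames must be at least 2")
        if self.box_edge <= 0:
            raise GeneratorError("box_edge must be positive")
        if self.n_particles < 1:
            raise GeneratorError("n_particles must be at least 1")
        if self.model not in MODELS:
            raise GeneratorError(f"model must be one of {MODELS}, got {self.model!r}")
        for key, value in self.model_params.items():
            if key == "hop_distances":
                if np.any(np.asarray(value, dtype=float) < 0):
                    raise GeneratorError("hop distances must be non-negative")
            elif np.isscalar(value) and not isinstance(value, str) and value < 0:
                raise GeneratorError(f"model parameter {key!r} must be non-negative")

    def sidecar(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_params"] = {
            k: (list(np.asarray(v, dtype=float)) if np.ndim(v) else v)
            for k, v in self.model_params.items()
        }
        return d


def generate(config: GeneratorConfig) -> Trajectory:
    """Dispatch to the generator named by ``config.model``."""
    return {
        "free_diffusion": generate_free_diffusion,
        "caged_hopping": generate_caged_hopping,
        "two_scale_trap": generate_two_scale_trap,
        "protein_scene": generate_protein_scene,
    }[config.model](config)


def _times(config: GeneratorConfig) -> np.ndarray:
    return np.arange(config.n_frames) * config.dt


def _finish(config: GeneratorConfig, true: np.ndarray, classes: np.ndarray) -> Trajectory:
    return Trajectory(
        coords=np.mod(true, config.box_edge),
        times=_times(config),
        box_edge=config.box_edge,
        atom_classes=classes,
        wrapped=True,
        true_coords=true,
    )


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a standard normal triple is never numerically zero in practice, but be safe
    norm[norm == 0] = 1.0
    return v / norm


# ---------------------------------------------------------------------------
# trajectory generators
# ---------------------------------------------------------------------------


def generate_free_diffusion(config: GeneratorConfig) -> Trajectory:
    """Independent Gaussian random walks with per-step coordinate variance 2 D dt."""
    if config.model != "free_diffusion":
        raise GeneratorError("config.model must be 'free_diffusion'")
    if "D" not in config.model_params:
        raise GeneratorError("free_diffusion requires model_params['D'] (nm^2/ps)")
    D = float(config.model_params["D"])
    if D < 0:
        raise GeneratorError("diffusion coefficient D must be non-negative")
    rng = np.random.default_rng(config.seed)
    n, F = config.n_particles, config.n_frames
    start = rng.uniform(0.0, config.box_edge, size=(1, n, 3))
    step_sd = np.sqrt(2.0 * D * config.dt)
    true = np.empty((F, n, 3))
    true[0] = start
    if step_sd > 0:
        steps = rng.standard_normal((F - 1, n, 3)) * step_sd
        np.cumsum(steps, axis=0, out=steps)
        true[1:] = start + steps
    else:
        true[1:] = start
    classes = np.full(n, WATER_CLASS, dtype=object)
    return _finish(config, true, classes)


def _hop_mask(rng: np.random.Generator, n: int, rate: float, dt: float) -> np.ndarray:
    # Poisson process thinned to at most one event per frame; valid for rate*dt << 1
    p = -np.expm1(-rate * dt)
    return rng.random(n) < p


def generate_caged_hopping(config: GeneratorConfig) -> Trajectory:
    """Harmonic-cage rattling with Poissonian hops to discrete shell distances.

    The cage centre of each particle stays fixed until a Poisson event (rate
    ``hop_rate``) moves it by a distance drawn uniformly from
    ``hop_distances`` in a uniformly random direction.  Around the current
    centre the position is resampled every frame from an isotropic Gaussian
    with per-coordinate standard deviation ``sigma`` (overdamped rattling, no
    inertial memory).  With ``hop_rate = 0`` the long-lag MSD plateaus at
    ``6 sigma^2``.
    """
    if config.model != "caged_hopping":
        raise GeneratorError("config.model must be 'caged_hopping'")
    p = config.model_params
    sigma = float(p.get("sigma", 0.0))
    rate = float(p.get("hop_rate", 0.0))
    dists = np.asarray(p.get("hop_distances", []), dtype=float)
    if rate > 0 and dists.size == 0:
        raise GeneratorError("hop_rate > 0 requires a non-empty hop_distances set")
    rng = np.random.default_rng(config.seed)
    n, F = config.n_particles, config.n_frames
    centres = rng.uniform(0.0, config.box_edge, size=(n, 3))
    true = np.empty((F, n, 3))
    for f in range(F):
        if f > 0 and rate > 0:
            hop = _hop_mask(rng, n, rate, config.dt)
            m = int(hop.sum())
            if m:
                d = rng.choice(dists, size=m)
                centres[hop] += d[:, None] * _unit_vectors(rng, m)
        true[f] = centres
        if sigma > 0:
            true[f] = true[f] + sigma * rng.standard_normal((n, 3))
    classes = np.full(n, WATER_CLASS, dtype=object)
    return _finish(config, true, classes)


def _reflect_into_sphere(rel: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect points about the sphere surface: r -> 2R - r, clipped to [0, R]."""
    r = np.linalg.norm(rel, axis=-1)
    out = r > radius
    if np.any(out):
        r_out = r[out]
        r_new = np.clip(2.0 * radius - r_out, 0.0, radius)
        rel = rel.copy()
        rel[out] *= (r_new / r_out)[:, None]
    return rel


def generate_two_scale_trap(config: GeneratorConfig) -> Trajectory:
    """Hierarchical trap model: neighbour cage inside a larger transient trap.

    Inner dynamics are those of :func:`generate_caged_hopping` (rattling
    ``sigma``, hop rate ``hop_rate``, distances ``hop_distances``) except the
    cage centre is confined to a sphere of radius ``trap_radius`` around the
    trap centre: proposed centres leaving the sphere are radially reflected
    about its surface.  Poisson events at rate ``escape_rate`` translate the
    whole trap (centre and cage) by ``jump_length`` in a uniformly random
    direction.  This produces an MSD with two plateaus -- ``6 sigma^2`` from
    the inner cage and roughly ``(6/5) trap_radius^2`` once the cage centre
    decorrelates inside the trap -- plus long-lag displacement features near
    ``jump_length``.
    """
    if config.model != "two_scale_trap":
        raise GeneratorError("config.model must be 'two_scale_trap'")
    p = config.model_params
    sigma = float(p.get("sigma", 0.0))
    rate1 = float(p.get("hop_rate", 0.0))
    dists = np.asarray(p.get("hop_distances", []), dtype=float)
    R = float(p.get("trap_radius", 0.0))
    rate2 = float(p.get("escape_rate", 0.0))
    Ljump = float(p.get("jump_length", 0.0))
    if rate1 > 0 and dists.size == 0:
        raise GeneratorError("hop_rate > 0 requires a non-empty hop_distances set")
    if R <= sigma:
        raise GeneratorError(
            "trap_radius must exceed sigma (inner cloud cannot exceed outer trap)"
        )
    rng = np.random.default_rng(config.seed)
    n, F = config.n_particles, config.n_frames
    trap = rng.uniform(0.0, config.box_edge, size=(n, 3))
    cage = trap.copy()
    true = np.empty((F, n, 3))
    for f in range(F):
        if f > 0:
            if rate2 > 0:
                esc = _hop_mask(rng, n, rate2, config.dt)
                m = int(esc.sum())
                if m:
                    shift = Ljump * _unit_vectors(rng, m)
                    trap[esc] += shift
                    cage[esc] += shift
            if rate1 > 0:
                hop = _hop_mask(rng, n, rate1, config.dt)
                m = int(hop.sum())
                if m:
                    d = rng.choice(dists, size=m)
                    prop = cage[hop] + d[:, None] * _unit_vectors(rng, m)
                    rel = _reflect_into_sphere(prop - trap[hop], R)
                    cage[hop] = trap[hop] + rel
        true[f] = cage
        if sigma > 0:
            true[f] = true[f] + sigma * rng.standard_normal((n, 3))
    classes = np.full(n, WATER_CLASS, dtype=object)
    return _finish(config, true, classes)


def generate_protein_scene(config: GeneratorConfig) -> Trajectory:
    """Rigid protein cluster plus free-diffusing waters, some seeded in the shell.

    ``n_particles`` counts the water oxygens; the cluster adds
    ``n_protein`` (default 30) static ``protein`` atoms inside a ball of
    radius ``cluster_radius`` (default 0.8 nm) at the box centre.  Half of
    the waters start 0.15-0.55 nm from a protein atom (inside the 0.6 nm
    hydration shell), the rest uniformly in the box; all waters diffuse
    freely with coefficient ``D`` (default 0.01 nm^2/ps).
    """
    if config.model != "protein_scene":
        raise GeneratorError("config.model must be 'protein_scene'")
    p = config.model_params
    n_protein = int(p.get("n_protein", 30))
    cluster_radius = float(p.get("cluster_radius", 0.8))
    D = float(p.get("D", 0.01))
    shell_fraction = float(p.get("shell_fraction", 0.5))
    rng = np.random.default_rng(config.seed)
    n_w, F, L = config.n_particles, config.n_frames, config.box_edge

    prot = 0.5 * L + cluster_radius * _unit_vectors(rng, n_protein) * rng.random(
        (n_protein, 1)
    ) ** (1.0 / 3.0)

    n_shell = int(round(shell_fraction * n_w))
    host = rng.integers(0, n_protein, size=n_shell)
    r0 = rng.uniform(0.15, 0.55, size=n_shell)
    w_shell = prot[host] + r0[:, None] * _unit_vectors(rng, n_shell)
    w_bulk = rng.uniform(0.0, L, size=(n_w - n_shell, 3))
    w_start = np.vstack([w_shell, w_bulk])

    true = np.empty((F, n_protein + n_w, 3))
    true[:, :n_protein] = prot  # rigid, static cluster
    step_sd = np.sqrt(2.0 * D * config.dt)
    true[0, n_protein:] = w_start
    if step_sd > 0:
        steps = rng.standard_normal((F - 1, n_w, 3)) * step_sd
        np.cumsum(steps, axis=0, out=steps)
        true[1:, n_protein:] = w_start + steps
    else:
        true[1:, n_protein:] = w_start
    classes = np.concatenate(
        [np.full(n_protein, PROTEIN_CLASS, object), np.full(n_w, WATER_CLASS, object)]
    )
    return _finish(config, true, classes)


# ---------------------------------------------------------------------------
# relaxation-time tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TemperatureSeries:
    """A tau(T) series: relaxation times (ps) on a temperature grid (K)."""

    temperatures: np.ndarray
    tau_values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        if self.temperatures.shape != self.tau_values.shape:
            raise GeneratorError("temperatures and tau_values must align")
        dT = np.diff(self.temperatures)
        if self.temperatures.size > 1 and not (np.all(dT > 0) or np.all(dT < 0)):
            raise GeneratorError("temperatures must be strictly monotone")
        if np.any(self.temperatures <= 0) or np.any(self.tau_values <= 0):
            raise GeneratorError("temperatures and tau values must be positive")

    def sorted_descending(self) -> "TemperatureSeries":
        order = np.argsort(self.temperatures)[::-1]
        return TemperatureSeries(
            self.temperatures[order], self.tau_values[order], self.label
        )

    def write_tsv(self, path) -> None:
        lines = [f"# tau(T) series label={self.label}", "# T_K\ttau_ps"]
        for T, tau in zip(self.temperatures, self.tau_values):
            lines.append(f"{T:.17g}\t{tau:.17g}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path, label: str = "") -> "TemperatureSeries":
        from pathlib import Path

        rows = [
            line.split()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        data = np.asarray(rows, dtype=float)
        return cls(data[:, 0], data[:, 1], label=label)


def tau_arrhenius(T: np.ndarray, EA: float, tau0: float) -> np.ndarray:
    """tau0 * exp(EA / (kB T)); EA in kJ/mol, T in K, result in the units of tau0."""
    T = np.asarray(T, dtype=float)
    return tau0 * np.exp(EA / (KB_KJ_PER_MOL_K * T))


def tau_power_law(T: np.ndarray, TC: float, gamma: float, tau0: float) -> np.ndarray:
    """Mode-coupling power law tau0 * (T - TC)**(-gamma); diverges at TC."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= TC):
        raise GeneratorError("power-law tau(T) requires every T > TC")
    return tau0 * (T - TC) ** (-gamma)


def generate_tau_table(
    law: str,
    params: dict,
    T_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TemperatureSeries:
    """Generate a tau(T) table following an Arrhenius or power law.

    ``noise_sd`` is a relative standard deviation applied multiplicatively in
    log space: ``ln tau -> ln tau + noise_sd * N(0, 1)``.  With
    ``noise_sd = 0`` the table reproduces the law to machine precision.
    """
    if noise_sd < 0:
        raise GeneratorError("noise_sd must be non-negative")
    T = np.asarray(T_grid, dtype=float)
    if law == "arrhenius":
        tau = tau_arrhenius(T, float(params["EA"]), float(params.get("tau0", 1.0)))
    elif law == "power_law":
        tau = tau_power_law(
            T, float(params["TC"]), float(params["gamma"]), float(params.get("tau0", 1.0))
        )
    else:
        raise GeneratorError(f"unknown law {law!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tau = tau * np.exp(noise_sd * rng.standard_normal(T.shape))
    return TemperatureSeries(T, tau, label=label or law)
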