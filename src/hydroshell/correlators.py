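"""Single-particle density correlators with time-origin averaging.

Estimators for the three observables that characterise translational dynamics
of (hydration) water:

* the self intermediate scattering function (SISF)
  ``F_self(Q, t) = < sin(Q |dr|) / (Q |dr|) >`` -- the exact isotropic
  (spherically averaged) form of ``< exp(-i Q . dr) >`` for a scalar
  wavenumber, standard for liquids;
* the radial self van Hove function (SVHF): the probability density of a
  displacement magnitude ``r`` after lag ``t`` (normalized so that
  ``integral dr = 1``);
* the mean square displacement (MSD) ``< |dr|^2 >``.

plus the radial distribution function g(r) used as the hopping-distance
reference, and the lag dependence of the SVHF main-maximum height, whose
plateaus track caging regimes.

All lag-dependent estimators average over sliding time origins; a shell
membership object restricts the admitted (origin, particle) pairs according
to its convention (member at the origin, at both ends, or continuously).
Displacements must come from *continuous* (unwrapped) coordinates.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .trajectory import ShellMembership, Trajectory, TrajectoryUsageError

OBSERVABLES = ("sisf", "msd", "svhf_peak_height")

#: default cap on the number of sliding time origins per lag
MAX_ORIGINS = 10_000


@dataclasses.dataclass
class CorrelationFunction:
    """A correlation estimate on a lag grid, with sampling counts.

    ``values`` are dimensionless for the SISF and nm^2 for the MSD.  Lags
    with no admitted pairs carry ``NaN`` values and zero counts (gaps, never
    zeros).  Lag 0 is handled analytically (SISF = 1, MSD = 0) and does not
    appear on the grid.
    """

    lags: np.ndarray  # ps, strictly increasing, > 0
    values: np.ndarray
    counts: np.ndarray
    observable: str
    Q: float | None = None  # nm^-1, SISF only
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.observable not in OBSERVABLES:
            raise TrajectoryUsageError(f"unknown observable {self.observable!r}")
        if np.any(np.diff(self.lags) <= 0) or (self.lags.size and self.lags[0] <= 0):
            raise TrajectoryUsageError("lags must be strictly increasing and positive")

    def valid(self) -> "CorrelationFunction":
        """Drop gap lags (zero admitted pairs)."""
        keep = self.counts > 0
        return CorrelationFunction(
            self.lags[keep], self.values[keep], self.counts[keep],
            self.observable, self.Q, dict(self.meta),
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"# observable={self.observable}"]
        if self.Q is not None:
            lines.append(f"# Q_nm^-1={self.Q:.17g}")
        for k, v in self.meta.items():
            lines.append(f"# {k}={v}")
        lines.append("lag_ps\tvalue\tcount")
        for lag, v, c in zip(self.lags, self.values, self.counts):
            lines.append(f"{lag:.17g}\t{v:.17g}\t{int(c)}")
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclasses.dataclass
class RadialDisplacementDistribution:
    """Binned probability density of the displacement magnitude at one lag.

    The density integrates to 1 over ``[0, r_max]``; samples beyond the last
    edge are excluded from the normalization and reported as
    ``overflow_fraction``.
    """

    lag: float  # ps
    bin_edges: np.ndarray  # nm
    density: np.ndarray  # per nm
    n_samples: int
    overflow_fraction: float = 0.0
    meta: dict = dataclasses.field(default_factory=dict)
    #: densities estimated on disjoint origin blocks; carries the sampling
    #: uncertainty (including time-origin correlation) for feature detection
    density_blocks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise TrajectoryUsageError("density must have one value per bin")
        if np.any(self.density < 0):
            raise TrajectoryUsageError("density must be non-negative")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def peak_height(self) -> float:
        return float(np.max(self.density))

    def peak_position(self) -> float:
        return float(self.bin_centres[int(np.argmax(self.density))])

    def refined_peak_position(self, half_window: int = 5) -> float:
        """Mode estimate refined by a local quadratic fit of log density.

        Fits ln(density) around the maximal bin over ``half_window`` bins on
        each side, which beats the raw argmax when the density is flat near
        its mode relative to histogram noise.
        """
        i = int(np.argmax(self.density))
        lo, hi = max(0, i - half_window), min(self.density.size, i + half_window + 1)
        r = self.bin_centres[lo:hi]
        d = self.density[lo:hi]
        ok = d > 0
        if ok.sum() < 3:
            return self.peak_position()
        c = np.polyfit(r[ok], np.log(d[ok]), 2)
        if c[0] >= 0:  # not concave locally; fall back
            return self.peak_position()
        return float(np.clip(-c[1] / (2 * c[0]), r[0], r[-1]))

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"# lag_ps={self.lag:.17g}", f"# n_samples={self.n_samples}",
                 f"# overflow_fraction={self.overflow_fraction:.6g}"]
        for k, v in self.meta.items():
            lines.append(f"# {k}={v}")
        lines.append("r_nm\tdensity_per_nm")
        for r, d in zip(self.bin_centres, self.density):
            lines.append(f"{r:.17g}\t{d:.17g}")
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclasses.dataclass
class RadialDistribution:
    """Pair distribution function g(r) on a radial grid."""

    bin_edges: np.ndarray  # nm
    g: np.ndarray

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["r_nm\tg"]
        for r, g in zip(self.bin_centres, self.g):
            lines.append(f"{r:.17g}\t{g:.17g}")
        path.write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# lag grids, origins and admitted pairs
# ---------------------------------------------------------------------------


def log_lag_grid(
    n_frames: int,
    dt: float,
    points_per_decade: int = 12,
    max_lag_fraction: float = 0.5,
) -> np.ndarray:
    """Logarithmically spaced lags (ps) snapped to frame multiples.

    Covers one frame spacing up to ``max_lag_fraction`` of the trajectory
    with roughly ``points_per_decade`` points per decade, deduplicated after
    snapping.
    """
    max_lag = max(1, int(np.floor((n_frames - 1) * max_lag_fraction)))
    if max_lag == 1:
        return np.array([dt])
    n_pts = max(2, int(np.ceil(np.log10(max_lag) * points_per_decade)) + 1)
    frames = np.unique(
        np.round(np.logspace(0, np.log10(max_lag), n_pts)).astype(int)
    )
    frames = frames[(frames >= 1) & (frames <= max_lag)]
    return frames * dt


def _lags_to_frames(traj: Trajectory, lag_grid: np.ndarray | None) -> np.ndarray:
    dt = traj.frame_spacing()
    if lag_grid is None:
        return np.round(log_lag_grid(traj.n_frames, dt) / dt).astype(int)
    frames = np.asarray(lag_grid, dtype=float) / dt
    snapped = np.round(frames).astype(int)
    if np.any(np.abs(frames - snapped) > 1e-6 * np.maximum(snapped, 1)):
        raise TrajectoryUsageError("lag_grid entries must be multiples of the frame spacing")
    snapped = np.unique(snapped[(snapped >= 1) & (snapped < traj.n_frames)])
    if snapped.size == 0:
        raise TrajectoryUsageError("lag_grid contains no usable lags")
    return snapped


def _require_continuous(traj: Trajectory) -> np.ndarray:
    if traj.wrapped:
        raise TrajectoryUsageError(
            "correlators need continuous coordinates; call unwrap_displacements "
            "or Trajectory.unwrapped() first"
        )
    return traj.coords


def _origins(n_frames: int, lag: int, stride: int, max_origins: int) -> np.ndarray:
    origins = np.arange(0, n_frames - lag, stride)
    if origins.size > max_origins:
        idx = np.linspace(0, origins.size - 1, max_origins).astype(int)
        origins = origins[np.unique(idx)]
    return origins


def _particle_columns(traj: Trajectory, membership: ShellMembership | None) -> np.ndarray:
    if membership is not None:
        return membership.water_atom_indices
    wat = traj.water_indices
    return wat if wat.size else np.arange(traj.n_atoms)


def _admitted(
    membership: ShellMembership | None,
    origins: np.ndarray,
    lag: int,
    cum: np.ndarray | None,
) -> np.ndarray | None:
    """Boolean (n_origins, n_particles) mask of admitted pairs, or None for all."""
    if membership is None:
        return None
    if membership.convention == "origin":
        return membership.member[origins]
    if membership.convention == "both_ends":
        return membership.member[origins] & membership.member[origins + lag]
    # continuous: in shell at every frame of the window
    assert cum is not None
    return (cum[origins + lag + 1] - cum[origins]) == (lag + 1)


def _membership_cumsum(membership: ShellMembership | None) -> np.ndarray | None:
    if membership is None or membership.convention != "continuous":
        return None
    csum = np.zeros(
        (membership.member.shape[0] + 1, membership.member.shape[1]), dtype=np.int64
    )
    np.cumsum(membership.member, axis=0, out=csum[1:])
    return csum


def _displacement_norms(
    coords: np.ndarray, cols: np.ndarray, origins: np.ndarray, lag: int,
    mask: np.ndarray | None,
) -> np.ndarray:
    disp = coords[origins + lag][:, cols] - coords[origins][:, cols]
    r = np.linalg.norm(disp, axis=-1)
    return r[mask] if mask is not None else r.ravel()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _time_origin_average(
    traj: Trajectory,
    membership: ShellMembership | None,
    lag_grid: np.ndarray | None,
    origin_stride: int,
    max_origins: int,
    kernel,
    observable: str,
    Q: float | None = None,
) -> CorrelationFunction:
    coords = _require_continuous(traj)
    cols = _particle_columns(traj, membership)
    lags_f = _lags_to_frames(traj, lag_grid)
    dt = traj.frame_spacing()
    cum = _membership_cumsum(membership)
    values = np.full(lags_f.size, np.nan)
    counts = np.zeros(lags_f.size, dtype=int)
    for i, lag in enumerate(lags_f):
        origins = _origins(traj.n_frames, lag, origin_stride, max_origins)
        mask = _admitted(membership, origins, lag, cum)
        r = _displacement_norms(coords, cols, origins, lag, mask)
        counts[i] = r.size
        if r.size:
            values[i] = kernel(r)
        else:
            warnings.warn(f"no admitted pairs at lag {lag * dt:g} ps; reported as gap")
    meta = {
        "origin_stride": origin_stride,
        "convention": membership.convention if membership is not None else "all",
    }
    return CorrelationFunction(lags_f * dt, values, counts, observable, Q, meta)


def isotropic_sisf_kernel(Q: float):
    """Exact spherical average of exp(-i Q . dr): sin(Qr)/(Qr), 1 at r = 0."""

    def kernel(r: np.ndarray) -> float:
        return float(np.mean(np.sinc(Q * r / np.pi)))

    return kernel


def compute_sisf(
    traj: Trajectory,
    membership: ShellMembership | None = None,
    Q: float = 22.5,
    lag_grid: np.ndarray | None = None,
    origin_stride: int = 1,
    max_origins: int = MAX_ORIGINS,
) -> CorrelationFunction:
    """Self intermediate scattering function at wavenumber ``Q`` (nm^-1).

    The default Q = 22.5 nm^-1 sits at the principal maximum of the structure
    factor of water, where slow-dynamics features are best resolved.
    """
    if Q <= 0:
        raise TrajectoryUsageError("Q must be positive")
    return _time_origin_average(
        traj, membership, lag_grid, origin_stride, max_origins,
        isotropic_sisf_kernel(Q), "sisf", Q,
    )


def compute_msd(
    traj: Trajectory,
    membership: ShellMembership | None = None,
    lag_grid: np.ndarray | None = None,
    origin_stride: int = 1,
    max_origins: int = MAX_ORIGINS,
) -> CorrelationFunction:
    """Mean square displacement (nm^2) over the lag grid."""
    return _time_origin_average(
        traj, membership, lag_grid, origin_stride, max_origins,
        lambda r: float(np.mean(r * r)), "msd",
    )


def compute_svhf(
    traj: Trajectory,
    membership: ShellMembership | None = None,
    lag: float = 1.0,
    bin_width: float = 0.005,
    r_max: float = 4.0,
    origin_stride: int = 1,
    max_origins: int = MAX_ORIGINS,
    overflow_warn_fraction: float = 0.01,
    n_blocks: int = 8,
) -> RadialDisplacementDistribution:
    """Radial self van Hove function at one lag (ps).

    Histogram of displacement magnitudes over admitted (origin, particle)
    pairs, normalized to a probability density over ``[0, r_max]``.  The
    default bin width of 0.005 nm resolves the ~0.05 nm cage scale with ten
    bins; the default ``r_max`` of 4 nm covers protein-driven hops.
    """
    if bin_width <= 0:
        raise TrajectoryUsageError("bin_width must be positive")
    coords = _require_continuous(traj)
    cols = _particle_columns(traj, membership)
    dt = traj.frame_spacing()
    lag_frames = int(round(lag / dt))
    if lag_frames < 1 or lag_frames >= traj.n_frames:
        raise TrajectoryUsageError(f"lag {lag} ps outside the trajectory range")
    cum = _membership_cumsum(membership)
    origins = _origins(traj.n_frames, lag_frames, origin_stride, max_origins)
    mask = _admitted(membership, origins, lag_frames, cum)
    disp = coords[origins + lag_frames][:, cols] - coords[origins][:, cols]
    r_all = np.linalg.norm(disp, axis=-1)
    r = r_all[mask] if mask is not None else r_all.ravel()
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(r, bins=edges)
    n_in = int(hist.sum())
    overflow = (r.size - n_in) / r.size if r.size else 0.0
    if overflow > overflow_warn_fraction:
        warnings.warn(
            f"{overflow:.1%} of displacement samples beyond r_max={r_max} nm"
        )
    density = hist / (n_in * bin_width) if n_in else hist.astype(float)
    # densities over disjoint particle blocks: particles are the independent
    # sampling units (origins of one particle are strongly correlated), so
    # the cross-block scatter is an honest sampling error for the density
    blocks = None
    n_cols = r_all.shape[1]
    if n_blocks >= 2 and n_cols >= 2 * n_blocks:
        bounds = np.linspace(0, n_cols, n_blocks + 1).astype(int)
        rows = []
        for b in range(n_blocks):
            sl = slice(bounds[b], bounds[b + 1])
            rb = (
                r_all[:, sl][mask[:, sl]] if mask is not None else r_all[:, sl].ravel()
            )
            hb, _ = np.histogram(rb, bins=edges)
            nb = hb.sum()
            rows.append(hb / (nb * bin_width) if nb else hb.astype(float))
        blocks = np.stack(rows)
    return RadialDisplacementDistribution(
        lag=lag_frames * dt,
        bin_edges=edges,
        density=density,
        n_samples=int(r.size),
        overflow_fraction=float(overflow),
        meta={"convention": membership.convention if membership is not None else "all"},
        density_blocks=blocks,
    )


def svhf_peak_height_curve(
    traj: Trajectory,
    membership: ShellMembership | None = None,
    lag_grid: np.ndarray | None = None,
    bin_width: float = 0.005,
    r_max: float = 4.0,
    origin_stride: int = 1,
    max_origins: int = MAX_ORIGINS,
) -> CorrelationFunction:
    """Height of the SVHF main maximum as a function of lag.

    The decay of the main maximum mirrors the SISF; its plateaus expose the
    caging regimes (neighbour cage at short lags, transient protein-scale
    trap at long lags).
    """
    dt = traj.frame_spacing()
    lags_f = _lags_to_frames(traj, lag_grid)
    values = np.full(lags_f.size, np.nan)
    counts = np.zeros(lags_f.size, dtype=int)
    for i, lag in enumerate(lags_f):
        dist = compute_svhf(
            traj, membership, lag * dt, bin_width, r_max, origin_stride, max_origins
        )
        counts[i] = dist.n_samples
        if dist.n_samples:
            values[i] = dist.peak_height()
    return CorrelationFunction(
        lags_f * dt, values, counts, "svhf_peak_height", None,
        {"bin_width": bin_width, "r_max": r_max},
    )


def compute_rdf(
    traj: Trajectory,
    class_filter: str | None = None,
    bin_width: float = 0.01,
    r_max: float | None = None,
    frame_stride: int = 1,
) -> RadialDistribution:
    """Radial distribution function of one atom class, frame-averaged.

    Pair-distance histogram under the minimum-image convention, normalized by
    ideal-gas shell counts in the periodic box.  ``r_max`` must not exceed
    half the box edge (default: exactly half).
    """
    L = traj.box_edge
    if r_max is None:
        r_max = 0.5 * L
    if r_max > 0.5 * L:
        raise TrajectoryUsageError("r_max must not exceed half the box edge")
    if class_filter is None:
        cols = np.arange(traj.n_atoms)
    else:
        cols = traj.class_indices(class_filter)
    n = cols.size
    if n < 2:
        raise TrajectoryUsageError("need at least two particles of the filtered class")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    frames = range(0, traj.n_frames, frame_stride)
    n_frames_used = 0
    iu = np.triu_indices(n, k=1)
    for f in frames:
        pos = np.mod(traj.coords[f, cols], L)
        diff = pos[:, None, :] - pos[None, :, :]
        diff -= L * np.round(diff / L)
        r = np.sqrt(np.sum(diff * diff, axis=-1))[iu]
        h, _ = np.histogram(r, bins=edges)
        hist += h
        n_frames_used += 1
    V = L**3
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n * (n - 1) / 2.0 * shell_vol / V
    g = hist / (n_frames_used * ideal)
    return RadialDistribution(bin_edges=edges, g=g)
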