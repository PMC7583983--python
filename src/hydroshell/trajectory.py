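"""Trajectory data model, extended-XYZ I/O, periodic unwrapping, shell selection.

Coordinates are in nm, times in ps throughout.  A trajectory is a stack of
frames in a cubic periodic box; atoms carry a class label (``protein``,
``water-oxygen`` or ``other``).  Correlation estimators require *continuous*
(unwrapped) coordinates so that displacements are true displacements rather
than minimum-image artefacts; :func:`unwrap_displacements` reconstructs them
from wrapped frames.

The hydration shell follows the standard definition for protein hydration
water: a water oxygen belongs to the shell at frame ``f`` when its
minimum-image distance to the nearest protein atom is at most the cutoff
(default 0.6 nm).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

PROTEIN_CLASS = "protein"
WATER_CLASS = "water-oxygen"

#: relative tolerance used to validate uniform frame spacing
_DT_RTOL = 1e-6

CONVENTIONS = ("origin", "both_ends", "continuous")


class TrajectoryFormatError(ValueError):
    """Raised when an extended-XYZ file does not parse consistently."""


class TrajectoryUsageError(ValueError):
    """Raised when an operation's preconditions on a trajectory are violated."""


@dataclasses.dataclass(eq=False)
class Trajectory:
    """Time-ordered frames of particle coordinates in a cubic periodic box.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in nm.  Wrapped trajectories keep every coordinate in
        ``[0, box_edge)``; unwrapped (continuous) trajectories may leave the
        box.
    times : ndarray, shape (n_frames,)
        Strictly increasing time stamps in ps.
    box_edge : float
        Cubic box edge in nm.
    atom_classes : sequence of str
        Per-atom class label.
    wrapped : bool
        Whether ``coords`` are wrapped into the box.
    true_coords : ndarray or None
        Ground-truth continuous coordinates, populated by the synthetic
        generators so tests can isolate unwrapping errors.  Never serialized.
    """

    coords: np.ndarray
    times: np.ndarray
    box_edge: float
    atom_classes: np.ndarray
    wrapped: bool = True
    true_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.atom_classes = np.asarray(self.atom_classes, dtype=object)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryUsageError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryUsageError("a trajectory needs at least one frame")
        if self.times.shape != (self.coords.shape[0],):
            raise TrajectoryUsageError("times must have one entry per frame")
        if self.coords.shape[0] > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryUsageError("times must be strictly increasing")
        if self.box_edge <= 0:
            raise TrajectoryUsageError("box_edge must be positive")
        if self.atom_classes.shape != (self.coords.shape[1],):
            raise TrajectoryUsageError("atom_classes must have one entry per atom")
        if self.wrapped:
            if np.any(self.coords < 0) or np.any(self.coords >= self.box_edge):
                raise TrajectoryUsageError(
                    "wrapped coordinates must lie in [0, box_edge)"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_spacing(self) -> float:
        """Uniform frame spacing dt in ps; raises if spacing is not uniform."""
        if self.n_frames < 2:
            raise TrajectoryUsageError("need >= 2 frames to define a frame spacing")
        dts = np.diff(self.times)
        dt = dts[0]
        if np.any(np.abs(dts - dt) > _DT_RTOL * dt):
            raise TrajectoryUsageError("frame spacing is not uniform")
        return float(dt)

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.atom_classes == label)

    @property
    def water_indices(self) -> np.ndarray:
        return self.class_indices(WATER_CLASS)

    @property
    def protein_indices(self) -> np.ndarray:
        return self.class_indices(PROTEIN_CLASS)

    def same_as(self, other: "Trajectory") -> bool:
        """Bit-exact equality of coordinates, times, box and labels."""
        return (
            np.array_equal(self.coords, other.coords)
            and np.array_equal(self.times, other.times)
            and self.box_edge == other.box_edge
            and np.array_equal(self.atom_classes, other.atom_classes)
        )

    def unwrapped(self) -> "Trajectory":
        """Continuous-coordinate view: ground truth if present, else unwrap."""
        if not self.wrapped:
            return self
        if self.true_coords is not None:
            return Trajectory(
                coords=self.true_coords,
                times=self.times,
                box_edge=self.box_edge,
                atom_classes=self.atom_classes,
                wrapped=False,
            )
        return unwrap_displacements(self)


# ---------------------------------------------------------------------------
# extended-XYZ I/O
#
# Frame layout:
#   <n_atoms>
#   box_edge=<nm> time=<ps>
#   <class-label> <x> <y> <z>      (nm, %.17g so floats round-trip exactly)
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a trajectory as extended XYZ; optionally a JSON sidecar of metadata.

    The sidecar (ground-truth generator parameters and the like) is written to
    ``<path>.meta.json`` when given.
    """
    if traj.n_frames == 0:
        raise TrajectoryUsageError("refusing to write an empty trajectory")
    path = Path(path)
    labels = [str(c) for c in traj.atom_classes]
    with open(path, "w") as fh:  # streamed per frame: trajectories can be large
        for f in range(traj.n_frames):
            frame = traj.coords[f]
            lines = [str(traj.n_atoms),
                     f"box_edge={traj.box_edge:.17g} time={traj.times[f]:.17g}"]
            lines.extend(
                f"{labels[a]} {frame[a, 0]:.17g} {frame[a, 1]:.17g} {frame[a, 2]:.17g}"
                for a in range(traj.n_atoms)
            )
            fh.write("\n".join(lines) + "\n")
    if sidecar is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _parse_comment(line: str, frame: int) -> tuple[float, float]:
    fields = dict(tok.split("=", 1) for tok in line.split() if "=" in tok)
    if "box_edge" not in fields or "time" not in fields:
        raise TrajectoryFormatError(
            f"frame {frame}: comment line must carry box_edge= and time=, got {line!r}"
        )
    return float(fields["box_edge"]), float(fields["time"])


def read_trajectory(path: str | Path, format: str = "extended_xyz") -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    if format != "extended_xyz":
        raise TrajectoryUsageError(f"unsupported format {format!r}")
    path = Path(path)
    raw = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    classes: list[str] | None = None
    box_edge: float | None = None
    i = 0
    frame_no = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(raw[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {frame_no}: expected an atom count, got {raw[i]!r}"
            ) from exc
        if i + 1 >= len(raw):
            raise TrajectoryFormatError(f"frame {frame_no}: truncated header")
        box, t = _parse_comment(raw[i + 1], frame_no)
        if box_edge is None:
            box_edge = box
        elif box != box_edge:
            raise TrajectoryFormatError(
                f"frame {frame_no}: box edge {box} differs from first frame {box_edge}"
            )
        body = raw[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise TrajectoryFormatError(
                f"frame {frame_no}: expected {n_atoms} atoms, file ends after {len(body)}"
            )
        labels: list[str] = []
        xyz = np.empty((n_atoms, 3))
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"frame {frame_no}: atom line {a} malformed: {line!r}"
                )
            labels.append(parts[0])
            xyz[a] = [float(p) for p in parts[1:]]
        if classes is None:
            classes = labels
        elif len(labels) != len(classes):
            raise TrajectoryFormatError(
                f"frame {frame_no}: atom count {len(labels)} differs from frame 0 ({len(classes)})"
            )
        frames.append(xyz)
        times.append(t)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    assert classes is not None and box_edge is not None
    return Trajectory(
        coords=np.stack(frames),
        times=np.asarray(times),
        box_edge=box_edge,
        atom_classes=np.asarray(classes, dtype=object),
    )


# ---------------------------------------------------------------------------
# periodic boundary handling
# ---------------------------------------------------------------------------


def minimum_image(delta: np.ndarray, box_edge: float) -> np.ndarray:
    """Map displacement components into (-box_edge/2, box_edge/2]."""
    return delta - box_edge * np.round(delta / box_edge)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image Euclidean distance between points ``a`` and ``b``."""
    return np.linalg.norm(minimum_image(np.asarray(a) - np.asarray(b), box_edge), axis=-1)


def unwrap_displacements(traj: Trajectory, max_step_fraction: float = 0.49) -> Trajectory:
    """Reconstruct continuous coordinates from a wrapped trajectory.

    Each inter-frame displacement is taken as the minimum-image displacement
    and accumulated onto the previous unwrapped position.  This is only
    unambiguous when no particle moves more than half a box edge per frame;
    steps beyond ``max_step_fraction * box_edge`` raise an error advising
    denser frame sampling.

    An already-continuous trajectory is returned unchanged.
    """
    if not traj.wrapped:
        return traj
    if traj.n_frames > 1:
        traj.frame_spacing()  # validates uniform spacing
    steps = np.diff(traj.coords, axis=0)
    steps = minimum_image(steps, traj.box_edge)
    if steps.size and np.max(np.abs(steps)) > max_step_fraction * traj.box_edge:
        raise TrajectoryUsageError(
            "per-frame displacement exceeds half the box edge; unwrapping is "
            "ambiguous -- sample frames more densely"
        )
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = out[0] + steps
    return Trajectory(
        coords=out,
        times=traj.times,
        box_edge=traj.box_edge,
        atom_classes=traj.atom_classes,
        wrapped=False,
    )


def rewrap(traj: Trajectory) -> Trajectory:
    """Wrap a continuous trajectory back into the box."""
    coords = np.mod(traj.coords, traj.box_edge)
    return Trajectory(
        coords=coords,
        times=traj.times,
        box_edge=traj.box_edge,
        atom_classes=traj.atom_classes,
        wrapped=True,
    )


# ---------------------------------------------------------------------------
# hydration-shell selection
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ShellMembership:
    """Per-frame membership of each water oxygen in the hydration shell.

    ``member[f, j]`` refers to the water oxygen whose atom index is
    ``water_atom_indices[j]``.  ``convention`` records how correlators admit
    (origin, particle) pairs: in shell at the time *origin*, at *both ends*
    of the lag, or *continuously* over the whole lag window.
    """

    member: np.ndarray  # (n_frames, n_water) bool
    water_atom_indices: np.ndarray
    cutoff: float
    convention: str = "origin"

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        self.water_atom_indices = np.asarray(self.water_atom_indices, dtype=int)
        if self.member.ndim != 2:
            raise TrajectoryUsageError("member must be a frame x water matrix")
        if self.member.shape[1] != self.water_atom_indices.size:
            raise TrajectoryUsageError("member columns must match water_atom_indices")
        if self.convention not in CONVENTIONS:
            raise TrajectoryUsageError(
                f"convention must be one of {CONVENTIONS}, got {self.convention!r}"
            )

    def counts_per_frame(self) -> np.ndarray:
        return self.member.sum(axis=1)

    def write_counts_tsv(self, path: str | Path, times: np.ndarray | None = None) -> Path:
        path = Path(path)
        counts = self.counts_per_frame()
        lines = [f"# shell counts, cutoff={self.cutoff} nm, convention={self.convention}"]
        lines.append("frame\ttime_ps\tcount" if times is not None else "frame\tcount")
        for f, c in enumerate(counts):
            if times is not None:
                lines.append(f"{f}\t{times[f]:.17g}\t{int(c)}")
            else:
                lines.append(f"{f}\t{int(c)}")
        path.write_text("\n".join(lines) + "\n")
        return path


def select_hydration_shell(
    traj: Trajectory,
    cutoff: float = 0.6,
    convention: str = "origin",
) -> ShellMembership:
    """Select hydration-shell waters: within ``cutoff`` of the nearest protein atom.

    Distances use the orthorhombic minimum-image convention in the cubic box
    (all 26 periodic images considered via a periodic KD-tree).  The default
    cutoff is 0.6 nm, the conventional hydration-shell thickness for protein
    hydration water.
    """
    if convention not in CONVENTIONS:
        raise TrajectoryUsageError(
            f"convention must be one of {CONVENTIONS}, got {convention!r}"
        )
    if cutoff < 0:
        raise TrajectoryUsageError("cutoff must be non-negative")
    prot = traj.protein_indices
    wat = traj.water_indices
    if prot.size == 0:
        raise TrajectoryUsageError("trajectory contains no protein atoms")
    if wat.size == 0:
        raise TrajectoryUsageError("trajectory contains no water-oxygen atoms")
    L = traj.box_edge
    member = np.empty((traj.n_frames, wat.size), dtype=bool)
    for f in range(traj.n_frames):
        ppos = np.mod(traj.coords[f, prot], L)
        wpos = np.mod(traj.coords[f, wat], L)
        # cKDTree with boxsize requires coordinates strictly inside [0, L)
        ppos[ppos >= L] = 0.0
        wpos[wpos >= L] = 0.0
        tree = cKDTree(ppos, boxsize=L)
        dist, _ = tree.query(wpos, k=1)
        member[f] = dist <= cutoff
    return ShellMembership(
        member=member,
        water_atom_indices=wat,
        cutoff=cutoff,
        convention=convention,
    )
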