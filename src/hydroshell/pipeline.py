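"""Pipeline orchestration: generate -> shell -> correlate -> fit -> features.

Each stage consumes and produces files; the run manifest records the config
snapshot, software version and per-file SHA-256 checksums so a run is
reproducible bit-for-bit under a fixed seed and resumable when outputs
already match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from ._version import __version__ as _version
from .correlators import (
    compute_msd,
    compute_rdf,
    compute_sisf,
    compute_svhf,
    log_lag_grid,
    svhf_peak_height_curve,
)
from .features import detect_peaks_and_shoulders, detect_plateaus
from .relaxation import detect_crossover, fit_relaxation, fit_temperature_law
from .synthetic import GeneratorConfig, TemperatureSeries, generate
from .trajectory import (
    Trajectory,
    TrajectoryUsageError,
    read_trajectory,
    select_hydration_shell,
    write_trajectory,
)

log = logging.getLogger("hydroshell.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Full configuration of a pipeline run; every parameter recorded."""

    output_dir: str
    seed: int = 0
    # input: either a trajectory file or a generator config
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    # shell selection
    shell_cutoff: float = 0.6
    shell_convention: str = "origin"
    # correlators
    Q_list: tuple[float, ...] = (22.5,)
    points_per_decade: int = 12
    origin_stride: int = 1
    max_origins: int = 2000
    svhf_lags: tuple[float, ...] = ()
    svhf_bin_width: float = 0.005
    svhf_r_max: float = 4.0
    rdf: bool = False
    # fitting
    fit_variant: str = "hydration_three_term"
    # features
    plateau_log_slope_threshold: float = 0.1
    plateau_min_decades: float = 0.5
    feature_min_prominence: float = 0.02

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.sidecar()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        for key in ("Q_list", "svhf_lags"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(generator=gen, **d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict
    warnings: list
    stages: dict  # stage -> {"wall_s": float, "outputs": [...], "skipped": bool}

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Stage order: input (generate or read) -> unwrap -> shell selection (when
    protein atoms are present) -> SISF per Q + MSD + SVHF peak-height ->
    SVHF snapshots -> optional g(r) -> relaxation fits -> feature detection.
    A stage failure aborts with the stage name; earlier outputs are kept and
    the manifest carries a failure marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_path is not None and not Path(config.input_path).exists():
        raise FileNotFoundError(f"input trajectory not found: {config.input_path}")
    if config.input_path is None and config.generator is None:
        raise TrajectoryUsageError("config needs either input_path or generator")

    manifest = RunManifest(
        config=config.as_dict(), version=_version, checksums={}, warnings=[], stages={}
    )
    files: dict[str, Path] = {}

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        for p in outputs:
            manifest.checksums[p.name] = _sha256(p)
        manifest.stages[stage] = {
            "wall_s": round(time.monotonic() - t0, 3),
            "outputs": [p.name for p in outputs],
            "skipped": False,
        }

    stage = "input"
    try:
        t0 = time.monotonic()
        if config.generator is not None:
            traj = generate(config.generator)
            traj_path = out / "trajectory.xyz"
            write_trajectory(traj, traj_path, sidecar=config.generator.sidecar())
            record(stage, t0, [traj_path, Path(str(traj_path) + ".meta.json")])
        else:
            traj = read_trajectory(config.input_path)
            record(stage, t0, [])
        cont = traj.unwrapped()

        stage = "shell"
        t0 = time.monotonic()
        membership = None
        shell_outputs: list[Path] = []
        if traj.protein_indices.size:
            membership = select_hydration_shell(
                traj, cutoff=config.shell_cutoff, convention=config.shell_convention
            )
            p = membership.write_counts_tsv(out / "shell_counts.tsv", traj.times)
            np.savez_compressed(
                out / "shell_membership.npz",
                member=membership.member,
                water_atom_indices=membership.water_atom_indices,
            )
            shell_outputs = [p]
        record(stage, t0, shell_outputs)

        stage = "correlate"
        t0 = time.monotonic()
        dt = traj.frame_spacing()
        lag_grid = log_lag_grid(traj.n_frames, dt, config.points_per_decade)
        outputs = []
        sisf_curves = {}
        for Q in config.Q_list:
            c = compute_sisf(
                cont, membership, Q, lag_grid,
                config.origin_stride, config.max_origins,
            )
            sisf_curves[Q] = c
            outputs.append(c.write_tsv(out / f"sisf_Q{Q:g}.tsv"))
        msd = compute_msd(
            cont, membership, lag_grid, config.origin_stride, config.max_origins
        )
        outputs.append(msd.write_tsv(out / "msd.tsv"))
        peak_curve = svhf_peak_height_curve(
            cont, membership, lag_grid, config.svhf_bin_width, config.svhf_r_max,
            config.origin_stride, config.max_origins,
        )
        outputs.append(peak_curve.write_tsv(out / "svhf_peak_height.tsv"))
        svhf_snapshots = {}
        for lag in config.svhf_lags:
            d = compute_svhf(
                cont, membership, lag, config.svhf_bin_width, config.svhf_r_max,
                config.origin_stride, config.max_origins,
            )
            svhf_snapshots[lag] = d
            outputs.append(d.write_tsv(out / f"svhf_lag{lag:g}ps.tsv"))
        if config.rdf:
            rdf = compute_rdf(traj, "water-oxygen", frame_stride=max(1, traj.n_frames // 10))
            outputs.append(rdf.write_tsv(out / "rdf.tsv"))
        record(stage, t0, outputs)

        stage = "fit"
        t0 = time.monotonic()
        outputs = []
        fits = {}
        for Q, c in sisf_curves.items():
            try:
                res = fit_relaxation(c, variant=config.fit_variant)
            except Exception as exc:  # degenerate curves are recorded, not fatal
                manifest.warnings.append(f"fit at Q={Q:g} failed: {exc}")
                continue
            fits[Q] = res
            if res.label_swapped:
                manifest.warnings.append(f"fit at Q={Q:g}: term labels swapped")
            if not res.converged:
                manifest.warnings.append(f"fit at Q={Q:g}: not converged")
            p = out / f"fit_sisf_Q{Q:g}.json"
            p.write_text(json.dumps(res.as_dict(), indent=1))
            outputs.append(p)
        record(stage, t0, outputs)

        stage = "features"
        t0 = time.monotonic()
        feat: dict = {"msd_plateaus": [], "peak_height_plateaus": [], "svhf_profiles": []}
        try:
            feat["msd_plateaus"] = [
                r.as_dict()
                for r in detect_plateaus(
                    msd, config.plateau_log_slope_threshold, config.plateau_min_decades
                )
            ]
        except Exception as exc:
            manifest.warnings.append(f"MSD plateau scan skipped: {exc}")
        try:
            feat["peak_height_plateaus"] = [
                r.as_dict()
                for r in detect_plateaus(
                    peak_curve, config.plateau_log_slope_threshold,
                    config.plateau_min_decades,
                )
            ]
        except Exception as exc:
            manifest.warnings.append(f"peak-height plateau scan skipped: {exc}")
        for lag, d in svhf_snapshots.items():
            try:
                prof = detect_peaks_and_shoulders(
                    d, min_prominence=config.feature_min_prominence
                )
                feat["svhf_profiles"].append(prof.as_dict())
            except Exception as exc:
                manifest.warnings.append(f"SVHF features at lag {lag:g} ps skipped: {exc}")
        p = out / "features.json"
        p.write_text(json.dumps(feat, indent=1))
        record(stage, t0, [p])
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        if isinstance(exc, (FileNotFoundError, PipelineError)):
            raise
        raise PipelineError(stage, exc) from exc

    manifest.write(out / "manifest.json")
    return manifest


def scan_temperatures(
    configs: list[RunConfig],
    labels: list[float],
    Q: float | None = None,
    candidate_laws: tuple[str, str] = ("power_law", "arrhenius"),
) -> dict:
    """Assemble tau_alpha(T) and tau_long(T) from per-temperature runs.

    Runs the pipeline for each labelled config, collects converged relaxation
    fits, and performs the temperature-law and crossover analysis on each
    assembled series.  Requires at least 3 converged fits.
    """
    if len(configs) != len(labels):
        raise TrajectoryUsageError("one temperature label per config required")
    rows = []
    failed = []
    for cfg, T in zip(configs, labels):
        manifest = run_pipeline(cfg)
        q = Q if Q is not None else cfg.Q_list[0]
        fit_file = Path(cfg.output_dir) / f"fit_sisf_Q{q:g}.json"
        if not fit_file.exists():
            failed.append(T)
            continue
        fit = json.loads(fit_file.read_text())
        if not fit["converged"] or fit["params"] is None:
            failed.append(T)
            log.warning("fit at T=%.1f K did not converge; dropped from the scan", T)
            continue
        rows.append((T, fit["params"]["tau_alpha"], fit["params"]["tau_long"]))
    if len(rows) < 3:
        raise TrajectoryUsageError(
            f"fewer than 3 converged fits; failed temperatures: {failed}"
        )
    rows.sort(key=lambda r: -r[0])
    T = np.array([r[0] for r in rows])
    result: dict = {"failed_temperatures": failed}
    for name, idx in (("tau_alpha", 1), ("tau_long", 2)):
        series = TemperatureSeries(T, np.array([r[idx] for r in rows]), label=name)
        entry: dict = {"series": {"T_K": T.tolist(),
                                  "tau_ps": series.tau_values.tolist()}}
        for law in set(candidate_laws):
            try:
                entry[f"fit_{law}"] = fit_temperature_law(series, law).as_dict()
            except Exception as exc:
                entry[f"fit_{law}"] = {"error": str(exc)}
        try:
            entry["crossover"] = detect_crossover(series, candidate_laws).as_dict()
        except Exception as exc:
            entry["crossover"] = {"error": str(exc)}
        result[name] = entry
    return result
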