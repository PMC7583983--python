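"""Quantitative detection of caging and hopping signatures.

Supercooled-liquid phenomenology shows up in the correlators as a handful of
geometric features:

* multimodality of the radial van Hove function -- secondary peaks and
  shoulders marking activated hops onto neighbour shells (sub-nm) or
  protein-driven displacements (0.8-3 nm);
* plateaus in the MSD and in the SVHF peak-height curve -- transient caging,
  whose level yields a localization length;
* sub-diffusive power-law segments of the MSD between caging regimes.

The detectors here turn those visual signatures into reproducible numbers:
smoothed-curvature shoulder detection, sliding log-log slope plateau scans,
and log-log regression for the sub-diffusion exponent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .correlators import (
    CorrelationFunction,
    RadialDisplacementDistribution,
    RadialDistribution,
)


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peaks and shoulders
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Feature:
    position: float  # nm
    height: float  # density at the feature
    kind: str  # main_peak | secondary_peak | shoulder
    prominence: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PeakProfile:
    """Ordered features of one radial displacement distribution."""

    lag: float  # ps
    features: list[Feature]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.position)
        mains = [f for f in self.features if f.kind == "main_peak"]
        if len(mains) != 1:
            raise FeatureError("a profile must contain exactly one main_peak")

    @property
    def main_peak(self) -> Feature:
        return next(f for f in self.features if f.kind == "main_peak")

    def non_main(self) -> list[Feature]:
        return [f for f in self.features if f.kind != "main_peak"]

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])

    def as_dict(self) -> dict:
        return {"lag": self.lag, "features": [f.as_dict() for f in self.features]}


def detect_peaks_and_shoulders(
    dist: RadialDisplacementDistribution,
    smoothing: int = 5,
    min_prominence: float = 0.02,
    curvature_prominence: float = 0.05,
    curvature_snr: float = 15.0,
    peak_snr: float = 8.0,
) -> PeakProfile:
    """Locate the main maximum, secondary maxima and shoulders of a SVHF.

    The density is smoothed with a moving quadratic (Savitzky-Golay) filter of
    ``smoothing`` bins.  The main peak is the global maximum; secondary peaks
    are further local maxima with prominence above ``min_prominence`` (relative
    to the main height).  Shoulders are pockets of negative curvature of the
    smoothed density -- local maxima of ``-d2 rho/dr2`` with curvature
    prominence above both ``curvature_prominence`` (relative to the strongest
    curvature) and ``curvature_snr`` times the noise level of the curvature
    estimate -- that do not coincide with a detected peak.  The per-bin
    histogram noise is measured from the smoothing residual (robust MAD) and
    propagated through the exact Savitzky-Golay curvature operator, so the
    gate adapts to the sampling quality: a smooth unimodal density yields
    exactly one feature regardless of counting noise.
    """
    rho = dist.density
    if rho.size < 20:
        raise FeatureError("need at least 20 bins to detect features")
    if not np.any(rho > 0):
        raise FeatureError("all-zero density")
    window = max(5, smoothing | 1)  # odd, >= 5
    smooth = savgol_filter(rho, window, polyorder=2)
    centres = dist.bin_centres
    dr = dist.bin_width

    # per-bin counting noise, measured from the smoothing residual
    resid = rho - smooth
    sigma_bin = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    c_smooth = savgol_coeffs(window, 2)

    i_main = int(np.argmax(smooth))
    scale = float(smooth[i_main])
    features = [Feature(float(centres[i_main]), float(smooth[i_main]), "main_peak",
                        prominence=1.0)]

    # standard error of the smoothed density: cross-block scatter over
    # particle blocks when available, else white per-bin propagation
    if dist.density_blocks is not None and dist.density_blocks.shape[0] >= 4:
        sm_blocks = np.stack(
            [savgol_filter(b, window, 2) for b in dist.density_blocks]
        )
        B = sm_blocks.shape[0]
        se_density = np.std(sm_blocks, axis=0, ddof=1) / np.sqrt(B)
    else:
        se_density = np.full(
            rho.size, sigma_bin * float(np.linalg.norm(c_smooth))
        )

    peak_floor = max(
        min_prominence * scale,
        4.0 * sigma_bin * float(np.linalg.norm(c_smooth)),
    )
    peak_idx, props = find_peaks(smooth, prominence=peak_floor)
    occupied = [i_main]
    for i, prom in zip(peak_idx, props["prominences"]):
        if abs(i - i_main) <= window:
            continue
        if prom < peak_snr * se_density[i]:
            continue
        features.append(
            Feature(float(centres[i]), float(smooth[i]), "secondary_peak",
                    prominence=float(prom / scale))
        )
        occupied.append(int(i))

    # curvature of the (already smoothed) density; double smoothing damps
    # histogram noise, which second derivatives amplify as 1/dr^2
    def curvature(y: np.ndarray) -> np.ndarray:
        s = savgol_filter(y, window, polyorder=2)
        return savgol_filter(s, window, polyorder=2, deriv=2, delta=dr)

    d2 = curvature(rho)
    neg_curv = -d2
    cmax = float(np.max(neg_curv)) if np.any(neg_curv > 0) else 0.0
    # standard error of the curvature: cross-block scatter when origin-block
    # densities are available (captures time-origin correlation), otherwise
    # white per-bin noise propagated through the composed filter
    if dist.density_blocks is not None and dist.density_blocks.shape[0] >= 4:
        d2_blocks = np.stack([curvature(b) for b in dist.density_blocks])
        B = d2_blocks.shape[0]
        se_curv = np.std(d2_blocks, axis=0, ddof=1) / np.sqrt(B)
    else:
        c_d2 = savgol_coeffs(window, 2, deriv=2, delta=dr)
        white = sigma_bin * float(np.linalg.norm(np.convolve(c_smooth, c_d2)))
        se_curv = np.full(rho.size, white)
    if cmax > 0:
        sh_idx, sh_props = find_peaks(
            neg_curv, prominence=curvature_prominence * cmax
        )
        for i, prom in zip(sh_idx, sh_props["prominences"]):
            if any(abs(i - j) <= window for j in occupied):
                continue
            if prom < curvature_snr * se_curv[i]:
                continue
            features.append(
                Feature(float(centres[i]), float(smooth[i]), "shoulder",
                        prominence=float(prom / cmax))
            )
            occupied.append(int(i))
    return PeakProfile(lag=dist.lag, features=features)


@dataclasses.dataclass
class ShellAlignment:
    matched: list[tuple[Feature, float]]  # (feature, matched g(r) peak position)
    unmatched: list[Feature]  # beyond-shell features (protein-type hopping)
    rdf_peaks: list[float]
    tolerance: float

    def as_dict(self) -> dict:
        return {
            "matched": [
                {"feature": f.as_dict(), "shell_position": p} for f, p in self.matched
            ],
            "unmatched": [f.as_dict() for f in self.unmatched],
            "rdf_peaks": self.rdf_peaks,
            "tolerance": self.tolerance,
        }


def align_shoulders_to_shells(
    profile: PeakProfile,
    rdf: RadialDistribution,
    tolerance: float = 0.05,
    rdf_prominence: float = 0.1,
) -> ShellAlignment:
    """Match SVHF shoulders/secondary peaks to g(r) shell positions.

    Each non-main feature is matched to the nearest g(r) peak within
    ``tolerance`` (nm).  Unmatched features flag displacements beyond the
    liquid's shell structure (protein-driven hopping).
    """
    peaks, _ = find_peaks(rdf.g, prominence=rdf_prominence)
    shell_pos = rdf.bin_centres[peaks]
    matched: list[tuple[Feature, float]] = []
    unmatched: list[Feature] = []
    for f in profile.non_main():
        if shell_pos.size:
            j = int(np.argmin(np.abs(shell_pos - f.position)))
            if abs(shell_pos[j] - f.position) <= tolerance:
                matched.append((f, float(shell_pos[j])))
                continue
        unmatched.append(f)
    return ShellAlignment(matched, unmatched, [float(p) for p in shell_pos], tolerance)


# ---------------------------------------------------------------------------
# plateaus
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PlateauRegion:
    t_start: float  # ps
    t_end: float  # ps
    level: float  # units of the source curve
    max_abs_log_slope: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def overlaps(self, other: "PlateauRegion") -> bool:
        return self.t_start < other.t_end and other.t_start < self.t_end


def detect_plateaus(
    curve: CorrelationFunction,
    log_slope_threshold: float = 0.1,
    min_decades: float = 0.5,
    slope_window: int = 5,
) -> list[PlateauRegion]:
    """Find plateau regions of a positive, log-sampled correlation curve.

    The local slope d(log value)/d(log lag) is estimated by linear regression
    in a sliding window of ``slope_window`` points; maximal runs with
    ``|slope| < log_slope_threshold`` spanning at least ``min_decades`` are
    reported, each with the median curve value as its level.  The default
    threshold of 0.1 separates true plateaus from the sub-diffusive
    (exponent ~0.66) segments between them.
    """
    cf = curve.valid()
    lags, values = cf.lags, cf.values
    if np.any(values <= 0):
        raise FeatureError("plateau detection needs strictly positive values")
    if lags.size < slope_window:
        return []
    x, y = np.log10(lags), np.log10(values)
    half = slope_window // 2
    slopes = np.empty(lags.size)
    for i in range(lags.size):
        lo, hi = max(0, i - half), min(lags.size, i + half + 1)
        A = np.polyfit(x[lo:hi], y[lo:hi], 1)
        slopes[i] = A[0]
    flat = np.abs(slopes) < log_slope_threshold
    regions: list[PlateauRegion] = []
    i = 0
    while i < flat.size:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j + 1 < flat.size and flat[j + 1]:
            j += 1
        if x[j] - x[i] >= min_decades:
            regions.append(
                PlateauRegion(
                    t_start=float(lags[i]),
                    t_end=float(lags[j]),
                    level=float(np.median(values[i : j + 1])),
                    max_abs_log_slope=float(np.max(np.abs(slopes[i : j + 1]))),
                )
            )
        i = j + 1
    return regions


def localization_length_from_msd_plateau(level: float) -> float:
    """Linear trapping distance sqrt(level) from an MSD plateau (nm^2 -> nm)."""
    if level < 0:
        raise FeatureError("MSD plateau level must be non-negative")
    return float(np.sqrt(level))


# ---------------------------------------------------------------------------
# sub-diffusion exponent
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubdiffusionFit:
    delta: float
    prefactor: float
    window: tuple[float, float]  # ps
    stderr: float
    n_points: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_subdiffusion_exponent(
    curve: CorrelationFunction,
    window: tuple[float, float],
) -> SubdiffusionFit:
    """Fit MSD ~ A t^delta by log-log linear regression inside ``window`` (ps)."""
    from scipy import stats

    if curve.observable != "msd":
        raise FeatureError("sub-diffusion fit expects an MSD curve")
    lo, hi = min(window), max(window)
    if np.log10(hi / lo) < 0.5:
        raise FeatureError("fit window must span at least half a decade")
    cf = curve.valid()
    keep = (cf.lags >= lo) & (cf.lags <= hi)
    lags, values = cf.lags[keep], cf.values[keep]
    if lags.size < 3:
        raise FeatureError("fewer than 3 curve points inside the fit window")
    if np.any(values <= 0):
        raise FeatureError("MSD must be positive inside the fit window")
    reg = stats.linregress(np.log(lags), np.log(values))
    return SubdiffusionFit(
        delta=float(reg.slope),
        prefactor=float(np.exp(reg.intercept)),
        window=(float(lo), float(hi)),
        stderr=float(reg.stderr),
        n_points=int(lags.size),
    )
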