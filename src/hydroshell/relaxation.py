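"""Multi-term relaxation model for the SISF and temperature-law analysis.

The SISF of protein hydration water decays through three processes and is
modelled as

    F(Q, t) = (1 - f_a - f_l) exp(-(t/tau_s)^2)
              + f_a exp(-(t/tau_a)^beta_a)
              + f_l exp(-(t/tau_l)^beta_l)

a Gaussian ballistic term plus two stretched exponentials (KWW): the alpha
(structural, bulk-like) relaxation and the slower "long" relaxation coupled
to protein internal motion.  Bulk water needs only the first two terms with
their amplitudes normalized to 1.

Relaxation times as a function of temperature are analysed with the two
canonical laws of glassy dynamics: the mode-coupling power law
``tau ~ (T - TC)^-gamma`` (fragile) and the Arrhenius law
``tau ~ exp(EA / kB T)`` (strong); a breakpoint scan locates
fragile-to-strong and strong-to-strong crossovers in ln(tau).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from lmfit import Parameters, minimize as lm_minimize
from scipy import optimize, stats

from .correlators import CorrelationFunction
from .synthetic import KB_KJ_PER_MOL_K, TemperatureSeries


class RelaxationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RelaxationParams:
    """Parameters of the three-term relaxation model (times in ps)."""

    tau_s: float
    f_alpha: float
    tau_alpha: float
    beta_alpha: float
    f_long: float
    tau_long: float
    beta_long: float

    def validate(self) -> None:
        if min(self.tau_s, self.tau_alpha, self.tau_long) <= 0:
            raise RelaxationError("all relaxation times must be positive")
        for beta in (self.beta_alpha, self.beta_long):
            if not 0 < beta <= 1:
                raise RelaxationError("stretching exponents must lie in (0, 1]")
        if self.f_alpha < 0 or self.f_long < 0:
            raise RelaxationError("amplitudes must be non-negative")
        if self.f_alpha + self.f_long > 1 + 1e-9:
            raise RelaxationError("f_alpha + f_long must not exceed 1")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def model_eval(params: RelaxationParams, t) -> np.ndarray | float:
    """Evaluate the three-term model; returns exactly 1 at t = 0."""
    params.validate()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise RelaxationError("t must be non-negative")
    f_s = 1.0 - params.f_alpha - params.f_long
    with np.errstate(divide="ignore"):
        value = (
            f_s * np.exp(-((t / params.tau_s) ** 2))
            + params.f_alpha * np.exp(-((t / params.tau_alpha) ** params.beta_alpha))
            + params.f_long * np.exp(-((t / params.tau_long) ** params.beta_long))
        )
    value = np.where(t == 0, 1.0, value)
    return float(value) if value.ndim == 0 else value


@dataclasses.dataclass
class RelaxationFitResult:
    params: RelaxationParams | None
    stderr: dict
    residual_norm: float
    variant: str
    converged: bool
    label_swapped: bool = False

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict() if self.params else None,
            "stderr": self.stderr,
            "residual_norm": self.residual_norm,
            "variant": self.variant,
            "converged": self.converged,
            "label_swapped": self.label_swapped,
        }


def _auto_init(lags: np.ndarray, values: np.ndarray, variant: str) -> RelaxationParams:
    """Deterministic initialization from the curve shape.

    tau_s from the ballistic (earliest) end, tau_alpha from the lag where the
    curve crosses midway between its early plateau and its tail, tau_long two
    decades above tau_alpha, stretching exponents at 0.8.
    """
    v0 = float(values[0])
    if 0 < v0 < 1:
        tau_s = lags[0] / np.sqrt(-np.log(v0))
    else:
        tau_s = lags[0]
    early = float(np.max(values[: max(1, values.size // 4)]))
    tail = float(values[-1])
    half = 0.5 * (early + tail)
    below = np.flatnonzero(values <= half)
    tau_a = float(lags[below[0]]) if below.size else float(lags[values.size // 2])
    tau_a = max(tau_a, 3.0 * tau_s)
    if variant == "bulk_two_term":
        return RelaxationParams(tau_s, 0.8, tau_a, 0.8, 0.0, 100.0 * tau_a, 0.8)
    return RelaxationParams(tau_s, 0.5, tau_a, 0.8, 0.25, 100.0 * tau_a, 0.8)


def fit_relaxation(
    corr: CorrelationFunction,
    variant: str = "hydration_three_term",
    init: RelaxationParams | None = None,
    bounds: dict | None = None,
) -> RelaxationFitResult:
    """Constrained least-squares fit of the relaxation model to a SISF curve.

    Uniform weights on the (log-spaced) lag grid.  The ``bulk_two_term``
    variant pins ``f_long = 0`` so the ballistic and alpha amplitudes
    normalize to 1.  The alpha and long labels are swapped at the optimum if
    needed so that ``tau_alpha <= tau_long``.
    """
    if corr.observable != "sisf":
        raise RelaxationError("fit_relaxation expects a SISF curve")
    if variant not in ("bulk_two_term", "hydration_three_term"):
        raise RelaxationError(f"unknown variant {variant!r}")
    cf = corr.valid()
    lags, values = cf.lags, cf.values
    if lags.size < 8:
        raise RelaxationError("need at least 8 valid points to fit")
    if init is None:
        init = _auto_init(lags, values, variant)
    bounds = bounds or {}
    tmin, tmax = float(lags[0]), float(lags[-1])

    p = Parameters()

    def add(name, value, lo, hi, vary=True):
        lo, hi = bounds.get(name, (lo, hi))
        p.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi, vary=vary)

    add("tau_s", init.tau_s, tmin / 100.0, tmax)
    add("f_alpha", init.f_alpha, 0.0, 1.0)
    add("tau_alpha", init.tau_alpha, tmin / 10.0, tmax * 100.0)
    add("beta_alpha", init.beta_alpha, 0.2, 1.0)
    three = variant == "hydration_three_term"
    # f_long = (1 - f_alpha) * g_long keeps the amplitude simplex constraint
    # f_alpha + f_long <= 1 built in and smooth
    g0 = init.f_long / max(1e-12, 1.0 - init.f_alpha) if three else 0.0
    add("g_long", g0, 0.0, 1.0, vary=three)
    p.add("f_long", expr="(1 - f_alpha) * g_long")
    add("tau_long", init.tau_long, tmin / 10.0, tmax * 1000.0, vary=three)
    add("beta_long", init.beta_long, 0.2, 1.0, vary=three)

    def residual(pars):
        f_a, f_l = pars["f_alpha"].value, pars["f_long"].value
        f_s = 1.0 - f_a - f_l
        model = (
            f_s * np.exp(-((lags / pars["tau_s"].value) ** 2))
            + f_a * np.exp(-((lags / pars["tau_alpha"].value) ** pars["beta_alpha"].value))
            + f_l * np.exp(-((lags / pars["tau_long"].value) ** pars["beta_long"].value))
        )
        return model - values

    try:
        out = lm_minimize(residual, p, method="leastsq")
    except Exception:
        return RelaxationFitResult(None, {}, np.inf, variant, converged=False)

    if not out.success or not np.isfinite(out.chisqr):
        return RelaxationFitResult(None, {}, np.inf, variant, converged=False)

    report = ("tau_s", "f_alpha", "tau_alpha", "beta_alpha",
              "f_long", "tau_long", "beta_long")
    v = {name: out.params[name].value for name in report}
    # degenerate data (e.g. a constant curve) pushes a *material* relaxation
    # time to its upper bound: flag, do not report parameters
    at_bound = (
        v["f_alpha"] > 0.02
        and v["tau_alpha"] >= 0.99 * out.params["tau_alpha"].max
    )
    if three:
        at_bound = at_bound or (
            v["f_long"] > 0.02
            and v["tau_long"] >= 0.99 * out.params["tau_long"].max
        )
    err = {
        name: (out.params[name].stderr if out.params[name].stderr is not None else np.nan)
        for name in report
    }
    # canonical labels: the model is symmetric under term exchange, so put
    # the dominant term in alpha when the other amplitude vanishes, and
    # enforce tau_alpha <= tau_long otherwise
    swapped = False
    need_swap = False
    total_amp = v["f_alpha"] + v["f_long"]
    if three and total_amp > 0:
        if v["f_alpha"] < 0.05 * total_amp:
            # alpha term collapsed; the dominant stretched term belongs in alpha
            need_swap = True
        elif v["f_long"] >= 0.05 * total_amp and v["tau_alpha"] > v["tau_long"]:
            warnings.warn("tau_alpha > tau_long at optimum; swapping term labels")
            need_swap = True
    if need_swap:
        for a, b in (("tau_alpha", "tau_long"), ("beta_alpha", "beta_long"),
                     ("f_alpha", "f_long")):
            v[a], v[b] = v[b], v[a]
            err[a], err[b] = err[b], err[a]
        swapped = True
    params = RelaxationParams(
        v["tau_s"], v["f_alpha"], v["tau_alpha"], v["beta_alpha"],
        v["f_long"], v["tau_long"], v["beta_long"],
    )
    return RelaxationFitResult(
        params=None if at_bound else params,
        stderr=err,
        residual_norm=float(np.sqrt(out.chisqr)),
        variant=variant,
        converged=not at_bound,
        label_swapped=swapped,
    )


# ---------------------------------------------------------------------------
# temperature laws
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TemperatureLawFit:
    law: str  # arrhenius | power_law
    prefactor: float
    EA: float | None = None  # kJ/mol (arrhenius)
    TC: float | None = None  # K (power_law)
    gamma: float | None = None
    fit_range: tuple[float, float] = (0.0, 0.0)
    stderr: dict = dataclasses.field(default_factory=dict)
    ssr: float = 0.0  # sum of squared residuals in ln(tau)
    n_points: int = 0

    def predict_log(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        if self.law == "arrhenius":
            return np.log(self.prefactor) + self.EA / (KB_KJ_PER_MOL_K * T)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log(self.prefactor) - self.gamma * np.log(T - self.TC)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _in_range(series: TemperatureSeries, fit_range) -> TemperatureSeries:
    if fit_range is None:
        return series.sorted_descending()
    lo, hi = min(fit_range), max(fit_range)
    keep = (series.temperatures >= lo) & (series.temperatures <= hi)
    return TemperatureSeries(
        series.temperatures[keep], series.tau_values[keep], series.label
    ).sorted_descending()


def fit_temperature_law(
    series: TemperatureSeries,
    law: str,
    fit_range: tuple[float, float] | None = None,
) -> TemperatureLawFit:
    """Fit tau(T) with an Arrhenius or mode-coupling power law.

    Arrhenius: linear regression of ln(tau) on 1/T, EA = slope * kB.
    Power law: nonlinear fit of ln(tau) on ln(T - TC) with TC profiled out
    (inner linear regression, outer bounded scalar minimization of the SSR).
    """
    s = _in_range(series, fit_range)
    T, tau = s.temperatures, s.tau_values
    if T.size < 3:
        raise RelaxationError("need at least 3 points in the fit range")
    ln_tau = np.log(tau)
    rng_ = (float(T.min()), float(T.max()))
    if law == "arrhenius":
        reg = stats.linregress(1.0 / T, ln_tau)
        EA = reg.slope * KB_KJ_PER_MOL_K
        resid = ln_tau - (reg.intercept + reg.slope / T)
        return TemperatureLawFit(
            law="arrhenius",
            prefactor=float(np.exp(reg.intercept)),
            EA=float(EA),
            fit_range=rng_,
            stderr={"EA": float(reg.stderr * KB_KJ_PER_MOL_K)},
            ssr=float(np.sum(resid**2)),
            n_points=int(T.size),
        )
    if law != "power_law":
        raise RelaxationError(f"unknown law {law!r}")

    T_min = float(T.min())

    def profile_ssr(TC: float) -> float:
        x = np.log(T - TC)
        reg = stats.linregress(x, ln_tau)
        resid = ln_tau - (reg.intercept + reg.slope * x)
        return float(np.sum(resid**2))

    hi = T_min - 1e-3 * max(1.0, T_min)
    res = optimize.minimize_scalar(
        profile_ssr, bounds=(1e-3, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    TC = float(res.x)
    x = np.log(T - TC)
    reg = stats.linregress(x, ln_tau)
    gamma = -reg.slope
    resid = ln_tau - (reg.intercept + reg.slope * x)
    ssr = float(np.sum(resid**2))
    # TC uncertainty from the curvature of the profiled SSR
    h = max(1e-4, 1e-4 * TC)
    if TC + h < hi and TC - h > 0:
        d2 = (profile_ssr(TC + h) - 2 * ssr + profile_ssr(TC - h)) / h**2
        dof = max(1, T.size - 3)
        tc_err = float(np.sqrt(max(0.0, 2.0 * (ssr / dof) / d2))) if d2 > 0 else np.nan
    else:
        tc_err = np.nan
    return TemperatureLawFit(
        law="power_law",
        prefactor=float(np.exp(reg.intercept)),
        TC=TC,
        gamma=float(gamma),
        fit_range=rng_,
        stderr={"gamma": float(reg.stderr), "TC": tc_err},
        ssr=ssr,
        n_points=int(T.size),
    )


@dataclasses.dataclass
class CrossoverResult:
    kind: str  # fragile_to_strong | strong_to_strong | no_crossover
    T_cross: float | None
    T_cross_err: float | None
    law_high: TemperatureLawFit | None
    law_low: TemperatureLawFit | None
    breakpoint_T: float | None = None
    total_ssr: float = np.inf
    single_law_ssr: float = np.inf

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "T_cross": self.T_cross,
            "T_cross_err": self.T_cross_err,
            "breakpoint_T": self.breakpoint_T,
            "total_ssr": self.total_ssr,
            "single_law_ssr": self.single_law_ssr,
            "law_high": self.law_high.as_dict() if self.law_high else None,
            "law_low": self.law_low.as_dict() if self.law_low else None,
        }


def _intersection(high: TemperatureLawFit, low: TemperatureLawFit,
                  T_lo: float, T_hi: float) -> float | None:
    """Temperature where the two fitted laws intersect in ln(tau)."""

    def diff(T):
        return high.predict_log(np.array([T]))[0] - low.predict_log(np.array([T]))[0]

    lo = T_lo
    if high.law == "power_law" and high.TC is not None:
        lo = max(lo, high.TC + 1e-6)
    grid = np.linspace(lo, T_hi, 512)
    vals = np.array([diff(T) for T in grid])
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]
    sign = np.sign(vals)
    flips = np.flatnonzero(np.diff(sign) != 0)
    if flips.size == 0:
        return None
    i = flips[0]
    try:
        return float(optimize.brentq(diff, grid[i], grid[i + 1]))
    except ValueError:
        return float(0.5 * (grid[i] + grid[i + 1]))


def detect_crossover(
    series: TemperatureSeries,
    candidate_laws: tuple[str, str] = ("power_law", "arrhenius"),
    margin: float = 0.05,
    min_branch_points: int = 3,
) -> CrossoverResult:
    """Locate a dynamic crossover between two temperature laws.

    ``candidate_laws`` = (law of the high-T branch, law of the low-T branch);
    (power_law, arrhenius) detects a fragile-to-strong crossover,
    (arrhenius, arrhenius) a strong-to-strong one.  Every interior breakpoint
    with at least ``min_branch_points`` on each side is scanned; the pair of
    branch fits minimizing the total SSR in ln(tau) wins, provided it
    improves on the best single-law fit by at least ``margin`` (relative).
    The crossover temperature is the intersection of the two fitted laws in
    ln(tau); its spread over adjacent breakpoints is the quoted uncertainty.
    """
    law_high, law_low = candidate_laws
    s = series.sorted_descending()
    T = s.temperatures
    if T.size < 2 * min_branch_points:
        raise RelaxationError(
            f"need at least {2 * min_branch_points} points to scan for a crossover"
        )

    single_ssr = np.inf
    for law in set(candidate_laws):
        try:
            single_ssr = min(single_ssr, fit_temperature_law(s, law).ssr)
        except Exception:
            continue

    best = None  # (total_ssr, k, fit_high, fit_low)
    candidates = []
    for k in range(min_branch_points, T.size - min_branch_points + 1):
        high = TemperatureSeries(T[:k], s.tau_values[:k], s.label)
        low = TemperatureSeries(T[k:], s.tau_values[k:], s.label)
        try:
            fh = fit_temperature_law(high, law_high)
            fl = fit_temperature_law(low, law_low)
        except (RelaxationError, ValueError):
            continue
        total = fh.ssr + fl.ssr
        candidates.append((k, total, fh, fl))
        if best is None or total < best[1]:
            best = (k, total, fh, fl)

    kind = "fragile_to_strong" if candidate_laws == ("power_law", "arrhenius") else (
        "strong_to_strong" if candidate_laws == ("arrhenius", "arrhenius") else "custom"
    )
    # a single law already at numerical perfection cannot be improved upon
    if best is None or single_ssr < 1e-12 or not (best[1] < (1.0 - margin) * single_ssr):
        return CrossoverResult(
            "no_crossover", None, None, None, None,
            total_ssr=best[1] if best else np.inf, single_law_ssr=float(single_ssr),
        )
    k, total, fh, fl = best
    bp_T = float(0.5 * (T[k - 1] + T[k]))
    T_cross = _intersection(fh, fl, float(T.min()), float(T.max()))
    if T_cross is None:
        T_cross = bp_T
    # uncertainty: spread of the intersection over adjacent breakpoints
    neighbours = [c for c in candidates if abs(c[0] - k) == 1]
    spread = []
    for kk, _tot, fhh, fll in neighbours:
        tc = _intersection(fhh, fll, float(T.min()), float(T.max()))
        if tc is not None:
            spread.append(tc)
    err = float(np.max(np.abs(np.asarray(spread) - T_cross))) if spread else None
    return CrossoverResult(
        kind=kind, T_cross=float(T_cross), T_cross_err=err,
        law_high=fh, law_low=fl, breakpoint_T=bp_T,
        total_ssr=float(total), single_law_ssr=float(single_ssr),
    )


# ---------------------------------------------------------------------------
# cage radius
# ---------------------------------------------------------------------------


def cage_radius_from_sisf_plateau(phi: float, Q: float) -> float:
    """Localization (cage) radius from the SISF plateau height.

    Under Gaussian confinement the plateau is the Debye-Waller factor
    ``phi = exp(-Q^2 a^2 / 3)`` with ``a^2`` the mean-square vibrational
    amplitude about the cage centre, hence ``a = sqrt(-3 ln phi) / Q`` (nm
    for Q in nm^-1).
    """
    if not 0 < phi < 1:
        raise RelaxationError("plateau height phi must lie strictly in (0, 1)")
    if Q <= 0:
        raise RelaxationError("Q must be positive")
    return float(np.sqrt(-3.0 * np.log(phi)) / Q)
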