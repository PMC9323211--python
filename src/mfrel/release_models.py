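"""Cumulative drug-release models, nonlinear fitting and preprocessing.

The central release law is the bounded "Kink" solution of a Riccati-type
rate equation: a tanh sigmoid

    M(t) = B + a * tanh(a * (t - t0) / A)

with offset ``B`` (the release level at the lag time t0), amplitude
``a > 0`` (plateau = B + a), time-scaling constant ``A > 0`` (units of
release x min; a/A is the rate at the inflection) and lag ``t0`` (min).
Four classical dissolution baselines accompany it:

    korsmeyer-peppas  M = k * t^n
    higuchi           M = kH * sqrt(t)
    hixson-crowell    M = M0 * (1 - (1 - kHC*t)^3), clipped at M0
    weibull           M = Minf * (1 - exp(-(t/lam)^b))

Fits are weighted least squares (1/sd^2 when replicate SDs are present)
via scipy, compared by small-sample-corrected AICc.  Absorbance series
from a dialysis-bag release assay are converted to cumulative release
through a calibration line with the usual withdrawn-and-replaced sample
volume correction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

MODEL_NAMES = ("kink", "korsmeyer-peppas", "higuchi", "hixson-crowell", "weibull")


@dataclass
class ReleaseCurve:
    """Replicate-averaged cumulative release of one drug/formulation."""

    drug: str
    times_min: np.ndarray
    mean_release: np.ndarray
    sd_release: np.ndarray | None = None
    n_replicates: int = 3
    units: str = "fraction"  # "fraction" or a concentration/mass unit tag

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.mean_release = np.asarray(self.mean_release, dtype=float)
        if self.sd_release is not None:
            self.sd_release = np.asarray(self.sd_release, dtype=float)
            if len(self.sd_release) != len(self.times_min):
                raise ValueError("sd series length must match times")
            if np.any(self.sd_release < 0):
                raise ValueError("sd values must be nonnegative")
        if len(self.mean_release) != len(self.times_min):
            raise ValueError("mean series length must match times")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_min < 0):
            raise ValueError("times must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.units == "fraction" and (
            np.any(self.mean_release < -0.05) or np.any(self.mean_release > 1.05)
        ):
            raise ValueError("fractional release must lie in [0, 1.05] up to noise")


@dataclass(frozen=True)
class KinkParams:
    """Parameters of the tanh release law."""

    B: float
    a: float
    A_scale: float
    t0: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("amplitude a must be positive")
        if not self.A_scale > 0:
            raise ValueError("A_scale must be positive")

    @property
    def plateau(self) -> float:
        return self.B + self.a

    @property
    def rate(self) -> float:
        """tanh argument rate a/A (1/min)."""
        return self.a / self.A_scale


@dataclass(frozen=True)
class ModelFit:
    model_name: str
    params: dict[str, float]
    rss: float
    r_squared: float
    aicc: float
    converged: bool
    n_points: int = 0
    message: str = ""


@dataclass(frozen=True)
class CalibrationLine:
    """UV-Vis calibration: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float = 0.0
    wavelength_nm: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


def kink_mass(t: float | np.ndarray, p: KinkParams) -> float | np.ndarray:
    """Evaluate the Kink release law M(t) = B + a*tanh(a*(t-t0)/A)."""
    return p.B + p.a * np.tanh(p.a * (np.asarray(t, dtype=float) - p.t0) / p.A_scale)


def classical_model(
    name: str, t: float | np.ndarray, params: Mapping[str, float]
) -> float | np.ndarray:
    """Evaluate one of the classical dissolution models at time(s) t."""
    t = np.asarray(t, dtype=float)
    if name == "korsmeyer-peppas":
        return params["k"] * np.power(t, params["n"])
    if name == "higuchi":
        return params["k"] * np.sqrt(t)
    if name == "hixson-crowell":
        core = np.clip(1.0 - params["k"] * t, 0.0, None)
        return params["M0"] * (1.0 - core**3)
    if name == "weibull":
        return params["Minf"] * (1.0 - np.exp(-np.power(t / params["lam"], params["b"])))
    if name == "kink":
        return kink_mass(t, KinkParams(params["B"], params["a"], params["A_scale"], params["t0"]))
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def _aicc(n: int, k: int, rss: float) -> float:
    """Small-sample corrected Akaike criterion from a Gaussian RSS."""
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


#: shrinkage of per-point variances toward the pooled variance; SD
#: estimates from n=3 replicates are noisy enough that raw 1/sd^2
#: weights degrade the fit, so half the weight information comes from
#: the pooled level (empirical-Bayes style moderation)
SD_SHRINKAGE = 0.5


def _weights(curve: ReleaseCurve) -> np.ndarray | None:
    """Per-point sigma for curve_fit (None -> uniform weights).

    Per-point variances are shrunk toward the pooled variance with
    weight :data:`SD_SHRINKAGE` to moderate the sampling noise of
    replicate SD estimates from small n.
    """
    if curve.sd_release is None or np.all(curve.sd_release == 0):
        logger.info("no replicate SDs on %s: uniform weighting", curve.drug)
        return None
    var = curve.sd_release**2
    pooled = float(np.mean(var))
    sd = np.sqrt((1.0 - SD_SHRINKAGE) * var + SD_SHRINKAGE * pooled)
    return np.maximum(sd, 1e-12)


def _fit_stats(curve: ReleaseCurve, pred: np.ndarray, k: int) -> tuple[float, float, float]:
    y = curve.mean_release
    sigma = _weights(curve)
    w = 1.0 / sigma**2 if sigma is not None else np.ones_like(y)
    rss = float(np.sum(w * (y - pred) ** 2))
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else -math.inf
    return rss, r2, _aicc(len(y), k, rss)


def _kink_initial_guess(curve: ReleaseCurve) -> tuple[float, float, float, float]:
    t, y = curve.times_min, curve.mean_release
    B0 = float(y[0])
    a0 = max(float(y[-1] - y[0]), 1e-6)
    half = B0 + 0.5 * a0
    t0 = float(np.interp(half, y, t)) if y[-1] > y[0] else float(np.median(t))
    dy = np.gradient(y, t)
    slope = max(float(dy.max()), 1e-9)
    # at the inflection dM/dt = a^2/A  =>  A ~ a^2/slope
    A0 = max(a0**2 / slope, 1e-6)
    return B0, a0, A0, t0


def fit_kink(curve: ReleaseCurve) -> ModelFit:
    """Weighted least-squares fit of the Kink law to a release curve.

    Initialisation: B = first observation, a = total rise, t0 = time of
    half-rise, A from the maximal slope.  Bounds keep a, A positive and
    B nonnegative.  Non-convergence is reported in the flag, never
    raised.
    """
    if len(curve.times_min) < 5:
        raise ValueError("need at least 5 time points to fit the Kink law")
    if np.ptp(curve.mean_release) == 0:
        raise ValueError("cannot fit a constant release curve")
    p0 = _kink_initial_guess(curve)
    bounds = ([0.0, 1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf])

    def f(t, B, a, A, t0):
        return B + a * np.tanh(a * (t - t0) / A)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                f,
                curve.times_min,
                curve.mean_release,
                p0=p0,
                sigma=_weights(curve),
                bounds=bounds,
                maxfev=20000,
            )
        converged, msg = True, ""
    except RuntimeError as exc:
        popt, converged, msg = np.array(p0), False, str(exc)
    pred = f(curve.times_min, *popt)
    rss, r2, aicc = _fit_stats(curve, pred, k=4)
    return ModelFit(
        model_name="kink",
        params={"B": popt[0], "a": popt[1], "A_scale": popt[2], "t0": popt[3]},
        rss=rss,
        r_squared=r2,
        aicc=aicc,
        converged=converged,
        n_points=len(curve.times_min),
        message=msg,
    )


def _fit_classical(curve: ReleaseCurve, name: str) -> ModelFit:
    t, y = curve.times_min, curve.mean_release
    ymax = float(y.max())
    tmax = float(t.max())
    if name == "higuchi":
        # weighted closed form: k = sum(w y sqrt(t)) / sum(w t)
        sigma = _weights(curve)
        w = 1.0 / sigma**2 if sigma is not None else np.ones_like(y)
        k = float(np.sum(w * y * np.sqrt(t)) / np.sum(w * t))
        pred = k * np.sqrt(t)
        rss, r2, aicc = _fit_stats(curve, pred, k=1)
        return ModelFit("higuchi", {"k": k}, rss, r2, aicc, True, len(t))
    if name == "korsmeyer-peppas":
        f: Callable = lambda t, k, n: k * np.power(t, n)
        p0 = (max(ymax / math.sqrt(max(tmax, 1.0)), 1e-6), 0.5)
        bounds = ([1e-12, 0.01], [np.inf, 3.0])
        names = ("k", "n")
    elif name == "hixson-crowell":
        f = lambda t, M0, k: M0 * (1.0 - np.clip(1.0 - k * t, 0.0, None) ** 3)
        p0 = (max(ymax, 1e-6), 0.3 / max(tmax, 1.0))
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
        names = ("M0", "k")
    elif name == "weibull":
        f = lambda t, Minf, lam, b: Minf * (1.0 - np.exp(-np.power(t / lam, b)))
        t_half = float(np.interp(0.5 * ymax, y, t)) if ymax > 0 else max(tmax / 2, 1.0)
        p0 = (max(ymax, 1e-6), max(t_half, 1e-3), 1.0)
        bounds = ([1e-12, 1e-9, 0.05], [np.inf, np.inf, 20.0])
        names = ("Minf", "lam", "b")
    else:
        raise ValueError(f"unknown model {name!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with np.errstate(all="ignore"):
                popt, _ = curve_fit(
                    f, t, y, p0=p0, sigma=_weights(curve), bounds=bounds, maxfev=20000
                )
        converged, msg = True, ""
    except RuntimeError as exc:
        popt, converged, msg = np.array(p0), False, str(exc)
    with np.errstate(all="ignore"):
        pred = f(t, *popt)
    rss, r2, aicc = _fit_stats(curve, pred, k=len(popt))
    return ModelFit(name, dict(zip(names, popt)), rss, r2, aicc, converged, len(t), msg)


def fit_model(curve: ReleaseCurve, name: str) -> ModelFit:
    """Fit one named model to a release curve."""
    if name == "kink":
        return fit_kink(curve)
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return _fit_classical(curve, name)


def fit_all_models(
    curve: ReleaseCurve, models: Sequence[str] = MODEL_NAMES
) -> list[ModelFit]:
    """Fit the requested models and rank them by AICc (best first).

    A model that fails to converge keeps its flagged result and competes
    with its achieved AICc; the harness never aborts on a single model.
    """
    fits = []
    for name in models:
        try:
            fits.append(fit_model(curve, name))
        except ValueError:
            raise
    return sorted(fits, key=lambda m: (not m.converged, m.aicc))


def release_from_absorbance(
    absorbances: Sequence[float],
    cal: CalibrationLine,
    bath_volume_mL: float,
    sample_volume_mL: float = 0.0,
    drug: str = "drug",
) -> ReleaseCurve:
    """Convert a UV-Vis absorbance series to cumulative released mass.

    Concentration at draw i is (A_i - intercept)/slope (clipped at 0;
    clip events are counted in a warning log).  Because each draw
    removes ``sample_volume_mL`` of bath and replaces it with fresh
    medium, the cumulative mass adds back the withdrawn amounts:

        m_i = V_bath * C_i + V_sample * sum_{j<i} C_j     (micrograms)

    Times are draw indices (caller attaches real times by rebuilding the
    curve); with zero sample volume the correction vanishes.
    """
    if not bath_volume_mL > 0:
        raise ValueError("bath volume must be positive")
    if not 0 <= sample_volume_mL < bath_volume_mL:
        raise ValueError("sample volume must be in [0, bath volume)")
    A = np.asarray(absorbances, dtype=float)
    conc = (A - cal.intercept) / cal.slope
    n_clipped = int(np.sum(conc < 0))
    if n_clipped:
        logger.warning("%d absorbance(s) below intercept clipped to zero", n_clipped)
    conc = np.clip(conc, 0.0, None)
    csum_prev = np.concatenate([[0.0], np.cumsum(conc)[:-1]])
    mass = bath_volume_mL * conc + sample_volume_mL * csum_prev
    return ReleaseCurve(
        drug=drug,
        times_min=np.arange(1, len(A) + 1, dtype=float),
        mean_release=mass,
        sd_release=None,
        n_replicates=1,
        units="ug",
    )


def plateau_time(curve: ReleaseCurve, frac: float = 0.95) -> float:
    """First time the curve reaches ``frac`` of its plateau (min).

    The plateau is the mean of the last three observations, which must
    agree with the curve maximum to within 2% (of the maximum) for a
    plateau to be declared; when replicate SDs are present the
    tolerance is widened by three pooled standard errors of the mean so
    that the detection rule is robust to the replicate noise the curve
    itself reports.  The crossing time is linearly interpolated.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    y = curve.mean_release
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    tail = y[-3:]
    peak = float(y.max())
    tol = 0.02 * peak
    if curve.sd_release is not None:
        pooled_sem = math.sqrt(float(np.mean(curve.sd_release**2)) / curve.n_replicates)
        tol += 3.0 * pooled_sem
    if peak <= 0 or np.any(np.abs(tail - peak) > tol):
        raise ValueError("no plateau detected (last three points not within 2% of max)")
    plateau = float(tail.mean())
    target = frac * plateau
    above = np.nonzero(y >= target)[0]
    if len(above) == 0:
        raise ValueError("curve never reaches the plateau fraction")
    i = int(above[0])
    if i == 0:
        return float(curve.times_min[0])
    t0, t1 = curve.times_min[i - 1], curve.times_min[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))
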