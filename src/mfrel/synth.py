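"""Seeded synthetic-data generators.

Every generator is a pure function of its spec (seed included) and
emulates the statistical structure of the wet-lab measurements the
analysis consumes: replicated sigmoidal release curves plateauing
within 200-360 min, a three-drug panel with graded curve roughness,
log-normal DLS size distributions with prescribed mean and PDI,
layer-by-layer zeta-sign alternation, and HET-CAM onset times that land
in a requested irritation category.

PDI follows the DLS cumulant convention variance/mean^2 of the size
distribution.  Replicate noise is i.i.d. Gaussian per time point per
replicate; the default magnitude is 2% of the plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import hetcam
from .release_models import KinkParams, ReleaseCurve, classical_model, kink_mass

#: dissolution-style sampling grid (min): dense through the release
#: phase, sparse over the 72 h tail
DEFAULT_TIMES_MIN = (
    0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0,
    300.0, 360.0, 420.0, 480.0, 540.0, 600.0, 720.0, 1440.0, 2880.0, 4320.0,
)


def default_kink_params(
    plateau: float = 0.9, t0_min: float = 30.0, t95_min: float = 280.0, B: float = 0.2
) -> KinkParams:
    """Kink parameters for the default demo curve.

    Plateau fraction 0.9 with lag t0 = 30 min and the rise scaled so
    95% of the plateau is reached at 280 min (inside the observed
    200-360 min window); the offset B = 0.2 keeps the extrapolated
    t = 0 release to a small burst (~6%).
    """
    a = plateau - B
    if not 0 < B < plateau:
        raise ValueError("need 0 < B < plateau")
    target = (0.95 * plateau - B) / a
    rate = math.atanh(target) / (t95_min - t0_min)
    return KinkParams(B=B, a=a, A_scale=a / rate, t0=t0_min)


def recovery_kink_params(
    plateau: float = 0.9, t0_min: float = 150.0, t95_min: float = 280.0
) -> KinkParams:
    """Well-identified Kink truth for parameter-recovery trials.

    A symmetric S-curve (B = a = plateau/2) whose lag phase, rise and
    plateau all fall inside the sampling window, so all four parameters
    are identifiable at 2%-of-plateau noise: the Cramer-Rao bound on
    the relative error is ~1% for B, a, t0 and ~5% for A.  The demo
    default (:func:`default_kink_params`, lag 30 min) observes only the
    upper branch of the tanh and leaves B and t0 poorly determined —
    use this truth when the question is estimator quality.
    """
    B = plateau / 2.0
    a = plateau - B
    rate = math.atanh((0.95 * plateau - B) / a) / (t95_min - t0_min)
    return KinkParams(B=B, a=a, A_scale=a / rate, t0=t0_min)


#: per-model truth parameters for self-consistency trials (fraction
#: units, plateau-scale 0.9, over the default 72 h sampling grid)
SELF_CONSISTENCY_TRUTH: dict[str, dict[str, float]] = {
    "kink": {
        "B": recovery_kink_params().B,
        "a": recovery_kink_params().a,
        "A_scale": recovery_kink_params().A_scale,
        "t0": recovery_kink_params().t0,
    },
    "korsmeyer-peppas": {"k": 0.9 / 4320.0**0.6, "n": 0.6},
    "higuchi": {"k": 0.9 / math.sqrt(4320.0)},
    "hixson-crowell": {"M0": 0.9, "k": 1.0 / 400.0},
    "weibull": {"Minf": 0.9, "lam": 150.0, "b": 1.5},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification for one synthetic release curve."""

    seed: int
    model_name: str = "kink"
    params: Mapping[str, float] = field(
        default_factory=lambda: {
            "B": default_kink_params().B,
            "a": default_kink_params().a,
            "A_scale": default_kink_params().A_scale,
            "t0": default_kink_params().t0,
        }
    )
    times_min: Sequence[float] = DEFAULT_TIMES_MIN
    noise_sd: float = 0.018  # 2% of the 0.9 plateau
    n_replicates: int = 3
    drug: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


def gen_release_curve(spec: SyntheticSpec) -> ReleaseCurve:
    """Replicate-averaged noisy release curve from a named model.

    With noise_sd = 0 the mean equals the model exactly and the SD is
    identically zero.  Same spec (incl. seed) -> identical curve.
    """
    t = np.asarray(spec.times_min, dtype=float)
    model = classical_model(spec.model_name, t, dict(spec.params))
    rng = np.random.default_rng(spec.seed)
    reps = model[None, :] + rng.normal(0.0, spec.noise_sd, size=(spec.n_replicates, len(t)))
    if spec.noise_sd == 0.0:  # exact contract: mean = model, SD identically 0
        mean = model.copy()
        sd = np.zeros_like(mean)
    else:
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else np.zeros_like(mean)
    units = "fraction" if float(np.max(model)) <= 1.0 else "ug_per_ml"
    if units == "fraction":
        mean = np.clip(mean, 0.0, 1.05)
    return ReleaseCurve(
        drug=spec.drug,
        times_min=t,
        mean_release=mean,
        sd_release=sd,
        n_replicates=spec.n_replicates,
        units=units,
    )


#: roughness amplitudes (fraction units) for the three-drug panel, ratio 1:2:4
PANEL_ROUGHNESS = {
    "pilocarpine-like": 0.009,
    "dexamethasone-like": 0.018,
    "bevacizumab-like": 0.036,
}

#: uniform grid for the panel (fractality estimators need uniform sampling)
PANEL_TIMES_MIN = tuple(np.arange(0.0, 722.0, 2.0))


def gen_drug_panel(seed: int) -> list[ReleaseCurve]:
    """Three-drug panel sharing a Kink backbone with graded roughness.

    The drugs differ only in the amplitude of i.i.d. high-frequency
    roughness added to the mean curve (ratio 1:2:4, base 1% of the
    plateau), so the fractality ordering of the panel is decidable:
    bevacizumab-like > dexamethasone-like > pilocarpine-like.
    """
    base = default_kink_params()
    t = np.asarray(PANEL_TIMES_MIN)
    backbone = kink_mass(t, base)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(101,))
    child_seeds = ss.generate_state(len(PANEL_ROUGHNESS))
    curves = []
    for (name, amp), s in zip(PANEL_ROUGHNESS.items(), child_seeds):
        rng = np.random.default_rng(int(s))
        mean = np.clip(backbone + rng.normal(0.0, amp, size=len(t)), 0.0, 1.05)
        curves.append(
            ReleaseCurve(
                drug=name,
                times_min=t,
                mean_release=mean,
                sd_release=np.full(len(t), amp),
                n_replicates=3,
                units="fraction",
            )
        )
    return curves


def gen_dls_sizes(
    mean_nm: float, pdi: float, n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, dict[str, float]]:
    """Log-normal DLS size sample with prescribed mean and PDI.

    The log-normal parameters are chosen so the theoretical mean equals
    ``mean_nm`` and the theoretical PDI (= variance/mean^2) equals
    ``pdi``; the returned summary is recomputed from the sample.
    """
    if not mean_nm > 0:
        raise ValueError("mean size must be positive")
    if not 0 <= pdi < 0.5:
        raise ValueError("pdi must lie in [0, 0.5)")
    if n < 100:
        raise ValueError("need at least 100 samples")
    sigma2 = math.log1p(pdi)
    mu = math.log(mean_nm) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    m = float(sizes.mean())
    v = float(sizes.var())
    return sizes, {"mean_nm": m, "pdi": v / m**2}


def gen_lbl_series(
    core_zeta_mV: float, n_layers: int, seed: int = 0, core_size_nm: float = 200.0
) -> list[tuple[float, float]]:
    """Layer-by-layer (size, zeta) sequence: core then alternating layers.

    Sizes never decrease step to step; zeta alternates sign with each
    polyelectrolyte layer (polyanion negative, chitosan positive),
    starting opposite to the core charge, with magnitudes in [5, 50] mV.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    out = [(core_size_nm, core_zeta_mV)]
    size = core_size_nm
    sign = -math.copysign(1.0, core_zeta_mV) if core_zeta_mV != 0 else -1.0
    for _ in range(n_layers):
        size += rng.uniform(5.0, 30.0)
        zeta = sign * rng.uniform(5.0, 50.0)
        out.append((size, zeta))
        sign = -sign
    return out


#: per-category onset-time windows (s); with all three onsets anywhere in
#: the window, the continuous score stays inside the category's range
_CATEGORY_WINDOWS = {
    "non-irritant": (290.0, 301.0),
    "less irritant": (235.0, 280.0),
    "moderate irritant": (180.0, 225.0),
    "severe irritant": (1.0, 170.0),
}


def gen_hetcam_observation(irritant_level: str, seed: int = 0) -> hetcam.HetcamObservation:
    """Draw onset times that score inside the requested category.

    Onsets are drawn independently and uniformly from a per-category
    window constructed so that any combination lands in the category;
    the resulting score/category pair is re-checked at generation time.
    """
    if irritant_level not in _CATEGORY_WINDOWS:
        raise ValueError(
            f"unknown category {irritant_level!r}; expected one of {sorted(_CATEGORY_WINDOWS)}"
        )
    lo, hi = _CATEGORY_WINDOWS[irritant_level]
    rng = np.random.default_rng(seed)
    obs = hetcam.HetcamObservation(*rng.uniform(lo, hi, size=3))
    got = hetcam.classify_irritation(hetcam.irritation_score(obs))
    if got != irritant_level:  # closed-loop contract; windows guarantee this
        raise AssertionError(f"generated observation classified as {got}")
    return obs
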