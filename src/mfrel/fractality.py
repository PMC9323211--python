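"""Fractal-dimension ("fractality degree") estimation of release curves.

The roughness of a cumulative-release curve carries information about
the complexity of the drug-polymer interaction; a fractal dimension of
the planar curve quantifies it.  Two standard estimators are provided
and deliberately kept independent:

* box counting on the min-max-normalised curve (primary): slope of
  log N(eps) vs log(1/eps) over a geometric ladder of box sizes;
* a Higuchi-type curve-length estimator (cross-check): slope of
  log L(k) vs log(1/k) for subsampled curve lengths.

Both return values in [1, 2] (a smooth curve -> 1, space-filling noise
-> 2), are deterministic, and invariant to affine rescaling of either
axis (normalisation precedes counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .release_models import ReleaseCurve

#: default geometric ladder of box sizes (fractions of the unit square)
DEFAULT_BOX_SIZES = (1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64)


@dataclass(frozen=True)
class FractalityResult:
    drug: str
    dimension_boxcount: float | None = None
    dimension_higuchi: float | None = None
    scale_range: tuple[float, float] = (min(DEFAULT_BOX_SIZES), max(DEFAULT_BOX_SIZES))
    r_squared_loglog: float = float("nan")

    def dimension(self, estimator: str = "boxcount") -> float:
        v = getattr(self, f"dimension_{estimator}", None)
        if v is None:
            raise ValueError(f"no {estimator} dimension on result for {self.drug}")
        return v


def _normalize_to_unit_square(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if np.ptp(t) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate curve: zero extent on an axis")
    return (t - t.min()) / np.ptp(t), (y - y.min()) / np.ptp(y)


def _count_boxes(x: np.ndarray, y: np.ndarray, eps: float) -> int:
    n = int(round(1.0 / eps))
    ix = np.minimum((x / eps).astype(np.int64), n - 1)
    iy = np.minimum((y / eps).astype(np.int64), n - 1)
    return len(set(zip(ix.tolist(), iy.tolist())))


def box_counting_dimension(
    curve: ReleaseCurve,
    box_sizes: Sequence[float] = DEFAULT_BOX_SIZES,
    oversample: int = 4096,
) -> FractalityResult:
    """Box-counting dimension of the normalised release polyline.

    The curve is min-max scaled to the unit square, the polyline densely
    resampled (so segments, not just vertices, populate boxes), and the
    box count fitted log-log against the ladder of box sizes.
    """
    if len(curve.times_min) < 16:
        raise ValueError("need at least 16 points for box counting")
    if len(box_sizes) < 5:
        raise ValueError("need at least 5 box sizes for the log-log fit")
    x, y = _normalize_to_unit_square(curve.times_min, curve.mean_release)
    # dense resampling along the polyline keeps segment interiors counted
    s = np.linspace(0.0, 1.0, oversample)
    xd = np.interp(s, x, x)
    yd = np.interp(s, x, y)
    eps = np.asarray(sorted(box_sizes, reverse=True), dtype=float)
    counts = np.array([_count_boxes(xd, yd, e) for e in eps], dtype=float)
    logx = np.log(1.0 / eps)
    logn = np.log(counts)
    slope, intercept = np.polyfit(logx, logn, 1)
    pred = slope * logx + intercept
    ss_res = float(np.sum((logn - pred) ** 2))
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dim = float(np.clip(slope, 1.0, 2.0))
    return FractalityResult(
        drug=curve.drug,
        dimension_boxcount=dim,
        scale_range=(float(eps.min()), float(eps.max())),
        r_squared_loglog=r2,
    )


def higuchi_dimension(series: Sequence[float], k_max: int = 8) -> float:
    """Higuchi curve-length fractal dimension of a uniformly sampled series.

    For each delay k <= k_max, the mean normalised curve length L(k) is
    computed over the k phase-shifted subsamples; the dimension is the
    slope of log L(k) against log(1/k).  Requires a uniform grid (the
    caller resamples non-uniform curves first).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 2 * k_max:
        raise ValueError("series too short for the requested k_max")
    if k_max < 4:
        raise ValueError("k_max must be at least 4")
    N = len(y)
    ks = np.arange(1, k_max + 1)
    L = np.empty(len(ks))
    for j, k in enumerate(ks):
        lengths = []
        for m in range(k):
            idx = np.arange(m, N, k)
            if len(idx) < 2:
                continue
            diffs = np.abs(np.diff(y[idx]))
            norm = (N - 1) / (len(idx) - 1) / k
            lengths.append(diffs.sum() * norm / k)
        L[j] = np.mean(lengths)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(L), 1)
    return float(np.clip(slope, 1.0, 2.0))


def higuchi_dimension_curve(curve: ReleaseCurve, k_max: int = 8) -> FractalityResult:
    """Higuchi dimension of a release curve (uniform time grid required)."""
    dt = np.diff(curve.times_min)
    if not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("non-uniform time grid: resample before Higuchi estimation")
    dim = higuchi_dimension(curve.mean_release, k_max=k_max)
    return FractalityResult(drug=curve.drug, dimension_higuchi=dim)


def estimate_both(curve: ReleaseCurve, k_max: int = 8) -> FractalityResult:
    """Box-counting and Higuchi dimensions on one curve."""
    box = box_counting_dimension(curve)
    hig = higuchi_dimension_curve(curve, k_max=k_max)
    return FractalityResult(
        drug=curve.drug,
        dimension_boxcount=box.dimension_boxcount,
        dimension_higuchi=hig.dimension_higuchi,
        scale_range=box.scale_range,
        r_squared_loglog=box.r_squared_loglog,
    )


def drug_ordering(
    results: Sequence[FractalityResult], estimator: str = "boxcount"
) -> list[tuple[str, float]]:
    """Sort drugs by descending fractal dimension (most complex first).

    All results must carry the requested estimator and share its scale
    range; exact ties are flagged with a warning tag in the label.
    """
    if len(results) == 0:
        raise ValueError("no results to order")
    dims = []
    ranges = set()
    for res in results:
        v = getattr(res, f"dimension_{estimator}")
        if v is None:
            raise ValueError(f"result for {res.drug} lacks the {estimator} estimator")
        if estimator == "boxcount":
            ranges.add(res.scale_range)
        dims.append((res.drug, float(v)))
    if len(ranges) > 1:
        raise ValueError("mixed scale ranges across results")
    ordered = sorted(dims, key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in ordered]
    for i in range(len(values) - 1):
        if values[i] == values[i + 1]:
            ordered[i] = (ordered[i][0] + " (tie)", values[i])
            ordered[i + 1] = (ordered[i + 1][0] + " (tie)", values[i + 1])
    return ordered
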