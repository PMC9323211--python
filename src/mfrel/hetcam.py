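"""HET-CAM irritation scoring.

The hen's-egg chorioallantoic-membrane assay records the onset time, in
seconds within a 300 s observation window, of three vascular effects:
hemorrhage, lysis/hyperemia and coagulation.  The continuous irritation
score combines them as

    IS = 5*(301 - h)/300 + 7*(301 - l)/300 + 9*(301 - c)/300

giving 0 (no reaction anywhere in the window) to 21 (all three effects
immediate at 1 s).  An effect that is never observed is encoded as
onset 301 s so its contribution is exactly zero.  The discrete
window-score variant assigns fixed integer points per effect depending
on whether onset fell within 0.5, 2 or 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: effect -> Eq weight in the continuous score
_WEIGHTS = {"hemorrhage": 5.0, "lysis": 7.0, "coagulation": 9.0}

#: onset encoding for "not observed within 300 s"
NOT_OBSERVED_S = 301.0

#: Irritation categories, lower score bound first (half-open intervals,
#: closing the printed gaps, e.g. (0.9, 1.0)); the last is closed at 21.
_CATEGORIES = (
    (0.0, 1.0, "non-irritant"),
    (1.0, 5.0, "less irritant"),
    (5.0, 9.0, "moderate irritant"),
    (9.0, 21.0, "severe irritant"),
)

#: discrete points per effect for onset within 0.5 / 2 / 5 minutes
_WINDOW_POINTS = {
    "lysis": (5, 3, 1),
    "hemorrhage": (7, 5, 3),
    "coagulation": (9, 7, 5),
}


@dataclass(frozen=True)
class HetcamObservation:
    """Onset times (s) of the three effects; 301 means not observed."""

    hemorrhage_onset_s: float
    lysis_onset_s: float
    coagulation_onset_s: float

    def __post_init__(self) -> None:
        for name in ("hemorrhage_onset_s", "lysis_onset_s", "coagulation_onset_s"):
            v = getattr(self, name)
            if not 1.0 <= v <= NOT_OBSERVED_S:
                raise ValueError(f"{name}={v} outside [1, 301] s")


@dataclass(frozen=True)
class IrritationResult:
    score: float
    category: str


def irritation_score(obs: HetcamObservation) -> float:
    """Continuous irritation score in [0, 21]."""
    return (
        _WEIGHTS["hemorrhage"] * (NOT_OBSERVED_S - obs.hemorrhage_onset_s)
        + _WEIGHTS["lysis"] * (NOT_OBSERVED_S - obs.lysis_onset_s)
        + _WEIGHTS["coagulation"] * (NOT_OBSERVED_S - obs.coagulation_onset_s)
    ) / 300.0


def classify_irritation(score: float) -> str:
    """Map a score in [0, 21] onto the four irritation categories."""
    if not 0.0 <= score <= 21.0:
        raise ValueError(f"score {score} outside [0, 21]")
    for lo, hi, label in _CATEGORIES[:-1]:
        if lo <= score < hi:
            return label
    return _CATEGORIES[-1][2]


def score_observation(obs: HetcamObservation) -> IrritationResult:
    """Score and classify one observation."""
    s = irritation_score(obs)
    return IrritationResult(score=s, category=classify_irritation(s))


def discrete_window_score(effect: str, onset_s: float) -> int:
    """Discrete per-effect score from the 0.5 / 2 / 5 minute windows."""
    if effect not in _WINDOW_POINTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {sorted(_WINDOW_POINTS)}")
    if onset_s < 1:
        raise ValueError("onset must be >= 1 s")
    pts = _WINDOW_POINTS[effect]
    if onset_s <= 30:
        return pts[0]
    if onset_s <= 120:
        return pts[1]
    if onset_s <= 300:
        return pts[2]
    return 0
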