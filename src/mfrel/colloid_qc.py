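"""Colloid characterization math and rule-based formulation screening.

Dynamic light scattering instruments report a translational diffusion
coefficient; the Stokes-Einstein relation converts it to a hydrodynamic
diameter, and the Smoluchowski relation converts electrophoretic
mobility to a zeta potential.  On top of these, a small rule engine
screens pre-emulsion formulations for colloidal stability (size below
500 nm, PDI below 0.3) and ocular comfort (refractive index at most
1.476), and selects the working formulation as the smallest stable one.

Units are SI internally (m, s, K, V, Pa.s); nanometres and millivolts
appear only at I/O boundaries.  Callers supply the *absolute* dielectric
constant (F/m): the zeta relation is implemented literally as
``zeta = eta * mu / epsilon`` (some texts write mu*eta/(eps0*epsr) with
a relative permittivity instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class MediumProperties:
    """Dispersion-medium properties entering the colloid relations.

    Defaults are water-like at 25 C; instruments rarely report the
    values they assumed, so they are configuration, not assertions.
    """

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4
    dielectric_constant_F_per_m: float = 6.95e-10

    def __post_init__(self) -> None:
        for name in ("temperature_K", "viscosity_Pa_s", "dielectric_constant_F_per_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ColloidRecord:
    """One formulation's DLS/zeta characterization (a Table-style row)."""

    label: str
    ctab_pct: float
    mean_size_nm: float
    size_sd_nm: float = 0.0
    pdi: float = 0.0
    pdi_sd: float = 0.0
    zeta_mV: float = 0.0
    zeta_sd_mV: float = 0.0
    refractive_index: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.ctab_pct <= 100:
            raise ValueError("ctab_pct must be in [0, 100]")
        if not self.mean_size_nm > 0:
            raise ValueError("mean_size_nm must be positive")
        if self.size_sd_nm < 0 or self.pdi < 0 or self.pdi_sd < 0 or self.zeta_sd_mV < 0:
            raise ValueError("dispersions must be nonnegative")
        if self.refractive_index is not None and self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")


@dataclass(frozen=True)
class Violation:
    rule: str
    measured: float
    threshold: float


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    violations: tuple[Violation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.violations) == 0):
            raise ValueError("passed must be true iff violations is empty")


@dataclass(frozen=True)
class StabilityThresholds:
    """Screening rules: strict bounds on size and PDI, inclusive on RI."""

    max_size_nm: float = 500.0
    max_pdi: float = 0.3
    max_refractive_index: float = 1.476


def hydrodynamic_diameter(diffusion_m2_s: float, medium: MediumProperties) -> float:
    """Stokes-Einstein hydrodynamic diameter (m) from diffusivity (m^2/s).

    DH = kB*T / (3*pi*eta*D).
    """
    if not diffusion_m2_s > 0:
        raise ValueError("diffusion coefficient must be strictly positive")
    return BOLTZMANN_J_PER_K * medium.temperature_K / (
        3.0 * math.pi * medium.viscosity_Pa_s * diffusion_m2_s
    )


def diffusion_from_size(diameter_m: float, medium: MediumProperties) -> float:
    """Inverse Stokes-Einstein: diffusivity (m^2/s) from diameter (m)."""
    if not diameter_m > 0:
        raise ValueError("diameter must be strictly positive")
    return BOLTZMANN_J_PER_K * medium.temperature_K / (
        3.0 * math.pi * medium.viscosity_Pa_s * diameter_m
    )


def zeta_from_mobility(mobility_m2_Vs: float, medium: MediumProperties) -> float:
    """Smoluchowski zeta potential (V) from electrophoretic mobility.

    zeta = eta * mu / epsilon, with epsilon the absolute dielectric
    constant of the dispersion medium (F/m).  Odd in mu.
    """
    return medium.viscosity_Pa_s * mobility_m2_Vs / medium.dielectric_constant_F_per_m


def stability_screen(
    record: ColloidRecord, thresholds: StabilityThresholds | None = None
) -> ScreenResult:
    """Apply the stability/comfort rules to one formulation record.

    The refractive-index rule is skipped when the record carries no RI
    measurement (DLS characterization tables often omit it).
    """
    thr = thresholds or StabilityThresholds()
    violations: list[Violation] = []
    if not record.mean_size_nm < thr.max_size_nm:
        violations.append(Violation("size", record.mean_size_nm, thr.max_size_nm))
    if not record.pdi < thr.max_pdi:
        violations.append(Violation("pdi", record.pdi, thr.max_pdi))
    if record.refractive_index is not None and record.refractive_index > thr.max_refractive_index:
        violations.append(
            Violation("refractive_index", record.refractive_index, thr.max_refractive_index)
        )
    return ScreenResult(passed=not violations, violations=tuple(violations))


def select_formulation(
    records: Sequence[ColloidRecord], max_pdi: float = 0.3
) -> str:
    """Select the working formulation: minimum mean size subject to PDI.

    Among records with pdi < max_pdi, returns the label of the smallest
    mean size; ties break toward lower PDI, then lower CTAB fraction.
    """
    if not records:
        raise ValueError("no records to select from")
    eligible = [r for r in records if r.pdi < max_pdi]
    if not eligible:
        raise ValueError(f"no record satisfies pdi < {max_pdi}")
    best = min(eligible, key=lambda r: (r.mean_size_nm, r.pdi, r.ctab_pct))
    return best.label


def records_from_frame(df: pd.DataFrame) -> list[ColloidRecord]:
    """Build ColloidRecords from a characterization table.

    Expected columns: label, ctab_pct, size_nm, size_sd_nm, pdi, pdi_sd,
    zeta_mv, zeta_sd_mv and optionally refractive_index.
    """
    records = []
    for row in df.itertuples(index=False):
        ri = getattr(row, "refractive_index", None)
        if ri is not None and pd.isna(ri):
            ri = None
        records.append(
            ColloidRecord(
                label=str(row.label),
                ctab_pct=float(row.ctab_pct),
                mean_size_nm=float(row.size_nm),
                size_sd_nm=float(row.size_sd_nm),
                pdi=float(row.pdi),
                pdi_sd=float(row.pdi_sd),
                zeta_mV=float(row.zeta_mv),
                zeta_sd_mV=float(row.zeta_sd_mv),
                refractive_index=None if ri is None else float(ri),
            )
        )
    return records


def read_formulation_table(path) -> list[ColloidRecord]:
    """Read a formulation characterization CSV into ColloidRecords."""
    return records_from_frame(pd.read_csv(path))


def load_pre_emulsion_table() -> list[ColloidRecord]:
    """Packaged CTAB pre-emulsion characterization table (printed values)."""
    with resources.files("mfrel").joinpath("data/pre_emulsions.csv").open("r") as fh:
        return records_from_frame(pd.read_csv(fh))
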