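"""Reduction of raw TLD chip readings to TG-43 quantities.

A chip's background-corrected reader charge R (nC) converts to dose rate per
unit air-kerma strength as

    Ḋ(r, θ)/Sk = (R · chip_factor) / (T · Sk · ε · E(r) · d(T) · F_lin)

with T the exposure time (h), Sk the source air-kerma strength at the start
of the measurement (U), ε the calibration factor (nC/cGy), E(r) the energy
dependence correction, d(T) the decay-during-irradiation correction and
F_lin the supralinearity correction.  For Cs-137 and doses in the 10–100 cGy
linear range, E(r) = d(T) = F_lin = 1.  All correction factors sit in the
denominator; the per-chip sensitivity factor is applied to R first.  (The
published equation is typeset without the division bar between R·T and the
correction product; the denominator placement reproduces the stated units
and the unity-correction behaviour and is the reading adopted here.  The
numerator-vs-denominator placement of E(r) is untestable while E(r) = 1.)

Source strength bookkeeping: Sk at measurement follows from the assay value
by radioactive decay, Sk = Sk0 · 2^(−t/T½) with T½ = 30 y for Cs-137.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    R0_CM,
    THETA0_DEG,
    AnisotropyGrid,
    RadialTable,
    TG43Error,
)
from .engine import (
    DosePoint,
    GeometryModel,
    NormalizationError,
    derive_F_from_grid,
    derive_g_from_transverse_profile,
)

__all__ = [
    "CS137_HALF_LIFE_Y",
    "TLDReading",
    "CalibrationSet",
    "SourceStrengthRecord",
    "decay_sk",
    "reduce_reading",
    "lambda_from_readings",
    "measured_tables",
    "chip_factors_from_coirradiation",
    "read_readings_table",
    "write_readings_table",
]

CS137_HALF_LIFE_Y = 30.0
DAYS_PER_YEAR = 365.25
#: Dose range (cGy) over which the TLD response is linear with F_lin = 1.
LINEAR_RANGE_CGY = (10.0, 100.0)


@dataclass(frozen=True)
class TLDReading:
    """One chip's background-corrected response with exposure metadata."""

    raw_nC: float
    chip_factor: float
    position: DosePoint
    exposure_T_h: float
    chip_id: str = ""

    def __post_init__(self) -> None:
        if self.raw_nC < 0:
            raise ValueError("raw_nC must be non-negative (background-corrected)")
        if not (self.chip_factor > 0):
            raise ValueError("chip_factor must be positive")
        if not (self.exposure_T_h > 0):
            raise ValueError("exposure time must be positive")


@dataclass(frozen=True)
class CalibrationSet:
    """Calibration factor and the correction factors of the reduction formula."""

    epsilon_nC_per_cGy: float
    E_r: float = 1.0  # energy dependence (unity: calibrated with Cs-137)
    F_lin: float = 1.0  # supralinearity (unity on 10-100 cGy)
    d_T: float = 1.0  # source decay during irradiation (unity for 30 y T1/2)
    rel_uncertainty: float = 0.0  # relative calibration uncertainty on epsilon

    def __post_init__(self) -> None:
        for name in ("epsilon_nC_per_cGy", "E_r", "F_lin", "d_T"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SourceStrengthRecord:
    """Assayed air-kerma strength with decay bookkeeping."""

    Sk0: float  # U, at assay
    elapsed_days: float
    half_life_y: float = CS137_HALF_LIFE_Y

    def __post_init__(self) -> None:
        if not (self.Sk0 > 0):
            raise ValueError("Sk0 must be positive")
        if self.elapsed_days < 0:
            raise ValueError("elapsed time must be non-negative")


def decay_sk(rec: SourceStrengthRecord) -> float:
    """Air-kerma strength at measurement: Sk0 · 2^(−elapsed/half-life)."""
    half_life_days = rec.half_life_y * DAYS_PER_YEAR
    return rec.Sk0 * 2.0 ** (-rec.elapsed_days / half_life_days)


def reduce_reading(reading: TLDReading, cal: CalibrationSet, sk: float) -> float:
    """Dose rate per unit air-kerma strength (cGy·h⁻¹·U⁻¹) from one chip.

    Emits a warning annotation if the implied absorbed dose falls outside the
    linear response range while F_lin is left at unity.
    """
    if not (sk > 0):
        raise ValueError("sk must be positive")
    response = reading.raw_nC * reading.chip_factor
    implied_dose_cgy = response / cal.epsilon_nC_per_cGy
    if cal.F_lin == 1.0 and not (
        LINEAR_RANGE_CGY[0] <= implied_dose_cgy <= LINEAR_RANGE_CGY[1]
    ):
        warnings.warn(
            f"implied dose {implied_dose_cgy:.3g} cGy outside the linear range "
            f"{LINEAR_RANGE_CGY} with F_lin = 1",
            stacklevel=2,
        )
    return response / (
        reading.exposure_T_h
        * sk
        * cal.epsilon_nC_per_cGy
        * cal.E_r
        * cal.d_T
        * cal.F_lin
    )


def lambda_from_readings(
    readings: list[TLDReading],
    cal: CalibrationSet,
    sk: float,
    r_tol_cm: float = 1e-6,
    theta_tol_deg: float = 1e-6,
) -> tuple[float, float]:
    """Dose-rate constant Λ from chips at the reference point (1 cm, 90°).

    Returns (Λ, absolute uncertainty): the mean of the reduced reference
    readings, with the chip standard error combined in quadrature with the
    stated relative calibration uncertainty.
    """
    ref = [
        rd
        for rd in readings
        if abs(rd.position.r_cm - R0_CM) <= r_tol_cm
        and abs(rd.position.theta_deg - THETA0_DEG) <= theta_tol_deg
    ]
    if not ref:
        raise NormalizationError(
            "no readings at the reference point (1 cm, 90 deg)"
        )
    reduced = np.array([reduce_reading(rd, cal, sk) for rd in ref])
    lam = float(reduced.mean())
    sem = float(reduced.std(ddof=1) / math.sqrt(reduced.size)) if reduced.size > 1 else 0.0
    unc = math.hypot(sem, cal.rel_uncertainty * lam)
    return lam, unc


def measured_tables(
    readings: list[TLDReading],
    cal: CalibrationSet,
    sk: float,
    model: GeometryModel,
) -> tuple[RadialTable, AnisotropyGrid]:
    """Measured g(r) and F(r, θ) from a polar grid of chip readings.

    Readings at the same (r, θ) are averaged after reduction; the transverse
    (θ = 90°) profile feeds the radial-dose inversion and the full grid the
    anisotropy inversion.  Raises a normalisation error naming the radius if
    any radius lacks a θ = 90° entry.
    """
    cells: dict[tuple[float, float], list[float]] = {}
    for rd in readings:
        key = (round(rd.position.r_cm, 9), round(rd.position.theta_deg, 9))
        cells.setdefault(key, []).append(reduce_reading(rd, cal, sk))
    doses = {k: float(np.mean(v)) for k, v in cells.items()}

    radii = sorted({r for r, _ in doses})
    for r in radii:
        if not any(np.isclose(t, THETA0_DEG) for rr, t in doses if rr == r):
            raise NormalizationError(
                f"radius r = {r} cm has no transverse (90 deg) reading"
            )
    transverse = {
        r: doses[(r, t)] for (r, t) in doses if np.isclose(t, THETA0_DEG)
    }
    radial = derive_g_from_transverse_profile(transverse, model)
    grid = derive_F_from_grid(doses, model)
    return radial, grid


def chip_factors_from_coirradiation(responses_nC: dict[str, float]) -> dict[str, float]:
    """Per-chip sensitivity factors from a co-irradiation: the factor is the
    group-mean response divided by the chip's response, so factor × response
    is the same for every chip."""
    if not responses_nC:
        raise TG43Error("empty co-irradiation table")
    vals = np.array(list(responses_nC.values()), dtype=float)
    if np.any(vals <= 0):
        raise TG43Error("co-irradiation responses must be positive")
    mean = vals.mean()
    return {cid: float(mean / v) for cid, v in responses_nC.items()}


_COLUMNS = ["chip_id", "raw_nC", "chip_factor", "r_cm", "theta_deg", "T_h"]


def read_readings_table(path: str | Path) -> list[TLDReading]:
    """Read a delimited readings file (chip_id, raw_nC, chip_factor, r_cm,
    theta_deg, T_h)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TG43Error(f"{path}: readings table missing columns {missing}")
    return [
        TLDReading(
            raw_nC=float(row.raw_nC),
            chip_factor=float(row.chip_factor),
            position=DosePoint(float(row.r_cm), float(row.theta_deg)),
            exposure_T_h=float(row.T_h),
            chip_id=str(row.chip_id),
        )
        for row in df.itertuples()
    ]


def write_readings_table(readings: list[TLDReading], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chip_id": [rd.chip_id for rd in readings],
            "raw_nC": [rd.raw_nC for rd in readings],
            "chip_factor": [rd.chip_factor for rd in readings],
            "r_cm": [rd.position.r_cm for rd in readings],
            "theta_deg": [rd.position.theta_deg for rd in readings],
            "T_h": [rd.exposure_T_h for rd in readings],
        }
    )
    df.to_csv(path, sep="\t", index=False)
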