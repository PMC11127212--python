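"""TWIMS collision cross-section calibration and CCS deviation metrics.

Traveling-wave ion mobility does not yield CCS from first principles; a
power-law calibration against ions of known (drift-tube-derived) CCS is the
standard practice. The workflow implemented here:

1. correct measured drift times for the m/z-dependent post-mobility flight
   time (EDC correction): ``t' = t - c * sqrt(m/z) / 1000``;
2. reduce literature CCS values to charge/gas-independent form,
   ``omega' = omega * sqrt(mu) / z`` with reduced mass
   ``mu = m_ion * m_gas / (m_ion + m_gas)``;
3. fit ``ln(omega') = ln(A) + B * ln(t')`` by ordinary least squares;
4. optionally apply a single-point multiplicative lock-CCS correction from a
   continuously infused reference compound (leucine enkephalin in practice).

CCS deviations are reported both absolute (A^2) and relative (%), matching
how accuracy, matrix-effect and adduct-shift statistics are expressed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N2_GAS_MASS",
    "CalibrantPoint",
    "CalibrationModel",
    "CcsDeviation",
    "corrected_drift_time",
    "normalize_ccs",
    "denormalize_ccs",
    "fit_ccs_calibration",
    "drift_to_ccs",
    "lock_ccs_correction",
    "delta_ccs",
    "read_calibrant_table",
]

#: Mass of molecular nitrogen (the default TWIMS drift gas) in Da.
N2_GAS_MASS = 28.0134


class CalibrationError(ValueError):
    """Raised for unusable calibrant sets or out-of-range corrections."""


@dataclass(frozen=True)
class CalibrantPoint:
    """One calibrant ion: m/z, charge, measured drift time and literature CCS."""

    mz: float
    charge: int
    drift_time: float  # ms
    reference_ccs: float  # A^2

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.drift_time <= 0 or self.reference_ccs <= 0:
            raise ValueError("calibrant fields must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted power-law calibration ``omega' = A * t'^B`` on normalized CCS.

    ``edc_coefficient`` is instrument-specific and deliberately has no
    universal default; it must be supplied by configuration. ``lock_factor``
    is a multiplicative single-point correction, 1.0 when uncorrected.
    """

    A: float
    B: float
    edc_coefficient: float
    gas_mass: float = N2_GAS_MASS
    lock_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")
        if self.gas_mass <= 0:
            raise ValueError("gas_mass must be positive")
        if not (0.5 < self.lock_factor < 2.0):
            raise CalibrationError(
                f"lock_factor {self.lock_factor} outside (0.5, 2); gross miscalibration"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CcsDeviation:
    """Measured-vs-reference CCS difference, absolute (A^2) and relative (%)."""

    measured_ccs: float
    reference_ccs: float
    delta_abs: float
    delta_pct: float


def corrected_drift_time(drift_time: float, mz: float, edc_coefficient: float) -> float:
    """EDC-corrected drift time ``t' = t - c * sqrt(m/z) / 1000`` (ms).

    Raises if the correction consumes the whole drift time, which signals a
    wrong coefficient or wrong units.
    """
    if drift_time <= 0:
        raise ValueError("drift time must be positive")
    corrected = drift_time - edc_coefficient * math.sqrt(mz) / 1000.0
    if corrected <= 0:
        raise CalibrationError(
            f"corrected drift time {corrected:.4f} ms <= 0 "
            f"(t={drift_time}, m/z={mz}, c={edc_coefficient})"
        )
    return corrected


def _reduced_mass(ion_mass: float, gas_mass: float) -> float:
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def normalize_ccs(ccs: float, mz: float, charge: int, gas_mass: float = N2_GAS_MASS) -> float:
    """Charge/reduced-mass normalized CCS, ``omega' = omega * sqrt(mu) / z``."""
    if ccs <= 0 or mz <= 0 or charge < 1 or gas_mass <= 0:
        raise ValueError("all arguments must be positive (charge >= 1)")
    mu = _reduced_mass(mz * charge, gas_mass)
    return ccs * math.sqrt(mu) / charge


def denormalize_ccs(normalized: float, mz: float, charge: int,
                    gas_mass: float = N2_GAS_MASS) -> float:
    """Inverse of :func:`normalize_ccs`."""
    mu = _reduced_mass(mz * charge, gas_mass)
    return normalized * charge / math.sqrt(mu)


def fit_ccs_calibration(
    calibrants: Sequence[CalibrantPoint],
    edc_coefficient: float,
    gas_mass: float = N2_GAS_MASS,
) -> CalibrationModel:
    """Fit the power-law CCS calibration by OLS in log-log space.

    Parameters
    ----------
    calibrants : sequence of CalibrantPoint
        At least two points with distinct corrected drift times.
    edc_coefficient : float
        Instrument EDC delay coefficient used for drift-time correction.
    gas_mass : float
        Drift gas mass in Da (nitrogen by default).
    """
    if len(calibrants) < 2:
        raise CalibrationError("need at least 2 calibrant points")
    log_t = np.array(
        [math.log(corrected_drift_time(p.drift_time, p.mz, edc_coefficient))
         for p in calibrants]
    )
    log_omega = np.array(
        [math.log(normalize_ccs(p.reference_ccs, p.mz, p.charge, gas_mass))
         for p in calibrants]
    )
    if np.ptp(log_t) == 0:
        raise CalibrationError("calibrants have identical corrected drift times")
    slope, intercept = np.polyfit(log_t, log_omega, 1)
    return CalibrationModel(
        A=float(math.exp(intercept)),
        B=float(slope),
        edc_coefficient=edc_coefficient,
        gas_mass=gas_mass,
    )


def drift_to_ccs(model: CalibrationModel, drift_time: float, mz: float, charge: int = 1) -> float:
    """CCS (A^2) of an ion from its measured drift time under a fitted model."""
    t_prime = corrected_drift_time(drift_time, mz, model.edc_coefficient)
    normalized = model.A * t_prime ** model.B
    return model.lock_factor * denormalize_ccs(normalized, mz, charge, model.gas_mass)


def lock_ccs_correction(
    model: CalibrationModel, lock_measured_ccs: float, lock_reference_ccs: float
) -> CalibrationModel:
    """Single-point lock-CCS correction: scale output by reference/measured."""
    if lock_measured_ccs <= 0 or lock_reference_ccs <= 0:
        raise ValueError("lock CCS values must be positive")
    factor = lock_reference_ccs / lock_measured_ccs
    if not (0.5 < factor < 2.0):
        raise CalibrationError(
            f"lock factor {factor:.3f} outside (0.5, 2); gross miscalibration"
        )
    return replace(model, lock_factor=factor)


def delta_ccs(measured: float, reference: float) -> CcsDeviation:
    """CCS difference error of a measured value against a reference value."""
    if reference <= 0:
        raise ValueError("reference CCS must be positive")
    delta = measured - reference
    return CcsDeviation(
        measured_ccs=measured,
        reference_ccs=reference,
        delta_abs=delta,
        delta_pct=100.0 * delta / reference,
    )


def read_calibrant_table(path: str | Path) -> list[CalibrantPoint]:
    """Read a delimited calibrant table (mz, charge, drift_time_ms, reference_ccs_A2)."""
    df = pd.read_csv(path)
    required = {"mz", "charge", "drift_time_ms", "reference_ccs_A2"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"calibrant table missing columns: {sorted(missing)}")
    return [
        CalibrantPoint(
            mz=float(r.mz),
            charge=int(r.charge),
            drift_time=float(r.drift_time_ms),
            reference_ccs=float(r.reference_ccs_A2),
        )
        for r in df.itertuples()
    ]
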