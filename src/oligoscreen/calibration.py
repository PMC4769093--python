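"""Travelling-wave ion-mobility CCS calibration.

On a travelling-wave instrument the drift-time to collision-cross-section
relation is empirical and is calibrated against ions of known drift-tube CCS
(typically denatured proteins and tryptic peptides).  The standard protocol
implemented here:

1. Correct each drift time for the m/z-dependent, mobility-independent
   transit through the transfer optics (enhanced-duty-cycle delay):
   ``t_d' = t_d - edc_delay * sqrt(m/z) / 1000``.
2. Reduce each literature CCS for charge and reduced mass with the drift gas:
   ``Omega' = Omega / (z * sqrt(1/m_ion + 1/m_gas))``.
3. Fit the power law ``Omega' = A * t_d'**B`` by least squares on the
   log-log line ``ln Omega' = ln A + B ln t_d'``.

Estimation then applies the fitted law in the forward direction and restores
charge and reduced mass.  A single global fit is used for all charge states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

#: Average mass of N2 drift gas, Da.
N2_MASS = 28.0134

#: Default enhanced-duty-cycle coefficient in instrument-native units
#: (ms per sqrt(Th)/1000 scale).  Instrument-specific; override per dataset.
DEFAULT_EDC_DELAY = 1.41


class CalibrationDomainError(ValueError):
    """Corrected drift time fell outside the calibrated domain."""


class InsufficientCalibrantsError(ValueError):
    """Fewer calibrants than required for a power-law fit."""


@dataclass(frozen=True)
class Calibrant:
    """One calibration ion with a literature drift-tube CCS.

    ``mass`` is the ion mass in Da, ``reference_ccs`` the drift-tube CCS in
    square Angstroms, ``observed_drift`` the measured travelling-wave arrival
    time in ms.
    """

    identity: str
    mass: float
    charge: int
    reference_ccs: float
    observed_drift: float

    def __post_init__(self) -> None:
        for name in ("mass", "charge", "reference_ccs", "observed_drift"):
            if not getattr(self, name) > 0:
                raise ValueError(f"calibrant {self.identity}: {name} must be positive")


@dataclass
class CcsCalibration:
    """Fitted power-law mapping corrected drift time -> reduced CCS.

    ``A`` (scale) and ``B`` (exponent) parameterise ``Omega' = A * t_d'**B``.
    ``r_squared`` is the coefficient of determination of the log-log line.
    """

    A: float
    B: float
    edc_delay: float = DEFAULT_EDC_DELAY
    gas_mass: float = N2_MASS
    r_squared: float = 1.0
    calibrants: list[Calibrant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("power-law scale A must be positive")
        if not 0 < self.B < 2:
            raise ValueError(f"power-law exponent B={self.B} outside plausible (0, 2)")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "A": self.A,
            "B": self.B,
            "edc_delay": self.edc_delay,
            "gas_mass": self.gas_mass,
            "r_squared": self.r_squared,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CcsCalibration":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def correct_drift(t_d: float, mz: float, edc_delay: float) -> float:
    """Remove the mobility-independent m/z-dependent transit from a drift time.

    Raises :class:`CalibrationDomainError` when the corrected value is not
    positive, i.e. the recorded drift is shorter than the transit itself.
    """
    if t_d < 0:
        raise ValueError(f"drift time must be >= 0, got {t_d}")
    t_prime = t_d - edc_delay * math.sqrt(mz) / 1000.0
    if t_prime <= 0:
        raise CalibrationDomainError(
            f"corrected drift {t_prime:.4g} ms <= 0 (t_d={t_d}, mz={mz})"
        )
    return t_prime


def reduced_ccs(ccs: float, z: int, ion_mass: float, gas_mass: float) -> float:
    """Charge- and reduced-mass-normalised CCS used on the calibration line."""
    return ccs / (z * math.sqrt(1.0 / ion_mass + 1.0 / gas_mass))


def fit_calibration(
    calibrants: Sequence[Calibrant],
    edc_delay: float = DEFAULT_EDC_DELAY,
    gas_mass: float = N2_MASS,
) -> CcsCalibration:
    """Least-squares power-law fit of reduced CCS against corrected drift.

    Requires at least three calibrants with distinct corrected drift times.
    """
    if len(calibrants) < 3:
        raise InsufficientCalibrantsError(
            f"need >= 3 calibrants for a power-law fit, got {len(calibrants)}"
        )
    t_prime = np.array(
        [
            correct_drift(c.observed_drift, (c.mass / c.charge), edc_delay)
            for c in calibrants
        ]
    )
    omega_prime = np.array(
        [reduced_ccs(c.reference_ccs, c.charge, c.mass, gas_mass) for c in calibrants]
    )
    ln_t = np.log(t_prime)
    if np.ptp(ln_t) == 0:
        raise InsufficientCalibrantsError("calibrant corrected drifts are identical")
    fit = stats.linregress(ln_t, np.log(omega_prime))
    return CcsCalibration(
        A=float(np.exp(fit.intercept)),
        B=float(fit.slope),
        edc_delay=edc_delay,
        gas_mass=gas_mass,
        r_squared=float(fit.rvalue**2),
        calibrants=list(calibrants),
    )


def estimate_ccs(
    t_d: float, mz: float, z: int, ion_mass: float, calibration: CcsCalibration
) -> float:
    """CCS estimate in square Angstroms for an observed drift time.

    ``ion_mass`` is the intact-ion mass in Da (same convention as the
    calibrant table the calibration was fitted with).
    """
    t_prime = correct_drift(t_d, mz, calibration.edc_delay)
    omega_prime = calibration.A * t_prime**calibration.B
    return omega_prime * z * math.sqrt(1.0 / ion_mass + 1.0 / calibration.gas_mass)


def invert_ccs(
    ccs: float, z: int, ion_mass: float, calibration: CcsCalibration
) -> float:
    """Drift time at which :func:`estimate_ccs` would return ``ccs``.

    The exact inverse of the calibration (used by the synthetic generator and
    by drift-based degeneracy resolution).  The ion's m/z is taken as
    ``ion_mass / z`` since ``ion_mass`` includes the charging protons.
    """
    if not ccs > 0:
        raise ValueError(f"ccs must be positive, got {ccs}")
    if calibration.B == 0:
        raise ValueError("calibration with B=0 is not invertible")
    omega_prime = reduced_ccs(ccs, z, ion_mass, calibration.gas_mass)
    t_prime = (omega_prime / calibration.A) ** (1.0 / calibration.B)
    mz = ion_mass / z
    return t_prime + calibration.edc_delay * math.sqrt(mz) / 1000.0
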