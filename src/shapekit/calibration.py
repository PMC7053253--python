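"""Unit conversions and acoustic bookkeeping for the pressure-phantom setup.

Everything downstream (bubble model, synthetic RF, regressions) works in SI
internally but the experimental protocol is stated in clinical units:
hydrostatic pressure in mmHg gauge, acoustic drive in kPa, signal loss in dB,
geometry in mm.  This module holds the conversions and the small amount of
acoustic arithmetic (incident-pressure derating, mechanical index, spatial
pulse length, effective imaging depth of an obliquely insonated chamber).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMHG_PA",
    "ATM_PA",
    "WATER_DENSITY",
    "MERCURY_DENSITY",
    "SOUND_SPEED_WATER",
    "LossBudget",
    "ChamberGeometry",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "water_column_to_mmhg",
    "incident_pressure",
    "effective_depth",
    "pulse_length",
    "mechanical_index",
]

#: Conventional millimetre of mercury in pascal.
MMHG_PA = 133.322387415
#: Standard atmosphere, Pa.  Gauge pressures are referenced to this.
ATM_PA = 101_325.0
#: Densities (kg/m^3) at reference conditions used for the water-column
#: calibration of the pressure meter.
WATER_DENSITY = 1000.0
MERCURY_DENSITY = 13_595.1
#: Speed of sound in water at ~21 degC room temperature, m/s.
SOUND_SPEED_WATER = 1482.0


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LossBudget:
    """Acoustic signal loss between transducer and chamber interior.

    Parameters
    ----------
    foam_attenuation : float
        One-way attenuation through the absorbing foam layer, dB (>= 0).
    insertion_loss : float
        Insertion loss through one chamber window, dB (>= 0).
    """

    foam_attenuation: float
    insertion_loss: float

    def __post_init__(self) -> None:
        for name in ("foam_attenuation", "insertion_loss"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0 dB, got {v}")

    @property
    def total(self) -> float:
        """Total signal loss, dB (sum of the components)."""
        return self.foam_attenuation + self.insertion_loss


@dataclass(frozen=True)
class ChamberGeometry:
    """Pressure-chamber slab geometry seen by an oblique beam."""

    thickness_mm: float = 3.7
    insonation_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        t = _require_finite("thickness_mm", self.thickness_mm)
        a = _require_finite("insonation_angle_deg", self.insonation_angle_deg)
        if t <= 0:
            raise ValueError(f"thickness_mm must be > 0, got {t}")
        if not 0 <= a < 90:
            raise ValueError(f"insonation_angle_deg must be in [0, 90), got {a}")


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert pressure in mmHg to Pa (negative values allowed: gauge
    differences)."""
    return _require_finite("p_mmhg", p_mmhg) * MMHG_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure in Pa to mmHg."""
    return _require_finite("p_pa", p_pa) / MMHG_PA


def water_column_to_mmhg(height_m: float) -> float:
    """Static pressure of a water column expressed in mmHg.

    A 2-m column reads 147 mmHg, the calibration point of the digital
    pressure meter used with the phantom.
    """
    h = _require_finite("height_m", height_m)
    if h < 0:
        raise ValueError(f"column height must be >= 0 m, got {h}")
    return h * 1000.0 * (WATER_DENSITY / MERCURY_DENSITY)


def incident_pressure(p_waterbath_kpa: float, loss_db: float) -> float:
    """Acoustic pressure inside the chamber after the loss budget.

    ``p_waterbath * 10**(-loss/20)`` — the free-field water-bath pressure
    derated by the total one-way signal loss in dB.
    """
    p = _require_finite("p_waterbath_kpa", p_waterbath_kpa)
    loss = _require_finite("loss_db", loss_db)
    if p < 0:
        raise ValueError(f"water-bath pressure must be >= 0, got {p}")
    if loss < 0:
        raise ValueError(f"loss must be >= 0 dB (gain is not modelled), got {loss}")
    return p * 10.0 ** (-loss / 20.0)


def effective_depth(geom: ChamberGeometry) -> float:
    """Effective chamber depth along the beam, mm.

    Insonating a slab of thickness ``d`` at angle ``theta`` from normal
    stretches the in-image depth to ``d / cos(theta)`` (3.7 mm at 45
    degrees -> 5.2 mm).
    """
    return geom.thickness_mm / math.cos(math.radians(geom.insonation_angle_deg))


def pulse_length(c_m_s: float, n_cycles: int, f_hz: float) -> float:
    """Nominal spatial length of an ``n_cycles`` tone burst, mm."""
    c = _require_finite("c_m_s", c_m_s)
    f = _require_finite("f_hz", f_hz)
    if c <= 0 or n_cycles <= 0 or f <= 0:
        raise ValueError("sound speed, cycle count and frequency must be positive")
    return 1000.0 * c * n_cycles / f


def mechanical_index(p_neg_mpa: float, f_mhz: float) -> float:
    """Mechanical index: peak-negative pressure (MPa) / sqrt(frequency, MHz)."""
    p = _require_finite("p_neg_mpa", p_neg_mpa)
    f = _require_finite("f_mhz", f_mhz)
    if p < 0:
        raise ValueError(f"peak-negative pressure must be >= 0, got {p}")
    if f <= 0:
        raise ValueError(f"frequency must be > 0 MHz, got {f}")
    return p / math.sqrt(f)
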