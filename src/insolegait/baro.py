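"""Barometric pressure to relative altitude, with noise propagation.

Altitude changes are estimated from absolute pressure with the hypsometric
formula of the standard atmosphere (linear temperature lapse).  The altitude
precision achievable by a barometric sensor follows from dividing its pressure
noise by the local pressure gradient |dP/dh|; at sea level and 15 degC the
gradient is about 12.0 Pa/m, so a 1.3 Pa noise floor maps to roughly 0.11 m of
altitude noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BaroConfig", "pressure_to_altitude", "altitude_to_pressure", "altitude_noise_std"]

_G = 9.80665          # m/s^2
_R = 8.31446          # J/(mol K)
_M = 0.0289644        # kg/mol, dry air
_LAPSE = 0.0065       # K/m


@dataclass
class BaroConfig:
    """Sensor and atmosphere reference parameters."""

    pressure_noise_pa: float = 1.3
    fs: float = 125.0
    p0_hpa: float = 1013.25        # sea-level reference pressure
    t0_k: float = 288.15           # reference temperature (15 degC)

    def __post_init__(self) -> None:
        if self.pressure_noise_pa < 0:
            raise ValueError("noise must be non-negative")
        if not (300.0 <= self.p0_hpa <= 1100.0):
            raise ValueError("reference pressure outside sensor range [300, 1100] hPa")
        if self.t0_k <= 0:
            raise ValueError("reference temperature must be positive")


def pressure_to_altitude(p_pa, cfg: BaroConfig = BaroConfig()):
    """Altitude [m] relative to the reference pressure level (hypsometric formula).

    Monotone decreasing in pressure; for small deviations the linearization
    ``h ~= -dp / (rho0 * g)`` holds.
    """
    p = np.asarray(p_pa, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    p0 = cfg.p0_hpa * 100.0
    expo = _R * _LAPSE / (_G * _M)
    h = cfg.t0_k / _LAPSE * (1.0 - (p / p0) ** expo)
    return float(h) if np.isscalar(p_pa) else h


def altitude_to_pressure(h_m, cfg: BaroConfig = BaroConfig()):
    """Inverse of :func:`pressure_to_altitude`."""
    h = np.asarray(h_m, dtype=float)
    p0 = cfg.p0_hpa * 100.0
    expo = _G * _M / (_R * _LAPSE)
    p = p0 * (1.0 - _LAPSE * h / cfg.t0_k) ** expo
    return float(p) if np.isscalar(h_m) else p


def altitude_noise_std(cfg: BaroConfig = BaroConfig()) -> float:
    """Altitude noise [m] implied by the sensor's pressure noise at the reference level.

    ``sigma_h = sigma_p / |dP/dh|`` with ``|dP/dh| = rho0 * g`` and the air
    density from the ideal-gas law at the reference pressure and temperature.
    """
    rho0 = cfg.p0_hpa * 100.0 * _M / (_R * cfg.t0_k)
    return cfg.pressure_noise_pa / (rho0 * _G)
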