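"""Light field inside a bottom-illuminated, orbitally shaken flask.

The flask is treated as a flat photobioreactor lit from one side: the height
``h`` of the liquid column plays the role of the reactor depth. Light enters
at the flask bottom with incident intensity ``I0`` (an empirical polynomial of
the lamp set-point ``I_S``), decays with height according to Lambert–Beer with
an effective extinction coefficient ``eps`` obtained from a two-flux radiative
approximation (mass absorption ``E_a``, mass scattering ``E_s`` and backward
scattering fraction ``b``), and is averaged over the well-mixed volume. A
periodic on/off schedule models ``L`` hours of artificial light per day.

Unit convention (project-wide): biomass ``X`` in g/L is numerically identical
to kg/m**3, heights in m, mass optical coefficients in m**2/kg, so the optical
depth ``eps * X * z`` is dimensionless. Intensities are PPFD in umol/(m**2 s),
times in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LightSetting",
    "RadiativeParams",
    "FlaskGeometry",
    "incident_intensity",
    "scattering_modulus",
    "extinction_coefficient",
    "local_intensity",
    "average_intensity",
    "light_on",
    "scheduled_average_intensity",
]

#: Default coefficients of the lamp set-point -> incident intensity
#: regression (intercept, linear, quadratic); calibrated for the LED lighting
#: tablet used in the reference experiments. Other devices recalibrate these.
DEFAULT_I0_COEFFS = (6.92, 0.436, -8.1e-5)

#: Optical depth below which the volume average switches to its Taylor
#: expansion to avoid 0/0 at vanishing biomass.
_TAYLOR_THRESHOLD = 1e-8


@dataclass(frozen=True)
class LightSetting:
    """One flask's lighting condition.

    Parameters
    ----------
    I_S : float
        Set intensity of the lighting tablet [umol/(m2 s)].
    L : float
        Light duration per day [h], between 0 and 24.
    """

    I_S: float
    L: float

    def __post_init__(self) -> None:
        if self.I_S < 0:
            raise ValueError(f"set intensity I_S must be >= 0, got {self.I_S}")
        if not 0.0 <= self.L <= 24.0:
            raise ValueError(f"light duration L must be in [0, 24] h, got {self.L}")


@dataclass(frozen=True)
class RadiativeParams:
    """Two-flux optical properties of the suspension plus the I0 regression.

    ``alpha`` (linear scattering modulus) and ``epsilon`` (effective
    extinction coefficient, m2/kg) are derived quantities; ``epsilon >= E_a``
    always, with equality when there is no backscattered flux.
    """

    E_a: float = 227.0
    E_s: float = 800.0
    b: float = 0.0008
    i0_coeffs: tuple[float, float, float] = field(default=DEFAULT_I0_COEFFS)

    def __post_init__(self) -> None:
        if self.E_a <= 0:
            raise ValueError(f"mass absorption coefficient E_a must be > 0, got {self.E_a}")
        if self.E_s < 0:
            raise ValueError(f"mass scattering coefficient E_s must be >= 0, got {self.E_s}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"backward scattering fraction b must be in [0, 1], got {self.b}")
        if len(self.i0_coeffs) != 3:
            raise ValueError("i0_coeffs must be (c0, c1, c2)")

    @property
    def alpha(self) -> float:
        return scattering_modulus(self)

    @property
    def epsilon(self) -> float:
        return extinction_coefficient(self)


@dataclass(frozen=True)
class FlaskGeometry:
    """Working volume [L] and liquid height above the flask bottom [m]."""

    V: float = 0.2
    h: float = 0.04

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"working volume V must be > 0, got {self.V}")
        if self.h <= 0:
            raise ValueError(f"liquid height h must be > 0, got {self.h}")


def incident_intensity(I_S, params: RadiativeParams | None = None):
    """Incident intensity I0 at the flask bottom from the lamp set-point.

    Evaluates the device calibration polynomial ``c0 + c1*I_S + c2*I_S**2``.
    Accepts scalars or arrays.
    """
    I_S = np.asarray(I_S, dtype=float)
    if np.any(I_S < 0):
        raise ValueError("set intensity I_S must be >= 0")
    c0, c1, c2 = (params or RadiativeParams()).i0_coeffs
    out = c0 + c1 * I_S + c2 * I_S**2
    return float(out) if out.ndim == 0 else out


def scattering_modulus(params: RadiativeParams) -> float:
    """Linear scattering modulus alpha = sqrt(E_a / (E_a + 2 b E_s)).

    alpha lies in (0, 1]; alpha == 1 exactly when there is no effective
    backscattering (b * E_s == 0).
    """
    if params.E_a <= 0:
        raise ValueError("E_a must be > 0")
    return math.sqrt(params.E_a / (params.E_a + 2.0 * params.b * params.E_s))


def extinction_coefficient(params: RadiativeParams) -> float:
    """Effective extinction coefficient eps = (1 + alpha) / (2 alpha) * E_a [m2/kg]."""
    a = scattering_modulus(params)
    return (1.0 + a) / (2.0 * a) * params.E_a


def local_intensity(I0, epsilon, X, z):
    """Lambert–Beer local intensity I = I0 * exp(-eps * X * z).

    ``X`` in g/L (== kg/m3), ``z`` in m. Accepts scalars or arrays.
    """
    I0, epsilon, X, z = (np.asarray(v, dtype=float) for v in (I0, epsilon, X, z))
    for name, v in (("I0", I0), ("epsilon", epsilon), ("X", X), ("z", z)):
        if np.any(v < 0):
            raise ValueError(f"{name} must be >= 0")
    out = I0 * np.exp(-(epsilon * X * z))
    return float(out) if out.ndim == 0 else out


def average_intensity(I0, epsilon, X, h):
    """Volume-averaged intensity of the exponentially attenuated light field.

    I_avg = I0 * (1 - exp(-eps X h)) / (eps X h); continuous at X -> 0 where
    it tends to I0 (a 2-term Taylor expansion is used below an optical depth
    of 1e-8).
    """
    I0, epsilon, X, h = (np.asarray(v, dtype=float) for v in (I0, epsilon, X, h))
    if np.any(h <= 0):
        raise ValueError("liquid height h must be > 0")
    if np.any(I0 < 0) or np.any(epsilon < 0) or np.any(X < 0):
        raise ValueError("I0, epsilon and X must be >= 0")
    u = epsilon * X * h
    small = u < _TAYLOR_THRESHOLD
    with np.errstate(divide="ignore", invalid="ignore"):
        full = I0 * (1.0 - np.exp(-u)) / u
    out = np.where(small, I0 * (1.0 - 0.5 * u), full)
    return float(out) if out.ndim == 0 else out


def light_on(t, L):
    """Pulse schedule indicator: 1 while (t mod 24) < L, else 0. Period 24 h."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    out = ((t - 24.0 * np.floor(t / 24.0)) < L).astype(float)
    return float(out) if out.ndim == 0 else out


def scheduled_average_intensity(
    t,
    I_S,
    L,
    X,
    params: RadiativeParams | None = None,
    h: float = FlaskGeometry().h,
):
    """Average intensity under the daily on/off schedule.

    Composition ``average_intensity(I0(I_S), eps, X, h) * light_on(t, L)``.
    """
    params = params or RadiativeParams()
    I0 = incident_intensity(I_S, params)
    eps = extinction_coefficient(params)
    return average_intensity(I0, eps, X, h) * light_on(t, L)
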