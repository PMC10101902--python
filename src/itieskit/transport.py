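"""Mass-transport estimation: Randles-Sevcik and Saito inversions.

Two textbook relations are used in opposite directions.  For a reversible,
diffusion-limited transfer at a *macroscopic* interface the peak current of
a linear-sweep voltammogram is

    I_p = 0.4463 * z * F * A * C * sqrt(z * F * v * D / (R * T)),

so regressing measured peak currents on sqrt(scan rate) yields the
diffusion coefficient from the slope.  At a *microscopic* disc-shaped
interface the forward wave instead reaches the steady-state limiting
current

    I_ss = 4 * z * F * D * C * r,

whose inversion sizes the interface radius from a measured plateau - the
routine quality-control step for capillary-supported micro-interfaces.

Unit contract: this module works in CGS-molar units (cm, cm^2, cm^2/s,
mol/cm^3, A, V); use :mod:`itieskit.units` to convert from uM / uA / nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditions import Conditions
from .errors import FitError, InvalidInputError

__all__ = [
    "RANDLES_SEVCIK_FACTOR",
    "CellGeometry",
    "ScanRateFit",
    "randles_sevcik_peak_current",
    "diffusion_from_scan_rate_series",
    "saito_current",
    "saito_radius",
]

#: Dimensionless peak factor of the reversible linear-diffusion voltammogram.
RANDLES_SEVCIK_FACTOR = 0.4463


@dataclass(frozen=True)
class CellGeometry:
    """Circular interface geometry.

    ``kind`` is ``"macro"`` (glass-cell interface, radii of order 1 cm) or
    ``"micro"`` (capillary-supported interface, radii of order 10 um).
    The electroactive area is the disc area pi*r^2.
    """

    kind: str
    radius: float  # cm

    def __post_init__(self) -> None:
        if self.kind not in ("macro", "micro"):
            raise InvalidInputError(f"kind must be 'macro' or 'micro', got {self.kind!r}")
        if not (self.radius > 0.0) or not math.isfinite(self.radius):
            raise InvalidInputError(f"radius must be positive, got {self.radius!r}")

    @property
    def area(self) -> float:
        """Disc area pi*r^2 in cm^2."""
        return math.pi * self.radius ** 2


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0.0:
            raise InvalidInputError(f"{name} must be positive and finite, got {value!r}")


def randles_sevcik_peak_current(
    charge: int,
    area: float,
    concentration: float,
    diffusion: float,
    scan_rate: float,
    conditions: Conditions = Conditions(),
) -> float:
    """Reversible peak current (A) for a linear-diffusion voltammogram.

    Parameters are in the module's CGS-molar contract: ``area`` cm^2,
    ``concentration`` mol/cm^3, ``diffusion`` cm^2/s, ``scan_rate`` V/s.
    ``concentration`` may be zero (returns 0 A); all other magnitudes must
    be positive.
    """
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    z = abs(charge)
    _require_positive(area=area, diffusion=diffusion, scan_rate=scan_rate)
    if concentration < 0 or not math.isfinite(concentration):
        raise InvalidInputError(f"concentration must be >= 0, got {concentration!r}")
    c = conditions
    return (
        RANDLES_SEVCIK_FACTOR
        * z
        * c.faraday
        * area
        * concentration
        * math.sqrt(z * c.faraday * scan_rate * diffusion / (c.gas_constant * c.temperature))
    )


@dataclass(frozen=True)
class ScanRateFit:
    """Diagnostics of the I_p vs sqrt(v) regression."""

    diffusion: float  # cm^2/s
    slope: float  # A / (V/s)^0.5
    intercept: float  # A
    slope_stderr: float
    r_squared: float
    n_points: int


def diffusion_from_scan_rate_series(
    points,
    charge: int,
    area: float,
    concentration: float,
    conditions: Conditions = Conditions(),
) -> ScanRateFit:
    """Diffusion coefficient from a (scan rate, peak current) series.

    Ordinary least squares of peak current on sqrt(scan rate) with a free
    intercept (kept as a diagnostic; real series rarely pass through the
    origin).  The diffusion coefficient comes from the slope alone:

        D = (slope / (0.4463 * z * F * A * C))^2 * R * T / (z * F).
    """
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    z = abs(charge)
    _require_positive(area=area, concentration=concentration)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (scan_rate, peak_current) pairs")
    if len(pts) < 3:
        raise InvalidInputError(f"need >= 3 points, got {len(pts)}")
    v = pts[:, 0]
    ip = pts[:, 1]
    if np.any(v <= 0):
        raise InvalidInputError("scan rates must be positive")
    if len(np.unique(v)) != len(v):
        raise InvalidInputError("scan rates must be distinct")

    x = np.sqrt(v)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, ip, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise FitError(
            f"fitted slope {slope:.3e} A*(V/s)^-0.5 is non-positive; "
            "peak currents must grow with scan rate for a diffusive transfer"
        )
    resid = ip - design @ coef
    ssr = float(resid @ resid)
    sst = float(np.sum((ip - ip.mean()) ** 2))
    r_squared = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    dof = max(len(pts) - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = math.sqrt(ssr / dof / sxx) if sxx > 0 else math.nan

    c = conditions
    k = RANDLES_SEVCIK_FACTOR * z * c.faraday * area * concentration
    diffusion = (slope / k) ** 2 * c.gas_constant * c.temperature / (z * c.faraday)
    return ScanRateFit(
        diffusion=diffusion,
        slope=slope,
        intercept=intercept,
        slope_stderr=slope_se,
        r_squared=r_squared,
        n_points=len(pts),
    )


def saito_current(
    radius: float,
    charge: int,
    diffusion: float,
    concentration: float,
    conditions: Conditions = Conditions(),
) -> float:
    """Steady-state limiting current I_ss = 4*z*F*D*C*r (A) at a microdisc."""
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    _require_positive(radius=radius, diffusion=diffusion, concentration=concentration)
    return 4.0 * abs(charge) * conditions.faraday * diffusion * concentration * radius


def saito_radius(
    steady_state_current: float,
    charge: int,
    diffusion: float,
    concentration: float,
    conditions: Conditions = Conditions(),
) -> float:
    """Interface radius (cm) from a measured steady-state current.

    Exact algebraic inverse of :func:`saito_current`:
    ``r = I_ss / (4*z*F*D*C)``.
    """
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    _require_positive(
        steady_state_current=steady_state_current,
        diffusion=diffusion,
        concentration=concentration,
    )
    return steady_state_current / (
        4.0 * abs(charge) * conditions.faraday * diffusion * concentration
    )
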