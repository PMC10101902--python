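"""Calibration, detection limits, standard addition, recovery and RSD.

Calibration lines are plain ordinary least squares of signal on
concentration.  The limit of detection follows the 3*sigma/a criterion with
``sigma`` the standard error of the fitted intercept and ``a`` the slope;
the limit of quantification uses 10*sigma/a.  Sensitivities may be
normalized by the electroactive area so macroscopic and microscopic cells
can be compared.

Standard addition quantifies an unknown by spiking known increments and
extrapolating the response line to its x-axis crossing; the dilution chain
(aliquot dilution factor, stock volume, molar mass) then converts the
measured-cell concentration into the mass of analyte in the original
sample, e.g. a pharmaceutical pill.  An optional volume correction accounts
for the growth of the droplet volume with each addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import (
    DegreesOfFreedomError,
    FitError,
    InvalidInputError,
    SingularDesignError,
)
from .transport import CellGeometry

__all__ = [
    "CalibrationResult",
    "StandardAdditionResult",
    "AdditionScheme",
    "fit_calibration",
    "normalize_sensitivity",
    "standard_addition",
    "recovery",
    "rsd",
]


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS of y on x; returns (slope, intercept, intercept_se, r_squared)."""
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    intercept, slope = fit.params
    intercept_se = float(fit.bse[0])
    resid = y - fit.fittedvalues
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else max(0.0, 1.0 - ssr / sst)
    if not math.isfinite(intercept_se):
        intercept_se = 0.0
    return float(slope), float(intercept), intercept_se, r2


@dataclass(frozen=True)
class CalibrationResult:
    """A fitted calibration line with its figures of merit.

    ``slope`` (A/M) doubles as the sensitivity; ``sigma_intercept`` is the
    standard error of the intercept; ``lod = 3*sigma/|slope|`` and
    ``loq = 10*sigma/|slope|`` are in the concentration unit of the input
    (M if concentrations were in M).
    """

    slope: float
    intercept: float
    sigma_intercept: float
    r_squared: float
    lod: float
    loq: float
    n_points: int
    normalized_sensitivity: float | None = None  # A/(M cm^2)

    @property
    def sensitivity(self) -> float:
        return self.slope


def fit_calibration(points, area: float | None = None) -> CalibrationResult:
    """Fit a calibration line and derive LOD/LOQ by the 3/10-sigma rules.

    Parameters
    ----------
    points:
        ``(concentration, signal)`` pairs, at least three distinct
        concentrations; any consistent unit pair works (M vs A, uM vs uA)
        and the LOD/LOQ inherit the concentration unit.
    area:
        Electroactive area in cm^2; when given the area-normalized
        sensitivity ``slope/area`` is reported as well.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (concentration, signal) pairs")
    if len(pts) < 3:
        raise DegreesOfFreedomError(f"need >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        if np.ptp(x) == 0.0:
            raise SingularDesignError("all concentrations identical: design is singular")
        raise DegreesOfFreedomError("need >= 3 distinct concentrations")

    slope, intercept, sigma, r2 = _ols_line(x, y)
    if slope == 0.0:
        raise FitError("zero calibration slope; LOD undefined")
    lod = 3.0 * sigma / abs(slope)
    loq = 10.0 * sigma / abs(slope)
    norm = None
    if area is not None:
        if not (area > 0):
            raise InvalidInputError(f"area must be positive, got {area!r}")
        norm = slope / area
    return CalibrationResult(
        slope=slope,
        intercept=intercept,
        sigma_intercept=sigma,
        r_squared=r2,
        lod=lod,
        loq=loq,
        n_points=len(pts),
        normalized_sensitivity=norm,
    )


def normalize_sensitivity(slope: float, geometry: CellGeometry) -> float:
    """Area-normalized sensitivity: slope / (pi * r^2), A M^-1 cm^-2.

    The geometry's radius is always caller-supplied; no nominal radius is
    ever substituted.
    """
    area = geometry.area
    if area <= 0:
        raise InvalidInputError("geometry area must be positive")
    return slope / area


@dataclass(frozen=True)
class AdditionScheme:
    """Volume accounting of a droplet-scale standard-addition series.

    Defaults mirror a micro-cell protocol: a 10 uL measured droplet and
    2.5 uL spikes of an 80 uM standard.
    """

    initial_volume: float = 10e-6  # L
    addition_volume: float = 2.5e-6  # L
    standard_concentration: float = 80e-6  # M

    def __post_init__(self) -> None:
        if self.initial_volume <= 0 or self.addition_volume <= 0:
            raise InvalidInputError("volumes must be positive")
        if self.standard_concentration <= 0:
            raise InvalidInputError("standard concentration must be positive")


@dataclass(frozen=True)
class StandardAdditionResult:
    """Outcome of a standard-addition quantification.

    ``x_intercept_concentration`` is the magnitude of the response line's
    x-axis crossing, i.e. the analyte concentration in the measured cell;
    ``content_mass`` back-calculates the analyte mass in the original
    sample through the dilution chain:

        mass = C_cell * dilution_factor * stock_volume * molar_mass.
    """

    slope: float
    intercept: float
    x_intercept_concentration: float
    dilution_factor: float
    stock_volume: float
    molar_mass: float
    content_mass: float
    r_squared: float
    volume_corrected: bool


def standard_addition(
    points,
    dilution_factor: float,
    stock_volume: float,
    molar_mass: float,
    volume_correction: bool = True,
    scheme: AdditionScheme | None = None,
) -> StandardAdditionResult:
    """Quantify an unknown from a standard-addition series.

    Parameters
    ----------
    points:
        ``(added_concentration_M, signal_A)`` pairs in measurement order;
        the first point must be the unspiked sample (added concentration 0)
        and at least three points are required.
    dilution_factor:
        Dilution applied between the stock solution and the measured cell
        (e.g. 50 for 20 uL made up to 1000 uL).
    stock_volume:
        Volume of the stock solution in litres (e.g. 0.025 for a pill
        dissolved in 25 mL).
    molar_mass:
        g/mol of the analyte; converts moles to mass.
    volume_correction:
        When True (default for new analyses) the added concentrations are
        recomputed per point from the addition volumes in ``scheme`` and
        the signals are scaled by the dilution of the droplet,
        ``y_k * (V0 + k*dV)/V0`` against ``x_k = C_std * k*dV / V0``, so the
        x-intercept refers to the original droplet.  Set False to take the
        supplied added concentrations at face value (e.g. when re-analysing
        a published fit).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (added_concentration, signal) pairs")
    if len(pts) < 3:
        raise DegreesOfFreedomError(f"need >= 3 points, got {len(pts)}")
    if pts[0, 0] != 0.0:
        raise InvalidInputError("first point must be the unspiked sample (added = 0)")
    for name, val in (
        ("dilution_factor", dilution_factor),
        ("stock_volume", stock_volume),
        ("molar_mass", molar_mass),
    ):
        if not (val > 0) or not math.isfinite(val):
            raise InvalidInputError(f"{name} must be positive, got {val!r}")

    y = pts[:, 1].copy()
    if volume_correction:
        sch = scheme if scheme is not None else AdditionScheme()
        k = np.arange(len(pts), dtype=float)
        total = sch.initial_volume + k * sch.addition_volume
        x = sch.standard_concentration * k * sch.addition_volume / sch.initial_volume
        y = y * total / sch.initial_volume
    else:
        x = pts[:, 0]

    slope, intercept, _sigma, r2 = _ols_line(x, y)
    if slope <= 0:
        raise FitError(f"non-positive standard-addition slope {slope:.3e}")
    x_intercept = abs(intercept / slope)
    content = x_intercept * dilution_factor * stock_volume * molar_mass
    return StandardAdditionResult(
        slope=slope,
        intercept=intercept,
        x_intercept_concentration=x_intercept,
        dilution_factor=dilution_factor,
        stock_volume=stock_volume,
        molar_mass=molar_mass,
        content_mass=content,
        r_squared=r2,
        volume_corrected=bool(volume_correction),
    )


def recovery(added: float, found: float) -> float:
    """Recovery in percent: 100 * found / added."""
    if not (added > 0) or not math.isfinite(added):
        raise InvalidInputError(f"added concentration must be positive, got {added!r}")
    return 100.0 * found / added


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need >= 2 values for an RSD")
    mean = float(arr.mean())
    if mean == 0.0:
        raise InvalidInputError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)
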