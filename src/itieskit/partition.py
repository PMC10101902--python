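"""Ion-partition diagrams, distribution-constant fitting and logP.

At an electrified liquid-liquid interface the apparent (formal) transfer
potential of a protonatable cation moves with pH: at low pH the drug
transfers as the simple cation at its own formal potential, while above the
relevant pKa the signal is carried by facilitated proton transfer to the
neutral base partitioned into the organic phase.  The boundary line of the
ion-partition diagram captures both regimes in one expression,

    dphi(pH) = dphi' + (R*T/F) * ln(1 + 10**(pH - pKa) * (1 + KD)),

where ``dphi'`` is the formal transfer potential of the protonated form and
``KD`` is the distribution constant of the neutral form between the organic
and aqueous solvents (org/aq: larger KD = more lipophilic neutral form; the
convention is documented because the verbal definitions in the literature
are not always consistent with the fitted magnitudes).

The formal potential itself carries the partition coefficient of the ion:

    logP = -dphi' * z * F / (ln(10) * R * T).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .conditions import LN10, Conditions
from .errors import DegreesOfFreedomError, FitError, InvalidInputError

__all__ = [
    "IonPartitionModel",
    "Mechanism",
    "PartitionFit",
    "boundary_potential",
    "fit_partition_model",
    "logp_from_potential",
    "potential_from_logp",
    "mechanism_at",
]


class Mechanism(enum.Enum):
    """Charge-transfer regime of a point on the partition diagram."""

    SIMPLE_ION_TRANSFER = "simple_ion_transfer"
    FACILITATED_PROTON_TRANSFER = "facilitated_proton_transfer"


@dataclass(frozen=True)
class IonPartitionModel:
    """Boundary-line model of one cation/neutral pair.

    Parameters
    ----------
    formal_potential:
        Formal Galvani transfer potential of the protonated ion
        (aqueous -> organic), volts.
    pka:
        The deprotonation step linking the transferring cation to its
        neutral conjugate base (``Ka = 10**-pka``).
    kd:
        Distribution constant of the neutral form, org/aq convention,
        dimensionless, >= 0.
    charge:
        Charge of the transferring ion; nonzero.
    conditions:
        Temperature and constants for the Nernstian factor.
    """

    formal_potential: float
    pka: float
    kd: float
    charge: int = 1
    conditions: Conditions = Conditions()

    def __post_init__(self) -> None:
        if not math.isfinite(self.formal_potential):
            raise InvalidInputError("formal_potential must be finite")
        if not math.isfinite(self.pka):
            raise InvalidInputError("pka must be finite")
        if not (self.kd >= 0.0):
            raise InvalidInputError(f"kd must be >= 0, got {self.kd!r}")
        if self.charge == 0:
            raise InvalidInputError("charge must be nonzero")


def boundary_potential(model: IonPartitionModel, ph) -> float | np.ndarray:
    """Boundary line of the ion-partition diagram at ``ph`` (volts).

    Flat at ``formal_potential`` for pH well below the pKa (simple ion
    transfer) and rising with the Nernstian slope ln(10)RT/F per pH unit in
    the facilitated-proton-transfer regime.  Monotone non-decreasing in both
    ``ph`` and ``kd``.  Accepts scalars or arrays.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise InvalidInputError("ph must be finite")
    # ln(1 + 10**(ph-pka)*(1+kd)) via logaddexp for overflow safety
    ln_term = np.logaddexp(0.0, LN10 * (ph - model.pka) + math.log1p(model.kd))
    out = model.formal_potential + model.conditions.thermal_voltage * ln_term
    return float(out) if out.ndim == 0 else out


def mechanism_at(model: IonPartitionModel, ph: float) -> Mechanism:
    """Dominant charge-transfer regime at ``ph``.

    The crossover sits where the rising term of the boundary line reaches
    the plateau term, i.e. where ``10**(ph-pka) * (1+kd) = 1``; the tie is
    broken toward facilitated transfer.
    """
    if not math.isfinite(ph):
        raise InvalidInputError("ph must be finite")
    rising = 10.0 ** (ph - model.pka) * (1.0 + model.kd)
    if rising < 1.0:
        return Mechanism.SIMPLE_ION_TRANSFER
    return Mechanism.FACILITATED_PROTON_TRANSFER


def logp_from_potential(
    formal_potential: float, charge: int, conditions: Conditions = Conditions()
) -> float:
    """Partition coefficient (log10) of an ion from its formal transfer potential.

    ``logP = -dphi' * z * F / (ln(10) * R * T)``.  A positive transfer
    potential for a cation means work is needed to push it into the organic
    phase, i.e. a negative logP.
    """
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    if not math.isfinite(formal_potential):
        raise InvalidInputError("formal_potential must be finite")
    c = conditions
    return -formal_potential * charge * c.faraday / (LN10 * c.gas_constant * c.temperature)


def potential_from_logp(
    logp: float, charge: int, conditions: Conditions = Conditions()
) -> float:
    """Algebraic inverse of :func:`logp_from_potential` (volts)."""
    if charge == 0:
        raise InvalidInputError("charge must be nonzero")
    c = conditions
    return -logp * LN10 * c.gas_constant * c.temperature / (charge * c.faraday)


@dataclass(frozen=True)
class PartitionFit:
    """An :class:`IonPartitionModel` recovered from (pH, potential) data."""

    model: IonPartitionModel
    kd_stderr: float
    formal_potential_stderr: float
    residual_norm: float
    n_points: int

    @property
    def kd(self) -> float:
        return self.model.kd

    @property
    def formal_potential(self) -> float:
        return self.model.formal_potential


def fit_partition_model(
    points,
    pka: float,
    charge: int = 1,
    conditions: Conditions = Conditions(),
    fit_formal_potential: bool = True,
    formal_potential: float | None = None,
) -> PartitionFit:
    """Least-squares fit of the boundary line to (pH, potential) data.

    Parameters
    ----------
    points:
        Sequence of ``(ph, observed_potential_volts)`` pairs; at least three.
    pka:
        Known deprotonation exponent of the transferring cation (held fixed).
    charge:
        Ion charge (held fixed).
    fit_formal_potential:
        If True (default) the plateau potential is a second free parameter,
        initialised from the mean of the points with ``ph <= pka - 1`` (the
        flat simple-transfer region); at least one point with ``ph < pka``
        is then required to pin the plateau.  If False, ``formal_potential``
        must be supplied and only KD is fitted.

    Notes
    -----
    KD is optimised on a log10 scale, which enforces positivity and makes
    the step size scale-free across the decades of plausible KD values.
    Standard errors come from the Gauss-Newton covariance
    ``(J^T J)^-1 * SSR/(n-p)`` and are propagated back to the linear KD
    scale; on noiseless data they are ~0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (ph, potential) pairs")
    ph = pts[:, 0]
    obs = pts[:, 1]
    n_free = 2 if fit_formal_potential else 1
    if len(pts) < 3:
        raise DegreesOfFreedomError(f"need >= 3 points, got {len(pts)}")
    if len(pts) <= n_free:
        raise DegreesOfFreedomError(
            f"{len(pts)} points cannot constrain {n_free} free parameters"
        )

    if fit_formal_potential:
        plateau = obs[ph <= pka - 1.0]
        if not np.any(ph < pka):
            raise InvalidInputError(
                "fitting the formal potential requires at least one point "
                "with ph < pka to pin the plateau"
            )
        phi0 = float(plateau.mean()) if plateau.size else float(obs[np.argmin(ph)])
    else:
        if formal_potential is None:
            raise InvalidInputError(
                "formal_potential must be given when fit_formal_potential=False"
            )
        phi0 = float(formal_potential)

    rt_f = conditions.thermal_voltage

    def predict(log10_kd: float, phi: float) -> np.ndarray:
        ln_term = np.logaddexp(
            0.0, LN10 * (ph - pka) + np.log1p(10.0 ** log10_kd)
        )
        return phi + rt_f * ln_term

    if fit_formal_potential:
        def residuals(theta):
            return predict(theta[0], theta[1]) - obs
        x0 = np.array([0.0, phi0])
    else:
        def residuals(theta):
            return predict(theta[0], phi0) - obs
        x0 = np.array([0.0])

    result = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not result.success:
        raise FitError(f"partition fit did not converge: {result.message}")

    log10_kd = float(result.x[0])
    phi_hat = float(result.x[1]) if fit_formal_potential else phi0
    kd_hat = 10.0 ** log10_kd

    # Gauss-Newton covariance; guard the rank-deficient / zero-residual cases.
    dof = max(len(pts) - n_free, 1)
    ssr = float(np.sum(result.fun ** 2))
    jac = result.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * ssr / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_free, np.nan)
    kd_se = float(se[0]) * LN10 * kd_hat  # delta method: d(kd)/d(log10 kd)
    phi_se = float(se[1]) if fit_formal_potential else 0.0

    model = IonPartitionModel(
        formal_potential=phi_hat,
        pka=pka,
        kd=kd_hat,
        charge=charge,
        conditions=conditions,
    )
    return PartitionFit(
        model=model,
        kd_stderr=kd_se,
        formal_potential_stderr=phi_se,
        residual_norm=math.sqrt(ssr),
        n_points=len(pts),
    )
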