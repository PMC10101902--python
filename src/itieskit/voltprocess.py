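"""Voltammogram signal processing.

Everything downstream of the potentiostat (or of the synthetic generator)
lives here: splitting a triangular potential program into forward and
backward sweeps, straight-line baseline correction, peak and steady-state
wave extraction, re-anchoring the potential axis on an internal reference
ion, measuring the usable potential window of a blank, and the qualitative
"is the analyte there" call used for complex matrices.

Conventions: potentials in volts, currents in amperes; the forward sweep is
whichever segment comes first in time.  A positive peak is a cation moving
from the aqueous to the organic phase, the negative return peak is the back
transfer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    AlignmentError,
    InvalidInputError,
    NoPeakError,
    NotAPlateauError,
    SegmentationError,
)

__all__ = [
    "Voltammogram",
    "Sweep",
    "PeakMeasurement",
    "WaveMeasurement",
    "segment_sweeps",
    "extract_peaks",
    "extract_wave",
    "reference_correct",
    "potential_window_width",
    "detect_analyte",
    "estimate_noise_sd",
    "smooth_current",
]

MIN_SAMPLES = 16


@dataclass(frozen=True)
class Voltammogram:
    """A potential/current series with acquisition metadata.

    ``potential`` (V) must follow a piecewise-monotone (triangular) program;
    ``current`` (A) has the same length; ``metadata`` carries free-form keys
    such as ``ph``, ``analyte``, ``concentration_uM``, ``cell`` and the
    generator parameters when the trace is synthetic.
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float  # V/s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pot = np.asarray(self.potential, dtype=float)
        cur = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "potential", pot)
        object.__setattr__(self, "current", cur)
        if pot.ndim != 1 or cur.ndim != 1:
            raise InvalidInputError("potential and current must be 1-D series")
        if pot.size != cur.size:
            raise InvalidInputError(
                f"length mismatch: {pot.size} potentials vs {cur.size} currents"
            )
        if pot.size < MIN_SAMPLES:
            raise InvalidInputError(
                f"need at least {MIN_SAMPLES} samples, got {pot.size}"
            )
        if not (np.all(np.isfinite(pot)) and np.all(np.isfinite(cur))):
            raise InvalidInputError("potential and current must be finite")
        if not (self.scan_rate > 0) or not math.isfinite(self.scan_rate):
            raise InvalidInputError(f"scan_rate must be positive, got {self.scan_rate!r}")

    def __len__(self) -> int:
        return int(self.potential.size)


@dataclass(frozen=True)
class Sweep:
    """One monotone branch of a voltammogram."""

    potential: np.ndarray
    current: np.ndarray

    @property
    def direction(self) -> int:
        return 1 if self.potential[-1] >= self.potential[0] else -1


@dataclass(frozen=True)
class PeakMeasurement:
    """Baseline-corrected forward/backward peak pair."""

    forward_peak_potential: float
    forward_peak_current: float  # > 0
    backward_peak_potential: float
    backward_peak_current: float  # < 0
    baseline_method: str

    def __post_init__(self) -> None:
        if not (self.forward_peak_current > 0 > self.backward_peak_current):
            raise InvalidInputError(
                "expected forward peak > 0 > backward peak, got "
                f"{self.forward_peak_current!r} / {self.backward_peak_current!r}"
            )

    @property
    def midpoint_potential(self) -> float:
        """Mean of the two peak potentials; the formal-potential estimator."""
        return 0.5 * (self.forward_peak_potential + self.backward_peak_potential)

    @property
    def peak_separation(self) -> float:
        return self.forward_peak_potential - self.backward_peak_potential


@dataclass(frozen=True)
class WaveMeasurement:
    """Steady-state wave extracted from a micro-interface forward sweep."""

    steady_state_current: float  # > 0
    half_wave_potential: float

    def __post_init__(self) -> None:
        if not (self.steady_state_current > 0):
            raise InvalidInputError("steady_state_current must be positive")


def segment_sweeps(v: Voltammogram) -> tuple[Sweep, Sweep]:
    """Split a triangular scan into its forward and backward branches.

    The split point is the first potential extremum.  If the program holds
    more than one cycle, only the first is used and a warning is emitted.
    A monotone-only (or constant) potential series cannot be segmented.
    """
    pot = v.potential
    dp = np.diff(pot)
    signs = np.sign(dp)
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        raise SegmentationError("constant potential series cannot be segmented")
    # indices (into dp) where the sweep direction flips
    direction = np.where(signs == 0, np.nan, signs)
    # forward-fill zero steps with the previous direction
    filled = direction.copy()
    for i in range(1, filled.size):
        if np.isnan(filled[i]):
            filled[i] = filled[i - 1]
    # leading zeros take the first real direction
    first = nonzero[0]
    filled = np.where(np.isnan(filled), first, filled)
    turns = np.nonzero(filled[1:] != filled[:-1])[0] + 1  # dp index of new direction
    if turns.size == 0:
        raise SegmentationError("monotone potential series has no turning point")
    vertex = int(turns[0])  # last sample of the forward sweep is pot[vertex]
    end = len(pot)
    if turns.size > 1:
        end = int(turns[1]) + 1
        warnings.warn(
            "potential program holds multiple cycles; using the first cycle only",
            stacklevel=2,
        )
    fwd = Sweep(pot[: vertex + 1].copy(), v.current[: vertex + 1].copy())
    bwd = Sweep(pot[vertex + 1 : end].copy(), v.current[vertex + 1 : end].copy())
    if len(bwd.potential) == 0:
        raise SegmentationError("backward sweep is empty")
    return fwd, bwd


def estimate_noise_sd(values: np.ndarray, detrend: bool = True) -> float:
    """Robust noise SD: 1.4826 * median absolute deviation.

    A straight line is removed first so a sloping background does not
    inflate the estimate.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise InvalidInputError("need >= 3 samples for a noise estimate")
    if detrend:
        x = np.arange(y.size, dtype=float)
        coef = np.polyfit(x, y, 1)
        y = y - np.polyval(coef, x)
    mad = np.median(np.abs(y - np.median(y)))
    return float(1.4826 * mad)


def smooth_current(current: np.ndarray, window: int = 5) -> np.ndarray:
    """Adjacent-averaging (moving mean) smoother; edges use shorter windows."""
    if window < 1 or window % 2 == 0:
        raise InvalidInputError("window must be a positive odd integer")
    y = np.asarray(current, dtype=float)
    kernel = np.ones(window) / window
    padded = np.pad(y, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _baseline_correct(sweep: Sweep, window: tuple[float, float], method: str):
    """Fit a pre-window straight line and return the corrected current.

    The baseline is an ordinary least-squares line over the 30% of the
    sweep samples immediately preceding the search window (in sweep
    direction).  Returns (corrected_current, in_window_mask, noise_sd).
    """
    lo, hi = min(window), max(window)
    pot, cur = sweep.potential, sweep.current
    in_window = (pot >= lo) & (pot <= hi)
    if not np.any(in_window):
        raise InvalidInputError(
            f"search window [{lo}, {hi}] V lies outside the scanned range "
            f"[{pot.min():.3f}, {pot.max():.3f}] V"
        )
    if method == "none":
        corrected = cur.copy()
        pre = cur[: max(3, int(0.3 * len(cur)))]
        return corrected, in_window, estimate_noise_sd(pre)
    if method != "linear_pre_peak":
        raise InvalidInputError(f"unknown baseline method {method!r}")

    first_idx = int(np.argmax(in_window))
    n_pre = int(0.3 * len(pot))
    start = max(0, first_idx - n_pre)
    if first_idx - start < 3:
        # window starts at the very beginning of the sweep: fall back to the
        # leading 30% of the sweep itself
        start, first_idx = 0, max(3, n_pre)
    x = pot[start:first_idx]
    y = cur[start:first_idx]
    coef = np.polyfit(x, y, 1)
    corrected = cur - np.polyval(coef, pot)
    noise = estimate_noise_sd(y - np.polyval(coef, x), detrend=False)
    return corrected, in_window, noise


def extract_peaks(
    v: Voltammogram,
    search_window: tuple[float, float],
    baseline: str = "linear_pre_peak",
) -> PeakMeasurement:
    """Locate the forward (positive) and backward (negative) peak pair.

    Each sweep is baseline-corrected with a straight line fitted to the 30%
    of the sweep preceding the window, then the forward maximum and
    backward minimum inside ``search_window`` are taken.  If either
    extremum fails to exceed three times the local noise SD a
    :class:`~itieskit.errors.NoPeakError` is raised - this is the negative
    pathway of the qualitative presence call.
    """
    fwd, bwd = segment_sweeps(v)
    # the backward sweep runs the window in the opposite direction; flip it so
    # "preceding the window" is correct for the baseline fit
    bwd_flipped = Sweep(bwd.potential, bwd.current)

    f_corr, f_mask, f_noise = _baseline_correct(fwd, search_window, baseline)
    b_corr, b_mask, b_noise = _baseline_correct(bwd_flipped, search_window, baseline)

    f_idx_candidates = np.nonzero(f_mask)[0]
    f_rel = np.argmax(f_corr[f_mask])
    f_idx = int(f_idx_candidates[f_rel])
    f_peak = float(f_corr[f_idx])

    b_idx_candidates = np.nonzero(b_mask)[0]
    b_rel = np.argmin(b_corr[b_mask])
    b_idx = int(b_idx_candidates[b_rel])
    b_peak = float(b_corr[b_idx])

    floor = 3.0 * max(f_noise, 1e-30)
    if f_peak < floor or -b_peak < 3.0 * max(b_noise, 1e-30):
        raise NoPeakError(
            f"no peak pair above 3x noise (forward {f_peak:.3e} A vs floor "
            f"{floor:.3e} A; backward {b_peak:.3e} A)"
        )
    return PeakMeasurement(
        forward_peak_potential=float(fwd.potential[f_idx]),
        forward_peak_current=f_peak,
        backward_peak_potential=float(bwd.potential[b_idx]),
        backward_peak_current=b_peak,
        baseline_method=baseline,
    )


def extract_wave(
    v: Voltammogram, plateau_window: tuple[float, float]
) -> WaveMeasurement:
    """Steady-state current and half-wave potential of a micro-interface wave.

    The forward sweep is baseline-corrected against its leading 30% (the
    pre-wave foot), the steady-state current is the mean corrected current
    over ``plateau_window``, and the half-wave potential is where the
    corrected current first crosses half of it (linear interpolation).
    The window must be flat: a slope above 10% of I_ss per 100 mV raises
    :class:`~itieskit.errors.NotAPlateauError`.
    """
    fwd, _ = segment_sweeps(v)
    lo, hi = min(plateau_window), max(plateau_window)
    pot, cur = fwd.potential, fwd.current
    mask = (pot >= lo) & (pot <= hi)
    if int(mask.sum()) < 3:
        raise InvalidInputError(
            f"plateau window [{lo}, {hi}] V covers {int(mask.sum())} samples; need >= 3"
        )

    n_foot = max(3, int(0.3 * len(pot)))
    foot_x, foot_y = pot[:n_foot], cur[:n_foot]
    coef = np.polyfit(foot_x, foot_y, 1)
    corrected = cur - np.polyval(coef, pot)
    noise = estimate_noise_sd(foot_y - np.polyval(coef, foot_x), detrend=False)

    i_ss = float(np.mean(corrected[mask]))
    if i_ss <= 3.0 * max(noise, 1e-30):
        raise NotAPlateauError(
            f"mean window current {i_ss:.3e} A does not rise above the noise"
        )
    slope = float(np.polyfit(pot[mask], corrected[mask], 1)[0])  # A/V
    if abs(slope) * 0.1 > 0.10 * i_ss:
        raise NotAPlateauError(
            f"window slope {slope:.3e} A/V exceeds 10% of I_ss per 100 mV"
        )

    half = 0.5 * i_ss
    above = corrected >= half
    cross = np.nonzero(above[1:] & ~above[:-1])[0]
    if cross.size == 0:
        idx = int(np.argmax(above)) if above.any() else 0
        half_pot = float(pot[idx])
    else:
        i = int(cross[0])
        y0, y1 = corrected[i], corrected[i + 1]
        frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.0
        half_pot = float(pot[i] + frac * (pot[i + 1] - pot[i]))
    return WaveMeasurement(steady_state_current=i_ss, half_wave_potential=half_pot)


def reference_correct(
    v: Voltammogram,
    reference_midpoint_measured: float,
    reference_formal_potential: float,
) -> Voltammogram:
    """Re-anchor the potential axis on an internal reference ion.

    The whole potential series is shifted by
    ``reference_formal_potential - reference_midpoint_measured`` so the
    measured midpoint of the reference ion (e.g. TMA+ or TPrA+) lands on
    its assigned formal transfer potential.  Currents are untouched.
    """
    for name, val in (
        ("reference_midpoint_measured", reference_midpoint_measured),
        ("reference_formal_potential", reference_formal_potential),
    ):
        if not math.isfinite(val):
            raise InvalidInputError(f"{name} must be finite")
    shift = reference_formal_potential - reference_midpoint_measured
    meta = dict(v.metadata)
    meta["reference_shift_V"] = meta.get("reference_shift_V", 0.0) + shift
    return replace(v, potential=v.potential + shift, metadata=meta)


def potential_window_width(
    blank: Voltammogram, current_threshold: float
) -> float:
    """Width (V) of the widest usable potential window of a blank trace.

    The usable window is the largest contiguous interval of the forward
    sweep where ``|current| < current_threshold``; the exponential walls of
    the supporting electrolytes close it on both sides.  The threshold must
    exceed the blank's own noise level to be meaningful.
    """
    fwd, _ = segment_sweeps(blank)
    # first-difference MAD: insensitive to the smooth walls and offset
    noise = estimate_noise_sd(np.diff(fwd.current), detrend=False) / math.sqrt(2.0)
    if not (current_threshold > noise):
        raise InvalidInputError(
            f"threshold {current_threshold:.3e} A must exceed the blank noise "
            f"SD {noise:.3e} A"
        )
    quiet = np.abs(fwd.current) < current_threshold
    if not quiet.any():
        warnings.warn("no sample below the threshold; window width is zero", stacklevel=2)
        return 0.0
    # longest run of True
    best_lo = best_hi = -1
    run_lo = None
    for i, q in enumerate(quiet):
        if q and run_lo is None:
            run_lo = i
        if (not q or i == len(quiet) - 1) and run_lo is not None:
            run_hi = i if q else i - 1
            if best_lo < 0 or run_hi - run_lo > best_hi - best_lo:
                best_lo, best_hi = run_lo, run_hi
            run_lo = None
    return float(abs(fwd.potential[best_hi] - fwd.potential[best_lo]))


def detect_analyte(
    sample: Voltammogram,
    blank: Voltammogram,
    expected_potential: float,
    tolerance: float,
) -> int:
    """Qualitative presence call: 1 if a signal stands out of the blank.

    The blank's forward sweep is resampled onto the sample's potential grid,
    subtracted, and the maximum blank-subtracted current within
    ``expected_potential +/- tolerance`` is compared against three times the
    blank's local noise SD.  This is a screening heuristic (the 3-sigma rule
    applied pointwise), not a validated classifier.
    """
    if not (tolerance > 0):
        raise InvalidInputError("tolerance must be positive")
    s_fwd, _ = segment_sweeps(sample)
    b_fwd, _ = segment_sweeps(blank)

    s_lo, s_hi = float(np.min(s_fwd.potential)), float(np.max(s_fwd.potential))
    b_lo, b_hi = float(np.min(b_fwd.potential)), float(np.max(b_fwd.potential))
    if s_hi < b_lo or b_hi < s_lo:
        raise AlignmentError("sample and blank potential ranges do not overlap")

    order = np.argsort(b_fwd.potential)
    blank_on_sample = np.interp(
        s_fwd.potential, b_fwd.potential[order], b_fwd.current[order]
    )
    diff = s_fwd.current - blank_on_sample

    window = (s_fwd.potential >= expected_potential - tolerance) & (
        s_fwd.potential <= expected_potential + tolerance
    )
    if not window.any():
        raise AlignmentError(
            f"expected potential {expected_potential:.3f} +/- {tolerance:.3f} V "
            "is outside the sample's scanned range"
        )

    # local noise: first-difference MAD of the blank near (but outside) the
    # expected window -- insensitive to the smooth wall/capacitive background
    near = (np.abs(b_fwd.potential - expected_potential) <= 5 * tolerance) & (
        np.abs(b_fwd.potential - expected_potential) > tolerance
    )
    region = b_fwd.current[near] if int(near.sum()) >= 8 else b_fwd.current
    noise = estimate_noise_sd(np.diff(region), detrend=False) / math.sqrt(2.0)

    return int(np.max(diff[window]) > 3.0 * max(noise, 1e-30))
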