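"""Generic model of a biochemical measurement process.

An assay reads out a signal, maps it to a concentration through a linear
calibration curve, and is only trusted where its relative imprecision — the
coefficient of variation (CV), the SD of replicate signals over their mean —
stays below an acceptance cutoff (commonly 10% or 20%). The concentrations
where the CV curve crosses that cutoff are the lower and upper limits of
quantification (LLOQ/ULOQ). Values measured below a lower cutoff LC are
reported as below-cutoff (BC, non-detectable) and values above an upper
cutoff UC as above-cutoff (AC, outlying); only their censoring status is
retained, not a number.

This module simulates that pipeline: calibration fitting, a parametric CV
precision profile, LLOQ/ULOQ derivation, multiplicative measurement noise,
and cutoff censoring into :class:`CensoredDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    NoOperationalRangeError,
)

__all__ = [
    "CalibratorSet",
    "CalibrationCurve",
    "PrecisionProfile",
    "MeasurementRange",
    "CensoredDataset",
    "DEFAULT_PROFILE",
    "compute_cv",
    "fit_calibration_curve",
    "fit_precision_profile",
    "derive_loqs",
    "sd_rule_cutoff",
    "measure",
    "censor",
]


@dataclass(frozen=True)
class CalibratorSet:
    """Replicate signal readings of calibrators with known concentrations.

    Parameters
    ----------
    concentrations
        Known calibrator concentrations, strictly increasing, all > 0.
    signals
        One sequence of replicate signal readings per concentration;
        at least two replicates each (an SD must be computable).
    """

    concentrations: tuple[float, ...]
    signals: tuple[tuple[float, ...], ...]

    def __init__(self, concentrations: Sequence[float], signals: Sequence[Sequence[float]]):
        conc = tuple(float(c) for c in concentrations)
        sig = tuple(tuple(float(s) for s in row) for row in signals)
        if len(conc) < 2:
            raise InsufficientDataError("need at least 2 calibrator concentrations")
        if any(c <= 0 for c in conc):
            raise DomainError("calibrator concentrations must be > 0")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ConfigurationError("calibrator concentrations must be strictly increasing")
        if len(sig) != len(conc):
            raise ConfigurationError("one replicate group per concentration required")
        if any(len(row) < 2 for row in sig):
            raise InsufficientDataError("each calibrator needs >= 2 replicate signals")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signals", sig)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal = intercept + slope * concentration map; slope > 0."""

    intercept: float
    slope: float

    def __post_init__(self):
        if not self.slope > 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")

    def to_concentration(self, signal: float) -> float:
        """Invert the curve: concentration implied by a signal reading."""
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class PrecisionProfile:
    """Parametric CV-versus-concentration curve.

    CV(x) = cv_base + k_low / x + k_high * x.

    The hyperbolic term dominates at low concentrations (signal close to
    background noise) and the linear term at high concentrations (detector
    saturation), giving the characteristic U shape with a floor of
    ``cv_base``. ``cv_cutoff`` is the largest CV accepted as quantifiable.
    """

    cv_base: float = 0.0
    k_low: float = 0.0
    k_high: float = 0.0
    cv_cutoff: float = 0.10

    def __post_init__(self):
        if self.cv_base < 0 or self.k_low < 0 or self.k_high < 0:
            raise DomainError("cv_base, k_low and k_high must be >= 0")
        if not 0 < self.cv_cutoff < 1:
            raise DomainError("cv_cutoff must lie in (0, 1)")

    def cv(self, x):
        """CV at concentration(s) ``x`` (> 0)."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise DomainError("CV is defined for concentrations > 0 only")
        return self.cv_base + self.k_low / x + self.k_high * x


#: Noise profile used by the shipped simulation configurations: a 4% CV
#: floor with mild inflation toward both ends of the working range
#: (CV roughly 5-10% near typical cutoffs), accepted up to 10%.
DEFAULT_PROFILE = PrecisionProfile(cv_base=0.04, k_low=1.0, k_high=0.0002, cv_cutoff=0.10)


@dataclass(frozen=True)
class MeasurementRange:
    """Assay measurement range and the derived quantification limits.

    ``range_min``/``range_max`` bound what the instrument reports at all;
    ``lloq``/``uloq`` bound what it reports *reliably*. Degenerate cases
    with ``lloq == range_min`` and/or ``uloq == range_max`` mean no finite
    limit exists on that side (the whole range is acceptably precise).
    """

    range_min: float
    range_max: float
    lloq: float = None  # type: ignore[assignment]
    uloq: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.lloq is None:
            object.__setattr__(self, "lloq", self.range_min)
        if self.uloq is None:
            object.__setattr__(self, "uloq", self.range_max)
        if self.range_min < 0:
            raise DomainError("range_min must be >= 0")
        if not self.range_min < self.range_max:
            raise ConfigurationError("range_min must be < range_max")
        ok = self.range_min <= self.lloq < self.uloq <= self.range_max
        if not ok:
            raise ConfigurationError(
                "limits must satisfy range_min <= lloq < uloq <= range_max"
            )

    @property
    def no_finite_limits(self) -> bool:
        """True when neither quantification limit is interior to the range."""
        return self.lloq == self.range_min and self.uloq == self.range_max


@dataclass(frozen=True)
class CensoredDataset:
    """A univariate sample after cutoff censoring.

    Records measured inside ``[lc, uc]`` keep their value (``observed``);
    records measured strictly below ``lc`` or strictly above ``uc`` are
    reduced to the counts ``n_bc``/``n_ac`` — censoring discards the number,
    not the record. ``true_values`` holds the full generating sample and is
    populated only in simulation mode, where the truth is known.
    """

    observed: np.ndarray
    n_bc: int
    n_ac: int
    lc: float
    uc: float
    true_values: np.ndarray | None = None

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "observed", obs)
        if not self.lc < self.uc:
            raise ConfigurationError(f"lc ({self.lc}) must be < uc ({self.uc})")
        if self.n_bc < 0 or self.n_ac < 0:
            raise DomainError("censored counts must be >= 0")
        if obs.size and (obs.min() < self.lc or obs.max() > self.uc):
            raise DomainError("observed values must lie within [lc, uc]")
        if self.true_values is not None:
            tv = np.asarray(self.true_values, dtype=float)
            object.__setattr__(self, "true_values", tv)
            if tv.size != self.n:
                raise ConfigurationError("true_values must have length n_obs + n_bc + n_ac")

    @property
    def n_obs(self) -> int:
        return int(self.observed.size)

    @property
    def n(self) -> int:
        """Total record count including censored records."""
        return self.n_obs + self.n_bc + self.n_ac


def compute_cv(signals: Sequence[float]) -> float:
    """Coefficient of variation of replicate signals: sample SD / mean.

    Raises
    ------
    InsufficientDataError
        Fewer than two replicates (no SD can be formed).
    DomainError
        Nonpositive mean signal.
    """
    arr = np.asarray(signals, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("CV needs at least 2 replicate signals")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError("CV undefined for nonpositive mean signal")
    return float(arr.std(ddof=1) / mean)


def fit_calibration_curve(cal: CalibratorSet) -> CalibrationCurve:
    """Least-squares line of mean replicate signal on concentration.

    Raises :class:`CalibrationError` if the fitted slope is not positive
    (signal must increase with concentration for the curve to be invertible).
    """
    x = np.asarray(cal.concentrations, dtype=float)
    y = np.array([np.mean(row) for row in cal.signals])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError(f"fitted calibration slope {slope:.4g} is not positive")
    return CalibrationCurve(intercept=float(intercept), slope=float(slope))


def fit_precision_profile(cal: CalibratorSet, cv_cutoff: float = 0.10) -> PrecisionProfile:
    """Fit the parametric CV curve to per-calibrator empirical CVs.

    Nonnegative least squares on the basis (1, 1/x, x) keeps all three
    profile coefficients in their valid domain.
    """
    x = np.asarray(cal.concentrations, dtype=float)
    cvs = np.array([compute_cv(row) for row in cal.signals])
    basis = np.column_stack([np.ones_like(x), 1.0 / x, x])
    coef, _ = optimize.nnls(basis, cvs)
    return PrecisionProfile(
        cv_base=float(coef[0]), k_low=float(coef[1]), k_high=float(coef[2]),
        cv_cutoff=cv_cutoff,
    )


def derive_loqs(profile: PrecisionProfile, rng: MeasurementRange) -> MeasurementRange:
    """Locate the LLOQ and ULOQ on a measurement range.

    The LLOQ is the smallest and the ULOQ the largest concentration in
    ``[range_min, range_max]`` whose CV does not exceed ``profile.cv_cutoff``;
    crossings are found by bisection to relative tolerance 1e-9. When the CV
    stays below the cutoff over the whole range the returned limits collapse
    onto the range bounds (``no_finite_limits`` is then true).

    Raises
    ------
    NoOperationalRangeError
        ``cv_cutoff <= cv_base`` (no concentration can qualify) or the CV
        exceeds the cutoff everywhere on the range.
    """
    if profile.cv_cutoff <= profile.cv_base:
        raise NoOperationalRangeError(
            f"cv_cutoff {profile.cv_cutoff} does not exceed cv_base {profile.cv_base}"
        )
    lo = max(rng.range_min, 1e-12 * max(rng.range_max, 1.0))
    hi = rng.range_max

    def excess(x):
        return float(profile.cv(x) - profile.cv_cutoff)

    # Concentration of minimal CV: interior stationary point when the curve
    # is genuinely U-shaped, else the favourable endpoint.
    if profile.k_low > 0 and profile.k_high > 0:
        x_best = float(np.clip(np.sqrt(profile.k_low / profile.k_high), lo, hi))
    elif profile.k_low > 0:
        x_best = hi
    else:
        x_best = lo
    if excess(x_best) > 0:
        raise NoOperationalRangeError(
            "CV exceeds the cutoff over the entire measurement range"
        )

    xtol = 1e-9 * max(abs(hi), 1.0)
    if excess(lo) <= 0:
        lloq = rng.range_min
    else:
        lloq = float(optimize.brentq(excess, lo, x_best, xtol=xtol, rtol=1e-12))
    if excess(hi) <= 0:
        uloq = rng.range_max
    else:
        uloq = float(optimize.brentq(excess, x_best, hi, xtol=xtol, rtol=1e-12))
    return MeasurementRange(rng.range_min, rng.range_max, lloq=lloq, uloq=uloq)


def sd_rule_cutoff(values: Sequence[float], k: float) -> float:
    """Distance-rule outlier cutoff: mean + k * sample SD (e.g. k = 2.5 or 3)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("SD distance rule needs at least 2 values")
    return float(arr.mean() + k * arr.std(ddof=1))


def measure(
    true_values: Sequence[float],
    profile: PrecisionProfile,
    seed: int | np.random.Generator | np.random.SeedSequence,
    max_redraws: int = 100,
) -> np.ndarray:
    """Apply multiplicative CV noise to true concentrations.

    Each true value y* is read out as ``y = y* * (1 + CV(y*) * eps)`` with
    eps standard normal, so the relative error SD at concentration y* equals
    the profile's CV there. Draws that land at or below zero are redrawn
    (concentrations are positive); after ``max_redraws`` failed rounds a
    :class:`DomainError` is raised rather than returning invalid values.
    Deterministic for a given seed.
    """
    y_true = np.asarray(true_values, dtype=float)
    if np.any(y_true <= 0):
        raise DomainError("true concentrations must be > 0")
    rng = np.random.default_rng(seed)
    cv = np.broadcast_to(np.asarray(profile.cv(y_true), dtype=float), y_true.shape)
    y = y_true * (1.0 + cv * rng.standard_normal(y_true.shape))
    bad = y <= 0
    attempts = 0
    while np.any(bad):
        attempts += 1
        if attempts > max_redraws:
            raise DomainError(
                f"could not draw positive measurements after {max_redraws} redraws"
            )
        n_bad = int(bad.sum())
        y[bad] = y_true[bad] * (1.0 + cv[bad] * rng.standard_normal(n_bad))
        bad = y <= 0
    return y


def censor(
    measured: Sequence[float],
    lc: float,
    uc: float,
    true_values: Sequence[float] | None = None,
) -> CensoredDataset:
    """Classify measured values against the cutoffs.

    Strictly below ``lc`` counts as BC and strictly above ``uc`` as AC; a
    value exactly on a cutoff is kept as observed. Observed values keep
    their input order. Record count is conserved:
    ``n_obs + n_bc + n_ac == len(measured)``.
    """
    if not lc < uc:
        raise ConfigurationError(f"lc ({lc}) must be < uc ({uc})")
    y = np.asarray(measured, dtype=float)
    below = y < lc
    above = y > uc
    keep = ~(below | above)
    return CensoredDataset(
        observed=y[keep],
        n_bc=int(below.sum()),
        n_ac=int(above.sum()),
        lc=float(lc),
        uc=float(uc),
        true_values=None if true_values is None else np.asarray(true_values, dtype=float),
    )
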