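"""The six handling methods for censored records and Rubin's-rules pooling.

Methods (BC = record measured below LC, AC = above UC):

========  ==============================================================
M_del     drop every BC/AC record (complete-cases analysis)
M_fix1    BC -> measurement-range minimum, AC -> measurement-range maximum
M_fix2    BC -> LC/2 (midpoint of [0, LC]), AC -> (UC + range_max)/2
M_fix3    BC -> LC, AC -> UC (winsorizing to the cutoffs)
M_uni     BC ~ Uniform(0, LC), AC ~ Uniform(UC, range_max)
M_log     censored-lognormal ML fit, then BC from the fit truncated to
          (0, LC) and AC from the fit truncated to (UC, inf)
========  ==============================================================

M_uni and M_log are multiple-imputation methods: the draw is repeated m
times and per-dataset estimates are pooled with Rubin's rules. The fixed
methods and deletion are deterministic, so m is forced to 1 for them.
Censored records are missing not at random — their absence itself signals a
genuinely low or high concentration — which is why observed-data summaries
(overall mean/median imputation) are not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .censored_fit import FitResult, fit_censored_lognormal, truncated_lognormal_sample
from .errors import ConfigurationError, InsufficientDataError, MissingRangeError
from .measurement import CensoredDataset, MeasurementRange

__all__ = [
    "METHODS",
    "DETERMINISTIC_METHODS",
    "MethodSpec",
    "ImputedDatasets",
    "PooledEstimate",
    "impute_dataset",
    "pool_rubin",
]

METHODS = ("M_del", "M_fix1", "M_fix2", "M_fix3", "M_uni", "M_log")
DETERMINISTIC_METHODS = ("M_del", "M_fix1", "M_fix2", "M_fix3")

#: Provenance flags attached to every record of a completed dataset.
PROV_OBSERVED = "observed"
PROV_BC = "imputed_bc"
PROV_AC = "imputed_ac"


@dataclass(frozen=True)
class MethodSpec:
    """A handling method plus its options.

    ``m`` is the number of imputations; it is forced to 1 for the
    deterministic methods where repetition would duplicate identical
    datasets. ``range`` supplies the measurement-range bounds needed by
    M_fix1/M_fix2/M_uni when AC records exist.
    """

    method: str
    m: int = 10
    seed: int = 0
    range: MeasurementRange | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.method in DETERMINISTIC_METHODS and self.m != 1:
            object.__setattr__(self, "m", 1)


@dataclass(frozen=True)
class ImputedDatasets:
    """m completed value vectors plus per-record provenance.

    Completed vectors keep the layout (observed records in input order,
    then BC, then AC); ``provenance`` flags each position. For M_del there
    is a single vector holding only the observed records.
    """

    datasets: tuple[np.ndarray, ...]
    provenance: tuple[str, ...]
    spec: MethodSpec
    lc: float
    uc: float
    fit: FitResult | None = None

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooling of m per-imputation estimates.

    qbar = mean estimate, w = mean within-imputation variance, b = sample
    variance of the estimates (0 when m = 1), t = w + (1 + 1/m) b.
    """

    qbar: float
    w: float
    b: float
    t: float
    m: int


def _range_bounds(spec: MethodSpec) -> tuple[float, float | None]:
    if spec.range is None:
        return 0.0, None
    return spec.range.range_min, spec.range.range_max


def _require_range_max(spec: MethodSpec, what: str) -> float:
    _, rmax = _range_bounds(spec)
    if rmax is None or not np.isfinite(rmax):
        raise MissingRangeError(
            f"{spec.method} needs a finite measurement-range maximum to impute {what}"
        )
    return rmax


def impute_dataset(data: CensoredDataset, spec: MethodSpec) -> ImputedDatasets:
    """Apply one handling method, producing m completed datasets.

    Observed values are never altered by any method. M_log fits the censored
    lognormal once and draws all m imputations from that single fit.
    Deterministic given ``spec.seed``.
    """
    method = spec.method
    obs = data.observed
    lc, uc = data.lc, data.uc

    if method == "M_del":
        return ImputedDatasets(
            datasets=(obs.copy(),),
            provenance=(PROV_OBSERVED,) * data.n_obs,
            spec=spec, lc=lc, uc=uc,
        )

    provenance = (
        (PROV_OBSERVED,) * data.n_obs + (PROV_BC,) * data.n_bc + (PROV_AC,) * data.n_ac
    )

    fit: FitResult | None = None
    if method in ("M_fix1", "M_fix2", "M_fix3"):
        if method == "M_fix1":
            rmin, _ = _range_bounds(spec)
            bc_val = rmin
            ac_val = _require_range_max(spec, "AC records") if data.n_ac else None
        elif method == "M_fix2":
            bc_val = lc / 2.0
            ac_val = (uc + _require_range_max(spec, "AC records")) / 2.0 if data.n_ac else None
        else:  # M_fix3
            bc_val, ac_val = lc, uc
        parts = [obs, np.full(data.n_bc, bc_val, dtype=float)]
        if data.n_ac:
            parts.append(np.full(data.n_ac, ac_val, dtype=float))
        datasets = (np.concatenate(parts),)
    elif method == "M_uni":
        rmax = _require_range_max(spec, "AC records") if data.n_ac else None
        rng = np.random.default_rng(spec.seed)
        datasets = tuple(
            np.concatenate([
                obs,
                rng.uniform(0.0, lc, size=data.n_bc),
                rng.uniform(uc, rmax, size=data.n_ac) if data.n_ac else np.empty(0),
            ])
            for _ in range(spec.m)
        )
    elif method == "M_log":
        fit = fit_censored_lognormal(data)
        ss = np.random.SeedSequence(spec.seed)
        streams = ss.spawn(2 * spec.m)
        datasets = tuple(
            np.concatenate([
                obs,
                truncated_lognormal_sample(fit.params, 0.0, lc, data.n_bc, streams[2 * i])
                if data.n_bc else np.empty(0),
                truncated_lognormal_sample(fit.params, uc, np.inf, data.n_ac, streams[2 * i + 1])
                if data.n_ac else np.empty(0),
            ])
            for i in range(spec.m)
        )
    else:  # pragma: no cover - guarded by MethodSpec validation
        raise ConfigurationError(f"unknown method {method!r}")

    return ImputedDatasets(
        datasets=datasets, provenance=provenance, spec=spec, lc=lc, uc=uc, fit=fit
    )


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Pool m point estimates and their variances with Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise InsufficientDataError("pooling requires at least one estimate")
    if q.shape != u.shape:
        raise ConfigurationError("estimates and variances must have equal length")
    m = int(q.size)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    return PooledEstimate(qbar=qbar, w=w, b=b, t=t, m=m)
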