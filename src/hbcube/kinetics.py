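"""Monoexponential fitting of kinetic traces.

Handles stopped-flow O2-dissociation absorbance traces (seconds) and
autoxidation A541/A630 ratio series (hours) with the shared model
value(t) = offset + amplitude * exp(-rate * t).

Note on units: dissociation rates are reported in s^-1 as dictated by
the monoexponential model, even though figure-style k_off values are
sometimes labelled M^-1 s^-1; the discrepancy is recorded in output
metadata rather than rescaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "KineticTrace",
    "KineticFit",
    "fit_monoexponential",
    "autoxidation_rate",
    "fold_change",
    "TRACE_KINDS",
    "RATE_QUALITY_R2",
]

TRACE_KINDS = ("dissociation", "autoxidation")

#: fits below this r^2 are flagged low-quality
RATE_QUALITY_R2 = 0.99

#: unit metadata note attached to dissociation fits
KOFF_UNIT_NOTE = (
    "rate reported in s^-1 (monoexponential decay constant); "
    "bimolecular M^-1 s^-1 labelling of k_off is not dimensionally "
    "derivable from a monoexponential trace"
)


@dataclass(frozen=True)
class KineticTrace:
    """A time series: absorbance decay or A541/A630 ratio decay."""

    genotype: str
    kind: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    replicate_id: str = "r1"
    time_unit: str = ""  # "s" or "h"; defaulted from kind if empty

    def __post_init__(self) -> None:
        if self.kind not in TRACE_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {TRACE_KINDS}, got {self.kind!r}"
            )
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.size != v.size:
            raise InvalidParameterError("times and values lengths differ")
        if t.size < 5:
            raise InsufficientDataError(
                f"need >=5 points, got {t.size} "
                f"({self.genotype}/{self.kind}/{self.replicate_id})"
            )
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("values must be finite")
        if not self.time_unit:
            object.__setattr__(
                self, "time_unit", "s" if self.kind == "dissociation" else "h"
            )


@dataclass(frozen=True)
class KineticFit:
    """Fitted monoexponential value(t) = offset + amplitude*exp(-rate*t)."""

    rate: float  # s^-1 (dissociation) or h^-1 (autoxidation)
    amplitude: float
    offset: float
    rate_se: float
    r_squared: float
    genotype: str = ""
    kind: str = ""
    replicate_id: str = ""
    time_unit: str = ""
    low_quality: bool = False
    sign_error: bool = False
    unit_note: str = ""

    @property
    def half_life(self) -> float:
        """ln(2)/rate, in the trace's time unit."""
        return math.log(2.0) / self.rate


def _init_params(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """offset <- last value; amplitude <- first - last; rate <- ln2 / t_half."""
    offset = v[-1]
    amplitude = v[0] - v[-1]
    half_level = offset + amplitude / 2.0
    # first crossing of half amplitude
    if amplitude >= 0:
        below = np.nonzero(v <= half_level)[0]
    else:
        below = np.nonzero(v >= half_level)[0]
    t_half = t[below[0]] if below.size and t[below[0]] > 0 else (t[-1] - t[0]) / 2.0
    if t_half <= 0:
        t_half = (t[-1] - t[0]) / 2.0
    return (offset, amplitude, math.log(2.0) / t_half)


def fit_monoexponential(trace: KineticTrace, max_nfev: int = 10_000) -> KineticFit:
    """Least-squares monoexponential fit of a kinetic trace.

    Raises on constant traces.  A fitted rate <= 0 on a decay-kind trace
    is flagged (``sign_error``), and r^2 below ``RATE_QUALITY_R2`` is
    flagged low-quality; neither is silently dropped.
    """
    t = np.asarray(trace.times, float)
    v = np.asarray(trace.values, float)
    if np.allclose(v, v[0]):
        raise DegenerateDataError(
            f"constant trace ({trace.genotype}/{trace.kind}/{trace.replicate_id})"
        )
    off0, amp0, rate0 = _init_params(t, v)
    if rate0 <= 0 or not math.isfinite(rate0):
        rate0 = 1.0 / max(t[-1] - t[0], 1e-12)

    def model(theta: np.ndarray) -> np.ndarray:
        off, amp, rate = theta
        return off + amp * np.exp(-rate * t)

    sol = least_squares(
        lambda th: model(th) - v,
        x0=np.array([off0, amp0 if amp0 != 0 else np.ptp(v) or 1.0, rate0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    off, amp, rate = sol.x
    res = sol.fun
    ss_res = float(res @ res)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan

    rate_se = math.nan
    dof = t.size - 3
    if dof > 0:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            rate_se = float(math.sqrt(max(jtj_inv[2, 2] * ss_res / dof, 0.0)))
        except np.linalg.LinAlgError:
            pass

    return KineticFit(
        rate=float(rate),
        amplitude=float(amp),
        offset=float(off),
        rate_se=rate_se,
        r_squared=r2,
        genotype=trace.genotype,
        kind=trace.kind,
        replicate_id=trace.replicate_id,
        time_unit=trace.time_unit,
        low_quality=bool(r2 < RATE_QUALITY_R2),
        sign_error=bool(rate <= 0),
        unit_note=KOFF_UNIT_NOTE if trace.kind == "dissociation" else "",
    )


def autoxidation_rate(series: KineticTrace) -> KineticFit:
    """Autoxidation rate (h^-1) from a decaying A541/A630 ratio series."""
    if series.kind != "autoxidation":
        raise InvalidParameterError(
            f"expected an autoxidation series, got kind {series.kind!r}"
        )
    return fit_monoexponential(series)


def fold_change(rate_a: float, rate_b: float) -> float:
    """rate_b / rate_a; both must be positive."""
    if rate_a <= 0 or rate_b <= 0:
        raise InvalidParameterError("rates must be positive")
    return rate_b / rate_a


def summarize_rates(fits: Sequence[KineticFit]) -> tuple[float, float | None, int]:
    """(mean rate, SEM, n) over fits without sign errors."""
    good = [f for f in fits if not f.sign_error]
    if not good:
        from .errors import NoDataError

        raise NoDataError("no usable kinetic fits to summarize")
    rates = np.array([f.rate for f in good])
    n = len(good)
    sem = float(np.std(rates, ddof=1) / math.sqrt(n)) if n > 1 else None
    return (float(rates.mean()), sem, n)
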