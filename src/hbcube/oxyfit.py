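"""Cooperative O2-equilibrium curve modelling.

Fits the Hill equation Y = PO2**n / (P50**n + PO2**n) to fractional
saturation data by nonlinear least squares, summarizes replicate fits,
and computes anion-sensitivity indices (delta log10 P50 between effector
treatments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
    NoDataError,
)

__all__ = [
    "EffectorTreatment",
    "SaturationCurve",
    "HillFit",
    "AnionSensitivity",
    "ReplicateSummary",
    "hill_saturation",
    "fit_hill",
    "summarize_replicates",
    "anion_sensitivity",
    "TREATMENT_LABELS",
    "kpa_to_torr",
]

TREATMENT_LABELS = ("stripped", "KCl", "IHP", "KCl+IHP")

#: 1 kPa in torr (mmHg); conversion for I/O only — the pipeline works in torr.
TORR_PER_KPA = 7.50062


def kpa_to_torr(kpa: float) -> float:
    return kpa * TORR_PER_KPA


@dataclass(frozen=True)
class EffectorTreatment:
    """An O2-equilibrium measurement condition.

    ``stripped`` means no allosteric effectors; otherwise KCl molarity
    and/or the IHP:tetramer molar ratio are set.
    """

    label: str
    ph: float = 7.4
    temperature_c: float = 37.0
    kcl_molar: float | None = None
    ihp_ratio: float | None = None
    heme_mM: float | None = None

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise InvalidParameterError(
                f"treatment label must be one of {TREATMENT_LABELS}, got {self.label!r}"
            )
        if self.label == "stripped" and (
            self.kcl_molar is not None or self.ihp_ratio is not None
        ):
            raise InvalidParameterError(
                "stripped treatment cannot carry effector concentrations"
            )


@dataclass(frozen=True)
class SaturationCurve:
    """One replicate's O2 saturation curve for one genotype/treatment."""

    genotype: str
    treatment: EffectorTreatment
    po2_torr: tuple[float, ...]
    saturation: tuple[float, ...]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        po2 = np.asarray(self.po2_torr, float)
        sat = np.asarray(self.saturation, float)
        if po2.size != sat.size:
            raise InvalidParameterError("po2 and saturation lengths differ")
        if po2.size < 3:
            raise InsufficientDataError(
                f"need >=3 points, got {po2.size} "
                f"({self.genotype}/{self.treatment.label}/{self.replicate_id})"
            )
        if not np.all(po2 > 0):
            raise InvalidParameterError("PO2 values must be strictly positive")
        if not np.all(np.diff(po2) > 0):
            raise InvalidParameterError("PO2 values must be strictly increasing")
        # small tolerance for measurement noise around the physical bounds
        if np.any(sat < -0.05) or np.any(sat > 1.05):
            raise InvalidParameterError("saturations outside [0,1] beyond tolerance")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill-equation parameters for one saturation curve."""

    p50_torr: float
    n50: float
    p50_se: float
    n50_se: float
    r_squared: float
    converged: bool
    genotype: str = ""
    treatment: str = ""
    replicate_id: str = ""


@dataclass(frozen=True)
class AnionSensitivity:
    """log10(P50 with effector) - log10(P50 stripped)."""

    delta_log_p50: float
    treatment_pair: tuple[str, str] = ("stripped", "KCl+IHP")


@dataclass(frozen=True)
class ReplicateSummary:
    mean_p50: float
    sem_p50: float | None
    n: int
    mean_n50: float = math.nan
    sem_n50: float | None = None


def hill_saturation(po2: float, p50: float, n: float):
    """Fractional saturation Y = PO2**n / (P50**n + PO2**n).

    Accepts scalars or arrays for ``po2``; strictly increasing in po2,
    with Y(p50) = 0.5 exactly and Y(0) = 0.
    """
    if p50 <= 0 or n <= 0:
        raise InvalidParameterError(f"p50 and n must be positive (p50={p50}, n={n})")
    po2 = np.asarray(po2, float)
    if np.any(po2 < 0):
        raise InvalidParameterError("po2 must be non-negative")
    # computed in log space via expit-like form for numerical stability
    with np.errstate(divide="ignore"):
        z = n * (np.log(po2) - math.log(p50))
    y = np.where(po2 == 0, 0.0, 1.0 / (1.0 + np.exp(-z)))
    return float(y) if y.ndim == 0 else y


def _hill_plot_init(po2: np.ndarray, sat: np.ndarray) -> tuple[float, float]:
    """Initial (p50, n) from the log-linear Hill plot.

    Regresses logit(Y) on log(PO2) over points with 0.05 < Y < 0.95;
    falls back to interpolation when fewer than two such points exist.
    """
    mask = (sat > 0.05) & (sat < 0.95)
    if mask.sum() >= 2:
        x = np.log(po2[mask])
        y = np.log(sat[mask] / (1.0 - sat[mask]))
        n, intercept = np.polyfit(x, y, 1)
        if n > 0:
            return (float(np.exp(-intercept / n)), float(n))
    # fall back: p50 at the half-saturation crossing, n = 2
    idx = int(np.argmin(np.abs(sat - 0.5)))
    return (float(po2[idx]), 2.0)


def fit_hill(
    curve: SaturationCurve,
    init: tuple[float, float] | None = None,
    max_nfev: int = 10_000,
) -> HillFit:
    """Least-squares Hill fit of a saturation curve.

    Unweighted residuals on the saturation scale; parameters optimized
    in log space to enforce positivity.  ``converged`` is True only when
    the optimizer reports success and the fitted P50 lies within the
    observed PO2 range extended by one decade either side.  Degenerate
    (constant-saturation) curves raise; non-convergence is returned with
    ``converged=False``, never silently.
    """
    po2 = np.asarray(curve.po2_torr, float)
    sat = np.asarray(curve.saturation, float)
    if np.allclose(sat, sat[0]):
        raise DegenerateDataError(
            f"all saturations identical ({curve.genotype}/{curve.replicate_id})"
        )
    p0, n0 = init if init is not None else _hill_plot_init(po2, sat)
    if p0 <= 0 or n0 <= 0:
        raise InvalidParameterError("init (p50, n) must be positive")

    def resid(theta: np.ndarray) -> np.ndarray:
        p50, n = np.exp(theta)
        return hill_saturation(po2, p50, n) - sat

    sol = least_squares(
        resid,
        x0=np.log([p0, n0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    p50, n50 = np.exp(sol.x)
    res = sol.fun
    ss_res = float(res @ res)
    ss_tot = float(np.sum((sat - sat.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan

    # delta-method SEs from the log-space jacobian
    p50_se = n50_se = math.nan
    dof = po2.size - 2
    if dof > 0:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            sigma2 = ss_res / dof
            log_se = np.sqrt(np.clip(np.diag(jtj_inv) * sigma2, 0, None))
            p50_se = float(p50 * log_se[0])
            n50_se = float(n50 * log_se[1])
        except np.linalg.LinAlgError:
            pass

    in_range = po2[0] / 10.0 <= p50 <= po2[-1] * 10.0
    return HillFit(
        p50_torr=float(p50),
        n50=float(n50),
        p50_se=p50_se,
        n50_se=n50_se,
        r_squared=r2,
        converged=bool(sol.success and in_range),
        genotype=curve.genotype,
        treatment=curve.treatment.label,
        replicate_id=curve.replicate_id,
    )


def summarize_replicates(fits: Sequence[HillFit]) -> ReplicateSummary:
    """Mean P50 across converged replicate fits with its SEM.

    SEM = sample standard deviation / sqrt(n); ``None`` for n = 1.
    Non-converged fits are excluded; zero converged fits raise.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise NoDataError("no converged fits to summarize")
    p50s = np.array([f.p50_torr for f in good])
    n50s = np.array([f.n50 for f in good])
    n = len(good)
    sem_p = float(np.std(p50s, ddof=1) / math.sqrt(n)) if n > 1 else None
    sem_n = float(np.std(n50s, ddof=1) / math.sqrt(n)) if n > 1 else None
    return ReplicateSummary(
        mean_p50=float(p50s.mean()),
        sem_p50=sem_p,
        n=n,
        mean_n50=float(n50s.mean()),
        sem_n50=sem_n,
    )


def anion_sensitivity(
    p50_stripped: float,
    p50_effector: float,
    effector_label: str = "KCl+IHP",
) -> AnionSensitivity:
    """delta log P50 = log10(P50 effector) - log10(P50 stripped)."""
    if p50_stripped <= 0 or p50_effector <= 0:
        raise InvalidParameterError("P50 values must be positive")
    return AnionSensitivity(
        delta_log_p50=math.log10(p50_effector) - math.log10(p50_stripped),
        treatment_pair=("stripped", effector_label),
    )
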