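"""Trade-off screen: correlate mutational changes across traits.

Pairs per-mutation (or per-genotype) changes in one trait against
another and reports Pearson correlations.  The pairing convention is an
explicit, recorded choice because different conventions give different
coefficients on the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientDataError, UndefinedCorrelationError
from .landscape import Genotype, GenotypePhenotypeTable, enumerate_genotypes

__all__ = [
    "EdgeDelta",
    "CorrelationResult",
    "CONVENTIONS",
    "edge_deltas",
    "pearson",
    "correlation_screen",
]

CONVENTIONS = ("all-hypercube-edges", "first-step-from-ancestor", "genotype-level")


@dataclass(frozen=True)
class EdgeDelta:
    """Paired trait changes along one hypercube edge (or one genotype)."""

    from_code: str
    to_code: str
    site: str  # "" for genotype-level pairing
    delta_x: float
    delta_y: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    convention: str
    trait_x: str = ""
    trait_y: str = ""


def _log_delta(table: GenotypePhenotypeTable, frm: str, to: str, trait: str) -> float:
    return math.log10(table.mean(to, trait)) - math.log10(table.mean(frm, trait))


def edge_deltas(
    table: GenotypePhenotypeTable,
    trait_x: str,
    trait_y: str,
    convention: str = "all-hypercube-edges",
) -> list[EdgeDelta]:
    """Deterministic paired deltas under the chosen pairing convention.

    - ``all-hypercube-edges``: every single-site edge, ancestral->derived
      direction; deltas are log10 differences (k * 2**(k-1) edges).
    - ``first-step-from-ancestor``: only the k edges leaving the
      ancestral corner.
    - ``genotype-level``: no differencing; each genotype contributes its
      raw trait values directly as (x, y).
    """
    if convention not in CONVENTIONS:
        raise ConfigError(
            f"unknown convention {convention!r}; choose from {CONVENTIONS}"
        )
    out: list[EdgeDelta] = []
    if convention == "genotype-level":
        for code in table.genotypes:
            out.append(
                EdgeDelta(
                    from_code=code,
                    to_code=code,
                    site="",
                    delta_x=table.mean(code, trait_x),
                    delta_y=table.mean(code, trait_y),
                )
            )
        return out

    if convention == "first-step-from-ancestor":
        anc = Genotype.ancestral(table.sites)
        backgrounds = [anc]
    else:
        backgrounds = [
            g for g in enumerate_genotypes(table.sites)
        ]
    for g in backgrounds:
        for site in table.sites:
            if g.is_derived_at(site.label):
                continue
            nb = g.toggled(site.label)
            out.append(
                EdgeDelta(
                    from_code=g.code,
                    to_code=nb.code,
                    site=site.label,
                    delta_x=_log_delta(table, g.code, nb.code, trait_x),
                    delta_y=_log_delta(table, g.code, nb.code, trait_y),
                )
            )
    return out


def pearson(deltas: Sequence[EdgeDelta], convention: str = "") -> CorrelationResult:
    """Pearson r over paired deltas with a two-tailed t-distribution p."""
    if len(deltas) < 3:
        raise InsufficientDataError(f"need >=3 pairs, got {len(deltas)}")
    x = np.array([d.delta_x for d in deltas])
    y = np.array([d.delta_y for d in deltas])
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise UndefinedCorrelationError("non-finite values in pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one coordinate")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        n=len(deltas),
        p_value=float(res.pvalue),
        convention=convention,
    )


def correlation_screen(
    table: GenotypePhenotypeTable,
    trait_x: str,
    trait_ys: Sequence[str],
    conventions: Sequence[str] = CONVENTIONS,
) -> list[CorrelationResult]:
    """All (trait_y, convention) correlations against ``trait_x``."""
    results = []
    for trait_y in trait_ys:
        for conv in conventions:
            deltas = edge_deltas(table, trait_x, trait_y, conv)
            res = pearson(deltas, convention=conv)
            results.append(
                CorrelationResult(
                    r=res.r,
                    n=res.n,
                    p_value=res.p_value,
                    convention=conv,
                    trait_x=trait_x,
                    trait_y=trait_y,
                )
            )
    return results
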