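"""Genotype-hypercube analysis.

Enumerates the 2**k genotype lattice spanned by k biallelic amino-acid
sites, walks the k! forward mutational pathways between the ancestral and
fully derived corners, and quantifies per-background mutation effects,
order dependence, reversion symmetry and double-mutant-cycle epistasis on
ratio-scale traits (effects are log10-based so they telescope along
pathways).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InvalidParameterError,
    InvalidSitesError,
    InvalidSiteStateError,
    MissingDataError,
    SizeLimitError,
)

__all__ = [
    "SiteDef",
    "Genotype",
    "TraitValue",
    "GenotypePhenotypeTable",
    "MutationEffect",
    "PathwayStep",
    "Pathway",
    "ReversionPair",
    "DoubleMutantCycle",
    "RankSummary",
    "enumerate_genotypes",
    "enumerate_pathways",
    "mutation_effect",
    "pathway_trajectory",
    "rank_largest_effect",
    "effects_on_all_backgrounds",
    "reversion_symmetry",
    "double_mutant_cycle",
    "welch_from_summary",
    "round_half_away",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Maximum k for full-hypercube enumeration.
MAX_SITES = 16
#: Maximum k for pathway (k!) enumeration.
MAX_PATHWAY_SITES = 8


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def welch_from_summary(
    mean_a: float, sem_a: float | None, n_a: int,
    mean_b: float, sem_b: float | None, n_b: int,
) -> tuple[float, float, float]:
    """Welch's two-sample t-test from (mean, SEM, n) summaries.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite df and a
    two-tailed p from the t distribution.  Returns ``(nan, nan, nan)``
    when either SEM is unavailable or both are zero, or when either
    sample has n < 2.
    """
    if sem_a is None or sem_b is None or n_a < 2 or n_b < 2:
        return (math.nan, math.nan, math.nan)
    va, vb = sem_a**2, sem_b**2
    if va + vb == 0:
        return (math.nan, math.nan, math.nan)
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (t, df, p)


@dataclass(frozen=True)
class SiteDef:
    """A biallelic amino-acid site with declared ancestral/derived states."""

    label: str
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        for state in (self.ancestral, self.derived):
            if len(state) != 1 or state not in AMINO_ACIDS:
                raise InvalidSitesError(
                    f"site {self.label!r}: state {state!r} is not a one-letter amino acid"
                )
        if self.ancestral == self.derived:
            raise InvalidSitesError(
                f"site {self.label!r}: ancestral and derived states are identical"
            )


def _check_sites(sites: Sequence[SiteDef]) -> None:
    labels = [s.label for s in sites]
    if len(set(labels)) != len(labels):
        raise InvalidSitesError(f"duplicate site labels: {labels}")
    if not sites:
        raise InvalidSitesError("at least one site is required")


@dataclass(frozen=True)
class Genotype:
    """Ordered amino-acid states at a declared set of biallelic sites."""

    sites: tuple[SiteDef, ...]
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        if len(self.states) != len(self.sites):
            raise InvalidSiteStateError(
                f"{len(self.states)} states for {len(self.sites)} sites"
            )
        for site, state in zip(self.sites, self.states):
            if state not in (site.ancestral, site.derived):
                raise InvalidSiteStateError(
                    f"state {state!r} at site {site.label!r} is neither "
                    f"ancestral {site.ancestral!r} nor derived {site.derived!r}"
                )

    @property
    def code(self) -> str:
        """Concatenated one-letter states, e.g. ``'GAP'``."""
        return "".join(self.states)

    def state_at(self, label: str) -> str:
        for site, state in zip(self.sites, self.states):
            if site.label == label:
                return state
        raise MissingDataError(f"no site labelled {label!r}")

    def is_derived_at(self, label: str) -> bool:
        for site, state in zip(self.sites, self.states):
            if site.label == label:
                return state == site.derived
        raise MissingDataError(f"no site labelled {label!r}")

    def toggled(self, label: str) -> "Genotype":
        """The single-site neighbour differing only at ``label``."""
        states = list(self.states)
        for i, site in enumerate(self.sites):
            if site.label == label:
                states[i] = (
                    site.derived if states[i] == site.ancestral else site.ancestral
                )
                return Genotype(self.sites, tuple(states))
        raise MissingDataError(f"no site labelled {label!r}")

    @classmethod
    def from_code(cls, sites: Sequence[SiteDef], code: str) -> "Genotype":
        return cls(tuple(sites), tuple(code))

    @classmethod
    def ancestral(cls, sites: Sequence[SiteDef]) -> "Genotype":
        return cls(tuple(sites), tuple(s.ancestral for s in sites))

    @classmethod
    def derived(cls, sites: Sequence[SiteDef]) -> "Genotype":
        return cls(tuple(sites), tuple(s.derived for s in sites))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass(frozen=True)
class TraitValue:
    """A per-genotype trait summary: mean, SEM (may be absent) and n."""

    mean: float
    sem: float | None = None
    n: int = 1


class GenotypePhenotypeTable:
    """Per-genotype trait summaries keyed by genotype code.

    The substrate for all hypercube operations.  Rows may be added for
    any genotype over the table's declared sites; hypercube operations
    fail loudly (``MissingDataError``) when a required corner is absent.
    """

    def __init__(self, sites: Sequence[SiteDef], traits: Iterable[str] = ()):
        _check_sites(sites)
        self.sites: tuple[SiteDef, ...] = tuple(sites)
        self.traits: list[str] = list(traits)
        self._rows: dict[str, dict[str, TraitValue]] = {}

    # -- construction -------------------------------------------------
    def set_value(
        self, code: str, trait: str, mean: float,
        sem: float | None = None, n: int = 1,
    ) -> None:
        Genotype.from_code(self.sites, code)  # validates the code
        if trait not in self.traits:
            self.traits.append(trait)
        self._rows.setdefault(code, {})[trait] = TraitValue(mean, sem, n)

    # -- access -------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return sorted(self._rows)

    def __contains__(self, code: str) -> bool:
        return code in self._rows

    def value(self, code: str, trait: str) -> TraitValue:
        try:
            return self._rows[code][trait]
        except KeyError:
            raise MissingDataError(
                f"no value for genotype {code!r}, trait {trait!r}"
            ) from None

    def mean(self, code: str, trait: str) -> float:
        return self.value(code, trait).mean

    def missing_corners(self, trait: str) -> list[str]:
        """Hypercube genotype codes lacking a value for ``trait``."""
        out = []
        for g in enumerate_genotypes(self.sites):
            if g.code not in self._rows or trait not in self._rows[g.code]:
                out.append(g.code)
        return out

    def require_full_hypercube(self, trait: str) -> None:
        missing = self.missing_corners(trait)
        if missing:
            raise MissingDataError(
                f"trait {trait!r} missing for genotype(s): {', '.join(missing)}"
            )


@dataclass(frozen=True)
class MutationEffect:
    """Effect of switching one site ancestral->derived on a fixed background.

    ``delta_log10`` is the primary effect size; ``percent_change`` is the
    signed raw-scale change, 100*(10**delta_log10 - 1) (negative for a
    reduction).  ``percent_reduction`` = -percent_change.
    """

    site: str
    background: Genotype
    from_code: str
    to_code: str
    delta_log10: float
    percent_change: float
    welch_t: float
    welch_df: float
    p_value: float
    significant: bool

    @property
    def percent_reduction(self) -> float:
        return -self.percent_change


@dataclass(frozen=True)
class PathwayStep:
    from_genotype: Genotype
    to_genotype: Genotype
    effect: MutationEffect


@dataclass(frozen=True)
class Pathway:
    """One mutational ordering from the ancestral to the derived corner."""

    order: tuple[str, ...]
    steps: tuple[PathwayStep, ...] = ()

    @property
    def genotype_codes(self) -> list[str]:
        if not self.steps:
            return []
        return [self.steps[0].from_genotype.code] + [
            s.to_genotype.code for s in self.steps
        ]

    @property
    def total_delta_log10(self) -> float:
        return sum(s.effect.delta_log10 for s in self.steps)


@dataclass(frozen=True)
class ReversionPair:
    """Forward effect on one background paired with the reversion on another."""

    site: str
    background_fwd: Genotype
    background_rev: Genotype
    forward_delta_log10: float
    reverse_delta_log10: float

    @property
    def asymmetry_index(self) -> float:
        """forward + reverse; zero on an additive landscape."""
        return self.forward_delta_log10 + self.reverse_delta_log10


@dataclass(frozen=True)
class DoubleMutantCycle:
    """Four-corner (ab, Ab, aB, AB) epistasis construct for two sites."""

    site_a: str
    site_b: str
    fixed_background: tuple[tuple[str, str], ...]  # (site label, state) pairs
    corner_ab: tuple[str, float]
    corner_Ab: tuple[str, float]
    corner_aB: tuple[str, float]
    corner_AB: tuple[str, float]
    epistasis_log10: float

    @property
    def compensation_ratio(self) -> float:
        """AB-corner mean over ab-corner mean (~1 means full compensation)."""
        return self.corner_AB[1] / self.corner_ab[1]


@dataclass
class RankSummary:
    """Per-pathway largest-effect winners plus per-site counts."""

    winners: list[tuple[Pathway, tuple[str, ...]]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    tied_pathways: int = 0


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_genotypes(sites: Sequence[SiteDef]) -> list[Genotype]:
    """All 2**k genotypes over ``sites`` in deterministic order.

    Ordering is lexicographic in (ancestral=0, derived=1) bit vectors, so
    the fully ancestral genotype comes first and the fully derived one
    last; intermediates number 2**k - 2.
    """
    _check_sites(sites)
    if len(sites) > MAX_SITES:
        raise SizeLimitError(f"{len(sites)} sites exceeds limit of {MAX_SITES}")
    out = []
    for bits in itertools.product((0, 1), repeat=len(sites)):
        states = tuple(
            s.derived if b else s.ancestral for s, b in zip(sites, bits)
        )
        out.append(Genotype(tuple(sites), states))
    return out


def enumerate_pathways(sites: Sequence[SiteDef]) -> list[Pathway]:
    """All k! forward pathway skeletons (site orderings), deterministic."""
    _check_sites(sites)
    if len(sites) > MAX_PATHWAY_SITES:
        raise SizeLimitError(
            f"{len(sites)}! pathways exceeds the k<={MAX_PATHWAY_SITES} limit"
        )
    labels = [s.label for s in sites]
    return [Pathway(order=perm) for perm in itertools.permutations(labels)]


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

def mutation_effect(
    table: GenotypePhenotypeTable,
    site: str,
    background: Genotype,
    trait: str,
    alpha: float = 0.05,
) -> MutationEffect:
    """Effect of the ancestral->derived switch at ``site`` on ``background``.

    ``background`` gives the states at all sites and must carry the
    *ancestral* state at ``site``; the effect compares it against its
    single-site derived neighbour.  Significance is a Welch test from the
    stored (mean, SEM, n) summaries.
    """
    if background.is_derived_at(site):
        raise InvalidSiteStateError(
            f"background {background.code!r} already carries the derived state "
            f"at {site!r}"
        )
    neighbour = background.toggled(site)
    va = table.value(background.code, trait)
    vd = table.value(neighbour.code, trait)
    if va.mean <= 0 or vd.mean <= 0:
        raise InvalidParameterError(
            f"trait {trait!r} must be positive for log effects "
            f"({background.code}: {va.mean}, {neighbour.code}: {vd.mean})"
        )
    delta = math.log10(vd.mean) - math.log10(va.mean)
    percent = 100.0 * (vd.mean / va.mean - 1.0)
    t, df, p = welch_from_summary(vd.mean, vd.sem, vd.n, va.mean, va.sem, va.n)
    return MutationEffect(
        site=site,
        background=background,
        from_code=background.code,
        to_code=neighbour.code,
        delta_log10=delta,
        percent_change=percent,
        welch_t=t,
        welch_df=df,
        p_value=p,
        significant=bool(p == p and p < alpha),
    )


def pathway_trajectory(
    table: GenotypePhenotypeTable,
    pathway: Pathway,
    trait: str,
    alpha: float = 0.05,
) -> Pathway:
    """Fill a pathway skeleton with per-step effects for ``trait``.

    Step effects telescope: they sum exactly to
    log10(derived mean) - log10(ancestral mean).
    """
    table.require_full_hypercube(trait)
    current = Genotype.ancestral(table.sites)
    steps = []
    for label in pathway.order:
        eff = mutation_effect(table, label, current, trait, alpha=alpha)
        nxt = current.toggled(label)
        steps.append(PathwayStep(current, nxt, eff))
        current = nxt
    return Pathway(order=pathway.order, steps=tuple(steps))


def rank_largest_effect(
    table: GenotypePhenotypeTable,
    trait: str,
    direction: str = "decrease",
    alpha: float = 0.05,
    tie_tol: float = 1e-12,
) -> RankSummary:
    """Largest-effect step per forward pathway, with per-site counts.

    ``direction`` declares what "largest" means: ``'decrease'`` picks the
    most negative delta_log10 per pathway, ``'increase'`` the most
    positive.  Ties within ``tie_tol`` list every tied site and flag the
    pathway; tied pathways contribute to no site's count.
    """
    if direction not in ("decrease", "increase"):
        raise InvalidParameterError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "decrease" else 1.0
    summary = RankSummary(counts={s.label: 0 for s in table.sites})
    for skeleton in enumerate_pathways(table.sites):
        pw = pathway_trajectory(table, skeleton, trait, alpha=alpha)
        scores = [sign * s.effect.delta_log10 for s in pw.steps]
        best = max(scores)
        tied = tuple(
            s.effect.site
            for s, sc in zip(pw.steps, scores)
            if best - sc <= tie_tol
        )
        summary.winners.append((pw, tied))
        if len(tied) == 1:
            summary.counts[tied[0]] += 1
        else:
            summary.tied_pathways += 1
    return summary


def effects_on_all_backgrounds(
    table: GenotypePhenotypeTable,
    site: str,
    trait: str,
    alpha: float = 0.05,
) -> list[MutationEffect]:
    """One effect per combination of states at the other k-1 sites."""
    table.require_full_hypercube(trait)
    effects = []
    for g in enumerate_genotypes(table.sites):
        if not g.is_derived_at(site):
            effects.append(mutation_effect(table, site, g, trait, alpha=alpha))
    return effects


def reversion_symmetry(
    table: GenotypePhenotypeTable,
    site: str,
    trait: str,
) -> list[ReversionPair]:
    """Forward/reverse effect pairs for ``site`` across background pairs.

    For every unordered pair of distinct backgrounds (b1, b2) the forward
    delta on b1 is paired with the reversion delta (the negated forward
    delta) on b2.  On an additive landscape every asymmetry index is 0.
    """
    table.require_full_hypercube(trait)
    backgrounds = [
        g for g in enumerate_genotypes(table.sites) if not g.is_derived_at(site)
    ]
    fwd = {
        g.code: mutation_effect(table, site, g, trait).delta_log10
        for g in backgrounds
    }
    pairs = []
    for b1, b2 in itertools.combinations(backgrounds, 2):
        pairs.append(
            ReversionPair(
                site=site,
                background_fwd=b1,
                background_rev=b2.toggled(site),
                forward_delta_log10=fwd[b1.code],
                reverse_delta_log10=-fwd[b2.code],
            )
        )
    return pairs


def double_mutant_cycle(
    table: GenotypePhenotypeTable,
    site_a: str,
    site_b: str,
    fixed_background: Mapping[str, str],
    trait: str,
) -> DoubleMutantCycle:
    """Four-corner epistasis for ``site_a`` x ``site_b``.

    ``fixed_background`` maps every remaining site label to its held
    state.  epistasis_log10 = [log10(AB) - log10(aB)] - [log10(Ab) - log10(ab)]
    where lower-case is ancestral and upper-case derived; a is site_a's
    state, b site_b's.
    """
    if site_a == site_b:
        raise InvalidSitesError("site_a and site_b must differ")
    by_label = {s.label: s for s in table.sites}
    for s in (site_a, site_b):
        if s not in by_label:
            raise MissingDataError(f"no site labelled {s!r}")
    others = [s for s in table.sites if s.label not in (site_a, site_b)]
    if set(fixed_background) != {s.label for s in others}:
        raise InvalidSitesError(
            f"fixed_background must give states for exactly {[s.label for s in others]}"
        )

    def corner(a_derived: bool, b_derived: bool) -> tuple[str, float]:
        states = []
        for s in table.sites:
            if s.label == site_a:
                states.append(s.derived if a_derived else s.ancestral)
            elif s.label == site_b:
                states.append(s.derived if b_derived else s.ancestral)
            else:
                states.append(fixed_background[s.label])
        code = Genotype(table.sites, tuple(states)).code
        mean = table.mean(code, trait)
        if mean <= 0:
            raise InvalidParameterError(
                f"trait {trait!r} must be positive at corner {code!r}"
            )
        return (code, mean)

    ab = corner(False, False)
    Ab = corner(True, False)
    aB = corner(False, True)
    AB = corner(True, True)
    epi = (math.log10(AB[1]) - math.log10(aB[1])) - (
        math.log10(Ab[1]) - math.log10(ab[1])
    )
    return DoubleMutantCycle(
        site_a=site_a,
        site_b=site_b,
        fixed_background=tuple(sorted(fixed_background.items())),
        corner_ab=ab,
        corner_Ab=Ab,
        corner_aB=aB,
        corner_AB=AB,
        epistasis_log10=epi,
    )


def interaction_decomposition(
    table: GenotypePhenotypeTable, trait: str
) -> dict[tuple[str, ...], float]:
    """Exact 2**k interaction decomposition of log10 trait means.

    Solves log10(y(g)) = b0 + sum over non-empty site subsets S of
    e_S * prod_{i in S} x_i for the full coefficient vector (x_i = 1 when
    derived).  Keys are tuples of site labels; () is the baseline.
    Exact linear solve, so it doubles as an oracle for cycle epistasis.
    """
    table.require_full_hypercube(trait)
    sites = table.sites
    k = len(sites)
    if k > 12:
        raise SizeLimitError("decomposition limited to k <= 12")
    subsets = [()] + [
        tuple(c)
        for r in range(1, k + 1)
        for c in itertools.combinations(range(k), r)
    ]
    gts = enumerate_genotypes(sites)
    X = np.zeros((len(gts), len(subsets)))
    y = np.zeros(len(gts))
    for row, g in enumerate(gts):
        bits = [1 if g.is_derived_at(s.label) else 0 for s in sites]
        for col, sub in enumerate(subsets):
            X[row, col] = np.prod([bits[i] for i in sub]) if sub else 1.0
        mean = table.mean(g.code, trait)
        if mean <= 0:
            raise InvalidParameterError(f"non-positive mean at {g.code!r}")
        y[row] = math.log10(mean)
    beta = np.linalg.solve(X, y)
    return {
        tuple(sites[i].label for i in sub): float(b)
        for sub, b in zip(subsets, beta)
    }
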