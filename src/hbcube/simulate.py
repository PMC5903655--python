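"""Synthetic-data generation with planted ground truth.

Every generator is driven by a single integer seed plus a validated
config and is bit-reproducible: identical (config, seed) pairs yield
identical outputs.  Each generator returns its ground truth alongside
the data so recovery tests can close the loop without external files.

Defaults mirror the bundled reference dataset: 5-8 equilibration steps
and triplicates for saturation curves, 90-hour autoxidation series, and
the reference autoxidation/P50 values as planted rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from . import datasets
from .ancestry import PhyloTree, SiteStateMatrix
from .errors import ConfigError
from .kinetics import KineticTrace
from .landscape import GenotypePhenotypeTable, Genotype, SiteDef, enumerate_genotypes
from .oxyfit import EffectorTreatment, SaturationCurve, hill_saturation

__all__ = [
    "SaturationConfig",
    "KineticsConfig",
    "AutoxidationConfig",
    "LandscapeConfig",
    "TreeConfig",
    "SimulationConfig",
    "SimulatedCurves",
    "SimulatedTraces",
    "SimulatedLandscape",
    "SimulatedTree",
    "gen_saturation_curves",
    "gen_kinetic_traces",
    "gen_autoxidation_series",
    "gen_landscape",
    "gen_site_state_matrix",
]

_REF_P50 = {code: row[0] for code, row in datasets.ALPHA_ROWS.items()} | {
    code: row[0] for code, row in datasets.BETA_ROWS.items() if code != "TD"
}
_REF_KAUTO = {code: row[5] for code, row in datasets.ALPHA_ROWS.items()} | {
    code: row[5] for code, row in datasets.BETA_ROWS.items() if code != "TD"
}


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SaturationConfig(_Forbid):
    """Hill-curve generator settings (log-spaced PO2 spanning p50/8..8*p50)."""

    genotypes: list[str] = list(_REF_P50)
    p50_torr: list[float] = list(_REF_P50.values())
    n50: list[float] | float = 2.4
    steps: int = 8
    noise_sd: float = 0.01
    replicates: int = 3
    treatment: str = "stripped"

    @field_validator("steps")
    @classmethod
    def _steps_range(cls, v: int) -> int:
        if not 3 <= v <= 16:
            raise ValueError(f"steps must be in [3, 16], got {v}")
        return v

    @field_validator("noise_sd")
    @classmethod
    def _sd(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
        return v


class KineticsConfig(_Forbid):
    """Stopped-flow monoexponential decay generator (seconds)."""

    genotypes: list[str] = ["A", "B", "C"]
    rates: list[float] = [2.0, 1.0, 0.5]
    offset: float = 0.1
    amplitude: float = 0.5
    duration: float = 3.0
    points: int = 50
    noise_sd: float = 0.005
    replicates: int = 3


class AutoxidationConfig(_Forbid):
    """A541/A630 ratio decay generator (hours, 90 h default span)."""

    genotypes: list[str] = list(_REF_KAUTO)
    rates: list[float] = list(_REF_KAUTO.values())
    offset: float = 0.2
    amplitude: float = 1.0
    duration_h: float = 90.0
    interval_h: float = 1.0
    noise_sd: float = 0.01
    replicates: int = 3


class LandscapeConfig(_Forbid):
    """Additive-plus-epistatic log10 landscape over 2-4+ biallelic sites.

    ``effects`` maps site label -> additive log10 effect; ``epistasis``
    maps '*'-joined label tuples (e.g. ``"alpha18*alpha63"``) -> an
    interaction coefficient of any order >= 2.
    """

    sites: list[tuple[str, str, str]] = list(datasets.ALPHA_SITES)
    baseline_log10: float = math.log10(4.30)
    effects: dict[str, float] = {
        "alpha18": -0.0336,
        "alpha63": -0.0676,
        "alpha119": -0.0857,
    }
    epistasis: dict[str, float] = {}
    sem: float = 0.0
    replicates: int = 3
    trait: str = "p50_stripped"

    def site_defs(self) -> tuple[SiteDef, ...]:
        return tuple(SiteDef(*s) for s in self.sites)

    def terms(self) -> dict[tuple[str, ...], float]:
        labels = {s[0] for s in self.sites}
        out: dict[tuple[str, ...], float] = {}
        for key, coef in self.epistasis.items():
            parts = tuple(key.split("*"))
            if len(parts) < 2 or len(set(parts)) != len(parts) or not set(
                parts
            ) <= labels:
                raise ConfigError(f"bad epistasis key {key!r}")
            out[parts] = coef
        for label in self.effects:
            if label not in labels:
                raise ConfigError(f"effect for unknown site {label!r}")
        return out


class TreeConfig(_Forbid):
    """Random rooted tree with planted single-origin site substitutions."""

    tips: int = 12
    sites: list[str] = ["s1", "s2", "s3"]
    substitutions_per_site: int = 1
    ancestral_state: str = "A"
    derived_state: str = "S"


class SimulationConfig(_Forbid):
    """Top-level config; the seed is mandatory and drives every stream."""

    seed: int
    saturation: SaturationConfig = SaturationConfig()
    kinetics: KineticsConfig = KineticsConfig()
    autoxidation: AutoxidationConfig = AutoxidationConfig()
    landscape: LandscapeConfig = LandscapeConfig()
    tree: TreeConfig = TreeConfig()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCurves:
    curves: list[SaturationCurve]
    truth: dict[str, tuple[float, float]]  # genotype -> (p50, n50)
    clipped_points: int = 0


@dataclass
class SimulatedTraces:
    traces: list[KineticTrace]
    truth: dict[str, float]  # genotype -> rate


@dataclass
class SimulatedLandscape:
    table: GenotypePhenotypeTable
    true_log10: dict[str, float]  # genotype code -> noiseless log10 trait
    terms: dict[tuple[str, ...], float]
    baseline_log10: float
    effects: dict[str, float]


@dataclass
class SimulatedTree:
    tree: PhyloTree
    matrix: SiteStateMatrix
    truth: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # site -> [(branch child label, from state, to state)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_saturation_curves(config: SimulationConfig) -> SimulatedCurves:
    """Noisy Hill curves at log-spaced PO2 spanning [p50/8, 8*p50]."""
    cfg = config.saturation
    if len(cfg.p50_torr) != len(cfg.genotypes):
        raise ConfigError("p50_torr and genotypes must have equal length")
    n50s = (
        [float(cfg.n50)] * len(cfg.genotypes)
        if isinstance(cfg.n50, (int, float))
        else list(cfg.n50)
    )
    if len(n50s) != len(cfg.genotypes):
        raise ConfigError("n50 list and genotypes must have equal length")
    rng = _rng(config, 1)
    treatment = EffectorTreatment(label=cfg.treatment) if cfg.treatment == "stripped" else None
    if treatment is None:
        kw = {}
        if "KCl" in cfg.treatment:
            kw["kcl_molar"] = 0.1
        if "IHP" in cfg.treatment:
            kw["ihp_ratio"] = 2.0
        treatment = EffectorTreatment(label=cfg.treatment, **kw)
    curves, truth, clipped = [], {}, 0
    for genotype, p50, n50 in zip(cfg.genotypes, cfg.p50_torr, n50s):
        truth[genotype] = (p50, n50)
        po2 = np.geomspace(p50 / 8.0, p50 * 8.0, cfg.steps)
        clean = hill_saturation(po2, p50, n50)
        for rep in range(1, cfg.replicates + 1):
            sat = clean + rng.normal(0.0, cfg.noise_sd, size=po2.size)
            lo, hi = sat < 0.0, sat > 1.0
            clipped += int(lo.sum() + hi.sum())
            sat = np.clip(sat, 0.0, 1.0)
            curves.append(
                SaturationCurve(
                    genotype=genotype,
                    treatment=treatment,
                    po2_torr=tuple(po2),
                    saturation=tuple(sat),
                    replicate_id=f"r{rep}",
                )
            )
    return SimulatedCurves(curves=curves, truth=truth, clipped_points=clipped)


def _gen_decays(
    genotypes: Sequence[str],
    rates: Sequence[float],
    times: np.ndarray,
    offset: float,
    amplitude: float,
    noise_sd: float,
    replicates: int,
    kind: str,
    rng: np.random.Generator,
) -> SimulatedTraces:
    if len(rates) != len(genotypes):
        raise ConfigError("rates and genotypes must have equal length")
    traces, truth = [], {}
    for genotype, rate in zip(genotypes, rates):
        truth[genotype] = rate
        clean = offset + amplitude * np.exp(-rate * times)
        for rep in range(1, replicates + 1):
            values = clean + rng.normal(0.0, noise_sd, size=times.size)
            traces.append(
                KineticTrace(
                    genotype=genotype,
                    kind=kind,
                    times=tuple(times),
                    values=tuple(values),
                    replicate_id=f"r{rep}",
                )
            )
    return SimulatedTraces(traces=traces, truth=truth)


def gen_kinetic_traces(config: SimulationConfig) -> SimulatedTraces:
    """Stopped-flow style monoexponential decays (time in seconds)."""
    cfg = config.kinetics
    times = np.linspace(0.0, cfg.duration, cfg.points)
    return _gen_decays(
        cfg.genotypes, cfg.rates, times, cfg.offset, cfg.amplitude,
        cfg.noise_sd, cfg.replicates, "dissociation", _rng(config, 2),
    )


def gen_autoxidation_series(config: SimulationConfig) -> SimulatedTraces:
    """Decaying absorbance-ratio series sampled over ``duration_h`` hours."""
    cfg = config.autoxidation
    n = int(round(cfg.duration_h / cfg.interval_h)) + 1
    times = np.arange(n, dtype=float) * cfg.interval_h
    return _gen_decays(
        cfg.genotypes, cfg.rates, times, cfg.offset, cfg.amplitude,
        cfg.noise_sd, cfg.replicates, "autoxidation", _rng(config, 3),
    )


def gen_landscape(config: SimulationConfig) -> SimulatedLandscape:
    """Full 2^k table from a log10-additive model plus interaction terms.

    log10 y(g) = baseline + sum effects[i]*x_i + sum terms[S]*prod x_i
    with replicate-level Gaussian(0, sem) noise on the log10 scale; means
    and SEMs are computed from the replicates (exact at sem = 0).
    """
    cfg = config.landscape
    sites = cfg.site_defs()
    terms = cfg.terms()
    rng = _rng(config, 4)
    table = GenotypePhenotypeTable(sites, [cfg.trait])
    true_log10 = {}
    for g in enumerate_genotypes(sites):
        bits = {s.label: g.is_derived_at(s.label) for s in sites}
        log_y = cfg.baseline_log10
        log_y += sum(e for lab, e in cfg.effects.items() if bits.get(lab))
        log_y += sum(c for labs, c in terms.items() if all(bits[l] for l in labs))
        true_log10[g.code] = log_y
        if cfg.sem > 0:
            reps = 10.0 ** (log_y + rng.normal(0.0, cfg.sem, size=cfg.replicates))
            mean = float(reps.mean())
            sem = float(reps.std(ddof=1) / math.sqrt(cfg.replicates))
            table.set_value(g.code, cfg.trait, mean, sem, cfg.replicates)
        else:
            table.set_value(g.code, cfg.trait, 10.0**log_y, 0.0, cfg.replicates)
    return SimulatedLandscape(
        table=table,
        true_log10=true_log10,
        terms=terms,
        baseline_log10=cfg.baseline_log10,
        effects=dict(cfg.effects),
    )


def _random_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random rooted binary topology over tips t1..tN."""
    nodes = [f"t{i + 1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def gen_site_state_matrix(config: SimulationConfig) -> SimulatedTree:
    """Random rooted tree with planted single-origin substitutions.

    Each site receives at most one substitution, planted on a uniformly
    chosen branch that is not adjacent to the root (root-adjacent
    placements are ambiguous under parsimony on a bifurcating root, so
    they are excluded to keep the planted history recoverable).  With
    ``substitutions_per_site = 0`` the matrix is invariant.
    """
    cfg = config.tree
    if cfg.tips < 4:
        raise ConfigError("need >= 4 tips to plant recoverable substitutions")
    if cfg.substitutions_per_site not in (0, 1):
        raise ConfigError("substitutions_per_site must be 0 or 1")
    if cfg.ancestral_state == cfg.derived_state:
        raise ConfigError("ancestral and derived states must differ")
    rng = _rng(config, 5)
    tree = PhyloTree.from_newick(_random_newick(cfg.tips, rng))

    root = tree.tree.seed_node
    candidates = []  # nodes whose stem branch can host a recoverable change
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None or node.parent_node is root:
            continue
        candidates.append(node)

    states: dict[str, dict[str, str]] = {t: {} for t in tree.tip_labels}
    truth: dict[str, list[tuple[str, str, str]]] = {}
    for site in cfg.sites:
        for tip in tree.tip_labels:
            states[tip][site] = cfg.ancestral_state
        truth[site] = []
        if cfg.substitutions_per_site == 1:
            node = candidates[int(rng.integers(len(candidates)))]
            for leaf in node.leaf_iter():
                states[leaf.taxon.label][site] = cfg.derived_state
            truth[site].append(
                (tree.node_label(node), cfg.ancestral_state, cfg.derived_state)
            )
    return SimulatedTree(
        tree=tree, matrix=SiteStateMatrix(states), truth=truth
    )
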