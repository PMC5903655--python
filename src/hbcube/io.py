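"""File formats and pipeline configuration.

CSV dialects (UTF-8, header required, dot decimal, ``#`` comment lines):

- saturation (long form): genotype, treatment, replicate, po2_torr, saturation
- kinetic traces: genotype, kind, replicate, time, value
- genotype-phenotype: genotype_code, trait, mean, sem, n
- site-state matrix: taxon column + one column per site

Every output file starts with comment lines recording the package
version, the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .ancestry import PhyloTree, SiteStateMatrix
from .errors import ConfigError, ParseError
from .kinetics import KineticTrace
from .landscape import GenotypePhenotypeTable, SiteDef
from .oxyfit import EffectorTreatment, SaturationCurve, TREATMENT_LABELS

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "output_header",
    "read_csv",
    "write_csv",
    "read_saturation_csv",
    "write_saturation_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_gp_csv",
    "write_gp_csv",
    "read_site_matrix_csv",
    "write_site_matrix_csv",
    "read_tree",
    "write_tree",
]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    sites: list[tuple[str, str, str]] = []  # (label, ancestral, derived)
    seed: int = 0
    alpha: float = 0.05
    convention: str = "all-hypercube-edges"
    trait: str = "p50_stripped"
    pleiotropy_traits: list[str] = ["k_auto"]
    direction: str = "decrease"
    time_unit: str = "h"
    # input paths (any subset; stages lacking inputs are skipped)
    gp_csv: str | None = None
    saturation_csv: str | None = None
    traces_csv: str | None = None
    tree_newick: str | None = None
    site_matrix_csv: str | None = None
    ancestor_node: str | None = None

    def site_defs(self) -> tuple[SiteDef, ...]:
        return tuple(SiteDef(*s) for s in self.sites)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_hash(config: BaseModel | dict) -> str:
    """Short stable hash of a configuration object."""
    payload = config.model_dump() if isinstance(config, BaseModel) else config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(seed: int | None = None, cfg_hash: str = "") -> str:
    lines = [f"# hbcube {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash:
        lines.append(f"# config: {cfg_hash}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# generic CSV plumbing
# ---------------------------------------------------------------------------

def read_csv(
    path: str | Path, required: Sequence[str], warn_extra: bool = True
) -> pd.DataFrame:
    """Read a CSV, skipping ``#`` comments, validating required columns.

    Extra columns are preserved with a warning; a missing column or an
    empty/unreadable file raises :class:`ParseError` naming the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    extra = [c for c in df.columns if c not in required]
    if extra and warn_extra:
        warnings.warn(f"{path}: extra column(s) preserved: {extra}", stacklevel=2)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(output_header(seed, cfg_hash))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# saturation curves
# ---------------------------------------------------------------------------

def _treatment(label: str) -> EffectorTreatment:
    if label not in TREATMENT_LABELS:
        raise ParseError(f"unknown treatment {label!r}; expected {TREATMENT_LABELS}")
    kw = {}
    if label in ("KCl", "KCl+IHP"):
        kw["kcl_molar"] = 0.1
    if label in ("IHP", "KCl+IHP"):
        kw["ihp_ratio"] = 2.0
    return EffectorTreatment(label=label, **kw)


def read_saturation_csv(path: str | Path) -> list[SaturationCurve]:
    df = read_csv(path, ["genotype", "treatment", "replicate", "po2_torr", "saturation"])
    curves = []
    for (gt, tr, rep), grp in df.groupby(
        ["genotype", "treatment", "replicate"], sort=True
    ):
        grp = grp.sort_values("po2_torr")
        curves.append(
            SaturationCurve(
                genotype=str(gt),
                treatment=_treatment(str(tr)),
                po2_torr=tuple(grp["po2_torr"].astype(float)),
                saturation=tuple(grp["saturation"].astype(float)),
                replicate_id=str(rep),
            )
        )
    return curves


def write_saturation_csv(
    curves: Sequence[SaturationCurve],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    rows = [
        {
            "genotype": c.genotype,
            "treatment": c.treatment.label,
            "replicate": c.replicate_id,
            "po2_torr": p,
            "saturation": s,
        }
        for c in curves
        for p, s in zip(c.po2_torr, c.saturation)
    ]
    write_csv(pd.DataFrame(rows), path, seed, cfg_hash)


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------

def read_trace_csv(path: str | Path) -> list[KineticTrace]:
    df = read_csv(path, ["genotype", "kind", "replicate", "time", "value"])
    traces = []
    for (gt, kind, rep), grp in df.groupby(["genotype", "kind", "replicate"], sort=True):
        grp = grp.sort_values("time")
        traces.append(
            KineticTrace(
                genotype=str(gt),
                kind=str(kind),
                times=tuple(grp["time"].astype(float)),
                values=tuple(grp["value"].astype(float)),
                replicate_id=str(rep),
            )
        )
    return traces


def write_trace_csv(
    traces: Sequence[KineticTrace],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    rows = [
        {
            "genotype": t.genotype,
            "kind": t.kind,
            "replicate": t.replicate_id,
            "time": ti,
            "value": v,
        }
        for t in traces
        for ti, v in zip(t.times, t.values)
    ]
    write_csv(pd.DataFrame(rows), path, seed, cfg_hash)


# ---------------------------------------------------------------------------
# genotype-phenotype tables
# ---------------------------------------------------------------------------

def read_gp_csv(path: str | Path, sites: Sequence[SiteDef]) -> GenotypePhenotypeTable:
    df = read_csv(path, ["genotype_code", "trait", "mean", "sem", "n"])
    table = GenotypePhenotypeTable(sites)
    for i, row in df.iterrows():
        sem = None if pd.isna(row["sem"]) else float(row["sem"])
        try:
            table.set_value(
                str(row["genotype_code"]),
                str(row["trait"]),
                float(row["mean"]),
                sem,
                int(row["n"]),
            )
        except Exception as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return table


def write_gp_csv(
    table: GenotypePhenotypeTable,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    rows = []
    for code in table.genotypes:
        for trait in table.traits:
            try:
                tv = table.value(code, trait)
            except KeyError:
                continue
            rows.append(
                {
                    "genotype_code": code,
                    "trait": trait,
                    "mean": tv.mean,
                    "sem": "" if tv.sem is None else tv.sem,
                    "n": tv.n,
                }
            )
    write_csv(pd.DataFrame(rows), path, seed, cfg_hash)


# ---------------------------------------------------------------------------
# trees and site-state matrices
# ---------------------------------------------------------------------------

def read_site_matrix_csv(path: str | Path) -> SiteStateMatrix:
    # every non-taxon column is a site, so extra columns are expected
    df = read_csv(path, ["taxon"], warn_extra=False)
    return SiteStateMatrix.from_dataframe(df)


def write_site_matrix_csv(
    matrix: SiteStateMatrix,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "",
) -> None:
    write_csv(matrix.to_dataframe().reset_index(), path, seed, cfg_hash)


def read_tree(path: str | Path) -> PhyloTree:
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    try:
        return PhyloTree.from_newick(text)
    except Exception as exc:
        raise ParseError(f"{path}: invalid newick: {exc}") from exc


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(tree.to_newick() + "\n")
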