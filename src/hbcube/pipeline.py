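"""Pipeline orchestration: staged analysis and the plain-text report.

Stages: fit O2 equilibria -> fit kinetics -> landscape (effects,
pathways, cycles) -> ancestry -> pleiotropy.  Stages whose inputs are
not configured are skipped; any stage error aborts the run (the CLI
turns that into a nonzero exit).
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, io, kinetics, landscape, oxyfit, pleiotropy
from .errors import HbcubeError
from .io import PipelineConfig

logger = logging.getLogger("hbcube")

__all__ = ["run_pipeline", "fit_equilibria", "fit_kinetics_stage", "build_report"]


def _meta(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "cfg_hash": io.config_hash(config)}


def fit_equilibria(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Fit every saturation curve; write per-replicate fits and a
    per-genotype summary (stripped P50 +/- SEM and anion sensitivities)."""
    curves = io.read_saturation_csv(config.saturation_csv)
    fits = [oxyfit.fit_hill(c) for c in curves]
    fit_rows = [
        {
            "genotype": f.genotype,
            "treatment": f.treatment,
            "replicate": f.replicate_id,
            "p50_torr": f.p50_torr,
            "n50": f.n50,
            "p50_se": f.p50_se,
            "n50_se": f.n50_se,
            "r_squared": f.r_squared,
            "converged": f.converged,
        }
        for f in fits
    ]
    io.write_csv(pd.DataFrame(fit_rows), out_dir / "hill_fits.csv", **_meta(config))

    by_gt: dict[str, dict[str, list[oxyfit.HillFit]]] = defaultdict(lambda: defaultdict(list))
    for f in fits:
        by_gt[f.genotype][f.treatment].append(f)
    rows = []
    for genotype in sorted(by_gt):
        summaries = {
            tr: oxyfit.summarize_replicates(fs) for tr, fs in by_gt[genotype].items()
        }
        row: dict = {"genotype": genotype}
        if "stripped" in summaries:
            s = summaries["stripped"]
            row["p50_stripped"] = s.mean_p50
            row["p50_se"] = s.sem_p50 if s.sem_p50 is not None else np.nan
            row["n50_stripped"] = s.mean_n50
            for tr, col in (
                ("KCl", "dlog_kcl"),
                ("IHP", "dlog_ihp"),
                ("KCl+IHP", "dlog_kcl_ihp"),
            ):
                if tr in summaries:
                    row[col] = oxyfit.anion_sensitivity(
                        s.mean_p50, summaries[tr].mean_p50, tr
                    ).delta_log_p50
        rows.append(row)
    summary = pd.DataFrame(rows)
    io.write_csv(summary, out_dir / "p50_summary.csv", **_meta(config))
    return summary


def fit_kinetics_stage(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Fit every kinetic trace; write per-trace fits and per-genotype rates."""
    traces = io.read_trace_csv(config.traces_csv)
    fits = [kinetics.fit_monoexponential(t) for t in traces]
    fit_rows = [
        {
            "genotype": f.genotype,
            "kind": f.kind,
            "replicate": f.replicate_id,
            "rate": f.rate,
            "rate_se": f.rate_se,
            "amplitude": f.amplitude,
            "offset": f.offset,
            "half_life": f.half_life,
            "r_squared": f.r_squared,
            "time_unit": f.time_unit,
            "low_quality": f.low_quality,
            "sign_error": f.sign_error,
            "unit_note": f.unit_note,
        }
        for f in fits
    ]
    io.write_csv(pd.DataFrame(fit_rows), out_dir / "kinetic_fits.csv", **_meta(config))

    by_key: dict[tuple[str, str], list[kinetics.KineticFit]] = defaultdict(list)
    for f in fits:
        by_key[(f.genotype, f.kind)].append(f)
    rows = []
    for (genotype, kind), fs in sorted(by_key.items()):
        mean, sem, n = kinetics.summarize_rates(fs)
        rows.append(
            {
                "genotype": genotype,
                "kind": kind,
                "rate": mean,
                "sem": np.nan if sem is None else sem,
                "n": n,
                "time_unit": fs[0].time_unit,
            }
        )
    summary = pd.DataFrame(rows)
    io.write_csv(summary, out_dir / "rate_summary.csv", **_meta(config))
    auto = summary[summary["kind"] == "autoxidation"]
    if not auto.empty:
        io.write_csv(
            auto.rename(columns={"rate": "k_auto_per_h"})[
                ["genotype", "k_auto_per_h", "sem"]
            ],
            out_dir / "k_auto_summary.csv",
            **_meta(config),
        )
    return summary


def landscape_stage(
    config: PipelineConfig,
    table: landscape.GenotypePhenotypeTable,
    out_dir: Path,
) -> dict:
    """Effects on all backgrounds, pathway trajectories, winner counts and
    all double-mutant cycles for the configured trait."""
    sites = table.sites
    trait = config.trait
    results: dict = {}

    effect_rows = []
    for site in sites:
        for eff in landscape.effects_on_all_backgrounds(
            table, site.label, trait, alpha=config.alpha
        ):
            effect_rows.append(
                {
                    "site": eff.site,
                    "from": eff.from_code,
                    "to": eff.to_code,
                    "delta_log10": eff.delta_log10,
                    "percent_change": eff.percent_change,
                    "welch_t": eff.welch_t,
                    "welch_df": eff.welch_df,
                    "p_value": eff.p_value,
                    "significant": eff.significant,
                }
            )
    io.write_csv(pd.DataFrame(effect_rows), out_dir / "effects.csv", **_meta(config))
    results["effects"] = effect_rows

    summary = landscape.rank_largest_effect(
        table, trait, direction=config.direction, alpha=config.alpha
    )
    results["winner_counts"] = summary.counts
    results["tied_pathways"] = summary.tied_pathways
    path_rows = []
    for pw, winners in summary.winners:
        for step_idx, step in enumerate(pw.steps, start=1):
            path_rows.append(
                {
                    "pathway": "->".join(pw.order),
                    "step": step_idx,
                    "from": step.from_genotype.code,
                    "to": step.to_genotype.code,
                    "site": step.effect.site,
                    "delta_log10": step.effect.delta_log10,
                    "percent_change": step.effect.percent_change,
                    "p_value": step.effect.p_value,
                    "winner": step.effect.site in winners,
                }
            )
    io.write_csv(pd.DataFrame(path_rows), out_dir / "pathways.csv", **_meta(config))

    cycle_rows = []
    labels = [s.label for s in sites]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            others = [s for s in sites if s.label not in (labels[i], labels[j])]
            for states in itertools.product(
                *[(s.ancestral, s.derived) for s in others]
            ):
                background = dict(zip([s.label for s in others], states))
                cyc = landscape.double_mutant_cycle(
                    table, labels[i], labels[j], background, trait
                )
                cycle_rows.append(
                    {
                        "site_a": cyc.site_a,
                        "site_b": cyc.site_b,
                        "background": ";".join(f"{k}={v}" for k, v in cyc.fixed_background),
                        "ab": cyc.corner_ab[0],
                        "Ab": cyc.corner_Ab[0],
                        "aB": cyc.corner_aB[0],
                        "AB": cyc.corner_AB[0],
                        "epistasis_log10": cyc.epistasis_log10,
                        "compensation_ratio": cyc.compensation_ratio,
                    }
                )
    io.write_csv(pd.DataFrame(cycle_rows), out_dir / "cycles.csv", **_meta(config))
    results["cycles"] = cycle_rows
    return results


def ancestry_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Parsimony reconstruction and per-branch substitution assignment."""
    tree = io.read_tree(config.tree_newick)
    matrix = io.read_site_matrix_csv(config.site_matrix_csv)
    recon = ancestry.reconstruct_all(tree, matrix)
    branches = ancestry.assign_branches(recon)
    rows = []
    for branch, events in sorted(branches.items()):
        for ev in events:
            sub = ev.substitution
            rows.append(
                {
                    "branch": branch,
                    "site": ev.site,
                    "from": "/".join(sorted(ev.from_states)),
                    "to": "/".join(sorted(ev.to_states)),
                    "certain": ev.certain,
                    "resolved": ev.resolved,
                    "substitution": f"{sub[0]}->{sub[1]}" if sub else "",
                }
            )
    io.write_csv(
        pd.DataFrame(rows, columns=[
            "branch", "site", "from", "to", "certain", "resolved", "substitution",
        ]),
        out_dir / "branch_substitutions.csv",
        **_meta(config),
    )

    # annotated newick: '#<count>' suffixed to the child label of each branch
    counts = {b: sum(1 for e in evs if e.resolved) for b, evs in branches.items()}
    annotated = ancestry.PhyloTree.from_newick(tree.to_newick())
    for node in annotated.tree.preorder_node_iter():
        label = annotated.node_label(node)
        if counts.get(label):
            new = f"{label}#{counts[label]}"
            if node.is_leaf():
                node.taxon.label = new
            else:
                node.label = new
    Path(out_dir, "annotated_tree.nwk").write_text(annotated.to_newick() + "\n")

    result = {"branch_counts": counts, "recon": recon}
    if config.ancestor_node:
        try:
            result["ancestor_states"] = {
                site: ancestry.ancestral_states(recon, config.ancestor_node, [site])
                for site in matrix.sites
            }
        except HbcubeError as exc:
            logger.warning("ancestor node query failed: %s", exc)
    return result


def pleiotropy_stage(
    config: PipelineConfig,
    table: landscape.GenotypePhenotypeTable,
    out_dir: Path,
) -> list[pleiotropy.CorrelationResult]:
    results = pleiotropy.correlation_screen(
        table, config.trait, config.pleiotropy_traits, conventions=[config.convention]
    )
    rows = [
        {
            "trait_x": r.trait_x,
            "trait_y": r.trait_y,
            "convention": r.convention,
            "r": r.r,
            "n": r.n,
            "p_value": r.p_value,
        }
        for r in results
    ]
    io.write_csv(pd.DataFrame(rows), out_dir / "correlations.csv", **_meta(config))
    return results


def build_report(results: dict) -> str:
    """Plain-text restatement of the headline statistics."""
    lines = ["hbcube pipeline report", "=" * 22, ""]
    if "winner_counts" in results:
        lines.append("Largest-effect step per forward pathway (site: pathway count):")
        for site, count in results["winner_counts"].items():
            lines.append(f"  {site}: {count}")
        if results.get("tied_pathways"):
            lines.append(f"  tied pathways: {results['tied_pathways']}")
        lines.append("")
    if "effects" in results:
        lines.append("Per-background mutation effects (delta log10, % change):")
        for row in results["effects"]:
            lines.append(
                f"  {row['site']}: {row['from']} -> {row['to']}: "
                f"{row['delta_log10']:+.4f} ({row['percent_change']:+.1f}%)"
                + ("  *" if row["significant"] else "")
            )
        lines.append("")
    if "cycles" in results:
        lines.append("Double-mutant cycles (epistasis log10, compensation ratio):")
        for row in results["cycles"]:
            lines.append(
                f"  {row['site_a']} x {row['site_b']} | {row['background'] or '-'}: "
                f"{row['epistasis_log10']:+.4f} (AB/ab = {row['compensation_ratio']:.3f})"
            )
        lines.append("")
    if "branch_counts" in results:
        lines.append("Branch substitution counts (resolved):")
        for branch, count in sorted(results["branch_counts"].items()):
            lines.append(f"  {branch}: {count}")
        lines.append("")
    if "ancestor_states" in results:
        states = results["ancestor_states"]
        lines.append(
            "Ancestor node states: "
            + ", ".join(f"{s}={v}" for s, v in sorted(states.items()))
        )
        lines.append("")
    if "correlations" in results:
        lines.append("Trait correlations:")
        for r in results["correlations"]:
            lines.append(
                f"  {r.trait_x} vs {r.trait_y} [{r.convention}]: "
                f"r = {r.r:+.3f} (n = {r.n}, p = {r.p_value:.3f})"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage whose inputs are configured; write the report.

    Returns the collected results dict.  Raises (and therefore exits
    nonzero from the CLI) on any stage error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.saturation_csv:
        logger.info("stage: fit-equilibria")
        results["p50_summary"] = fit_equilibria(config, out_dir)
    if config.traces_csv:
        logger.info("stage: fit-kinetics")
        results["rate_summary"] = fit_kinetics_stage(config, out_dir)

    table = None
    if config.gp_csv:
        table = io.read_gp_csv(config.gp_csv, config.site_defs())
    if table is not None:
        logger.info("stage: landscape")
        results.update(landscape_stage(config, table, out_dir))
    if config.tree_newick and config.site_matrix_csv:
        logger.info("stage: ancestry")
        anc = ancestry_stage(config, out_dir)
        results["branch_counts"] = anc["branch_counts"]
        if "ancestor_states" in anc:
            results["ancestor_states"] = anc["ancestor_states"]
    if table is not None and config.pleiotropy_traits:
        logger.info("stage: pleiotropy")
        results["correlations"] = pleiotropy_stage(config, table, out_dir)

    report = build_report(results)
    report_path = out_dir / "report.txt"
    report_path.write_text(io.output_header(config.seed, io.config_hash(config)) + report)
    results["report"] = report
    return results
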