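"""One-shot analysis pipeline: observation CSVs (or a synthetic config)
to association matrices, metric tables, permutation tests and archival
outputs.

Each analysis group (e.g. West, East) is analyzed as a separate
network.  Per group the pipeline produces:

* the association matrix (labeled adjacency CSV);
* the thresholded SRI-weighted network (GraphML + edge-list CSV);
* the per-node metric table and per-species summary (CSV);
* network density, mean +/- SD association rates (overall, within
  species, mixed species) and average path lengths;
* a data-stream randomization test of the mean mixed-species SRI
  (directional, lower tail: are mixed associations rarer than expected
  under randomized membership?) plus the same test on the overall mean;
* four node-label permutation t-tests (degree, eigenvector,
  betweenness, clustering; capuchin-style species 1 minus species 2)
  flagged against the Bonferroni-adjusted significance level;
* a run log recording seed, settings, solitary-sample and
  never-identified-dyad counts, and the package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .association import (
    association_matrix,
    mean_association_rate,
    mixed_species,
    within_species,
)
from .metrics import (
    METRICS,
    average_path_length,
    build_network,
    density,
    node_metrics,
    species_summary,
)
from .observation import (
    IndividualRecord,
    PointSample,
    ValidationError,
    build_gbi,
    read_point_samples,
    read_roster,
    roster_by_group,
    solitary_count,
    write_network,
)
from .permutation import (
    bonferroni_adjust,
    network_randomization_test,
    node_label_permutation_test,
)
from .synthetic import SyntheticConfig, generate_roster, simulate_point_samples

log = logging.getLogger("groupnet")


@dataclasses.dataclass
class AnalysisConfig:
    roster_path: str | Path | None = None
    samples_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    groups: list[str] | None = None
    threshold: float = 0.0
    iterations: int = 1000
    burn_in: int = 1000
    swaps_per_iteration: int = 10
    seed: int | None = None
    alpha: float = 0.05
    comparisons: int = 4
    distance: str = "weight"
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        from_files = self.roster_path is not None and self.samples_path is not None
        if from_files == (self.synthetic is not None):
            raise ValidationError(
                "set either (roster_path and samples_path) or a synthetic config"
            )
        if self.seed is None:
            raise ValidationError("a seed is required for permutation tests")


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[list[IndividualRecord], list[PointSample]]:
    if config.synthetic is not None:
        roster = generate_roster(config.synthetic)
        samples = simulate_point_samples(roster, config.synthetic)
    else:
        roster = read_roster(config.roster_path)
        samples = read_point_samples(config.samples_path, roster)
    return roster, samples


def _result_json(obj):
    if isinstance(obj, dict):
        return {str(k): _result_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_result_json(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def analyze_group(
    group: str,
    roster: Sequence[IndividualRecord],
    samples: Sequence[PointSample],
    config: AnalysisConfig,
    seed: int,
    outdir: Path | None,
) -> dict:
    """Run the full per-group analysis; returns a JSON-ready dict."""
    members = {r.id for r in roster}
    group_samples = [s for s in samples if s.focal_id in members]
    if not group_samples:
        raise ValidationError(f"group {group!r}: no point samples")
    stray = sorted(
        {i for s in group_samples for i in s.party} - members
    )
    if stray:
        raise ValidationError(
            f"group {group!r}: party members outside the group roster: {stray}"
        )
    log.info("[%s] %d individuals, %d point samples (%d solitary)",
             group, len(members), len(group_samples), solitary_count(group_samples))

    gbi = build_gbi(group_samples, roster)
    matrix = association_matrix(gbi)
    if matrix.never_identified:
        log.info("[%s] %d never-identified dyads (SRI fixed at 0)",
                 group, len(matrix.never_identified))
    net = build_network(matrix, roster=roster, threshold=config.threshold)
    metrics = node_metrics(net, distance=config.distance)
    summary = species_summary(metrics)

    dens = density(net)
    rates = {
        "overall": mean_association_rate(matrix),
        "within_species": mean_association_rate(matrix, within_species),
        "mixed_species": mean_association_rate(matrix, mixed_species),
    }
    paths = {"overall": dataclasses.asdict(
        average_path_length(net, distance=config.distance))}
    for species in sorted({r.species for r in roster}):
        subset = [r.id for r in roster if r.species == species]
        try:
            paths[species] = dataclasses.asdict(
                average_path_length(net, subset=subset, distance=config.distance))
        except ValidationError:
            paths[species] = None

    species_map = {r.id: r.species for r in roster}

    def mean_mixed_sri(m) -> float:
        return mean_association_rate(m, mixed_species, species=species_map)[0]

    def mean_overall_sri(m) -> float:
        return mean_association_rate(m, species=species_map)[0]

    seeds = [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(6)]
    association_tests = {}
    for name, stat, s in (
        ("mixed_species_mean_sri", mean_mixed_sri, seeds[0]),
        ("overall_mean_sri", mean_overall_sri, seeds[1]),
    ):
        log.info("[%s] randomization test on %s ...", group, name)
        res = network_randomization_test(
            gbi, stat,
            iterations=config.iterations,
            burn_in=config.burn_in,
            swaps_per_iteration=config.swaps_per_iteration,
            seed=s,
        )
        association_tests[name] = res.summary()

    alpha_adj = bonferroni_adjust(config.alpha, config.comparisons)
    labels = metrics["species"].to_numpy()
    metric_tests = {}
    for metric, s in zip(METRICS, seeds[2:]):
        res = node_label_permutation_test(
            metrics[metric].to_numpy(dtype=float), labels,
            iterations=config.iterations, seed=s,
        )
        metric_tests[metric] = res.summary()
        metric_tests[metric]["significant_at_bonferroni"] = bool(
            res.p_two_tailed < alpha_adj
        )
        log.info("[%s] %s: observed difference %.4g, two-tailed p %.4g",
                 group, metric, res.observed, res.p_two_tailed)

    result = {
        "group": group,
        "n_individuals": len(members),
        "n_periods": gbi.n_periods,
        "n_solitary_samples": solitary_count(group_samples),
        "n_never_identified_dyads": len(matrix.never_identified),
        "density": dens,
        "mean_sri": {k: {"mean": v[0], "sd": v[1]} for k, v in rates.items()},
        "average_path_length": paths,
        "association_tests": association_tests,
        "metric_tests": metric_tests,
        "alpha": config.alpha,
        "alpha_bonferroni": alpha_adj,
        "species_summary": _result_json(summary.reset_index().to_dict("records")),
    }

    if outdir is not None:
        gdir = outdir / group
        gdir.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(gdir / "association_matrix.csv")
        write_network(net, gdir / "network.graphml", format="graphml")
        write_network(net, gdir / "edges.csv", format="edgelist")
        metrics.to_csv(gdir / "node_metrics.csv")
        summary.to_csv(gdir / "species_summary.csv")
    return result


def run_analysis(config: AnalysisConfig) -> dict:
    """Analyze every requested group; returns (and optionally writes) the bundle."""
    outdir = Path(config.outdir) if config.outdir is not None else None
    handler = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    try:
        log.info("groupnet %s, seed %s", __version__, config.seed)
        roster, samples = _load_inputs(config)
        by_group = roster_by_group(roster)
        groups = config.groups if config.groups is not None else sorted(by_group)
        unknown = [g for g in groups if g not in by_group]
        if unknown:
            raise ValidationError(f"groups not present in roster: {unknown}")
        results = {
            "version": __version__,
            "seed": config.seed,
            "settings": {
                "threshold": config.threshold,
                "iterations": config.iterations,
                "burn_in": config.burn_in,
                "swaps_per_iteration": config.swaps_per_iteration,
                "alpha": config.alpha,
                "comparisons": config.comparisons,
                "distance": config.distance,
            },
            "groups": {},
        }
        base = np.random.SeedSequence(config.seed)
        for child, group in zip(base.spawn(len(groups)), groups):
            seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            results["groups"][group] = analyze_group(
                group, by_group[group], samples, config, seed, outdir
            )
        results = _result_json(results)
        if outdir is not None:
            (outdir / "results.json").write_text(json.dumps(results, indent=2))
        return results
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()


def format_report(results: dict) -> str:
    """Human-readable summary of a results bundle."""
    lines = [f"groupnet {results['version']} (seed {results['seed']})"]
    for group, res in results["groups"].items():
        lines.append("")
        lines.append(
            f"Group {group}: {res['n_individuals']} individuals, "
            f"{res['n_periods']} sampling periods "
            f"({res['n_solitary_samples']} solitary)"
        )
        lines.append(f"  network density: {res['density']:.3f}")
        for key, label in (
            ("overall", "all dyads"),
            ("within_species", "within-species dyads"),
            ("mixed_species", "mixed-species dyads"),
        ):
            m = res["mean_sri"][key]
            lines.append(f"  mean SRI, {label}: {m['mean']:.3f} (SD {m['sd']:.3f})")
        t = res["association_tests"]["mixed_species_mean_sri"]
        lines.append(
            f"  mixed-species association vs {t['iterations']} randomized networks: "
            f"observed {t['observed']:.4f}, lower-tail p = {t['p_lower']:.4g}"
        )
        lines.append(f"  species comparisons (Bonferroni alpha "
                     f"{res['alpha_bonferroni']:.4g}):")
        for metric, t in res["metric_tests"].items():
            flag = "*" if t["significant_at_bonferroni"] else " "
            lines.append(
                f"   {flag} {metric:12s} observed difference "
                f"{t['observed']: .4f}, two-tailed p = {t['p_two_tailed']:.4g}"
            )
        lines.append("  per-species means (mean, SD):")
        for row in res["species_summary"]:
            parts = ", ".join(
                f"{m} {row[f'{m}_mean']:.3f} ({row[f'{m}_sd']:.3f})" for m in METRICS
            )
            lines.append(f"    {row['species']} (n={row['n']}): {parts}")
    return "\n".join(lines)
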