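"""End-to-end analysis orchestration and interest-bias screening.

:func:`run_analysis` chains the whole pipeline — MITAB parsing, dataset
summary, anomaly flagging, network cleaning, the static measure suite,
power-law fitting, impact curves, targeted attacks, random failures and the
failure-cascade screen — into one JSON-serializable report.  Stages fail
independently: a stage error is recorded and later stages that do not depend
on it still run.

:func:`bias_flags` applies rule-based screens for the signatures of
interest-biased data collection: a single dominating hub, a degree exponent
outside the scale-free band (2, 3), one detection method or one publication
dominating the records, and assortative (r > 0) degree mixing, which is
atypical for protein interaction networks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import metrics as tm
from . import simulate as sim
from .mitab import flag_anomalies, read_edgelist, read_mitab, summarize_dataset
from .network import PPINetwork, build_network, connected_components, largest_component

__all__ = ["AnalysisConfig", "AnalysisReport", "BiasFlag", "run_analysis", "bias_flags"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a report needs to be recomputed bit-for-bit."""

    input_path: str
    input_format: str = "auto"  # auto | mitab | edgelist
    reference_taxid: int = 9606
    drop_non_protein: bool = False
    drop_foreign_taxa: bool = False
    attack_metrics: tuple[str, ...] = ("degree", "betweenness", "closeness", "eigenvector")
    decomposition_threshold: float = 0.01
    cascade_thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)
    mc: int = 100
    n_bootstrap: int = 0
    seed: int = 0
    skip_stages: tuple[str, ...] = ()
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BiasFlag:
    rule: str
    description: str
    observed: float
    threshold: float

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    """All computed results of one analysis run, keyed by stage."""

    config: AnalysisConfig
    config_hash: str
    dataset_summary: dict[str, Any] = field(default_factory=dict)
    anomalies: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    degree: dict[str, Any] = field(default_factory=dict)
    power_law: dict[str, Any] = field(default_factory=dict)
    assortativity: dict[str, Any] = field(default_factory=dict)
    centralities: dict[str, Any] = field(default_factory=dict)
    impact: dict[str, Any] = field(default_factory=dict)
    attacks: dict[str, Any] = field(default_factory=dict)
    random_failure: dict[str, Any] = field(default_factory=dict)
    cascades: dict[str, Any] = field(default_factory=dict)
    bias_flags: list[dict[str, Any]] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["config"] = dataclasses.asdict(self.config)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, default=str, sort_keys=True)


def _load_records(config: AnalysisConfig):
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    fmt = config.input_format
    if fmt == "auto":
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if line.strip() and not line.startswith("#"):
                    fmt = "mitab" if len(line.split("\t")) >= 15 else "edgelist"
                    break
            else:
                raise ValueError(f"input file {path} has no data lines")
    if fmt == "mitab":
        return read_mitab(path), "mitab"
    if fmt == "edgelist":
        return read_edgelist(path), "edgelist"
    raise ValueError(f"unknown input format {config.input_format!r}")


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full pipeline described by ``config``.

    The input is validated up front; afterwards each stage is attempted and
    failures are collected in ``report.errors`` without aborting independent
    later stages.  All randomness (Monte-Carlo failures, bootstrap) derives
    from ``config.seed``.
    """
    report = AnalysisReport(config=config, config_hash=config.config_hash())
    records, fmt = _load_records(config)  # raises before any stage on bad input
    skip = set(config.skip_stages)

    def stage(name: str):
        def decorator(fn):
            if name in skip:
                return None
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 — stage isolation is the point
                report.errors[name] = f"{type(exc).__name__}: {exc}"
                return None

        return decorator

    @stage("dataset_summary")
    def _summary():
        if fmt != "mitab":
            return None
        summary = summarize_dataset(records)
        report.dataset_summary = {
            "n_records": summary.n_records,
            "n_distinct_interactors": summary.n_distinct_interactors,
            "score_mean": summary.score_mean,
            "method_histogram": summary.method_histogram,
            "type_histogram": summary.type_histogram,
            "taxid_histogram": summary.taxid_histogram,
            "publication_histogram": summary.publication_histogram,
        }
        return summary

    @stage("anomalies")
    def _anomalies():
        if fmt != "mitab":
            return None
        rep = flag_anomalies(records, config.reference_taxid)
        report.anomalies = {
            "n_non_protein": rep.n_non_protein,
            "n_non_reference_taxon": rep.n_non_reference_taxon,
            "non_protein": rep.non_protein,
            "non_reference_taxon": rep.non_reference_taxon,
            "unknown_taxon": rep.unknown_taxon,
        }
        return rep

    usable = records
    if fmt == "mitab" and (config.drop_non_protein or config.drop_foreign_taxa):
        anomaly_report = flag_anomalies(records, config.reference_taxid)
        bad: set[str] = set()
        if config.drop_non_protein:
            bad |= set(anomaly_report.non_protein)
        if config.drop_foreign_taxa:
            bad |= set(anomaly_report.non_reference_taxon)
        usable = [r for r in records if r.id_a not in bad and r.id_b not in bad]

    net, log = build_network(usable)
    decomposition = connected_components(net)
    lcc = largest_component(net)
    report.network = {
        "n_raw_nodes": net.n_nodes,
        "n_raw_edges": net.n_edges,
        "n_records": log.n_records,
        "n_duplicate_records": log.n_duplicate_records,
        "n_reversed_repetitions": log.n_reversed_repetitions,
        "n_distinct_records": log.n_distinct_records,
        "n_self_loop_records": log.n_self_loop_records,
        "n_components": decomposition.n_components,
        "lcc_node_share": decomposition.largest_node_share(),
        "lcc_edge_share": decomposition.largest_edge_share(),
        "N": lcc.n_nodes,
        "L": lcc.n_edges,
    }

    @stage("degree")
    def _degree():
        dist = tm.degree_distribution(lcc)
        report.degree = {
            "k_max": dist.k_max,
            "k_max_node": dist.k_max_node,
            "k_max_over_n": dist.k_max / lcc.n_nodes,
            "mean_degree": 2 * lcc.n_edges / lcc.n_nodes,
        }
        return dist

    @stage("power_law")
    def _power_law():
        fit = tm.fit_power_law(
            list(lcc.degrees().values()),
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        report.power_law = {
            "gamma_hat": fit.gamma_hat,
            "k_min": fit.k_min,
            "ks_distance": fit.ks_distance,
            "p_value": fit.p_value,
            "fraction_covered": fit.fraction_covered,
            "small_tail": fit.small_tail,
        }
        return fit

    @stage("assortativity")
    def _assort():
        stats = tm.assortativity(lcc)
        report.assortativity = {"r": stats.r, "defined": stats.is_defined}
        return stats

    @stage("centralities")
    def _centralities():
        out: dict[str, Any] = {}
        for name, func in [
            ("betweenness", tm.betweenness),
            ("closeness", tm.closeness),
            ("eigenvector", tm.eigenvector_centrality),
            ("clustering", tm.clustering),
        ]:
            vec = func(lcc)
            out[name] = {
                "max": vec.max_value,
                "argmax": vec.argmax_node,
                "mean": vec.mean,
            }
        report.centralities = out
        return out

    @stage("impact")
    def _impact():
        curve = tm.impact_curves(lcc)
        cutoff_k, node_share, s1_at = curve.s1_at_node_share(0.90)
        report.impact = {
            "hub_contribution_top1": tm.hub_contribution(lcc, 1),
            "hub_contribution_top2": tm.hub_contribution(lcc, 2),
            "s1_at_90pct_nodes": s1_at,
            "k_at_90pct_nodes": cutoff_k,
            "node_share_at_cutoff": node_share,
        }
        return curve

    @stage("attacks")
    def _attacks():
        out = {}
        for metric in config.attack_metrics:
            traj = sim.targeted_attack(lcc, metric)
            out[metric] = {
                "d": sim.decomposition_point(traj, config.decomposition_threshold)
            }
        report.attacks = out
        return out

    @stage("random_failure")
    def _random():
        result = sim.random_failure(lcc, mc=config.mc, seed=config.seed)
        report.random_failure = {
            "mc": result.mc,
            "d": sim.decomposition_point(
                result.mean_trajectory(), config.decomposition_threshold
            ),
            "final_mean": float(result.s_mean[-1]),
        }
        return result

    @stage("cascades")
    def _cascades():
        out = {}
        for f_threshold in config.cascade_thresholds:
            summary = sim.cascade_summary(lcc, f_threshold)
            out[f"F={f_threshold:g}"] = {
                "propagating_fraction": summary.propagating_fraction,
                "p_max": summary.p_max,
                "p_max_nodes": summary.p_max_nodes[:10],
            }
        report.cascades = out
        return out

    report.bias_flags = [flag.to_dict() for flag in bias_flags(report)]

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        lcc.write_edgelist(outdir / "network_lcc.tsv")
        log.to_json(outdir / "build_log.json")
    return report


#: default bias-screen thresholds; observations from biased PPIN archetypes,
#: configurable rather than prescriptive
DEFAULT_BIAS_THRESHOLDS: dict[str, float] = {
    "hub_share": 0.15,
    "gamma_low": 2.0,
    "gamma_high": 3.0,
    "method_share": 0.90,
    "publication_share": 0.50,
    "assortative_r": 0.0,
}


def bias_flags(
    report: AnalysisReport, thresholds: dict[str, float] | None = None
) -> list[BiasFlag]:
    """Rule-based interest-bias screen over a finished report.

    Rules (each flag carries the observed value it fired on):

    a. a single hub incident to more than ``hub_share`` of all links;
    b. fitted degree exponent γ outside (``gamma_low``, ``gamma_high``);
    c. one detection method covering more than ``method_share`` of records;
    d. one publication contributing more than ``publication_share`` of records;
    e. assortative degree mixing (r > ``assortative_r``), atypical for PPINs.
    """
    t = dict(DEFAULT_BIAS_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    flags: list[BiasFlag] = []

    hub_share = report.impact.get("hub_contribution_top1")
    if hub_share is not None and hub_share > t["hub_share"]:
        flags.append(
            BiasFlag(
                rule="a:dominant_hub",
                description="a single hub is incident to a large share of all links",
                observed=hub_share,
                threshold=t["hub_share"],
            )
        )

    gamma = report.power_law.get("gamma_hat")
    if gamma is not None and not (t["gamma_low"] < gamma < t["gamma_high"]):
        flags.append(
            BiasFlag(
                rule="b:gamma_out_of_band",
                description="degree exponent outside the scale-free band (2, 3)",
                observed=gamma,
                threshold=t["gamma_low"] if gamma <= t["gamma_low"] else t["gamma_high"],
            )
        )

    methods = report.dataset_summary.get("method_histogram") or {}
    n_records = report.dataset_summary.get("n_records") or 0
    if methods and n_records:
        top_method_share = max(methods.values()) / n_records
        if top_method_share > t["method_share"]:
            flags.append(
                BiasFlag(
                    rule="c:dominant_method",
                    description="one detection method covers almost all records",
                    observed=top_method_share,
                    threshold=t["method_share"],
                )
            )

    pubs = report.dataset_summary.get("publication_histogram") or {}
    if pubs and n_records:
        top_pub_share = max(pubs.values()) / n_records
        if top_pub_share > t["publication_share"]:
            flags.append(
                BiasFlag(
                    rule="d:dominant_publication",
                    description="one publication contributes most of the records",
                    observed=top_pub_share,
                    threshold=t["publication_share"],
                )
            )

    r = report.assortativity.get("r")
    if r is not None and r > t["assortative_r"]:
        flags.append(
            BiasFlag(
                rule="e:assortative_mixing",
                description="assortative degree correlation (r > 0), atypical for PPINs",
                observed=r,
                threshold=t["assortative_r"],
            )
        )
    return flags
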