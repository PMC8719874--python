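"""End-to-end orchestration: simulate -> call -> burden -> transmit ->
network -> report, with a reproducibility manifest.

The run is driven by a single nested config (YAML on disk) with one block
per stage so every threshold scattered across the analysis lives on one
declarative surface. Outputs are TSV/JSON files; the manifest records the
config snapshot, seed, per-stage row counts and SHA-256 checksums of every
output file, so identical config + inputs reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden_stats import (
    carrier_counts,
    diagnostic_yield,
    fisher_carrier_test,
    format_report_row,
    poisson_burden_test,
)
from .genome import select_gene_set, toy_genome
from .network_enrichment import (
    cluster_length_check,
    edge_enrichment,
    extract_clusters,
    partition_by_deleteriousness,
)
from .rate_model import IndelRateModel, geneset_expected
from .synthetic_cohort import Cohort, CohortConfig, DepthModel, simulate_cohort, write_cohort
from .transmission import (
    count_recessive_opportunities,
    enumerate_qualifying,
    recessive_formation_test,
    overtransmission_from_qualifying,
)
from .trio_calling import (
    QCThresholds,
    annotate_calls,
    build_control_carrier_index,
    call_dnms,
    call_transmitted_mosaics,
    combine_callsets,
    exclude_outlier_trios,
)

YIELD_LABELS = ("pathogenic-DNM", "pathogenic-mosaic", "inherited-dominant", "biallelic-recessive")

_STAGE_KEYS = {"seed", "simulate", "calling", "burden", "network", "report"}


def validate_config(config: dict) -> dict:
    unknown = set(config) - _STAGE_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def summarize_yield(classifications: pd.DataFrame, n_trios: int) -> dict:
    """Per-category diagnostic yield plus a deduplicated total.

    ``classifications`` has columns (trio_id, label); a trio with findings
    in several categories counts once in the total.
    """
    unknown = set(classifications["label"]) - set(YIELD_LABELS)
    if unknown:
        raise ValueError(f"unknown yield label(s): {sorted(unknown)}")
    out: dict = {"n_trios": n_trios, "categories": {}}
    for label in YIELD_LABELS:
        trios = set(classifications.loc[classifications["label"] == label, "trio_id"])
        out["categories"][label] = {
            "n": len(trios),
            "percent": diagnostic_yield(len(trios), n_trios),
        }
    total = set(classifications["trio_id"])
    out["total"] = {"n": len(total), "percent": diagnostic_yield(len(total), n_trios)}
    return out


def synthetic_interaction_network(
    symbols: list[str],
    clustered: list[str],
    seed: int,
    p_background: float = 0.01,
    p_within: float = 0.25,
) -> nx.Graph:
    """A toy protein-interaction network over a gene catalogue.

    Background edges are uniform; genes in ``clustered`` (e.g. a disease
    gene set) interconnect far more densely, emulating the proclivity of
    functionally related proteins to interact. Edge channels mimic the
    usual evidence tiers.
    """
    rng = np.random.default_rng(seed)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(symbols)
    clustered_set = set(clustered)
    channels = ("curated", "experimental", "textmining")
    for i, a in enumerate(symbols):
        for b in symbols[i + 1 :]:
            p = p_within if (a in clustered_set and b in clustered_set) else p_background
            if rng.random() < p:
                graph.add_edge(a, b, channel=channels[int(rng.integers(0, 3))])
    return graph


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns the manifest dict. Fails fast with the stage name in the
    message on any stage error.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # -- simulate -----------------------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    geneset_size = int(sim_cfg.pop("enriched_geneset_size", 137))
    depth_cfg = sim_cfg.pop("depth_model", None)

    def _simulate() -> Cohort:
        genes = toy_genome()
        enriched = tuple(select_gene_set(genes, geneset_size, seed=1 + seed))
        kwargs = dict(sim_cfg)
        if depth_cfg:
            kwargs["depth_model"] = DepthModel(**depth_cfg)
        cohort_config = CohortConfig(seed=seed, enriched_geneset=enriched, **kwargs)
        return simulate_cohort(cohort_config, genes=genes)

    cohort = stage("simulate")(_simulate)
    write_cohort(cohort, outdir / "cohort")
    manifest["stages"]["simulate"] = {
        "n_trios": len(cohort.trios),
        "n_truth_events": int(len(cohort.truth)),
    }

    # -- calling ------------------------------------------------------------
    call_cfg = dict(config.get("calling", {}))
    thresholds = QCThresholds(**{
        k: tuple(v) if k == "mosaic_band" else v for k, v in call_cfg.items()
    })

    def _call():
        control_ids = [t.family_id for t in cohort.control_trios]
        index = build_control_carrier_index(cohort.records, control_ids)
        dnms, mosaics = [], []
        for trio in cohort.trios:
            recs = cohort.records[trio.family_id]
            dnms.extend(call_dnms(recs, trio, thresholds, index if trio.is_case else None))
            mosaics.extend(call_transmitted_mosaics(recs, trio, thresholds))
        dnms, excluded = exclude_outlier_trios(dnms, thresholds)
        mosaics = [m for m in mosaics if m.trio_id not in set(excluded)]
        combined, mosaic_pct = combine_callsets(dnms, mosaics)
        return annotate_calls(combined, cohort.annotations), excluded, mosaic_pct

    calls, excluded_trios, mosaic_pct = stage("calling")(_call)
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    manifest["stages"]["calling"] = {
        "n_calls": int(len(calls)),
        "n_excluded_trios": len(excluded_trios),
        "mosaic_percent": mosaic_pct,
    }

    # -- burden -------------------------------------------------------------
    burden_cfg = dict(config.get("burden", {}))
    include_mosaics = burden_cfg.get("include_mosaics", "internal") != "never"
    n_cases = len(cohort.case_trios) - sum(1 for t in excluded_trios if t.startswith("CASE"))
    enriched = list(cohort.config.enriched_geneset) if cohort.config else []

    def _burden():
        rows = []
        fisher_rows = []
        case_ids = {t.family_id for t in cohort.case_trios}
        case_calls = calls[calls["trio_id"].isin(case_ids)]
        for geneset_name, symbols in (("exome", None), ("enriched", enriched or None)):
            for effect_class in ("synonymous", "nonsynonymous"):
                expected, _ = geneset_expected(
                    cohort.genes, symbols, cohort.rate_table, effect_class, n_cases
                )
                if effect_class == "nonsynonymous":
                    expected += IndelRateModel(
                        cohort.config.mean_coding_indel_dnms_per_trio if cohort.config else 0.1
                    ).expected_count(cohort.genes, symbols, n_cases)
                subset = case_calls[case_calls["kind"] == "dnm"]
                mask = np.fromiter(
                    (effect_matches_row(e, effect_class) for e in subset["effect"]),
                    dtype=bool, count=len(subset),
                )
                subset = subset[mask]
                if symbols is not None:
                    subset = subset[subset["gene"].isin(set(symbols))]
                observed = int(len(subset))
                rows.append(format_report_row(
                    poisson_burden_test(observed, expected, geneset_name, effect_class)
                ))
                table = carrier_counts(
                    calls, cohort.trios, symbols, effect_class,
                    include_mosaics=include_mosaics, excluded_trio_ids=excluded_trios,
                )
                fr = fisher_carrier_test(table)
                fisher_rows.append(dict(
                    geneset=geneset_name, effect_class=effect_class,
                    cases_with=table.cases_with, controls_with=table.controls_with,
                    odds_ratio=round(fr.odds_ratio, 2) if fr.odds_ratio == fr.odds_ratio else None,
                    ci_lower=round(fr.ci_lower, 2) if fr.ci_lower == fr.ci_lower else None,
                    ci_upper=round(fr.ci_upper, 2) if fr.ci_upper == fr.ci_upper else None,
                    p_value=float(f"{fr.p_value:.2g}"),
                ))
        return pd.DataFrame(rows), pd.DataFrame(fisher_rows)

    burden_table, fisher_table = stage("burden")(_burden)
    burden_table.to_csv(outdir / "burden_rate.tsv", sep="\t", index=False)
    fisher_table.to_csv(outdir / "burden_carrier.tsv", sep="\t", index=False)
    manifest["stages"]["burden"] = {"n_rate_tests": int(len(burden_table)),
                                    "n_carrier_tests": int(len(fisher_table))}

    # -- transmission -------------------------------------------------------
    def _transmit():
        qualifying = enumerate_qualifying(
            cohort.records, cohort.case_trios, cohort.annotations
        )
        result = overtransmission_from_qualifying(qualifying) if qualifying else None
        formed, opportunities = count_recessive_opportunities(
            cohort.records, cohort.case_trios, cohort.annotations
        )
        recessive_p = (
            recessive_formation_test(formed, opportunities) if opportunities else None
        )
        return qualifying, result, formed, opportunities, recessive_p

    qualifying, trans_result, formed, opportunities, recessive_p = stage("transmit")(_transmit)
    transmission_summary = {
        "n_qualifying": trans_result.n_qualifying if trans_result else 0,
        "n_transmitted": trans_result.n_transmitted if trans_result else 0,
        "fraction": trans_result.fraction if trans_result else None,
        "p_value": trans_result.p_value if trans_result else None,
        "recessive": {"formed": formed, "opportunities": opportunities, "p_value": recessive_p},
    }
    (outdir / "transmission.json").write_text(json.dumps(transmission_summary, indent=2))
    manifest["stages"]["transmit"] = {"n_qualifying": transmission_summary["n_qualifying"]}

    # -- network ------------------------------------------------------------
    net_cfg = dict(config.get("network", {}))
    threshold = float(net_cfg.get("threshold", 15.0))
    n_perms = int(net_cfg.get("n_permutations", 1_999))
    null = net_cfg.get("null", "degree-matched")

    def _network():
        graph = synthetic_interaction_network(
            sorted(cohort.genes), enriched, seed=2 + seed
        )
        case_ids = {t.family_id for t in cohort.case_trios}
        case_calls = calls[calls["trio_id"].isin(case_ids)]
        hits_input = list(zip(case_calls["gene"], case_calls["score"]))
        high, low = partition_by_deleteriousness(hits_input, threshold)
        results = {}
        clusters_out = {}
        for name, part in (("high", high), ("low", low)):
            result = edge_enrichment(
                graph, [h.gene for h in part], n_permutations=n_perms, null=null, seed=3 + seed
            )
            results[name] = result
            clusters = extract_clusters(graph, [h.gene for h in part])
            clusters_out[name] = {
                "clusters": clusters,
                "mean_coding_length_kb": cluster_length_check(clusters, cohort.genes),
            }
        return results, clusters_out

    net_results, net_clusters = stage("network")(_network)
    network_summary = {
        name: {**asdict(r), "clusters": net_clusters[name]["clusters"],
               "mean_coding_length_kb": net_clusters[name]["mean_coding_length_kb"]}
        for name, r in net_results.items()
    }
    (outdir / "network.json").write_text(json.dumps(network_summary, indent=2))
    manifest["stages"]["network"] = {
        name: {"observed_edges": r.observed_edges, "p_value": r.p_value}
        for name, r in net_results.items()
    }

    # -- yield --------------------------------------------------------------
    def _report():
        rows = []
        case_ids = {t.family_id for t in cohort.case_trios}
        pathogenic = calls[
            calls["trio_id"].isin(case_ids)
            & calls["clinvar"].isin(["pathogenic", "likely_pathogenic"])
        ]
        for row in pathogenic.itertuples(index=False):
            label = "pathogenic-mosaic" if row.kind == "mosaic" else "pathogenic-DNM"
            rows.append({"trio_id": row.trio_id, "label": label})
        for qv in qualifying:
            if qv.transmitted and qv.rule == "ClinVar-pathogenic-missense":
                rows.append({"trio_id": qv.trio_id, "label": "inherited-dominant"})
        frame = pd.DataFrame(rows, columns=["trio_id", "label"])
        return summarize_yield(frame, n_cases)

    yield_summary = stage("report")(_report)
    (outdir / "yield.json").write_text(json.dumps(yield_summary, indent=2))
    manifest["stages"]["report"] = {"total_percent": yield_summary["total"]["percent"]}

    # -- manifest -----------------------------------------------------------
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def effect_matches_row(effect: str, effect_class: str) -> bool:
    from .burden_stats import effect_matches

    return effect_matches(effect, effect_class)
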