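"""End-to-end orchestration of the activation analysis.

Stages, in order: load → per-region Kruskal-Wallis + Dunn + effect sizes →
PCA → PERMANOVA with pairwise contrasts → per-group co-activation networks →
centrality rankings → pairwise network comparisons (edges and strengths) plus
the three-group omnibus tests.  A single global seed drives deterministic
per-stage substreams, so identical (input, config, seed) yields a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .data import ActivationMatrix, load_activation_table
from .multivariate import pairwise_permanova, pca_fit
from .network import (
    CoactivationNetwork,
    build_network,
    compare_networks,
    compare_networks_omnibus,
    rank_centrality,
)
from .rank_stats import dunn_posthoc, effect_size, kruskal_wallis_test

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "export_network"]

_STAGES = ("load", "region_tests", "pca", "permanova", "networks", "comparisons")


@dataclass
class AnalysisConfig:
    input_path: str | Path | None = None
    schema: str = "wide"
    region_order: tuple[str, ...] | None = None
    n_permutations: int = 999
    seed: int | None = None
    perm_mode: str = "values"
    adjust: str = "bh"
    negative_policy: str = "error"
    out_dir: str | Path | None = None
    standardize_pca: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.seed is None:
            raise ValueError("seed is required: Monte-Carlo stages must be reproducible")


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def export_network(net: CoactivationNetwork, out_dir) -> list[Path]:
    """Write a network as an edge-list CSV and a GraphML file.

    The CSV carries the unique edges (region_i, region_j, spearman_rho) with
    full float precision so a re-import reproduces the weights bit-exactly;
    the GraphML file carries node attributes (strength, eigenvector, median
    activation) and the edge weight attribute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(net.edge_list(), columns=["region_i", "region_j", "spearman_rho"])
    csv_path = out_dir / f"{net.group}_edges.csv"
    edges.to_csv(csv_path, index=False, float_format="%.17g")

    g = nx.Graph(group=net.group, n_individuals=net.n_individuals)
    for i, r in enumerate(net.regions):
        g.add_node(
            r,
            strength=float(net.strength[i]),
            eigenvector=float(net.eigenvector[i]),
            median_activation=float(net.node_activation[i]),
        )
    for a, b, w in net.edge_list():
        g.add_edge(a, b, weight=w)
    gml_path = out_dir / f"{net.group}.graphml"
    nx.write_graphml(g, gml_path)
    return [csv_path, gml_path]


def _region_tests(m: ActivationMatrix, adjust: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = m.group_labels
    summary_rows, posthoc_rows = [], []
    for region in m.regions:
        samples = [m.group_values(g)[region].to_numpy() for g in labels]
        kw = kruskal_wallis_test(samples)
        row = {"region": region, "kw_H": kw.statistic, "kw_df": kw.df,
               "kw_p": kw.p_value}
        for g, s in zip(labels, samples):
            row[f"median_{g}"] = float(np.median(s))
            row[f"iqr_{g}"] = float(np.subtract(*np.percentile(s, [75, 25])))
        summary_rows.append(row)
        dunn = dunn_posthoc(samples, labels=labels, adjust=adjust)
        for d in dunn:
            a, b = d.pair
            xa = samples[labels.index(a)]
            xb = samples[labels.index(b)]
            es = effect_size(xa, xb, kind="auto")
            posthoc_rows.append({
                "region": region, "group_a": a, "group_b": b,
                "dunn_z": d.statistic, "dunn_p": d.p_value,
                "dunn_p_adjusted": d.p_adjusted,
                "effect_size_kind": es.kind, "effect_size": es.value,
            })
    return pd.DataFrame(summary_rows), pd.DataFrame(posthoc_rows)


def run_full_analysis(cfg: AnalysisConfig, matrix: ActivationMatrix | None = None) -> dict:
    """Run every stage and (optionally) write all outputs.

    Returns the report as a dict; when ``cfg.out_dir`` is set, also writes
    activation_summary.csv, posthoc.csv, pca_loadings.csv, permanova.json,
    networks/*, comparisons.csv and report.json.  Any stage error aborts with
    the stage name, removing partial outputs.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    created_out = False
    if out_dir is not None and not out_dir.exists():
        created_out = True
    stage = "load"
    try:
        if matrix is None:
            if cfg.input_path is None:
                raise ValueError("either an input path or an in-memory matrix is required")
            matrix = load_activation_table(cfg.input_path, cfg.schema, cfg.region_order)
        labels = matrix.group_labels

        stage = "region_tests"
        summary, posthoc = _region_tests(matrix, cfg.adjust)

        stage = "pca"
        pca = pca_fit(matrix, standardize=cfg.standardize_pca)

        stage = "permanova"
        perm = pairwise_permanova(
            matrix, cfg.n_permutations, _stage_seed(cfg.seed, "permanova"), adjust="none"
        )

        stage = "networks"
        nets = [build_network(matrix, g, cfg.negative_policy) for g in labels]
        rankings = {
            n.group: {
                metric: rank_centrality(n, metric).order
                for metric in ("strength", "eigenvector")
            }
            for n in nets
        }

        stage = "comparisons"
        comp_rows = []
        comp_seed = _stage_seed(cfg.seed, "comparisons")
        for ci, ((a, b), target) in enumerate(
            (pair, t) for pair in combinations(labels, 2) for t in ("edges", "strengths")
        ):
            sub_seed = int(
                np.random.SeedSequence(comp_seed, spawn_key=(ci,)).generate_state(
                    1, dtype=np.uint32
                )[0] % (2**31)
            )
            comp = compare_networks(
                matrix, a, b, target=target, n_draws=cfg.n_permutations,
                seed=sub_seed, mode=cfg.perm_mode, negative_policy=cfg.negative_policy,
            )
            for r in comp.results:
                comp_rows.append({
                    "group_pair": f"{a}-{b}", "target": target, "method": r.method,
                    "statistic": r.statistic, "p_value": r.p_value, "mode": r.mode,
                    "B": cfg.n_permutations, "seed": sub_seed,
                    "perm_scheme": comp.mode,
                })
        omnibus = {}
        for target in ("edges", "strengths"):
            kw, dunn = compare_networks_omnibus(
                matrix, target, adjust=cfg.adjust, negative_policy=cfg.negative_policy
            )
            omnibus[target] = {
                "kruskal_wallis": kw.to_dict(),
                "dunn": [d.to_dict() for d in dunn],
            }

        report = {
            "provenance": {
                "software": f"cfosnet {__version__}",
                "seed": cfg.seed,
                "n_permutations": cfg.n_permutations,
                "perm_mode": cfg.perm_mode,
                "adjust": cfg.adjust,
                "n_individuals": len(matrix.individuals),
                "group_sizes": matrix.group_sizes(),
                "regions": matrix.regions,
            },
            "region_tests": {
                "summary": summary.to_dict(orient="records"),
                "posthoc": posthoc.to_dict(orient="records"),
            },
            "pca": {
                "standardized": pca.standardized,
                "sdev": pca.sdev.tolist(),
                "proportion": pca.proportion.tolist(),
                "cumulative": pca.cumulative.tolist(),
                "loadings": {
                    r: pca.loadings[i].tolist() for i, r in enumerate(pca.regions)
                },
            },
            "permanova": perm.to_dict(),
            "networks": {
                n.group: {
                    "total_connectivity": n.total_connectivity,
                    "strength": dict(zip(n.regions, n.strength.tolist())),
                    "eigenvector": dict(zip(n.regions, n.eigenvector.tolist())),
                    "n_individuals": n.n_individuals,
                }
                for n in nets
            },
            "rankings": rankings,
            "comparisons": comp_rows,
            "omnibus": omnibus,
        }

        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            summary.to_csv(out_dir / "activation_summary.csv", index=False)
            posthoc.to_csv(out_dir / "posthoc.csv", index=False)
            pca.to_frame().to_csv(out_dir / "pca_loadings.csv")
            (out_dir / "permanova.json").write_text(
                json.dumps(perm.to_dict(), indent=2, sort_keys=True)
            )
            for n in nets:
                export_network(n, out_dir / "networks")
            pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
            (out_dir / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
        return report
    except Exception as exc:
        if out_dir is not None and out_dir.exists() and created_out:
            shutil.rmtree(out_dir, ignore_errors=True)
        logger.error("analysis failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc
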