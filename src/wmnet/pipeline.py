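"""End-to-end orchestration: simulate -> construct -> metrics -> statistics.

The stages mirror how the analysis runs on real data: per-subject streamline
summaries become FA_wei/FA_bin matrices, every network gets its global and
nodal properties (plus small-world ratios against degree-preserving nulls),
and the statistical layer produces the covariate-adjusted group comparison and
the clinical partial correlations, all FDR-corrected within families.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, load_aal90, load_coordinates
from .io import RunConfig, write_manifest, write_matrix, write_streamlines, write_subjects
from .metrics import (distance_matrix, global_metrics, hub_detection,
                      nodal_metrics, null_ensemble, small_world)
from .network import ConnectivityMatrix, build_networks
from .simulate import simulate_cohort
from .stats import (comparison_frame, compare_all, correlate_clinical,
                    correlation_frame)

log = logging.getLogger("wmnet")

NETWORK_KINDS = ("FA_wei", "FA_bin")


def subject_metric_tables(
    networks: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]],
    cfg: RunConfig | None = None,
    kinds: tuple[str, ...] = NETWORK_KINDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (global_table, nodal_table) for a set of subjects.

    ``global_table``: subject_id, network_kind, metric, value — metrics Eg, Cp,
    Eloc, Lp and (when ``cfg.compute_sigma``) sigma/gamma/lambda.
    ``nodal_table``: subject_id, network_kind, region, Enodal, degree.
    """
    cfg = cfg or RunConfig()
    g_rows, n_rows = [], []
    for k, (sid, pair) in enumerate(sorted(networks.items())):
        by_kind = {m.kind: m for m in pair}
        for kind in kinds:
            m = by_kind[kind]
            if m.n_edges == 0:
                log.warning("subject %s %s: empty network, metrics degenerate",
                            sid, kind)
            d = distance_matrix(m, cfg.weight_to_length)
            gm = global_metrics(m, d, cfg.weight_to_length)
            nm = nodal_metrics(m, d, cfg.weight_to_length)
            for name, value in (("Eg", gm.Eg), ("Cp", gm.Cp),
                                ("Eloc", gm.Eloc), ("Lp", gm.Lp)):
                g_rows.append((sid, kind, name, value))
            if cfg.compute_sigma and m.n_edges > 1:
                ens = null_ensemble(m, cfg.n_null, cfg.swaps_per_edge,
                                    seed=_null_seed(cfg.seed, k, kind),
                                    weight_to_length=cfg.weight_to_length)
                sw = small_world(gm, ens)
                g_rows.extend([(sid, kind, "sigma", sw.sigma),
                               (sid, kind, "gamma", sw.gamma),
                               (sid, kind, "lambda", sw.lam)])
            for region0 in range(m.n_nodes):
                n_rows.append((sid, kind, region0 + 1,
                               float(nm.Enodal[region0]), int(nm.degree[region0])))
    global_table = pd.DataFrame(g_rows, columns=["subject_id", "network_kind",
                                                 "metric", "value"])
    nodal_table = pd.DataFrame(n_rows, columns=["subject_id", "network_kind",
                                                "region", "Enodal", "degree"])
    return global_table, nodal_table


def _null_seed(seed: int, subject_ordinal: int, kind: str) -> int:
    return int(np.random.SeedSequence(
        [seed, 7, subject_ordinal, 0 if kind == "FA_wei" else 1]
    ).generate_state(1)[0] % (2 ** 31))


def run_all(cfg: RunConfig | None = None, outdir: str | Path = "wmnet_run",
            seed: int | None = None, atlas: RegionAtlas | None = None):
    """Run the whole pipeline and write all artifacts under ``outdir``.

    Returns a dict with the in-memory results (subjects, networks, metric
    tables, comparison and correlation frames, hub tables).
    """
    cfg = cfg or RunConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.cohort = cfg.cohort.with_(seed=seed)
    atlas = atlas or load_aal90()
    coords = load_coordinates()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    # simulate
    records, streamlines, template = simulate_cohort(cfg.cohort, cfg.seed,
                                                     atlas, coords)
    write_subjects(outdir / "subjects.csv", records)
    artifacts.append("subjects.csv")
    sl_dir = outdir / "streamlines"
    sl_dir.mkdir(exist_ok=True)
    for sid, sl in streamlines.items():
        write_streamlines(sl_dir / f"{sid}.tsv", sl)
        artifacts.append(f"streamlines/{sid}.tsv")

    # construct
    networks = {sid: build_networks(sl, atlas, subject_id=sid,
                                    fa_threshold=cfg.fa_threshold,
                                    min_count=cfg.min_count)
                for sid, sl in streamlines.items()}
    mat_dir = outdir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for sid, (wei, binary) in networks.items():
        write_matrix(mat_dir / f"{sid}_FA_wei.edge", wei)
        write_matrix(mat_dir / f"{sid}_FA_bin.edge", binary)
        artifacts.extend([f"matrices/{sid}_FA_wei.edge",
                          f"matrices/{sid}_FA_bin.edge"])

    # metrics
    global_table, nodal_table = subject_metric_tables(networks, cfg)
    global_table.to_csv(outdir / "global_metrics.tsv", sep="\t", index=False)
    nodal_table.to_csv(outdir / "nodal_metrics.tsv", sep="\t", index=False)
    artifacts.extend(["global_metrics.tsv", "nodal_metrics.tsv"])

    subjects = pd.read_csv(outdir / "subjects.csv")

    # hubs (binary degree, per group) + BrainNet export
    from .io import export_brainnet_node
    from .metrics import NodalMetrics

    hub_tables = {}
    for group in ("patient", "control"):
        sids = subjects.loc[subjects["group"] == group, "subject_id"]
        nodal_list = []
        for sid in sids:
            rows = nodal_table[(nodal_table["subject_id"] == sid)
                               & (nodal_table["network_kind"] == "FA_bin")]
            rows = rows.sort_values("region")
            nodal_list.append(NodalMetrics(rows["Enodal"].to_numpy(),
                                           rows["degree"].to_numpy()))
        ht = hub_detection(nodal_list, cfg.sd_multiplier)
        hub_tables[group] = ht
        export_brainnet_node(outdir / f"hubs_{group}.node", coords, ht,
                             atlas.abbreviations)
        artifacts.append(f"hubs_{group}.node")

    # statistics
    comparisons = compare_all(global_table, nodal_table, subjects, atlas,
                              cfg.q_level)
    comp_df = comparison_frame(comparisons)
    comp_df.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    artifacts.append("group_comparison.tsv")

    correlations = correlate_clinical(nodal_table, subjects, atlas, cfg.q_level)
    corr_df = correlation_frame(correlations)
    corr_df.to_csv(outdir / "clinical_correlation.tsv", sep="\t", index=False)
    artifacts.append("clinical_correlation.tsv")

    write_manifest(outdir / "manifest.json", cfg, cfg.seed, "all", artifacts)
    return {
        "subjects": subjects,
        "template": template,
        "networks": networks,
        "global_table": global_table,
        "nodal_table": nodal_table,
        "hub_tables": hub_tables,
        "comparisons": comp_df,
        "correlations": corr_df,
    }
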