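"""End-to-end orchestration: simulate or ingest → threshold → DE → cluster
→ prioritize → isoform → enrich → qPCR, from one config, with a run
manifest recording inputs, parameters, seeds and output checksums.

Every stage output is a pure function of (inputs, parameters, seed), so
re-running the same config reproduces all outputs bitwise — the manifest
hashes are the reproducibility contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, de, enrichment, io, isoforms, network, qpcr, threshold
from .containers import ValidationError
from .simulate import SimulationConfig, IsoformConfig, NetworkConfig, QpcrConfig, simulate_all

log = logging.getLogger("sciseq")

DEFAULT_PARAMS = {
    "target_reliability": 0.99,
    "floor": None,          # None: use the selected threshold
    "fc_cutoff": 2.0,
    "p_cutoff": 0.05,
    "top_fraction": 0.10,
    "k": 9,
    "fuzzifier": 1.25,
    "top_n_variance": 3000,
    "n_perm": 1000,
    "log_base": 2.0,
    "isoform_margin": 1.0,
    "include_neighbors": True,
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    return cfg


def _simulation_config(cfg: dict, seed: int | None) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    if seed is not None:
        sim["seed"] = seed
    for key, cls in (("isoforms", IsoformConfig), ("network", NetworkConfig),
                     ("qpcr", QpcrConfig)):
        if key in sim and isinstance(sim[key], dict):
            sim[key] = cls(**sim[key])
    if "stages" in sim:
        sim["stages"] = tuple(sim["stages"])
    if "replicates" in sim:
        sim["replicates"] = tuple(sim["replicates"])
    return SimulationConfig(**sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Run the full analysis and return the manifest dictionary.

    ``cfg`` holds a ``simulation`` block (synthetic inputs) and an optional
    ``params`` block overriding :data:`DEFAULT_PARAMS`.  On stage failure a
    ``FAILED`` marker naming the stage is left in the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    manifest: dict = {"params": params, "outputs": {}, "counts": {}}
    stage = "setup"
    try:
        sim_cfg = _simulation_config(cfg, seed)
        manifest["seed"] = sim_cfg.seed
        manifest["simulation"] = json.loads(
            json.dumps(dataclasses.asdict(sim_cfg), default=str)
        )

        stage = "simulate"
        bundle = simulate_all(sim_cfg)
        study = bundle.study
        io.write_expression_matrix(
            study, outdir / "expression.tsv", outdir / "samples.tsv"
        )
        io.write_edge_list(bundle.edges, outdir / "edges.tsv")
        io.write_annotation(bundle.annotations, outdir / "annotation.tsv")
        io.write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
        io.write_tsv(bundle.ct_table, outdir / "ct_table.tsv")
        io.write_tsv(
            bundle.truth.stage_means.reset_index(), outdir / "truth_stage_means.tsv"
        )

        stage = "threshold"
        calls = threshold.label_reliability(study)
        curve = threshold.compute_detection_curve(calls)
        selection = threshold.select_threshold(curve, params["target_reliability"])
        io.write_tsv(curve, outdir / "detection_curve.tsv")
        floor = params["floor"] if params["floor"] else selection.threshold
        manifest["counts"]["selected_threshold"] = selection.threshold
        log.info("threshold %.4g (reliability %.4f)", selection.threshold,
                 selection.reliability)
        floored = threshold.floor_fpkm(study, floor)

        stage = "differential_expression"
        control, *injured = study.stages
        de_tables: dict[str, pd.DataFrame] = {}
        for s in injured:
            t = de.call_de(floored, (s, control), params["fc_cutoff"],
                           params["p_cutoff"])
            de_tables[f"{s}_vs_{control}"] = t
            io.write_tsv(t.reset_index(), outdir / f"de_{s}_vs_{control}.tsv")
            manifest["counts"][f"de_{s}_vs_{control}"] = int(t["is_significant"].sum())
        if len(injured) >= 2:
            venn = de.venn_partition(*list(de_tables.values())[:2])
            io.write_tsv(
                pd.DataFrame([venn.counts]), outdir / "venn_counts.tsv"
            )
            manifest["counts"]["venn"] = venn.counts

        stage = "clustering"
        varying = clustering.select_varying_genes(floored, params["fc_cutoff"],
                                                  floor)
        manifest["counts"]["trajectory_genes"] = len(varying)
        if len(varying) > params["k"]:
            profiles = clustering.standardize_profiles(
                floored.stage_means(floor=floor).loc[varying]
            )
            fc9 = clustering.fuzzy_cmeans(
                profiles, k=params["k"], m=params["fuzzifier"], seed=sim_cfg.seed
            )
            io.write_tsv(fc9.memberships.reset_index(), outdir / "memberships.tsv")
            io.write_tsv(fc9.centers.reset_index(names="cluster"),
                         outdir / "cluster_centers.tsv")
        dendro = clustering.hierarchical_samples(study, params["top_n_variance"])
        (outdir / "sample_dendrogram.txt").write_text(dendro.newick() + "\n")
        io.write_tsv(
            clustering.replicate_correlation(study).reset_index(),
            outdir / "replicate_correlation.tsv",
        )

        stage = "prioritization"
        for name, table in de_tables.items():
            top = de.select_top_fraction(table, params["top_fraction"])
            for direction in ("up", "down"):
                focus = top[direction]
                if not focus:
                    continue
                try:
                    ranked = network.prioritize(
                        focus, bundle.edges, bundle.annotations, table,
                        fc_cutoff=params["fc_cutoff"],
                        log_base=params["log_base"],
                        include_neighbors=params["include_neighbors"],
                    )
                except ValidationError as exc:
                    log.info("prioritization skipped for %s %s: %s", name,
                             direction, exc)
                    continue
                io.write_tsv(ranked.reset_index(),
                             outdir / f"ranked_{name}_{direction}.tsv")
                manifest["counts"][f"candidates_{name}_{direction}"] = len(ranked)

        stage = "isoforms"
        profiles_table = isoforms.profile_all_genes(
            bundle.isoform_study, threshold=floor, margin=params["isoform_margin"]
        )
        io.write_tsv(profiles_table.reset_index(), outdir / "isoform_profiles.tsv")
        _, hist = isoforms.count_expressed_isoforms(bundle.isoform_study, floor)
        io.write_tsv(hist.reset_index(), outdir / "isoforms_per_gene.tsv")
        manifest["counts"]["switch_genes"] = int(profiles_table["is_switch"].sum())

        stage = "enrichment"
        first = list(de_tables.values())[0]
        universe = list(first.index)
        query = list(first.index[first["is_significant"]])
        if query:
            fisher = enrichment.fisher_enrichment(query, bundle.gene_sets, universe)
            io.write_tsv(fisher.reset_index(), outdir / "fisher_enrichment.tsv")
        for name, table in de_tables.items():
            ranked_list = enrichment.rank_by_fold_change(table)
            gsea = enrichment.permutation_null(
                ranked_list, bundle.gene_sets, n_perm=params["n_perm"],
                seed=sim_cfg.seed,
            )
            io.write_tsv(gsea.reset_index(), outdir / f"gsea_{name}.tsv")

        stage = "qpcr"
        hk = sim_cfg.qpcr.housekeeping_gene
        qpcr_genes = sorted(set(bundle.ct_table["gene"]) - {hk})
        contrasts = [(s, control) for s in injured]
        folds = qpcr.qpcr_fold_table(bundle.ct_table, qpcr_genes, contrasts, hk)
        expr_rows = []
        for name, table in de_tables.items():
            for g in qpcr_genes:
                if g in table.index:
                    expr_rows.append(
                        {"gene": g, "contrast": name,
                         "fold_change": float(table.loc[g, "fold_change"])}
                    )
        expr_folds = pd.DataFrame(expr_rows)
        io.write_tsv(folds, outdir / "qpcr_folds.tsv")
        summary = qpcr.concordance(folds, expr_folds)
        io.write_tsv(summary["table"], outdir / "qpcr_concordance.tsv")
        manifest["counts"]["qpcr_pearson"] = summary["pearson"]
        manifest["counts"]["qpcr_sign_agreement"] = summary["sign_agreement"]
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.gmt")) + sorted(
        outdir.glob("*.txt")
    ):
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
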