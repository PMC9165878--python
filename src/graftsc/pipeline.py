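"""End-to-end pipeline: QC -> cluster -> doublet screen -> recluster ->
annotate -> origin -> pseudobulk -> differential filter -> matrisome -> IG.

Each stage writes its table under the configured output directory and the
run finishes with a machine-readable ``summary.json`` (cell counts per
stage, composition, origin fractions) plus a log echoing every parameter
and the inequality semantics in force.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

from . import io as gio
from .cluster import ClusterParams, cluster_pipeline, wilcoxon_markers, \
    annotate_by_markers, log_normalize
from .config import RunConfig
from .ig import cluster_ig_cells, dominant_isotype, ig_matrix
from .origin import (SamplePair, assign_origin, call_group_sex,
                     origin_composition, sex_detect_cells)
from .panels import (DEFAULT_LINEAGE_PANELS, DEFAULT_MARKER_PANELS,
                     DEFAULT_MATRISOME, IMMUNE_TYPES, PARENCHYMAL_TYPES)
from .pseudobulk import (composition_table, matrisome_score, maxgap_de,
                         pseudobulk_tpm)
from .qc import compute_cell_qc, filter_cells_round1, filter_genes, \
    flag_doublets_by_coexpression

log = logging.getLogger("graftsc")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _setup_logging(outdir: Path, level: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)


def run_pipeline(config: RunConfig, counts: AnnData | None = None,
                 pairs: dict[str, SamplePair] | None = None,
                 marker_catalog: dict[str, list[str]] | None = None,
                 lineage_panels: dict[str, list[str]] | None = None,
                 matrisome_catalog: dict[str, list[str]] | None = None) -> dict:
    """Execute the full analysis; returns the summary dict it also writes.

    ``counts`` may be passed directly (e.g. fresh from the simulator) or
    read from ``config.input_dir``; likewise ``pairs``.
    """
    outdir = Path(config.outdir)
    _setup_logging(outdir, config.log_level)
    log.info("parameters: %s", json.dumps(config.to_dict(), default=str))
    log.info("threshold semantics: strict=%s (bounds exclusive, mito <= max "
             "retained)", config.qc.strict)

    marker_catalog = marker_catalog or DEFAULT_MARKER_PANELS
    lineage_panels = lineage_panels or DEFAULT_LINEAGE_PANELS
    matrisome_catalog = matrisome_catalog or DEFAULT_MATRISOME
    parenchymal = set(config.parenchymal_types) or PARENCHYMAL_TYPES

    summary: dict = {"stages": {}}

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    try:
        name = stage("load")
        if counts is None:
            if config.input_dir is None:
                raise ValueError("no counts given and no input_dir configured")
            counts = gio.read_mtx_triplet(config.input_dir)
        if pairs is None and config.pairs_file:
            pairs = gio.read_sample_pairs(config.pairs_file)
        if "sample" not in counts.obs:
            # barcodes are written as <sample>-<number>; fall back to a
            # single pseudo-sample when no separator is present
            derived = [b.rsplit("-", 1)[0] if "-" in b else "sample1"
                       for b in counts.obs_names]
            counts.obs["sample"] = derived
        summary["stages"]["n_input"] = int(counts.n_obs)

        name = stage("qc_round1")
        metrics = compute_cell_qc(counts)
        gio.write_table(metrics, outdir / "cell_qc.tsv",
                        "per-cell QC; mito_fraction = MT- UMIs / total UMIs")
        genes_r1 = filter_genes(counts, config.qc, config.blacklist,
                                round2=False)
        cells_r1 = filter_cells_round1(genes_r1, metrics, config.qc)
        summary["stages"]["n_genes_round1"] = int(genes_r1.n_vars)
        summary["stages"]["n_round1"] = int(cells_r1.n_obs)

        name = stage("doublet_screen")
        current = cells_r1
        n_flagged_total = 0
        for it in range(config.doublets.max_iterations):
            norm = log_normalize(current)
            flags = flag_doublets_by_coexpression(norm, lineage_panels,
                                                  tau=config.doublets.tau)
            n_flagged = int(flags["is_doublet"].sum())
            log.info("doublet iteration %d: %d flagged", it + 1, n_flagged)
            if n_flagged == 0:
                break
            n_flagged_total += n_flagged
            current = current[~flags["is_doublet"].to_numpy()].copy()
        summary["stages"]["n_doublets_removed"] = n_flagged_total

        name = stage("qc_round2")
        counts_r2 = filter_genes(current, config.qc, config.blacklist,
                                 round2=True)
        summary["stages"]["n_genes_round2"] = int(counts_r2.n_vars)
        summary["stages"]["n_round2"] = int(counts_r2.n_obs)

        name = stage("cluster")
        assignment, norm, _ = cluster_pipeline(counts_r2, config.clustering)
        gio.write_table(assignment.labels.rename("cluster").to_frame(),
                        outdir / "clusters.tsv",
                        f"params: {assignment.params}")

        name = stage("markers")
        if len(assignment.clusters) >= 2:
            markers = wilcoxon_markers(norm, assignment.labels)
            gio.write_table(markers, outdir / "markers.tsv",
                            "one-vs-rest Wilcoxon; BH-adjusted per cluster",
                            index=False)

        name = stage("annotate")
        annotation = annotate_by_markers(norm, assignment.labels,
                                         marker_catalog)
        cell_types = assignment.labels.map(annotation["cell_type"])
        gio.write_table(annotation, outdir / "cluster_annotation.tsv")
        samples = counts_r2.obs["sample"]
        composition = composition_table(cell_types, samples,
                                        immune_types=IMMUNE_TYPES)
        gio.write_table(composition, outdir / "composition.tsv",
                        "per-sample cell-type proportions (rows sum to 1)")
        summary["composition"] = {
            str(s): {str(t): float(v) for t, v in row.items()}
            for s, row in composition.iterrows()}

        name = stage("origin")
        if pairs is not None:
            # sex panel read from the unfiltered matrix: the RPS prefix
            # blacklist would otherwise remove RPS4Y1
            detections = sex_detect_cells(counts[counts_r2.obs_names])
            grouping = pd.DataFrame({"cluster": assignment.labels,
                                     "sample": samples})
            group_sex = call_group_sex(detections, grouping,
                                       min_cells=config.origin.min_cells,
                                       tau_detect=config.origin.tau_detect,
                                       margin=config.origin.margin)
            group_origin = assign_origin(
                group_sex, pairs, parenchymal_types=parenchymal,
                group_cell_types=annotation["cell_type"].to_dict())
            gio.write_table(group_origin, outdir / "group_origin.tsv",
                            index=False)
            key = pd.MultiIndex.from_frame(grouping[["cluster", "sample"]])
            lookup = group_origin.set_index(["cluster", "sample"])["origin"]
            cell_origin = pd.Series(lookup.loc[key].to_numpy(),
                                    index=grouping.index, name="origin")
            gio.write_table(cell_origin.to_frame(), outdir / "cell_origin.tsv")
            origin_table = origin_composition(cell_origin, cell_types, samples)
            gio.write_table(origin_table, outdir / "origin_composition.tsv",
                            index=False)
            summary["origin"] = origin_table.to_dict(orient="records")

        name = stage("pseudobulk")
        group_key = pd.Series(
            [f"{t}|{s}" for t, s in zip(cell_types, samples)],
            index=counts_r2.obs_names)
        profiles = pseudobulk_tpm(counts_r2, group_key, scale=config.de.scale)
        gio.write_table(profiles, outdir / "pseudobulk_tpm.tsv",
                        f"TPM-like profiles, columns sum to {config.de.scale}")

        name = stage("maxgap_de")
        de_tables = {}
        for ctype in sorted(set(cell_types)):
            cols = [c for c in profiles.columns if c.startswith(f"{ctype}|")]
            if len(cols) < 2:
                continue
            by_sample = profiles[cols].rename(
                columns={c: c.split("|", 1)[1] for c in cols})
            de = maxgap_de(by_sample, min_tpm=config.de.min_tpm,
                           min_ratio=config.de.min_ratio)
            de_tables[ctype] = de[de["passes"]]
            gio.write_table(de, outdir / f"maxgap_de_{ctype}.tsv",
                            "max vs second-max TPM filter across samples")
        summary["maxgap_pass_counts"] = {t: int(len(d))
                                         for t, d in de_tables.items()}

        name = stage("matrisome")
        for category in matrisome_catalog:
            table = matrisome_score(profiles, matrisome_catalog, category,
                                    top_n=10)
            if len(table):
                safe = category.replace(" ", "_")
                gio.write_table(table, outdir / f"matrisome_{safe}.tsv",
                                "log2(TPM+1)")

        name = stage("ig")
        plasma = [b for b, t in cell_types.items() if t == "BC.PLASMA"]
        if len(plasma) >= 2:
            try:
                igm = ig_matrix(norm, plasma)
                calls = dominant_isotype(igm)
                gio.write_table(calls, outdir / "ig_isotypes.tsv")
                clust = cluster_ig_cells(igm)
                gio.write_table(
                    pd.DataFrame(clust.linkage,
                                 columns=["left", "right", "height", "size"]),
                    outdir / "ig_linkage.tsv",
                    f"complete linkage, Euclidean, genes: {clust.genes}",
                    index=False)
                summary["ig"] = {
                    "n_plasma": len(plasma),
                    "isotype_counts": calls.groupby(
                        ["heavy_class", "light_class"], observed=True)
                    .size().rename("n").reset_index()
                    .to_dict(orient="records")}
            except Exception as exc:  # IG genes may be absent from a run
                log.warning("ig stage skipped: %s", exc)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc

    flow = summary["stages"]
    assert flow["n_round2"] <= flow["n_round1"] <= flow["n_input"]
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("done; summary written")
    return summary
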