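"""End-to-end orchestration of the two analyses.

``run_transfer_analysis`` chains table/metadata loading, cohort assembly,
transfer detection, per-ASV summary and group statistics into a report
bundle; ``run_genomic_analysis`` does the same for the genome side (SNP
matrix, ANI, gene-content clustering, within/between partition, identity
calls). Both write plain TSV/JSON outputs plus a manifest with input
digests for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import genomics, stats, transfer
from .io import (
    build_cohort,
    read_alignment,
    read_feature_table,
    read_gene_matrix,
    read_genome_labels,
    read_sample_meta,
    read_taxonomy,
)

log = logging.getLogger("dyadtrace")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NOT_APPLICABLE = 3


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(config: dict, inputs: dict[str, str | Path], counts: dict[str, int]) -> dict:
    return {
        "config": {k: str(v) for k, v in config.items()},
        "inputs": {k: {"path": str(p), "sha256": _digest(p)} for k, p in inputs.items() if p},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "row_counts": counts,
    }


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_transfer_analysis(
    table_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
    taxonomy_path: str | Path | None = None,
    threshold: float = 0.001,
    orientation: str = "samples_as_rows",
    inclusive: bool = True,
) -> dict:
    """Amplicon transfer analysis: events, per-ASV summary, group statistics.

    Writes ``events.tsv``, ``summary.tsv``, ``per_dyad_counts.tsv``,
    ``stats.json`` and ``manifest.json`` under ``out_dir`` and returns the
    headline block (dyads with >=1 event, fraction, range, median among
    positive dyads).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(table_path, orientation=orientation)
    meta = read_sample_meta(meta_path)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
    else:
        log.warning("no taxonomy file supplied; summary rows labelled 'unassigned'")
    cohort = build_cohort(table, meta)
    log.info(
        "cohort: %d dyads (%s), %d samples, %d ASVs, threshold %g",
        len(cohort), cohort.report, len(table.sample_ids), len(table.asv_ids), threshold,
    )

    events = transfer.detect_transfers(cohort, table, threshold, inclusive=inclusive)
    per_dyad = transfer.count_per_dyad(events, cohort)
    summary = transfer.summarize_by_asv(events, table, taxonomy, cohort, threshold, inclusive)

    transfer.events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
    transfer.summaries_to_frame(summary).to_csv(out / "summary.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in per_dyad]).to_csv(
        out / "per_dyad_counts.tsv", sep="\t", index=False
    )

    counts = np.array([c.n_transfer_events for c in per_dyad])
    positive = counts[counts > 0]
    headline = {
        "n_dyads": len(cohort),
        "n_events": len(events),
        "n_by_category": {
            c: sum(ev.category == c for ev in events) for c in transfer.CATEGORIES
        },
        "n_positive_dyads": int((counts > 0).sum()),
        "fraction_positive": float((counts > 0).mean()) if len(counts) else 0.0,
        "events_per_positive_dyad_range": (
            [int(positive.min()), int(positive.max())] if len(positive) else [0, 0]
        ),
        "events_per_positive_dyad_median": float(np.median(positive)) if len(positive) else 0.0,
        "mean_events_per_dyad": float(counts.mean()) if len(counts) else 0.0,
    }

    stat_block: dict[str, Any] = {"headline": headline}
    for column in ("delivery_mode", "ip_antibiotics"):
        groups = [getattr(c, column) for c in per_dyad]
        if len(set(groups)) >= 2:
            res = stats.kruskal_dunn(counts.astype(float), groups)
            stat_block[column] = {
                "groups": res.groups,
                "n": res.n,
                "mean": res.mean,
                "sd": res.sd,
                "H": res.h_statistic,
                "df": res.df,
                "p_omnibus": res.p_omnibus,
                "pairwise": [dataclasses.asdict(p) for p in res.pairwise],
            }
        else:
            stat_block[column] = {"note": "fewer than 2 groups; test not applicable"}
    _write_json(stat_block, out / "stats.json")
    _write_json(
        _manifest(
            {"threshold": threshold, "orientation": orientation, "inclusive": inclusive},
            {"table": table_path, "meta": meta_path, "taxonomy": taxonomy_path},
            {"events": len(events), "dyads": len(cohort), "summary_rows": len(summary)},
        ),
        out / "manifest.json",
    )
    log.info("transfer analysis: %d events across %d dyads", len(events), len(cohort))
    return headline


def run_genomic_analysis(
    out_dir: str | Path,
    alignment_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    gene_matrix_path: str | Path | None = None,
    gene_matrix_dialect: str = "binary",
    ani_k: int = 21,
    ani_mode: str = "exact_sets",
    ani_threshold: float = 0.999,
    snp_threshold: int = 25,
) -> dict:
    """Genomic strain-identity analysis over an alignment and/or gene matrix.

    Emits SNP and ANI matrices, within/between-dyad partition summaries
    with Mann-Whitney tests, UPGMA newick trees, per-dyad identity calls
    and a manifest. Returns a summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = read_genome_labels(labels_path) if labels_path else {}
    origins = {g: info.get("origin") for g, info in labels.items()}
    summary: dict[str, Any] = {}
    inputs: dict[str, str | Path | None] = {}

    if alignment_path is not None:
        inputs["alignment"] = alignment_path
        genomes = read_alignment(alignment_path, aligned=True)
        if labels:
            genomes = genomes.relabel(labels)
        snp = genomics.snp_distance_matrix(genomes)
        snp.write(out / "snp_matrix.tsv")
        matrices = [("snp", snp)]
        if min(len(r.sequence) for r in genomes.records.values()) >= ani_k:
            ani = genomics.ani_matrix(genomes, k=ani_k, mode=ani_mode)
            ani.write(out / "ani_matrix.tsv")
            matrices.append(("ani", ani))
        else:
            log.warning("sequences shorter than k=%d; ANI stage skipped", ani_k)
            summary["ani"] = {"note": f"sequences shorter than k={ani_k}; not computed"}
        tree = genomics.upgma(snp)
        (out / "snp_upgma.nwk").write_text(tree.newick() + "\n")
        for name, matrix in matrices:
            if not matrix.dyad_ids:
                summary[name] = {"note": "no dyad labels; partition not applicable"}
                continue
            part = genomics.partition_by_dyad(matrix)
            block = {
                "median_within": part.median_within,
                "median_between": part.median_between,
                "n_within_pairs": len(part.within_values),
                "n_between_pairs": len(part.between_values),
            }
            if part.test is not None:
                block["mann_whitney_u"] = part.test.u_statistic
                block["p_value"] = part.test.p_value
            else:
                block["note"] = "within or between set empty; test not applicable"
            summary[name] = block
            calls = genomics.strain_identity_call(
                matrix, origins, ani_threshold=ani_threshold, snp_threshold=snp_threshold
            )
            summary[f"{name}_identity_calls"] = calls
        log.info("genomic analysis: %d genomes aligned, SNP+ANI matrices written",
                 len(genomes.genome_ids))

    if gene_matrix_path is not None:
        inputs["gene_matrix"] = gene_matrix_path
        gm = read_gene_matrix(gene_matrix_path, dialect=gene_matrix_dialect)
        dyads = {g: labels[g]["dyad_id"] for g in gm.columns if g in labels}
        jd = genomics.jaccard_gene_distance(gm, dyad_ids=dyads)
        jd.write(out / "gene_jaccard.tsv")
        gene_tree = genomics.upgma(jd)
        (out / "gene_upgma.nwk").write_text(gene_tree.newick() + "\n")
        summary["gene_content"] = {"n_genes": int(gm.shape[0]), "n_genomes": int(gm.shape[1])}

    _write_json(summary, out / "genomic_summary.json")
    _write_json(
        _manifest(
            {"ani_k": ani_k, "ani_mode": ani_mode, "ani_threshold": ani_threshold,
             "snp_threshold": snp_threshold},
            {k: v for k, v in {**inputs, "labels": labels_path}.items() if v},
            {},
        ),
        out / "manifest.json",
    )
    return summary
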