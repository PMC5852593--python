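"""End-to-end pipeline: mine -> annotate -> primers -> stats -> expression.

Stages exchange plain-text TSVs so each is independently testable and
diffable; a JSON manifest records input hashes, parameters and per-stage
record counts. A stage producing zero records halts the run with a clear
message. Identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import read_fasta, read_blast_tab, read_genotype_table, write_newick
from .ssr_mining import (SsrSearchParams, find_ssrs_many, loci_to_frame,
                         summarize_panel)
from .tf_annotation import (TfFilterThresholds, assign_family,
                            annotations_to_frame)
from .primer_design import PrimerConstraints, design_primers
from . import marker_stats as ms
from .expression_profile import (ExpressionMatrix, log2_fold_change,
                                 de_classify, time_course_sets,
                                 hierarchical_cluster, heatmap_export)

log = logging.getLogger("tfssr")


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    blast: str | None = None
    family_map: str | None = None
    genotypes: str | None = None
    fpkm: str | None = None
    baseline_time: str | None = None
    min_tract_length_nt: int = 12
    motif_lengths: tuple[int, ...] = (2, 3, 4, 5, 6)
    max_evalue: float = 1e-10
    min_query_coverage_pct: float = 65.0
    min_identity_pct: float = 40.0
    fst_estimator: str = "weir_cockerham"
    up_threshold: float = 1.0
    down_threshold: float = -1.0
    seed: int = ms.DEFAULT_SEED

    def validate(self) -> None:
        for pct in (self.min_query_coverage_pct, self.min_identity_pct):
            if not 0 <= pct <= 100:
                raise ValueError(f"percentage threshold {pct} outside [0, 100]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if not (self.up_threshold > 0 > self.down_threshold):
            raise ValueError("need up_threshold > 0 > down_threshold")
        for name in ("fasta", "blast", "family_map", "genotypes", "fpkm"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_family_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: subject_id <tab> tf_family."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            cols = ln.split("\t")
            if len(cols) != 2:
                raise ValueError(f"family map line not 2 columns: {ln!r}")
            out[cols[0]] = cols[1]
    return out


def read_fpkm_table(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in order; returns the manifest dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tfssr",
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for name in ("fasta", "blast", "family_map", "genotypes", "fpkm"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def halt_if_empty(stage: str, n: int) -> None:
        manifest["stages"][stage] = {"records": n}
        if n == 0:
            raise RuntimeError(
                f"stage {stage!r} produced zero records; halting "
                "(check thresholds and inputs)")
        log.info("stage %s: %d records", stage, n)

    # --- mine
    records = read_fasta(config.fasta)
    params = SsrSearchParams(
        motif_lengths=frozenset(config.motif_lengths),
        min_tract_length_nt=config.min_tract_length_nt)
    loci = find_ssrs_many(records, params)
    loci_df = loci_to_frame(loci)
    _write_tsv(loci_df, out_dir / "loci.tsv")
    manifest["outputs"]["loci"] = "loci.tsv"
    halt_if_empty("mine", len(loci))

    ssr_seq_ids = sorted(loci_df["seq_id"].unique())

    # --- annotate
    annotated = loci_df
    if config.blast and config.family_map:
        qlens = {r.id: len(r) for r in records}
        hits = read_blast_tab(config.blast, qlens)
        fam_map = read_family_map(config.family_map)
        thresholds = TfFilterThresholds(
            max_evalue=config.max_evalue,
            min_query_coverage_pct=config.min_query_coverage_pct,
            min_identity_pct=config.min_identity_pct)
        annots = assign_family(hits, fam_map, thresholds)
        annots = {q: a for q, a in annots.items() if q in set(ssr_seq_ids)}
        ann_df = annotations_to_frame(annots)
        _write_tsv(ann_df, out_dir / "tf_annotations.tsv")
        annotated = loci_df.merge(
            ann_df[["seq_id", "tf_family"]], on="seq_id", how="inner")
        _write_tsv(annotated, out_dir / "tf_markers.tsv")
        manifest["outputs"]["tf_markers"] = "tf_markers.tsv"
        halt_if_empty("annotate", len(annotated))

    summary = summarize_panel(
        [l for l in loci if l.seq_id in set(annotated["seq_id"])],
        n_sequences_searched=len(records),
        n_ssr_sequences=len(ssr_seq_ids))
    _write_tsv(summary, out_dir / "panel_summary.tsv", index=True)
    manifest["outputs"]["panel_summary"] = "panel_summary.tsv"

    # --- primers
    rec_by_id = {r.id: r for r in records}
    marker_loci = [l for l in loci if l.seq_id in set(annotated["seq_id"])]
    rows = []
    for i, locus in enumerate(marker_loci):
        pairs = design_primers(rec_by_id[locus.seq_id], locus,
                               PrimerConstraints())
        if pairs:
            p = pairs[0]
            rows.append((f"{locus.seq_id}:{locus.start}", p.forward_seq,
                         p.reverse_seq, round(p.forward_tm, 2),
                         round(p.reverse_tm, 2), p.product_size,
                         round(p.penalty, 3)))
    primers_df = pd.DataFrame(
        rows, columns=["locus_id", "fwd_seq", "rev_seq", "fwd_tm", "rev_tm",
                       "product_size", "penalty"])
    _write_tsv(primers_df, out_dir / "primers.tsv")
    manifest["outputs"]["primers"] = "primers.tsv"
    manifest["stages"]["primers"] = {"records": len(primers_df)}

    # --- stats
    if config.genotypes:
        gm = read_genotype_table(config.genotypes)
        stats_dir = out_dir / "stats"
        stats_dir.mkdir(exist_ok=True)
        _write_tsv(ms.per_locus_summary(gm), stats_dir / "per_locus.tsv",
                   index=True)
        if len(set(gm.populations)) >= 2:
            _write_tsv(ms.pairwise_fst_table(gm, config.fst_estimator),
                       stats_dir / "pairwise_fst.tsv", index=True)
            _write_tsv(ms.amova(gm).to_frame(), stats_dir / "amova.tsv",
                       index=True)
        dm = ms.genetic_distance(gm)
        _write_tsv(dm.to_frame(), stats_dir / "distance_matrix.tsv", index=True)
        if len(dm) >= 3:
            tree = ms.neighbor_joining(dm)
            write_newick(tree, stats_dir / "tree.nwk")
        pc = ms.pcoa(dm)
        coords = pd.DataFrame(
            pc.coordinates, index=pc.labels,
            columns=[f"PC{i+1}" for i in range(pc.coordinates.shape[1])])
        _write_tsv(coords, stats_dir / "pcoa_coords.tsv", index=True)
        _write_tsv(pd.DataFrame({"pct_variance": pc.pct_variance}),
                   stats_dir / "pcoa_variance.tsv")
        manifest["outputs"]["stats"] = "stats/"
        manifest["stages"]["stats"] = {"records": gm.n_loci}

    # --- expression
    if config.fpkm and config.baseline_time:
        em = read_fpkm_table(config.fpkm)
        expr_dir = out_dir / "expr"
        expr_dir.mkdir(exist_ok=True)
        lfc = log2_fold_change(em, config.baseline_time)
        _write_tsv(lfc, expr_dir / "log2fc.tsv", index=True)
        labels = de_classify(lfc, config.up_threshold, config.down_threshold)
        _write_tsv(labels, expr_dir / "de_labels.tsv", index=True)
        venn_rows = []
        for direction in ("UP", "DOWN"):
            for tps, count in sorted(time_course_sets(labels, direction).items(),
                                     key=lambda kv: sorted(kv[0])):
                venn_rows.append((direction, "|".join(sorted(tps)), count))
        _write_tsv(pd.DataFrame(venn_rows,
                                columns=["direction", "time_points", "count"]),
                   expr_dir / "venn_counts.tsv")
        clust = hierarchical_cluster(em)
        (expr_dir / "leaf_order.txt").write_text(
            "\n".join(clust.leaf_order) + "\n")
        _write_tsv(heatmap_export(em, clust), expr_dir / "heatmap.tsv",
                   index=True)
        manifest["outputs"]["expression"] = "expr/"
        manifest["stages"]["expression"] = {"records": len(em.gene_ids)}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
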