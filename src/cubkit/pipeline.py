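"""End-to-end orchestration: QC -> composition -> indices -> inference.

Every number written by the pipeline is produced by one of the library
operations; this module only sequences them, writes TSV/JSON artifacts and
hashes them into a manifest. Output directories are versioned (``run-001``,
``run-002`` ...) so a re-run never mutates earlier results in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import composition, evolution, indices, ingest_qc, plots
from .genetic_code import GeneticCode

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a run cannot produce its analysis outputs."""


@dataclass
class PipelineConfig:
    fasta: Optional[str] = None
    genbank: Optional[str] = None
    metadata: Optional[str] = None
    out_dir: str = "cubkit_out"
    code_table: int = 11
    accepted_starts: tuple = ("ATG",)
    min_len_nt: int = 300
    max_n_codon_frac: float = 0.05
    pr2_boxes: str = "eight"
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    near_curve_band: float = 2.0
    make_plots: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "accepted_starts" in data:
            data["accepted_starts"] = tuple(data["accepted_starts"])
        return cls(**data)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["accepted_starts"] = list(d["accepted_starts"])
        return yaml.safe_dump(d, sort_keys=True)


def _versioned_run_dir(base) -> Path:
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    k = 1
    while (base / f"run-{k:03d}").exists():
        k += 1
    run = base / f"run-{k:03d}"
    run.mkdir()
    return run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_sequences(config: PipelineConfig) -> list:
    if config.fasta is None and config.genbank is None:
        raise PipelineError("no input: set fasta or genbank")
    seqs = []
    if config.fasta is not None:
        seqs.extend(ingest_qc.read_cds_fasta(config.fasta,
                                             metadata=config.metadata))
    if config.genbank is not None:
        seqs.extend(ingest_qc.extract_cds_from_genbank(config.genbank))
    return seqs


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_tables(seqs, code: GeneticCode, config: PipelineConfig) -> dict:
    """Compute all per-record and group-level tables from passed sequences."""
    stripped = [ingest_qc.strip_terminal_stop(s, code) for s in seqs]
    per_record = [ingest_qc.count_codons(s) for s in stripped]
    tables: dict = {"codon_counts": ingest_qc.counts_frame(per_record)}

    comp_rows, index_rows, rscu_rows = [], [], []
    for seq, counts in zip(stripped, per_record):
        labels = {"gene": seq.gene, "taxon": seq.taxon, "family": seq.family}
        stats = composition.composition_stats(counts, code)
        comp_rows.append({**labels, "gc1": stats.gc1, "gc2": stats.gc2,
                          "gc3": stats.gc3, "gc12": stats.gc12,
                          "gc_total": stats.gc_total, "gc3s": stats.gc3s,
                          "n_codons": stats.n_codons})
        enc_res = indices.enc(counts, code)
        if enc_res.enc is None:
            logger.warning("ENC undefined for %s: %s", seq.id,
                           enc_res.undefined_reason)
        try:
            pr2 = indices.pr2_bias(counts, code, boxes=config.pr2_boxes)
            au, gc, n4 = pr2.au_bias, pr2.gc_bias, pr2.n_fourfold_codons
        except ValueError:
            au = gc = math.nan
            n4 = 0
        index_rows.append({**labels, "enc": enc_res.enc, "gc3s": stats.gc3s,
                           "au_bias": au, "gc_bias": gc,
                           "n_fourfold_codons": n4,
                           "n_codons": counts.n_codons})
        rscu_rows.append({**labels,
                          **indices.rscu(counts, code).values})
    tables["composition"] = pd.DataFrame(comp_rows)
    tables["indices"] = pd.DataFrame(index_rows)
    tables["rscu_records"] = pd.DataFrame(rscu_rows)

    # family-level RSCU on concatenated counts
    by_family: dict = {}
    for seq, counts in zip(stripped, per_record):
        by_family.setdefault(seq.family, []).append(counts)
    fam_rows = {}
    for family, group in sorted(by_family.items()):
        concat = ingest_qc.concatenate_counts(group, label=family)
        fam_rows[family] = indices.rscu(concat, code).values
    tables["rscu_families"] = pd.DataFrame.from_dict(fam_rows, orient="index") \
        .rename_axis("family")
    return tables


def analyze_tables(tables: dict, config: PipelineConfig) -> dict:
    """Group summaries, neutrality fits, ENC-plot points and clustering."""
    out: dict = {}
    idx = tables["indices"].dropna(subset=["enc"])
    comp = tables["composition"]

    out["summary_enc_gene_family"] = evolution.group_summary(
        idx, "enc", by=("gene", "family"))
    out["summary_enc_gene"] = evolution.group_summary(idx, "enc", by=("gene",))
    gc_summaries = []
    for stat in ("gc_total", "gc1", "gc2", "gc3"):
        s = evolution.group_summary(comp, stat, by=("family",))
        s.insert(1, "statistic", stat)
        gc_summaries.append(s)
    out["summary_gc_family"] = pd.concat(gc_summaries, ignore_index=True)

    fits = []
    pooled = None
    for family, sub in comp.groupby("family"):
        try:
            fits.append(evolution.neutrality_fit(sub["gc3"], sub["gc12"],
                                                 group=family))
        except ValueError as exc:
            logger.warning("neutrality fit skipped for %s: %s", family, exc)
    try:
        pooled = evolution.neutrality_fit(comp["gc3"], comp["gc12"],
                                          group="ALL")
    except ValueError as exc:
        logger.warning("pooled neutrality fit skipped: %s", exc)
    if pooled is not None:
        fits.append(pooled)
    out["neutrality"] = evolution.neutrality_table(fits)

    points = evolution.enc_gc3s_points(idx.dropna(subset=["gc3s"]))
    out["enc_gc3s_points"] = points
    near = evolution.near_curve_fraction(points, band=config.near_curve_band,
                                         by=("family",))
    out["near_curve"] = near.rename("near_curve_fraction").reset_index()

    fam_matrix = tables["rscu_families"]
    if fam_matrix.shape[0] >= 2:
        out["cluster"] = evolution.rscu_cluster(
            fam_matrix, metric=config.cluster_metric,
            method=config.cluster_method)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run everything; returns the manifest (also written as JSON)."""
    run_dir = _versioned_run_dir(config.out_dir)
    logger.info("output directory: %s", run_dir)
    (run_dir / "config.yaml").write_text(config.to_yaml())

    code = GeneticCode.from_ncbi(config.code_table,
                                 accepted_starts=config.accepted_starts)
    seqs = load_sequences(config)
    logger.info("ingest: %d sequences read", len(seqs))
    passed, reports = ingest_qc.qc_filter(
        seqs, code, min_len_nt=config.min_len_nt,
        max_n_codon_frac=config.max_n_codon_frac)
    _write_tsv(ingest_qc.qc_report_frame(reports), run_dir / "qc_report.tsv")
    logger.info("qc: %d of %d sequences passed", len(passed), len(seqs))
    if not passed:
        _finish_manifest(run_dir, config)
        raise PipelineError(
            f"no sequences passed QC (report in {run_dir / 'qc_report.tsv'})")

    tables = build_tables(passed, code, config)
    for name in ("codon_counts", "composition", "indices", "rscu_records"):
        _write_tsv(tables[name], run_dir / f"{name}.tsv")
    tables["rscu_families"].reset_index().pipe(
        _write_tsv, run_dir / "rscu_families.tsv")

    results = analyze_tables(tables, config)
    for name in ("summary_enc_gene_family", "summary_enc_gene",
                 "summary_gc_family", "neutrality", "enc_gc3s_points",
                 "near_curve"):
        _write_tsv(results[name], run_dir / f"{name}.tsv")
    cluster = results.get("cluster")
    if cluster is not None:
        cluster.matrix.reset_index().rename(columns={"index": "family"}).pipe(
            _write_tsv, run_dir / "rscu_clustered.tsv")
        (run_dir / "rscu_rows.nwk").write_text(cluster.row_newick() + "\n")
        (run_dir / "rscu_cols.nwk").write_text(cluster.col_newick() + "\n")

    if config.make_plots:
        plots.plot_enc_gc3s(results["enc_gc3s_points"],
                            run_dir / "enc_gc3s_plot")
        plots.plot_pr2(tables["indices"].dropna(subset=["au_bias", "gc_bias"]),
                       run_dir / "pr2_plot")
        plots.plot_neutrality(tables["composition"], results["neutrality"],
                              run_dir / "neutrality_plot")
        if cluster is not None:
            plots.plot_rscu_heatmap(cluster, run_dir / "rscu_heatmap")

    return _finish_manifest(run_dir, config)


def _finish_manifest(run_dir: Path, config: PipelineConfig) -> dict:
    manifest = {"run_dir": str(run_dir), "artifacts": {}}
    for path in sorted(run_dir.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["artifacts"][path.name] = {
            "sha256": _sha256(path), "bytes": path.stat().st_size}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
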