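"""End-to-end orchestration: scan -> classify -> duplicates -> Ka/Ks -> tree
-> promoters -> expression, with a manifest of hashed outputs.

Every stage reads and writes plain TSV (header row, '#' comments allowed),
so a run is fully reproducible from its config: rerunning with identical
inputs and parameters yields byte-identical outputs and hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as classify_mod
from . import duplication as dup_mod
from . import expression as expr_mod
from . import kaks as kaks_mod
from . import motif as motif_mod
from . import phylo as phylo_mod
from . import promoter as prom_mod
from . import sequence_io as seqio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    gene_table: str | None = None
    genome_fasta: str | None = None
    expression_tsv: str | None = None
    qpcr_tsv: str | None = None
    out_dir: str = "nsltp_out"
    # module parameters, with the survey's documented defaults
    scan_slack: int = 0
    max_score: int = 0
    min_identity: float = dup_mod.DEFAULT_MIN_IDENTITY
    min_coverage: float = dup_mod.DEFAULT_MIN_COVERAGE
    tandem_max_separation: int = dup_mod.DEFAULT_TANDEM_MAX_SEPARATION
    tandem_max_intervening: int = dup_mod.DEFAULT_TANDEM_MAX_INTERVENING
    clock_rate: float = kaks_mod.DEFAULT_CLOCK_RATE
    promoter_length: int = 2000
    control_condition: str = "control"
    seed: int = 0
    stages: tuple[str, ...] = (
        "scan", "classify", "duplicates", "kaks", "tree", "promoters", "expression",
    )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "outputs": {},
        "skipped": [s for s in (
            "scan", "classify", "duplicates", "kaks", "tree", "promoters", "expression",
        ) if s not in config.stages],
    }
    logger.info(
        "thresholds: identity>%s%% coverage>%s%% r=%s promoter=%sbp",
        config.min_identity, config.min_coverage, config.clock_rate,
        config.promoter_length,
    )

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _hash_file(path),
        }

    records = []
    if config.protein_fasta:
        proteins = seqio.read_fasta(config.protein_fasta, "protein")
        cds = (
            seqio.read_fasta(config.cds_fasta, "nucleotide")
            if config.cds_fasta
            else None
        )
        table = seqio.read_gene_table(config.gene_table) if config.gene_table else None
        records = seqio.build_records(proteins, cds, table)
    rec_by_id = {r.gene_id: r for r in records}

    assignments: dict[str, str] = {}
    if "scan" in config.stages and records:
        bounds = motif_mod.ScanBounds().widened(config.scan_slack)
        rows = []
        best: dict[str, motif_mod.EightCMMatch] = {}
        for r in records:
            matches = motif_mod.scan_8cm(r.protein_seq, bounds)
            m = motif_mod.best_match(matches)
            if m is not None:
                best[r.gene_id] = m
                rows.append(
                    dict(
                        gene_id=r.gene_id,
                        **dict(zip(motif_mod.GAP_NAMES, m.spacing)),
                        x_residue=m.x_residue,
                        cys_positions=",".join(map(str, m.cys_positions)),
                    )
                )
        path = out / "matches.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        record("matches", path)

        if "classify" in config.stages:
            assigns = [
                classify_mod.assign_type(m, gene_id=gid, max_score=config.max_score)
                for gid, m in best.items()
            ]
            assignments = {a.gene_id: a.type_label for a in assigns}
            path = out / "types.tsv"
            _write_tsv(
                pd.DataFrame(
                    [dataclasses.asdict(a) for a in assigns]
                ),
                path,
            )
            record("types", path)
            if assigns:
                path = out / "composition.tsv"
                _write_tsv(classify_mod.family_summary(assigns), path, index=True)
                record("composition", path)

    dup_pairs = []
    if "duplicates" in config.stages and len(records) >= 2:
        dup_pairs = dup_mod.call_duplicates(
            records, config.min_identity, config.min_coverage
        )
        if all(r.start is not None for r in records):
            dup_pairs = [
                dup_mod.classify_mode(
                    p, rec_by_id, records,
                    config.tandem_max_separation, config.tandem_max_intervening,
                )
                for p in dup_pairs
            ]
            dup_pairs = dup_mod.collapse_tandem_arrays(dup_pairs, rec_by_id)
        dup_pairs = [dup_mod.shared_type_label(p, assignments) for p in dup_pairs]
        path = out / "duplicates.tsv"
        _write_tsv(pd.DataFrame([dataclasses.asdict(p) for p in dup_pairs]), path)
        record("duplicates", path)

    if "kaks" in config.stages and dup_pairs:
        clock = kaks_mod.ClockConfig(config.clock_rate)
        rows = []
        for p in dup_pairs:
            a, b = rec_by_id[p.gene_a], rec_by_id[p.gene_b]
            if a.cds_seq is None or b.cds_seq is None:
                continue
            res = kaks_mod.kaks_report(
                a.protein_seq, b.protein_seq, a.coding_cds, b.coding_cds, clock
            )
            rows.append(
                dict(
                    gene_a=p.gene_a, gene_b=p.gene_b, type_label=p.type_label,
                    Ka=res.Ka, Ks=res.Ks,
                    ratio="NA" if res.ratio is None else res.ratio,
                    purifying="NA" if res.purifying is None
                    else ("Y" if res.purifying else "N"),
                    mode=p.mode, age_mya=res.age_mya,
                )
            )
        path = out / "kaks.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        record("kaks", path)

    if "tree" in config.stages and len(records) >= 3:
        tree = phylo_mod.neighbor_joining(phylo_mod.pdistance_matrix(records))
        path = out / "tree.nwk"
        path.write_text(phylo_mod.tree_to_newick(tree) + "\n")
        record("tree", path)

    if "promoters" in config.stages and config.genome_fasta and records:
        genome = dict(seqio.read_fasta(config.genome_fasta, "nucleotide"))
        proms = prom_mod.extract_promoters(records, genome, config.promoter_length)
        table = prom_mod.scan_elements(proms)
        path = out / "promoter_elements.tsv"
        _write_tsv(table, path, index=True)
        record("promoter_elements", path)
        by_cat, argmax = prom_mod.category_summary(table)
        path = out / "promoter_categories.tsv"
        _write_tsv(by_cat, path, index=True)
        record("promoter_categories", path)

    if "expression" in config.stages and config.expression_tsv:
        m = expr_mod.read_expression_tsv(config.expression_tsv)
        m = expr_mod.collapse_replicates(expr_mod.log2p1(m))
        path = out / "expression_log2_median.tsv"
        _write_tsv(m.values, path, index=True)
        record("expression_log2_median", path)
        if len(m.values) >= 2:
            _, leaf_order = expr_mod.hierarchical_cluster(m)
            path = out / "expression_gene_order.tsv"
            path.write_text("\n".join(leaf_order) + "\n")
            record("expression_gene_order", path)

    if "expression" in config.stages and config.qpcr_tsv:
        q = expr_mod.read_qpcr_tsv(config.qpcr_tsv)
        folds = expr_mod.ddct(q, config.control_condition)
        path = out / "qpcr_folds.tsv"
        _write_tsv(folds, path)
        record("qpcr_folds", path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
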