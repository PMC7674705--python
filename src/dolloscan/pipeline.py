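"""End-to-end orchestration: scan -> classify -> reconstruct -> report.

The pipeline consumes a dataset directory (per-species contig FASTA files,
a GFF3 of gene models, a rooted Newick species tree, a FASTA of intact
reference CDS per gene family) plus a configuration mapping, and produces
TSV/JSON reports: per-copy lesions, the species x gene status matrix, loss
events with bottleneck labels, and the minimal ancestral gene content per
tree node.  Reruns with the same inputs are byte-identical; every report
bundle embeds a hash of the configuration it was produced from.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    LossEvent,
    dollo_reconstruct,
    gene_content_report,
    label_bottlenecks,
)
from .formats import (
    GeneModel,
    read_fasta,
    read_gff3_gene_models,
    read_newick,
    write_status_matrix,
)
from .lesions import LesionReport, ScanParams, scan_gene, slice_first_exons
from .statuses import ClassificationParams, GeneStatusMatrix, classify, presence_vector
from .tree import SpeciesTree

log = logging.getLogger("dolloscan")


def first_intron_length(gene_model: GeneModel) -> Optional[int]:
    """Length (bp) of the intron between the first two exons in
    transcription order; ``None`` for single-exon models."""
    if gene_model.n_exons < 2:
        return None
    tx = gene_model.exons_in_transcription_order()
    if gene_model.strand == "+":
        return tx[1][0] - tx[0][1]
    return tx[0][0] - tx[1][1]


@dataclass
class PipelineResult:
    status_matrix: GeneStatusMatrix
    reports: dict[tuple[str, str], Optional[LesionReport]]
    loss_events: list[LossEvent]
    gene_content: pd.DataFrame
    config_hash: str
    out_dir: Optional[Path] = None


def _config_hash(config: dict) -> str:
    # out_dir is a destination, not an analysis parameter
    canon = json.dumps(
        {k: v for k, v in config.items() if k != "out_dir"},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _gene_of(model: GeneModel) -> str:
    # simulator convention "<species>__<gene>"; otherwise the id itself
    return model.gene_id.split("__", 1)[1] if "__" in model.gene_id else model.gene_id


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Run all stages.  Required config keys: ``data_dir`` (with
    ``genomes/``, ``models.gff3``, ``tree.nwk``, ``reference.fasta``).
    Optional: ``out_dir``, ``k_exons``, and per-stage parameter sections
    ``scan``, ``classification``, ``ancestry``."""
    cfg = _load_config(config)
    if "data_dir" not in cfg:
        raise ValueError("pipeline config needs 'data_dir'")
    data_dir = Path(cfg["data_dir"])
    cfg_hash = _config_hash(cfg)

    log.info("stage load: reading inputs from %s", data_dir)
    try:
        tree = read_newick(data_dir / "tree.nwk")
        models = read_gff3_gene_models(data_dir / "models.gff3")
        references = {r.id: r.seq for r in read_fasta(data_dir / "reference.fasta")}
    except Exception as exc:
        raise RuntimeError(f"stage load failed: {exc}") from exc

    species_list = tree.leaf_labels()
    if not species_list:
        raise ValueError("stage load: species tree has no leaves")

    genomes: dict[str, dict[str, str]] = {}
    for sp in species_list:
        fasta = data_dir / "genomes" / f"{sp}.fasta"
        if fasta.exists():
            genomes[sp] = {r.id: r.seq for r in read_fasta(fasta)}
        else:
            genomes[sp] = {}

    scan_cfg = cfg.get("scan", {}) or {}
    k_exons = cfg.get("k_exons")
    params = ScanParams(
        max_n_fraction=scan_cfg.get("max_n_fraction", 0.05),
        min_coverage=scan_cfg.get("min_coverage", 0.9),
        rescue_window=scan_cfg.get("rescue_window", 60),
    )

    genes = sorted(references)
    by_pair: dict[tuple[str, str], GeneModel] = {}
    for m in models:
        gene = _gene_of(m)
        if gene not in references:
            raise RuntimeError(
                f"stage scan failed: no reference CDS for gene {gene!r}"
            )
        by_pair[(m.species, gene)] = m

    log.info("stage scan: %d species x %d genes", len(species_list), len(genes))
    reports: dict[tuple[str, str], Optional[LesionReport]] = {}
    for sp in species_list:
        for gene in genes:
            model = by_pair.get((sp, gene))
            if model is None:
                reports[(sp, gene)] = None  # no sequence found -> ABSENT
                continue
            contig = genomes.get(sp, {}).get(model.contig)
            if contig is None:
                raise RuntimeError(
                    f"stage scan failed: contig {model.contig!r} missing for {sp}"
                )
            if k_exons:
                model = slice_first_exons(model, int(k_exons))
            reports[(sp, gene)] = scan_gene(contig, model, references[gene], params)

    cls_cfg = cfg.get("classification", {}) or {}
    cls_params = ClassificationParams(**cls_cfg)
    log.info("stage classify")
    matrix = classify(reports, tree, cls_params)

    anc_cfg = cfg.get("ancestry", {}) or {}
    policy = anc_cfg.get("policy", "drop")
    assert_root = bool(anc_cfg.get("assert_root_presence", False))
    log.info("stage reconstruct")
    loss_events: list[LossEvent] = []
    for gene in genes:
        presence = presence_vector(matrix, gene, policy=policy)
        known = {s: v for s, v in presence.items() if v != "unknown"}
        dropped = set(tree.leaf_labels()) - set(known)
        subtree = tree.pruned(dropped) if dropped else tree
        states = dollo_reconstruct(
            subtree, known, gene=gene, assert_root_presence=assert_root
        )
        loss_events.extend(label_bottlenecks(states, subtree))
    content = gene_content_report(matrix, tree, policy=policy,
                                  assert_root_presence=assert_root)

    out_dir = None
    if cfg.get("out_dir"):
        out_dir = Path(cfg["out_dir"])
        _write_reports(out_dir, cfg_hash, matrix, reports, loss_events, content)

    return PipelineResult(
        status_matrix=matrix,
        reports=reports,
        loss_events=loss_events,
        gene_content=content,
        config_hash=cfg_hash,
        out_dir=out_dir,
    )


def _write_reports(
    out_dir: Path,
    cfg_hash: str,
    matrix: GeneStatusMatrix,
    reports: dict[tuple[str, str], Optional[LesionReport]],
    loss_events: list[LossEvent],
    content: pd.DataFrame,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_status_matrix(matrix, out_dir / "status_matrix.tsv")

    rows = []
    for (sp, gene), rep in sorted(reports.items()):
        if rep is None:
            continue
        for l in rep.lesions:
            rows.append(
                {
                    "gene": gene,
                    "species": sp,
                    "kind": l.kind,
                    "cds_pos": l.cds_pos,
                    "genomic_pos": l.genomic_pos,
                    "exon_index": l.exon_index,
                    "detail": l.detail,
                    "rescuable": l.rescuable,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "species", "kind", "cds_pos", "genomic_pos",
            "exon_index", "detail", "rescuable",
        ],
    ).to_csv(out_dir / "lesions.tsv", sep="\t", index=False)

    ev_rows = [
        {
            "gene": ev.gene,
            "parent": ev.branch[0],
            "child": ev.branch[1],
            "kind": ev.kind,
            "affected_leaves": ",".join(sorted(ev.affected_leaves)),
            "age_interval": (
                f"{ev.age_interval[0]:.4f}-{ev.age_interval[1]:.4f}"
                if ev.age_interval
                else ""
            ),
        }
        for ev in sorted(loss_events, key=lambda e: (e.gene, e.branch[1] or ""))
    ]
    pd.DataFrame(
        ev_rows,
        columns=["gene", "parent", "child", "kind", "affected_leaves", "age_interval"],
    ).to_csv(out_dir / "loss_events.tsv", sep="\t", index=False)

    content.to_csv(out_dir / "gene_content.tsv", sep="\t")
    (out_dir / "report.json").write_text(
        json.dumps(
            {
                "config_hash": cfg_hash,
                "version": __version__,
                "n_species": len(matrix.species),
                "genes": matrix.genes,
                "n_loss_events": len(loss_events),
                "status_counts": {
                    s: sum(1 for v in matrix.statuses.values() if v == s)
                    for s in sorted(set(matrix.statuses.values()))
                },
            },
            indent=1,
        )
    )
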