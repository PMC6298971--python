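"""End-to-end orchestration: genomes -> PULs -> substrates -> SusC/D
reference trees -> expression profiles.

Input directory layout (as produced by ``synthetic_data.write_dataset``)::

    <in>/genomes/<genome_id>/genes.gff3
    <in>/genomes/<genome_id>/proteins.faa
    <in>/genomes/<genome_id>/evidence.tsv
    <in>/proteome/counts.tsv
    <in>/proteome/queries_susC.faa
    <in>/proteome/queries_susD.faa
    <in>/proteome/samples.tsv

Stages run in fixed order; every output is deterministic so repeated
runs on identical inputs yield identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import genome_io
from .feature_annotation import AnnotationConfig, annotate_genome, summarize_genome
from .model import ValidationError, format_float
from .pul_detection import detect_puls, pul_sus_proteins
from .substrate_rules import classify_pul, default_rule_table, load_rule_table, summarize_predictions
from .suscd_reference import (
    build_identity_matrix,
    build_nj_tree,
    extract_substrate_clusters,
    suscd_congruence,
)
from .expression_profiling import (
    assign_bloom_phase,
    average_technical_duplicates,
    build_substrate_profile,
    compute_pct_nsaf,
    place_expressed,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    gap_tolerance: int = 3
    min_cazymes: int = 2
    purity_threshold: float = 0.8
    min_cluster_size: int = 3
    identity_threshold: float = 40.0
    min_pct_nsaf: float = 0.05
    chl_threshold_early: float = 5.0
    chl_threshold_mid: float = 15.0
    seed: int = 0
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    rules_path: Optional[Path] = None

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.gap_tolerance < 0 or self.min_cazymes < 1:
            raise ValidationError("invalid detection parameters")
        if not (0 < self.purity_threshold <= 1):
            raise ValidationError("purity_threshold must be in (0, 1]")
        if self.min_pct_nsaf < 0 or self.identity_threshold < 0:
            raise ValidationError("thresholds must be non-negative")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["output_dir"] = str(self.output_dir)
        d["rules_path"] = str(self.rules_path) if self.rules_path else None
        d["annotation"]["tbdt_labels"] = sorted(self.annotation.tbdt_labels)
        d["annotation"]["susE_labels"] = sorted(self.annotation.susE_labels)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ann = AnnotationConfig(**raw.pop("annotation", {}))
        return cls(annotation=ann, **raw)


def run_genome_stage(config: RunConfig) -> dict:
    """Annotate genomes, detect PULs, classify substrates, build SusC/D
    reference trees and substrate clusters, measure congruence."""
    genome_dirs = sorted((config.input_dir / "genomes").iterdir())
    if not genome_dirs:
        raise ValidationError(f"no genomes under {config.input_dir / 'genomes'}")
    for gdir in genome_dirs:
        for fn in ("genes.gff3", "proteins.faa", "evidence.tsv"):
            if not (gdir / fn).exists():
                raise ValidationError(f"missing input file {gdir / fn}")

    rules = (
        load_rule_table(config.rules_path, base=default_rule_table())
        if config.rules_path
        else default_rule_table()
    )

    genomes, all_puls, all_predictions, summaries = [], [], [], []
    sus_seqs = {"susC": {}, "susD": {}}
    sus_labels = {"susC": {}, "susD": {}}
    pul_pairs = []
    prediction_by_pul = {}

    for gdir in genome_dirs:
        genome = genome_io.read_genome(gdir / "genes.gff3", gdir / "proteins.faa", gdir.name)
        evidence = genome_io.read_evidence(gdir / "evidence.tsv")
        assignments = annotate_genome(genome, evidence, config.annotation)
        puls = detect_puls(genome, assignments, config.gap_tolerance, config.min_cazymes)
        predictions = [classify_pul(p, rules) for p in puls]
        summaries.append(summarize_genome(genome, assignments, puls))
        genomes.append(genome)
        all_puls.extend(puls)
        all_predictions.extend(predictions)
        logger.info("genome %s: %d genes, %d PULs", genome.genome_id, len(genome.genes), len(puls))

        for pul, pred in zip(puls, predictions):
            prediction_by_pul[pul.pul_id] = pred
            sus = pul_sus_proteins(pul, genome, assignments)
            label = {
                "genome_id": genome.genome_id,
                "pul_id": pul.pul_id,
                "substrate": None if pred.substrate == "unclassified" else pred.substrate,
            }
            for cls in ("susC", "susD"):
                for gid, seq in sus[cls]:
                    sus_seqs[cls][gid] = seq
                    sus_labels[cls][gid] = dict(label)
            for c_id, d_id in pul.susCD_pairs:
                pul_pairs.append((pul.pul_id, c_id, d_id))

    identity, trees, clusters = {}, {}, {}
    for cls in ("susC", "susD"):
        if len(sus_seqs[cls]) >= 3:
            identity[cls] = build_identity_matrix(sus_seqs[cls])
            trees[cls] = build_nj_tree(identity[cls], sus_labels[cls])
            clusters[cls] = extract_substrate_clusters(
                trees[cls], config.purity_threshold, config.min_cluster_size
            )
        else:
            clusters[cls] = []
    congruence = suscd_congruence(clusters["susC"], clusters["susD"], pul_pairs)

    summary_df = pd.DataFrame(
        [
            {
                "genome_id": s.genome_id,
                "n_degradative_cazymes": s.n_degradative_cazymes,
                "degradative_cazymes_per_mbp": s.degradative_cazymes_per_mbp,
                "n_sulfatases": s.n_sulfatases,
                "n_peptidases": s.n_peptidases,
                "peptidase_cazyme_ratio": s.peptidase_cazyme_ratio
                if s.peptidase_cazyme_ratio is not None
                else float("nan"),
                "n_puls": s.n_puls,
            }
            for s in summaries
        ]
    )
    substrate_table, variant_table = summarize_predictions(
        all_predictions, all_puls, [g.genome_id for g in genomes]
    )
    return {
        "genomes": genomes,
        "puls": all_puls,
        "predictions": all_predictions,
        "prediction_by_pul": prediction_by_pul,
        "summaries": summary_df,
        "substrate_table": substrate_table,
        "variant_table": variant_table,
        "reference_seqs": sus_seqs,
        "reference_labels": sus_labels,
        "identity": identity,
        "trees": trees,
        "clusters": clusters,
        "pul_pairs": pul_pairs,
        "congruence": congruence,
    }


def run_expression_stage(config: RunConfig, genome_results: dict) -> dict:
    """%NSAF computation, placement of expressed homologs on the labelled
    reference, and substrate-by-sample profiles per protein class."""
    pdir = config.input_dir / "proteome"
    counts = genome_io.read_counts(pdir / "counts.tsv")
    metadata = genome_io.read_sample_metadata(pdir / "samples.tsv")
    metadata = assign_bloom_phase(
        metadata, config.chl_threshold_early, config.chl_threshold_mid
    )
    averaged = average_technical_duplicates(counts)
    expr = compute_pct_nsaf(averaged)

    frames = []
    for cls in ("susC", "susD"):
        qpath = pdir / f"queries_{cls}.faa"
        if not qpath.exists():
            continue
        queries = genome_io.read_protein_fasta(qpath)
        reference = {
            rid: (seq, genome_results["reference_labels"][cls][rid]["substrate"])
            for rid, seq in genome_results["reference_seqs"][cls].items()
        }
        if not reference:
            continue
        placements = place_expressed(queries, reference, config.identity_threshold)
        placements["protein_class"] = f"{cls}_like"
        frames.append(placements)
    placements = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["protein_id", "placed_reference", "placement_identity", "inherited_substrate", "status", "protein_class"]
        )
    )
    expression = expr.merge(placements, on="protein_id", how="inner")
    profile = build_substrate_profile(expression, metadata, config.min_pct_nsaf)
    return {
        "metadata": metadata,
        "expression": expression,
        "placements": placements,
        "profile": profile,
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run both stages and write every output plus a hashed manifest."""
    genome_results = run_genome_stage(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    results = {
        "puls": genome_results["puls"],
        "predictions": genome_results["predictions"],
        "summaries": genome_results["summaries"],
        "identity": genome_results["identity"],
        "trees": genome_results["trees"],
    }
    expression_results = None
    if (config.input_dir / "proteome" / "counts.tsv").exists():
        expression_results = run_expression_stage(config, genome_results)
        profile = expression_results["profile"]
        results["expression"] = expression_results["expression"][
            [
                "protein_id",
                "sample_id",
                "protein_class",
                "pct_nsaf",
                "placed_reference",
                "placement_identity",
                "inherited_substrate",
                "status",
            ]
        ]
        results["profiles"] = {"susC": profile.susC, "susD": profile.susD}

    rowcounts = genome_io.write_outputs(results, out)
    genome_io._write_tsv(genome_results["substrate_table"], out / "substrate_prevalence.tsv")
    rowcounts["substrate_prevalence.tsv"] = len(genome_results["substrate_table"])
    genome_io._write_tsv(genome_results["variant_table"], out / "variant_counts.tsv")
    rowcounts["variant_counts.tsv"] = len(genome_results["variant_table"])

    cluster_rows = [
        {
            "protein_class": cls,
            "cluster_id": c.cluster_id,
            "majority_substrate": c.majority_substrate,
            "purity": c.purity,
            "n_members": len(c.members),
            "members": ";".join(c.members),
        }
        for cls in ("susC", "susD")
        for c in genome_results["clusters"][cls]
    ]
    clusters_df = pd.DataFrame(
        cluster_rows,
        columns=["protein_class", "cluster_id", "majority_substrate", "purity", "n_members", "members"],
    )
    genome_io._write_tsv(clusters_df, out / "substrate_clusters.tsv")
    rowcounts["substrate_clusters.tsv"] = len(clusters_df)

    congruence = genome_results["congruence"]
    manifest = {
        "config": config.echo(),
        "congruence_susCD": format_float(congruence) if congruence is not None else None,
        "files": {
            fn: {"rows": n, "sha256": _hash_file(out / fn)}
            for fn, n in sorted(rowcounts.items())
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {
        "genome": genome_results,
        "expression": expression_results,
        "manifest": manifest,
    }
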