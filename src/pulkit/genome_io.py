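"""Readers and writers for all external formats.

Inputs: GFF3 (CDS features) + amino-acid FASTA per genome, TSV tables
for domain evidence, spectral counts and sample metadata.  Outputs:
deterministic TSV/JSON/Newick files (fixed column order, floats with 6
significant digits, rows sorted by primary key) plus a manifest listing
every file with its row count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    DomainEvidence,
    EVIDENCE_SOURCES,
    GeneRecord,
    Genome,
    GFFParseError,
    IdentityMatrix,
    LabelledTree,
    PUL,
    SubstratePrediction,
    ValidationError,
    format_float,
    serialize_family_counts,
)

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = [
    "protein_id",
    "sample_id",
    "replicate_id",
    "spectral_count",
    "protein_length_aa",
]
METADATA_COLUMNS = ["sample_id", "date"]  # chlorophyll_a / bloom_phase optional


def _prevalidate_gff(gff_path: Path) -> None:
    """Cheap structural scan so parse errors can name the offending line."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GFFParseError(
                    f"{gff_path}:{lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise GFFParseError(
                    f"{gff_path}:{lineno}: invalid coordinate range {start}..{end}"
                )


def read_genome(gff_path, faa_path, genome_id: Optional[str] = None) -> Genome:
    """Read a genome from GFF3 CDS features plus a protein FASTA.

    Gene identity is the GFF ``ID`` attribute, falling back to
    ``locus_tag``.  External 1-based inclusive coordinates are converted
    to the internal 0-based half-open convention.  CDS features without
    a matching FASTA record are dropped with a logged warning and
    counted in ``Genome.n_dropped``.
    """
    gff_path, faa_path = Path(gff_path), Path(faa_path)
    if genome_id is None:
        genome_id = gff_path.stem
    _prevalidate_gff(gff_path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(faa_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )

    genes: list[GeneRecord] = []
    seen: set[str] = set()
    dropped = 0
    contig_max: dict[str, int] = {}
    for feat in db.features_of_type("CDS"):
        gid = (feat.attributes.get("ID") or feat.attributes.get("locus_tag") or [None])[0]
        if gid is None:
            raise ValidationError(
                f"{gff_path}: CDS at {feat.seqid}:{feat.start}-{feat.end} "
                "has neither ID nor locus_tag"
            )
        if gid in seen:
            raise ValidationError(f"{gff_path}: duplicate gene id {gid!r}")
        seen.add(gid)
        contig_max[feat.seqid] = max(contig_max.get(feat.seqid, 0), feat.end)
        seq = seqs.get(gid)
        if seq is None:
            dropped += 1
            logger.warning("genome %s: no protein sequence for %s; dropped", genome_id, gid)
            continue
        genes.append(
            GeneRecord(
                gene_id=gid,
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                protein_seq=seq,
            )
        )

    size_bp = 0
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            if len(parts) >= 4:
                size_bp += int(parts[3])
    if size_bp == 0:
        size_bp = sum(contig_max.values())
    if size_bp == 0:
        raise ValidationError(f"{gff_path}: cannot determine genome size")
    if dropped:
        logger.warning("genome %s: dropped %d CDS without protein sequence", genome_id, dropped)
    return Genome(genome_id=genome_id, genes=genes, size_bp=size_bp, n_dropped=dropped)


def read_evidence(tsv_path) -> list[DomainEvidence]:
    """Read a domain-evidence table (gene_id, source, label, score)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, comment="#")
    if df.empty and list(df.columns) == []:
        return []
    missing = {"gene_id", "source", "label", "score"} - set(df.columns)
    if missing:
        raise ValidationError(f"{tsv_path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{tsv_path}: non-numeric score {row.score!r} for gene {row.gene_id}"
            ) from None
        out.append(DomainEvidence(row.gene_id, row.source, row.label, score))
    return out


def read_counts(tsv_path) -> pd.DataFrame:
    """Read spectral counts; validates types, non-negativity and key uniqueness."""
    df = pd.read_csv(tsv_path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{tsv_path}: missing columns {sorted(missing)}")
    df = df[COUNTS_COLUMNS].copy()
    df["spectral_count"] = df["spectral_count"].astype(float)
    df["protein_length_aa"] = df["protein_length_aa"].astype(int)
    if (df["spectral_count"] < 0).any():
        raise ValidationError(f"{tsv_path}: negative spectral counts")
    if (df["protein_length_aa"] < 1).any():
        raise ValidationError(f"{tsv_path}: protein_length_aa must be >= 1")
    key = ["protein_id", "sample_id", "replicate_id"]
    if df.duplicated(key).any():
        raise ValidationError(f"{tsv_path}: duplicate (protein, sample, replicate) keys")
    return df


def read_sample_metadata(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{tsv_path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if "chlorophyll_a" in df.columns:
        df["chlorophyll_a"] = df["chlorophyll_a"].astype(float)
    return df.sort_values("date", kind="stable").reset_index(drop=True)


def read_protein_fasta(faa_path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(faa_path), "fasta")}


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    float_cols = df.select_dtypes(include="float").columns
    out = df.copy()
    for c in float_cols:
        out[c] = out[c].map(format_float)
    out.to_csv(path, sep="\t", index=False)
    return len(out)


def write_gene_table(genome: Genome, path) -> int:
    rows = [
        {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "length_aa": g.length_aa,
        }
        for g in genome.genes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start", "end", "strand", "length_aa"])
    return _write_tsv(df, Path(path))


def write_genome_gff(genome: Genome, path) -> None:
    """Write genes back to GFF3 (1-based inclusive), one sequence-region per contig."""
    by_contig = genome.genes_by_contig()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        n_contigs = max(len(by_contig), 1)
        per_contig = genome.size_bp // n_contigs
        for contig in sorted(by_contig):
            span = max(per_contig, max(g.end for g in by_contig[contig]))
            fh.write(f"##sequence-region {contig} 1 {span}\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig_id}\tpulkit\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


def write_protein_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid in seqs:
            fh.write(f">{pid}\n{seqs[pid]}\n")


def write_evidence(evidence: Iterable[DomainEvidence], path) -> int:
    rows = [
        {"gene_id": e.gene_id, "source": e.source, "label": e.label, "score": e.score}
        for e in evidence
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "source", "label", "score"])
    return _write_tsv(df, Path(path))


def pul_table(puls: Iterable[PUL]) -> pd.DataFrame:
    rows = [
        {
            "pul_id": p.pul_id,
            "genome_id": p.genome_id,
            "contig_id": p.contig_id,
            "n_genes": p.n_genes,
            "completeness": p.completeness,
            "families": serialize_family_counts(p.family_multiset),
            "susCD_pairs": ";".join(f"{c}:{d}" for c, d in p.susCD_pairs) or "NA",
            "susE_genes": ";".join(p.susE_gene_ids) or "NA",
            "n_sulfatases": p.n_sulfatases,
            "n_peptidases": p.n_peptidases,
            "gene_ids": ";".join(p.gene_ids),
        }
        for p in puls
    ]
    cols = [
        "pul_id",
        "genome_id",
        "contig_id",
        "n_genes",
        "completeness",
        "families",
        "susCD_pairs",
        "susE_genes",
        "n_sulfatases",
        "n_peptidases",
        "gene_ids",
    ]
    return pd.DataFrame(rows, columns=cols).sort_values("pul_id", kind="stable")


def prediction_table(predictions: Iterable[SubstratePrediction]) -> pd.DataFrame:
    rows = [
        {
            "pul_id": p.pul_id,
            "substrate": p.substrate,
            "variant": p.variant or "NA",
            "matched_rule": p.matched_rule or "NA",
            "ambiguity": ",".join(p.ambiguity) or "NA",
        }
        for p in predictions
    ]
    cols = ["pul_id", "substrate", "variant", "matched_rule", "ambiguity"]
    return pd.DataFrame(rows, columns=cols).sort_values("pul_id", kind="stable")


def write_identity_matrix(matrix: IdentityMatrix, path) -> int:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df = df.map(format_float)
    df.to_csv(path, sep="\t", index_label="protein_id")
    return len(df)


def write_tree(tree: LabelledTree, newick_path, labels_path=None) -> int:
    with open(newick_path, "w") as fh:
        fh.write(tree.newick.rstrip("\n") + "\n")
    if labels_path is not None:
        rows = [
            {
                "protein_id": pid,
                "genome_id": lab.get("genome_id", "NA"),
                "pul_id": lab.get("pul_id", "NA"),
                "substrate": lab.get("substrate") or "unclassified",
            }
            for pid, lab in sorted(tree.leaf_labels.items())
        ]
        df = pd.DataFrame(rows, columns=["protein_id", "genome_id", "pul_id", "substrate"])
        _write_tsv(df, Path(labels_path))
    return len(tree.leaf_labels)


def write_outputs(results: dict, out_dir) -> dict:
    """Write all available result tables and return a manifest.

    ``results`` may contain any subset of: 'puls' (list[PUL]),
    'predictions' (list[SubstratePrediction]), 'summaries' (DataFrame),
    'identity' ({name: IdentityMatrix}), 'trees' ({name: LabelledTree}),
    'expression' (DataFrame), 'profiles' ({name: DataFrame}).  The
    manifest maps relative file names to row counts; re-running on the
    same results is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    if "puls" in results:
        manifest["puls.tsv"] = _write_tsv(pul_table(results["puls"]), out_dir / "puls.tsv")
    if "predictions" in results:
        df = prediction_table(results["predictions"])
        manifest["substrate_predictions.tsv"] = _write_tsv(
            df, out_dir / "substrate_predictions.tsv"
        )
        payload = [
            {
                "pul_id": p.pul_id,
                "substrate": p.substrate,
                "variant": p.variant,
                "matched_rule": p.matched_rule,
                "evidence": p.evidence,
                "ambiguity": p.ambiguity,
            }
            for p in sorted(results["predictions"], key=lambda x: x.pul_id)
        ]
        with open(out_dir / "substrate_predictions.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        manifest["substrate_predictions.json"] = len(payload)
    if "summaries" in results:
        manifest["genome_summaries.tsv"] = _write_tsv(
            results["summaries"], out_dir / "genome_summaries.tsv"
        )
    for name, matrix in results.get("identity", {}).items():
        fn = f"identity_{name}.tsv"
        manifest[fn] = write_identity_matrix(matrix, out_dir / fn)
    for name, tree in results.get("trees", {}).items():
        fn = f"tree_{name}.nwk"
        manifest[fn] = write_tree(tree, out_dir / fn, out_dir / f"tree_{name}_leaves.tsv")
    if "expression" in results:
        df = results["expression"].sort_values(
            ["protein_id", "sample_id"], kind="stable"
        ).reset_index(drop=True)
        manifest["expression.tsv"] = _write_tsv(df, out_dir / "expression.tsv")
    for name, df in results.get("profiles", {}).items():
        fn = f"profile_{name}.tsv"
        out = df.copy()
        out.insert(0, "substrate", out.index)
        manifest[fn] = _write_tsv(out.reset_index(drop=True), out_dir / fn)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
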