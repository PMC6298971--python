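"""PUL detection along contigs.

A signature gene carries a consensus CAZyme family or one of the roles
susC, susD, tbdt_non_susC or sulfatase.  Maximal runs of signature
genes in which consecutive signature genes are separated by at most
``gap_tolerance`` non-signature genes form candidate clusters; a
cluster is emitted as a PUL when it contains at least ``min_cazymes``
CAZyme genes, or at least one CAZyme gene together with a susC-susD
tandem.  Non-signature genes inside the span become member genes.  A
cluster of a susCD pair without any CAZyme gene is a transporter locus,
not a PUL, and is not emitted.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

from .model import (
    COMPLETE,
    FeatureAssignment,
    GeneRecord,
    Genome,
    NO_SUSCD,
    NO_SUSD,
    PUL,
    ROLE_SULFATASE,
    ROLE_PEPTIDASE,
    ROLE_SUSC,
    ROLE_SUSD,
    ROLE_SUSE,
    ROLE_TBDT,
    TBDT_ONLY,
    ValidationError,
)

#: maximum number of genes allowed between a susC and its paired susD
SUSCD_MAX_INTERVENING = 1


def _is_signature(a: FeatureAssignment) -> bool:
    return bool(a.cazyme_families) or bool(
        a.roles & {ROLE_SUSC, ROLE_SUSD, ROLE_TBDT, ROLE_SULFATASE}
    )


def _pair_susCD(span: list[GeneRecord], assign: Mapping[str, FeatureAssignment]):
    """Greedy susC-susD pairing within a cluster span.

    Each susC is matched to the nearest unused susD within
    ``SUSCD_MAX_INTERVENING`` intervening genes (strand is ignored;
    equidistant ties go to the lower index).  Returns pairs as
    (susC index, susD index) into the span.
    """
    c_pos = [i for i, g in enumerate(span) if ROLE_SUSC in assign[g.gene_id].roles]
    d_pos = [i for i, g in enumerate(span) if ROLE_SUSD in assign[g.gene_id].roles]
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for c in c_pos:
        best = None
        for d in d_pos:
            if d in used:
                continue
            gap = abs(c - d) - 1
            if gap > SUSCD_MAX_INTERVENING:
                continue
            key = (gap, d)
            if best is None or key < best:
                best = key
        if best is not None:
            used.add(best[1])
            pairs.append((c, best[1]))
    return pairs


def classify_completeness(
    has_pair: bool, has_susC: bool, has_tbdt: bool
) -> str:
    """Completeness class of a cluster.

    complete: >=1 adjacent susC-susD tandem; no_susD: susC without a
    paired susD; tbdt_only: a generic (non-SusC) TBDT without susC;
    no_susCD: neither transporter component.
    """
    if has_pair:
        return COMPLETE
    if has_susC:
        return NO_SUSD
    if has_tbdt:
        return TBDT_ONLY
    return NO_SUSCD


def detect_puls(
    genome: Genome,
    assignments: Mapping[str, FeatureAssignment],
    gap_tolerance: int = 3,
    min_cazymes: int = 2,
) -> list[PUL]:
    """Detect PULs on every contig of ``genome``.

    Emission is deterministic left-to-right per contig (contigs in
    lexicographic order); pul_id = ``<genome_id>_PUL<ordinal>``.
    Detection is invariant under reversal of contig gene order up to
    relabelling, and emitted PULs have disjoint gene sets.
    """
    if gap_tolerance < 0:
        raise ValidationError("gap_tolerance must be >= 0")
    if min_cazymes < 1:
        raise ValidationError("min_cazymes must be >= 1")
    missing = [g.gene_id for g in genome.genes if g.gene_id not in assignments]
    if missing:
        raise ValidationError(f"missing assignments for genes: {missing[:5]}")

    puls: list[PUL] = []
    ordinal = 0
    for contig in sorted(genome.genes_by_contig()):
        genes = genome.genes_by_contig()[contig]
        sig_idx = [i for i, g in enumerate(genes) if _is_signature(assignments[g.gene_id])]
        runs: list[list[int]] = []
        for i in sig_idx:
            if runs and i - runs[-1][-1] - 1 <= gap_tolerance:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            span = genes[run[0] : run[-1] + 1]
            pul = _emit_cluster(genome, contig, span, assignments, min_cazymes, ordinal)
            if pul is not None:
                puls.append(pul)
                ordinal += 1
    return puls


def _emit_cluster(
    genome: Genome,
    contig: str,
    span: list[GeneRecord],
    assign: Mapping[str, FeatureAssignment],
    min_cazymes: int,
    ordinal: int,
):
    cazy_genes = [g for g in span if assign[g.gene_id].cazyme_families]
    pairs = _pair_susCD(span, assign)
    qualifies = len(cazy_genes) >= min_cazymes or (len(cazy_genes) >= 1 and pairs)
    if not qualifies or len(span) < 2:
        return None

    # Putative susE: the gene on the far side of a paired susD (away from
    # its susC), inside the span, with neither families nor roles.  This
    # positional heuristic stands in for the missing susE profile and is
    # symmetric under gene-order reversal.
    susE_ids = [g.gene_id for g in span if ROLE_SUSE in assign[g.gene_id].roles]
    for c, d in pairs:
        e = d + 1 if d > c else d - 1
        if 0 <= e < len(span):
            a = assign[span[e].gene_id]
            if not a.cazyme_families and not a.roles:
                susE_ids.append(span[e].gene_id)

    roles_present = set()
    for g in span:
        roles_present |= assign[g.gene_id].roles
    completeness = classify_completeness(
        bool(pairs), ROLE_SUSC in roles_present, ROLE_TBDT in roles_present
    )
    family_multiset = Counter()
    gene_families: dict[str, frozenset[str]] = {}
    for g in span:
        fams = assign[g.gene_id].cazyme_families
        gene_families[g.gene_id] = fams
        for f in fams:
            family_multiset[f] += 1

    return PUL(
        pul_id=f"{genome.genome_id}_PUL{ordinal + 1:03d}",
        genome_id=genome.genome_id,
        contig_id=contig,
        gene_ids=[g.gene_id for g in span],
        susCD_pairs=[(span[c].gene_id, span[d].gene_id) for c, d in pairs],
        completeness=completeness,
        family_multiset=family_multiset,
        n_sulfatases=sum(1 for g in span if ROLE_SULFATASE in assign[g.gene_id].roles),
        n_peptidases=sum(1 for g in span if ROLE_PEPTIDASE in assign[g.gene_id].roles),
        susE_gene_ids=susE_ids,
        gene_families=gene_families,
    )


def pul_sus_proteins(
    pul: PUL, genome: Genome, assignments: Mapping[str, FeatureAssignment]
) -> dict[str, list[tuple[str, str]]]:
    """SusC/SusD member proteins of a PUL as {'susC': [(gene_id, seq)], 'susD': ...}."""
    seq = {g.gene_id: g.protein_seq for g in genome.genes}
    out: dict[str, list[tuple[str, str]]] = {"susC": [], "susD": []}
    for gid in pul.gene_ids:
        roles = assignments[gid].roles
        if ROLE_SUSC in roles:
            out["susC"].append((gid, seq[gid]))
        if ROLE_SUSD in roles:
            out["susD"].append((gid, seq[gid]))
    return out
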