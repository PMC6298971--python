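"""Consensus per-gene functional assignment.

A CAZyme family is assigned to a gene only when at least two of the
three CAZyme evidence sources (Pfam HMM, dbCAN HMM, CAZy BLASTp) report
that family at or above the source's acceptance threshold — a single
database hit is never sufficient.  SusC-like transporters are called
from the TIGRfam model TIGR04056; SusD-like lipoproteins from the Pfam
models PF12741 / PF12771 / PF14322.  Sulfatases come from SulfAtlas
evidence (with the S1 subfamily recorded) and peptidases from MEROPS.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import yaml

from .model import (
    CAZYME_VOTE_SOURCES,
    DomainEvidence,
    FeatureAssignment,
    Genome,
    GenomeFeatureSummary,
    ROLE_PEPTIDASE,
    ROLE_SULFATASE,
    ROLE_SUSC,
    ROLE_SUSD,
    ROLE_SUSE,
    ROLE_TBDT,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Label like GH16, PL7, CE6, CBM6, AA10; optional subfamily suffix (GH5_46).
CAZY_FAMILY_RE = re.compile(r"^(GH|PL|CE|CBM|AA)(\d+)(?:_\S+)?$")

SUSC_MODEL = "TIGR04056"
SUSD_MODELS = frozenset({"PF12741", "PF12771", "PF14322"})


def parent_family(label: str) -> Optional[str]:
    """Normalize a CAZy-style label to its parent family (GH5_46 -> GH5).

    Returns None for labels that are not CAZy families (e.g. PF12741).
    """
    m = CAZY_FAMILY_RE.match(label)
    return f"{m.group(1)}{m.group(2)}" if m else None


@dataclass
class AnnotationConfig:
    """Acceptance thresholds and role-detection label lists.

    HMM sources (pfam, dbcan, tigrfam, sulfatlas) are filtered on bit
    score; BLAST sources (cazy_blast, merops) on -log10(E-value), so the
    default of 4.0 corresponds to E <= 1e-4.
    """

    hmm_bits_min: float = 25.0
    blast_neglog10_e_min: float = 4.0
    tbdt_labels: frozenset[str] = frozenset({"PF00593", "PF07715"})
    susE_labels: frozenset[str] = frozenset()

    def threshold_for(self, source: str) -> float:
        if source in ("cazy_blast", "merops"):
            return self.blast_neglog10_e_min
        return self.hmm_bits_min

    def passes(self, ev: DomainEvidence) -> bool:
        return ev.score >= self.threshold_for(ev.source)

    @classmethod
    def from_yaml(cls, path) -> "AnnotationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("hmm_bits_min", "blast_neglog10_e_min"):
            if key in raw:
                kwargs[key] = float(raw[key])
        for key in ("tbdt_labels", "susE_labels"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        return cls(**kwargs)


def assign_cazyme_families(
    gene_id: str, evidence: Iterable[DomainEvidence], config: AnnotationConfig
) -> FeatureAssignment:
    """Two-of-three consensus CAZyme family assignment for one gene."""
    sources_by_family: dict[str, set[str]] = defaultdict(set)
    raw_by_family: dict[str, set[str]] = defaultdict(set)
    for ev in evidence:
        if ev.gene_id != gene_id or ev.source not in CAZYME_VOTE_SOURCES:
            continue
        fam = parent_family(ev.label)
        if fam is None or not config.passes(ev):
            continue
        sources_by_family[fam].add(ev.source)
        raw_by_family[fam].add(ev.label)
    accepted = {f for f, srcs in sources_by_family.items() if len(srcs) >= 2}
    return FeatureAssignment(
        gene_id=gene_id,
        cazyme_families=frozenset(accepted),
        supporting_sources={f: frozenset(sources_by_family[f]) for f in accepted},
        raw_labels={f: frozenset(raw_by_family[f]) for f in accepted},
    )


def detect_sus_components(
    gene_id: str, evidence: Iterable[DomainEvidence], config: AnnotationConfig
) -> tuple[frozenset[str], Optional[str]]:
    """Role flags for one gene: susC/susD/tbdt_non_susC/susE_like/sulfatase/peptidase.

    susC and susD are mutually exclusive; when both models hit the same
    gene the hit with the higher score relative to its threshold wins
    and the conflict is logged.
    """
    susc_score = susd_score = None
    tbdt = suse = sulfa = pept = False
    subfamily: Optional[str] = None
    for ev in evidence:
        if ev.gene_id != gene_id or not config.passes(ev):
            continue
        rel = ev.score / config.threshold_for(ev.source)
        if ev.source == "tigrfam" and ev.label == SUSC_MODEL:
            susc_score = max(susc_score or 0.0, rel)
        elif ev.source == "pfam" and ev.label in SUSD_MODELS:
            susd_score = max(susd_score or 0.0, rel)
        elif ev.label in config.tbdt_labels:
            tbdt = True
        elif ev.label in config.susE_labels:
            suse = True
        elif ev.source == "sulfatlas":
            sulfa = True
            if subfamily is None:
                subfamily = ev.label
        elif ev.source == "merops":
            pept = True

    roles: set[str] = set()
    if susc_score is not None and susd_score is not None:
        winner = ROLE_SUSC if susc_score >= susd_score else ROLE_SUSD
        logger.warning(
            "gene %s: both SusC and SusD models hit; keeping %s", gene_id, winner
        )
        roles.add(winner)
    elif susc_score is not None:
        roles.add(ROLE_SUSC)
    elif susd_score is not None:
        roles.add(ROLE_SUSD)
    if tbdt and ROLE_SUSC not in roles:
        roles.add(ROLE_TBDT)
    if suse:
        roles.add(ROLE_SUSE)
    if sulfa:
        roles.add(ROLE_SULFATASE)
    if pept:
        roles.add(ROLE_PEPTIDASE)
    return frozenset(roles), subfamily


def annotate_gene(
    gene_id: str, evidence: Iterable[DomainEvidence], config: AnnotationConfig
) -> FeatureAssignment:
    evidence = list(evidence)
    fam = assign_cazyme_families(gene_id, evidence, config)
    roles, subfamily = detect_sus_components(gene_id, evidence, config)
    return FeatureAssignment(
        gene_id=gene_id,
        cazyme_families=fam.cazyme_families,
        roles=roles,
        sulfatase_subfamily=subfamily,
        supporting_sources=fam.supporting_sources,
        raw_labels=fam.raw_labels,
    )


def annotate_genome(
    genome: Genome,
    evidence: Iterable[DomainEvidence],
    config: Optional[AnnotationConfig] = None,
) -> dict[str, FeatureAssignment]:
    """Consensus assignments for every gene of a genome (empty ones included)."""
    config = config or AnnotationConfig()
    by_gene: dict[str, list[DomainEvidence]] = defaultdict(list)
    for ev in evidence:
        by_gene[ev.gene_id].append(ev)
    return {
        g.gene_id: annotate_gene(g.gene_id, by_gene.get(g.gene_id, ()), config)
        for g in genome.genes
    }


def summarize_genome(
    genome: Genome,
    assignments: Mapping[str, FeatureAssignment],
    puls=None,
) -> GenomeFeatureSummary:
    """Genome-level CAZyme / sulfatase / peptidase statistics.

    The peptidase:CAZyme ratio uses degradative CAZyme genes (>=1 GH, PL
    or CE family) as denominator and is reported as missing when there
    are none.
    """
    if genome.size_bp <= 0:
        raise ValidationError(f"genome {genome.genome_id}: size_bp must be > 0")
    n_deg = sum(1 for a in assignments.values() if a.is_degradative_cazyme)
    n_sulf = sum(1 for a in assignments.values() if ROLE_SULFATASE in a.roles)
    n_pept = sum(1 for a in assignments.values() if ROLE_PEPTIDASE in a.roles)
    ratio = (n_pept / n_deg) if n_deg > 0 else None
    return GenomeFeatureSummary(
        genome_id=genome.genome_id,
        n_degradative_cazymes=n_deg,
        degradative_cazymes_per_mbp=n_deg / genome.size_mbp,
        n_sulfatases=n_sulf,
        n_peptidases=n_pept,
        peptidase_cazyme_ratio=ratio,
        n_puls=len(puls) if puls is not None else None,
    )
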