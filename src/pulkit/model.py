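"""Core data model for PUL analysis.

Conventions used throughout the package:

* Gene coordinates are stored 0-based, half-open (``start`` inclusive,
  ``end`` exclusive).  All GFF3 I/O converts from/to the external
  1-based inclusive convention.
* Percent identities live on the 0-100 scale; tree distances are
  ``1 - identity / 100``.
* Tabular data (spectral counts, sample metadata, expression records)
  are pandas DataFrames with documented column sets rather than bespoke
  record classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

# Amino-acid alphabet accepted in protein sequences (20 IUPAC letters + X).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_PROTEIN_CHARS = frozenset(AMINO_ACIDS + "X")

# Domain-evidence sources.  HMM-type sources carry bit scores; BLAST-type
# sources (cazy_blast, merops) carry -log10 E-values.
EVIDENCE_SOURCES = ("pfam", "dbcan", "cazy_blast", "tigrfam", "sulfatlas", "merops")
CAZYME_VOTE_SOURCES = frozenset({"pfam", "dbcan", "cazy_blast"})

# Gene roles.
ROLE_SUSC = "susC"
ROLE_SUSD = "susD"
ROLE_SUSE = "susE_like"
ROLE_TBDT = "tbdt_non_susC"
ROLE_SULFATASE = "sulfatase"
ROLE_PEPTIDASE = "peptidase"

# PUL completeness classes.
COMPLETE = "complete"
NO_SUSD = "no_susD"
TBDT_ONLY = "tbdt_only"
NO_SUSCD = "no_susCD"
COMPLETENESS_CLASSES = (COMPLETE, NO_SUSD, TBDT_ONLY, NO_SUSCD)

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


class GFFParseError(ValueError):
    """Raised for malformed GFF3 input; message names file and line."""


@dataclass(frozen=True)
class GeneRecord:
    """A located protein-coding gene with its translated sequence."""

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    protein_seq: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if len(self.protein_seq) < 1:
            raise ValidationError(f"gene {self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq.upper()) - VALID_PROTEIN_CHARS
        if bad:
            raise ValidationError(
                f"gene {self.gene_id}: invalid protein characters {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)


@dataclass
class Genome:
    """An annotated genome: genes sorted by (contig_id, start)."""

    genome_id: str
    genes: list[GeneRecord]
    size_bp: int
    n_dropped: int = 0  # CDS features dropped for lack of a protein sequence

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValidationError(f"genome {self.genome_id}: size_bp must be > 0")
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"genome {self.genome_id}: duplicate gene ids {dupes}"
            )

    def genes_by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        return out

    @property
    def size_mbp(self) -> float:
        return self.size_bp / 1e6


@dataclass(frozen=True)
class DomainEvidence:
    """One raw database hit for one gene.

    ``score`` semantics depend on the source: bit score for HMM sources
    (pfam, dbcan, tigrfam, sulfatlas) and -log10(E-value) for BLAST
    sources (cazy_blast, merops).
    """

    gene_id: str
    source: str
    label: str
    score: float

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ValidationError(
                f"unknown evidence source {self.source!r}; "
                f"expected one of {EVIDENCE_SOURCES}"
            )
        if not self.label:
            raise ValidationError("evidence label must be non-empty")
        if not np.isfinite(self.score):
            raise ValidationError("evidence score must be finite")


@dataclass
class FeatureAssignment:
    """Consensus functional call for one gene.

    ``cazyme_families`` holds parent-level family labels (GH5_46 is
    normalized to GH5); verbatim labels are kept in ``raw_labels``.
    """

    gene_id: str
    cazyme_families: frozenset[str] = frozenset()
    roles: frozenset[str] = frozenset()
    sulfatase_subfamily: Optional[str] = None
    supporting_sources: Mapping[str, frozenset[str]] = field(default_factory=dict)
    raw_labels: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def is_degradative_cazyme(self) -> bool:
        """True when the gene carries >=1 GH, PL, or CE family (CBM/AA-only
        genes bind or assist but do not cleave)."""
        return any(f.startswith(("GH", "PL", "CE")) for f in self.cazyme_families)


@dataclass
class GenomeFeatureSummary:
    genome_id: str
    n_degradative_cazymes: int
    degradative_cazymes_per_mbp: float
    n_sulfatases: int
    n_peptidases: int
    peptidase_cazyme_ratio: Optional[float]  # None when no degradative CAZymes
    n_puls: Optional[int] = None


@dataclass
class PUL:
    """A contiguous cluster of signature genes on one contig."""

    pul_id: str
    genome_id: str
    contig_id: str
    gene_ids: list[str]
    susCD_pairs: list[tuple[str, str]]
    completeness: str
    family_multiset: Counter
    n_sulfatases: int
    n_peptidases: int
    susE_gene_ids: list[str] = field(default_factory=list)
    gene_families: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.completeness not in COMPLETENESS_CLASSES:
            raise ValidationError(
                f"PUL {self.pul_id}: unknown completeness {self.completeness!r}"
            )
        if len(self.gene_ids) < 2:
            raise ValidationError(f"PUL {self.pul_id}: needs >= 2 genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def has_susCD_pair(self) -> bool:
        return bool(self.susCD_pairs)

    @property
    def has_susE(self) -> bool:
        return bool(self.susE_gene_ids)


@dataclass(frozen=True)
class SubstrateRule:
    """A declarative family-composition signature for one substrate.

    * ``required``: every (family, min_count) must be met by the PUL's
      family multiset (counts are numbers of member genes carrying the
      family).
    * ``any_of``: each (family_set, min_distinct) clause requires at
      least ``min_distinct`` distinct families of the set to be present.
    * ``forbidden``: families that must be absent.
    * ``requires_sulfatase`` / ``requires_susCDE``: tri-state
      ('yes' | 'no' | 'any') on PUL-internal sulfatase genes and on the
      presence of a susC-susD pair plus a susE-like gene.
    * ``priority``: rank; smaller values are preferred (variant rules
      rank before class-level rules).
    """

    name: str
    substrate: str
    priority: int
    variant: Optional[str] = None
    required: tuple[tuple[str, int], ...] = ()
    any_of: tuple[tuple[frozenset[str], int], ...] = ()
    forbidden: frozenset[str] = frozenset()
    requires_sulfatase: str = "any"
    requires_susCDE: str = "any"

    def __post_init__(self) -> None:
        req = {f for f, _ in self.required}
        if req & self.forbidden:
            raise ValidationError(
                f"rule {self.name}: required and forbidden families overlap"
            )
        for attr in ("requires_sulfatase", "requires_susCDE"):
            if getattr(self, attr) not in ("yes", "no", "any"):
                raise ValidationError(
                    f"rule {self.name}: {attr} must be 'yes', 'no' or 'any'"
                )


@dataclass
class SubstratePrediction:
    pul_id: str
    substrate: str = UNCLASSIFIED
    variant: Optional[str] = None
    matched_rule: Optional[str] = None
    evidence: dict[str, list[str]] = field(default_factory=dict)
    ambiguity: list[str] = field(default_factory=list)


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValidationError("identity matrix shape does not match ids")
        if n:
            if not np.allclose(np.diag(self.values), 100.0):
                raise ValidationError("identity matrix diagonal must be 100")
            if not np.allclose(self.values, self.values.T, atol=1e-9):
                raise ValidationError("identity matrix must be symmetric")
            if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
                raise ValidationError("identities must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class LabelledTree:
    """A Newick tree over protein ids with per-leaf annotations.

    ``leaf_labels`` maps protein id -> dict with keys genome_id, pul_id,
    substrate (substrate may be None for unclassified references).
    """

    newick: str
    leaf_labels: dict[str, dict]

    def to_skbio(self):
        import io

        from skbio import TreeNode

        return TreeNode.read(io.StringIO(self.newick))


@dataclass
class SubstrateCluster:
    cluster_id: str
    members: list[str]
    majority_substrate: str
    purity: float


@dataclass(frozen=True)
class PULTemplate:
    """An ordered gene-slot architecture used to plant synthetic PULs.

    Slots are either CAZy family labels (GH16, PL7, ...) or role tokens
    (susC, susD, susE, tbdt, sulfatase, peptidase, gene).
    """

    name: str
    slots: tuple[str, ...]
    substrate: str
    expected_rule: str
    expected_completeness: str = COMPLETE

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValidationError(f"template {self.name}: empty slot list")


def format_float(x: float) -> str:
    """Serialize a float with 6 significant digits (reproducible output)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def parse_family_counts(text: str) -> Counter:
    """Parse 'GH16:2,GH3:1' back into a Counter (inverse of serialization)."""
    out: Counter = Counter()
    if not text or text == "NA":
        return out
    for tok in text.split(","):
        fam, _, cnt = tok.partition(":")
        out[fam] = int(cnt) if cnt else 1
    return out


def serialize_family_counts(counts: Counter) -> str:
    return ",".join(f"{f}:{c}" for f, c in sorted(counts.items())) or "NA"
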