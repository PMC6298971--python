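"""Pairwise identities, neighbor-joining trees and substrate clusters
for PUL-associated SusC-like and SusD-like proteins.

Identity is computed from a single global (end-to-end) pairwise
alignment under BLOSUM62 with affine gaps (open 11, extend 1), as
100 x matches / alignment columns — gap columns count against identity.
Trees are built by neighbor joining on the uncorrected distance
d = 1 - identity/100; negative NJ branch lengths are clamped to zero.
Substrate clusters are maximal clades whose labelled leaves reach a
majority-substrate frequency of at least ``purity_threshold``;
unlabelled leaves are neutral.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import (
    IdentityMatrix,
    LabelledTree,
    SubstrateCluster,
    UNCLASSIFIED,
    VALID_PROTEIN_CHARS,
    ValidationError,
)

_aligner_cache: dict[tuple[float, float], Align.PairwiseAligner] = {}


def _get_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (gap_open, gap_extend)
    if key not in _aligner_cache:
        aligner = Align.PairwiseAligner(
            mode="global",
            open_gap_score=-abs(gap_open),
            extend_gap_score=-abs(gap_extend),
        )
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def pairwise_identity(
    seq_a: str, seq_b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Percent identity from one optimal global alignment.

    Symmetric in its arguments up to co-optimal alignment choice; the
    identity denominator is the full alignment length including gap
    columns.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValidationError(f"{name} is empty")
        bad = set(seq.upper()) - VALID_PROTEIN_CHARS
        if bad:
            raise ValidationError(f"{name} contains invalid characters {sorted(bad)}")
    aligner = _get_aligner(gap_open, gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def build_identity_matrix(
    sequences: Mapping[str, str],
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> IdentityMatrix:
    """All-vs-all identity matrix; each unordered pair aligned once."""
    ids = list(sequences)
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        ident = identity_fn(sequences[ids[i]], sequences[ids[j]])
        values[i, j] = values[j, i] = ident
    if n == 0:
        values = np.zeros((0, 0))
    return IdentityMatrix(ids=ids, values=values)


def identity_to_distance(matrix: IdentityMatrix) -> np.ndarray:
    """Uncorrected distance d = 1 - identity/100 (zero diagonal enforced)."""
    d = 1.0 - matrix.values / 100.0
    np.fill_diagonal(d, 0.0)
    return d


def build_nj_tree(
    matrix: IdentityMatrix,
    leaf_labels: Optional[Mapping[str, dict]] = None,
) -> LabelledTree:
    """Neighbor-joining tree on d = 1 - identity/100.

    Requires >= 3 sequences (smaller inputs have a trivial topology and
    are rejected).  Negative branch lengths are clamped at zero; the
    agglomeration is deterministic given the input order.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(matrix.ids) < 3:
        raise ValidationError(
            "neighbor joining needs >= 3 sequences; smaller inputs have a "
            "trivial topology"
        )
    dm = DistanceMatrix(identity_to_distance(matrix), matrix.ids)
    tree = nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    labels = {
        pid: dict(leaf_labels.get(pid, {})) if leaf_labels else {}
        for pid in matrix.ids
    }
    return LabelledTree(newick=str(tree).strip(), leaf_labels=labels)


def _substrate_of(label: dict) -> Optional[str]:
    sub = label.get("substrate")
    if sub in (None, "", "NA", UNCLASSIFIED):
        return None
    return sub


def extract_substrate_clusters(
    tree: LabelledTree,
    purity_threshold: float = 0.8,
    min_size: int = 3,
) -> list[SubstrateCluster]:
    """Maximal clades whose labelled-leaf majority substrate reaches
    ``purity_threshold`` and whose size is >= ``min_size``.

    The tree is midpoint-rooted first (NJ output is unrooted, and an
    arbitrary root can split a family across the root).  Clades are then
    visited root-down; once a clade qualifies its subclades are not
    reported separately.  Leaves outside every cluster are the
    'heterogeneous/undefined' remainder.  Majority ties are broken
    lexicographically for determinism.
    """
    root = tree.to_skbio()
    try:
        root = root.root_at_midpoint()
    except Exception:  # degenerate trees (e.g. all-zero branch lengths)
        pass
    clusters: list[SubstrateCluster] = []
    stack = [root]
    k = 0
    while stack:
        node = stack.pop(0)
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if len(tips) >= min_size:
            labelled = [
                _substrate_of(tree.leaf_labels.get(t, {}))
                for t in tips
                if _substrate_of(tree.leaf_labels.get(t, {})) is not None
            ]
            if labelled:
                counts: dict[str, int] = {}
                for s in labelled:
                    counts[s] = counts.get(s, 0) + 1
                majority = min(counts, key=lambda s: (-counts[s], s))
                purity = counts[majority] / len(labelled)
                if purity >= purity_threshold:
                    k += 1
                    clusters.append(
                        SubstrateCluster(
                            cluster_id=f"cluster{k:03d}",
                            members=sorted(tips),
                            majority_substrate=majority,
                            purity=purity,
                        )
                    )
                    continue  # do not descend into an emitted clade
        stack.extend(node.children)
    return clusters


def suscd_congruence(
    susC_clusters: Sequence[SubstrateCluster],
    susD_clusters: Sequence[SubstrateCluster],
    pul_pairs: Sequence[tuple[str, str, str]],
) -> Optional[float]:
    """Fraction of susC-susD pairs placed in same-substrate clusters.

    ``pul_pairs`` holds (pul_id, susC protein id, susD protein id).
    Only pairs whose SusC lies in some substrate cluster AND whose SusD
    lies in some substrate cluster are eligible; with zero eligible
    pairs the statistic is undefined and None is returned.
    """
    c_of = {m: c.majority_substrate for c in susC_clusters for m in c.members}
    d_of = {m: c.majority_substrate for c in susD_clusters for m in c.members}
    eligible = [
        (c_of[c], d_of[d]) for _, c, d in pul_pairs if c in c_of and d in d_of
    ]
    if not eligible:
        return None
    same = sum(1 for a, b in eligible if a == b)
    return same / len(eligible)
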