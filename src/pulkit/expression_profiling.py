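"""%NSAF expression profiling of SusC/D-like homologs.

Spectral counts from technical duplicates are averaged per (protein,
sample); within each sample the normalized spectral abundance factor is

    NSAF_i = (SpC_i / L_i) / sum_k (SpC_k / L_k)

over ALL proteins of the sample's table, and %NSAF = 100 x NSAF, so a
%NSAF of 1 is 1% of the sample's mass-adjusted spectral counts.
Expressed SusC/D-like query proteins are placed onto a
substrate-labelled reference set by best pairwise identity (default
threshold 40%, compared as >= on the value rounded to 0.1); placed
proteins whose %NSAF never reaches ``min_pct_nsaf`` (default 0.05) are
excluded from substrate-by-sample profiles.  SusC-like and SusD-like
sums are always reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import ValidationError
from .suscd_reference import pairwise_identity


@dataclass
class SubstrateProfile:
    """Substrate x sample %NSAF sums, one matrix per protein class."""

    susC: pd.DataFrame
    susD: pd.DataFrame
    sample_order: list[str]
    bloom_phase: Optional[pd.Series] = None  # sample_id -> phase

    def matrix(self, protein_class: str) -> pd.DataFrame:
        if protein_class == "susC_like":
            return self.susC
        if protein_class == "susD_like":
            return self.susD
        raise KeyError(protein_class)


def average_technical_duplicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of spectral counts over technical replicates.

    A missing replicate is treated as absent: the mean runs over the
    replicates actually present, and their number is reported in
    ``n_replicates``.
    """
    required = {"protein_id", "sample_id", "replicate_id", "spectral_count", "protein_length_aa"}
    missing = required - set(counts.columns)
    if missing:
        raise ValidationError(f"counts table missing columns {sorted(missing)}")
    grouped = (
        counts.groupby(["protein_id", "sample_id"], sort=True)
        .agg(
            spectral_count=("spectral_count", "mean"),
            protein_length_aa=("protein_length_aa", "first"),
            n_replicates=("replicate_id", "nunique"),
        )
        .reset_index()
    )
    return grouped


def compute_pct_nsaf(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``pct_nsaf`` column; normalization is per sample over all rows.

    Raises when any sample's total SpC/L is zero (normalizer undefined).
    Per sample, pct_nsaf sums to 100 exactly up to rounding error.
    """
    df = counts.copy()
    if (df["protein_length_aa"] < 1).any():
        raise ValidationError("protein lengths must be positive")
    df["_saf"] = df["spectral_count"] / df["protein_length_aa"]
    totals = df.groupby("sample_id")["_saf"].transform("sum")
    zero_samples = sorted(df.loc[totals == 0, "sample_id"].unique())
    if zero_samples:
        raise ValidationError(
            f"samples with all-zero spectral counts (normalizer undefined): {zero_samples}"
        )
    df["pct_nsaf"] = 100.0 * df["_saf"] / totals
    return df.drop(columns="_saf")


def place_expressed(
    query_seqs: Mapping[str, str],
    reference: Mapping[str, tuple[str, Optional[str]]],
    identity_threshold: float = 40.0,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> pd.DataFrame:
    """Place each query on its best reference and inherit the substrate.

    ``reference`` maps reference protein id -> (sequence, substrate
    label or None).  Identities are rounded to 0.1 before the >=
    threshold comparison.  Ties on the rounded best identity inherit
    the shared substrate when all tied references agree, otherwise the
    query is marked ambiguous.  Queries below threshold (or whose best
    references carry no label) stay unclassified.
    """
    if not reference:
        raise ValidationError("reference set is empty")
    rows = []
    ref_items = list(reference.items())
    for qid in sorted(query_seqs):
        idents = [
            (round(identity_fn(query_seqs[qid], seq), 1), rid, sub)
            for rid, (seq, sub) in ref_items
        ]
        best = max(i for i, _, _ in idents)
        tied = [(rid, sub) for i, rid, sub in idents if i == best]
        best_rid = min(rid for rid, _ in tied)
        substrate, status = None, "unclassified"
        if best >= identity_threshold:
            subs = {sub for _, sub in tied}
            if len(subs) == 1:
                (only,) = subs
                if only is not None:
                    substrate, status = only, "placed"
            else:
                status = "ambiguous"
        rows.append(
            {
                "protein_id": qid,
                "placed_reference": best_rid,
                "placement_identity": best,
                "inherited_substrate": substrate,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "placed_reference", "placement_identity", "inherited_substrate", "status"],
    )


def assign_bloom_phase(
    metadata: pd.DataFrame,
    threshold_early: float = 5.0,
    threshold_mid: float = 15.0,
) -> pd.DataFrame:
    """Assign pre/early/mid/late bloom phases from chlorophyll a.

    User-supplied ``bloom_phase`` labels pass through unchanged.
    Otherwise samples are ordered by date; with the chlorophyll maximum
    as bloom peak, a sample is 'mid' when chl >= threshold_mid, 'early'
    when threshold_early <= chl < threshold_mid before/at the peak,
    'late' after the peak below threshold_mid, and 'pre' below
    threshold_early before the peak.  A series that never reaches
    threshold_early has no bloom: all samples are 'pre'.
    """
    df = metadata.sort_values("date", kind="stable").reset_index(drop=True)
    if "bloom_phase" in df.columns and df["bloom_phase"].notna().all():
        return df
    if "chlorophyll_a" not in df.columns or df["chlorophyll_a"].isna().any():
        raise ValidationError(
            "bloom phases require chlorophyll_a values or explicit bloom_phase labels"
        )
    chl = df["chlorophyll_a"].to_numpy()
    if chl.max() < threshold_early:
        df["bloom_phase"] = "pre"
        return df
    peak = int(np.argmax(chl))
    phases = []
    for i, c in enumerate(chl):
        if c >= threshold_mid:
            phases.append("mid")
        elif i <= peak:
            phases.append("early" if c >= threshold_early else "pre")
        else:
            phases.append("late")
    df["bloom_phase"] = phases
    return df


def build_substrate_profile(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    min_pct_nsaf: float = 0.05,
) -> SubstrateProfile:
    """Substrate-by-sample %NSAF sums for placed SusC/D-like proteins.

    ``expression`` needs columns protein_id, sample_id, pct_nsaf,
    protein_class ('susC_like' | 'susD_like'), inherited_substrate.  A
    protein is retained iff its maximum pct_nsaf across samples is >=
    ``min_pct_nsaf``; retained proteins contribute all their samples.
    Sample columns follow chronological metadata order.
    """
    meta = metadata.sort_values("date", kind="stable").reset_index(drop=True)
    sample_order = list(meta["sample_id"])
    placed = expression[expression["inherited_substrate"].notna()].copy()
    if not placed.empty:
        peak = placed.groupby("protein_id")["pct_nsaf"].transform("max")
        placed = placed[peak >= min_pct_nsaf]

    matrices = {}
    for cls in ("susC_like", "susD_like"):
        sub = placed[placed["protein_class"] == cls]
        if sub.empty:
            matrices[cls] = pd.DataFrame(columns=sample_order, dtype=float)
            continue
        mat = (
            sub.pivot_table(
                index="inherited_substrate",
                columns="sample_id",
                values="pct_nsaf",
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(columns=sample_order, fill_value=0.0)
            .sort_index()
        )
        mat.index.name = None
        mat.columns.name = None
        matrices[cls] = mat.astype(float)

    phase = None
    if "bloom_phase" in meta.columns:
        phase = meta.set_index("sample_id")["bloom_phase"]
    return SubstrateProfile(
        susC=matrices["susC_like"],
        susD=matrices["susD_like"],
        sample_order=sample_order,
        bloom_phase=phase,
    )
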