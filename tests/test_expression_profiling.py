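"""%NSAF computation, homolog placement and substrate profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulkit.expression_profiling import (
    assign_bloom_phase,
    average_technical_duplicates,
    build_substrate_profile,
    compute_pct_nsaf,
    place_expressed,
)
from pulkit.model import ValidationError


def counts_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "sample_id", "replicate_id", "spectral_count", "protein_length_aa"]
    )


class TestAveraging:
    def test_mean_of_two_replicates(self):
        df = counts_frame([("p", "s", "r1", 4, 300), ("p", "s", "r2", 6, 300)])
        out = average_technical_duplicates(df)
        assert out.spectral_count.tolist() == [5.0]
        assert out.n_replicates.tolist() == [2]

    def test_single_replicate_passes_through(self):
        out = average_technical_duplicates(counts_frame([("p", "s", "r1", 7, 300)]))
        assert out.spectral_count.tolist() == [7.0]
        assert out.n_replicates.tolist() == [1]

    def test_zero_counts_are_retained(self):
        df = counts_frame([("p", "s", "r1", 0, 300), ("p", "s", "r2", 0, 300), ("q", "s", "r1", 5, 100)])
        out = average_technical_duplicates(df)
        assert out.set_index("protein_id").loc["p", "spectral_count"] == 0.0


class TestPctNsaf:
    def test_definitional_worked_example(self):
        """Two proteins of equal length with counts 30 and 2970: the first
        holds 1% of the mass-adjusted counts, so %NSAF = 1.0."""
        df = average_technical_duplicates(
            counts_frame([("A", "s", "r1", 30, 300), ("B", "s", "r1", 2970, 300)])
        )
        out = compute_pct_nsaf(df).set_index("protein_id")
        assert abs(out.loc["A", "pct_nsaf"] - 1.0) < 1e-12

    def test_single_protein_is_100(self):
        df = average_technical_duplicates(counts_frame([("A", "s", "r1", 12, 250)]))
        assert compute_pct_nsaf(df).pct_nsaf.tolist() == [100.0]

    def test_length_normalization(self):
        df = average_technical_duplicates(
            counts_frame([("A", "s", "r1", 10, 100), ("B", "s", "r1", 10, 400)])
        )
        out = compute_pct_nsaf(df).set_index("protein_id")
        assert out.loc["A", "pct_nsaf"] == pytest.approx(80.0)
        assert out.loc["B", "pct_nsaf"] == pytest.approx(20.0)

    def test_all_zero_sample_rejected(self):
        df = average_technical_duplicates(counts_frame([("A", "s", "r1", 0, 100)]))
        with pytest.raises(ValidationError, match="all-zero"):
            compute_pct_nsaf(df)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_and_scale_invariance(self, seed):
        """Per sample, %NSAF sums to 100; rescaling all counts by c > 0
        changes nothing."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        df = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(n)],
                "sample_id": "s1",
                "spectral_count": rng.integers(0, 500, n).astype(float),
                "protein_length_aa": rng.integers(50, 900, n),
            }
        )
        if df.spectral_count.sum() == 0:
            df.loc[0, "spectral_count"] = 1.0
        out = compute_pct_nsaf(df)
        assert out.pct_nsaf.sum() == pytest.approx(100.0, abs=1e-9)
        scaled = df.assign(spectral_count=df.spectral_count * float(rng.uniform(0.1, 40)))
        assert np.allclose(compute_pct_nsaf(scaled).pct_nsaf, out.pct_nsaf)


class TestPlacement:
    REF = {"refA": ("ACDEFGHIKL" * 30, "xylan_sulfated"), "refB": ("MKLVINTAAC" * 30, "laminarin")}

    def test_identical_query_inherits_substrate_at_100(self):
        out = place_expressed({"q": self.REF["refA"][0]}, self.REF)
        row = out.iloc[0]
        assert (row.placement_identity, row.inherited_substrate, row.status) == (
            100.0,
            "xylan_sulfated",
            "placed",
        )

    def test_threshold_is_inclusive_on_rounded_identity(self):
        ref = {"r": ("A" * 100, "laminarin")}
        out40 = place_expressed({"q": "Q"}, ref, identity_fn=lambda a, b: 40.0)
        out399 = place_expressed({"q": "Q"}, ref, identity_fn=lambda a, b: 39.9)
        assert out40.iloc[0].status == "placed"
        assert out399.iloc[0].status == "unclassified"
        assert out399.iloc[0].inherited_substrate is None

    def test_rounding_to_one_decimal_before_comparison(self):
        ref = {"r": ("A" * 100, "laminarin")}
        out = place_expressed({"q": "Q"}, ref, identity_fn=lambda a, b: 39.96)
        assert out.iloc[0].status == "placed"  # rounds to 40.0

    def test_ties_with_conflicting_substrates_are_ambiguous(self):
        ref = {"r1": ("A" * 50, "laminarin"), "r2": ("A" * 50, "alginate")}
        out = place_expressed({"q": "Q"}, ref, identity_fn=lambda a, b: 55.0)
        assert out.iloc[0].status == "ambiguous"
        assert out.iloc[0].inherited_substrate is None

    def test_ties_with_shared_substrate_inherit_it(self):
        ref = {"r1": ("A" * 50, "laminarin"), "r2": ("C" * 50, "laminarin")}
        out = place_expressed({"q": "Q"}, ref, identity_fn=lambda a, b: 55.0)
        assert out.iloc[0].inherited_substrate == "laminarin"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            place_expressed({"q": "ACDE"}, {})


class TestBloomPhase:
    def _meta(self, chl):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(chl))],
                "date": pd.date_range("2010-03-01", periods=len(chl), freq="7D"),
                "chlorophyll_a": chl,
            }
        )

    def test_rising_then_falling_series_orders_phases(self):
        out = assign_bloom_phase(self._meta([2, 4, 8, 20, 25, 18, 8, 3]), 5.0, 15.0)
        assert out.bloom_phase.tolist() == ["pre", "pre", "early", "mid", "mid", "mid", "late", "late"]

    def test_all_below_threshold_is_all_pre(self):
        out = assign_bloom_phase(self._meta([1, 2, 3, 2, 1]), 5.0, 15.0)
        assert set(out.bloom_phase) == {"pre"}

    def test_user_labels_pass_through(self):
        meta = self._meta([1, 2, 3])
        meta["bloom_phase"] = ["pre", "mid", "late"]
        assert assign_bloom_phase(meta).bloom_phase.tolist() == ["pre", "mid", "late"]

    def test_missing_chlorophyll_without_labels_rejected(self):
        meta = self._meta([1, 2, 3]).drop(columns="chlorophyll_a")
        with pytest.raises(ValidationError, match="chlorophyll"):
            assign_bloom_phase(meta)


class TestSubstrateProfile:
    def _meta(self, n=3):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "date": pd.date_range("2010-04-01", periods=n, freq="7D"),
                "bloom_phase": ["pre", "mid", "late"][:n],
            }
        )

    def _expr(self, rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "sample_id", "pct_nsaf", "protein_class", "inherited_substrate"]
        )

    def test_peak_above_filter_is_retained(self):
        expr = self._expr([("p", "s0", 0.13, "susC_like", "laminarin")])
        profile = build_substrate_profile(expr, self._meta())
        assert profile.susC.loc["laminarin", "s0"] == pytest.approx(0.13)

    def test_filter_uses_max_across_samples(self):
        expr = self._expr(
            [
                ("lo", "s0", 0.04, "susC_like", "laminarin"),
                ("hi", "s0", 0.05, "susC_like", "alginate"),
                ("hi", "s1", 0.01, "susC_like", "alginate"),
            ]
        )
        profile = build_substrate_profile(expr, self._meta())
        assert "laminarin" not in profile.susC.index  # peaked at 0.04 -> excluded
        assert profile.susC.loc["alginate", "s1"] == pytest.approx(0.01)  # retained everywhere

    def test_same_substrate_proteins_sum_per_cell(self):
        expr = self._expr(
            [
                ("p1", "s1", 0.06, "susD_like", "beta_mannan"),
                ("p2", "s1", 0.07, "susD_like", "beta_mannan"),
            ]
        )
        profile = build_substrate_profile(expr, self._meta())
        assert profile.susD.loc["beta_mannan", "s1"] == pytest.approx(0.13)

    def test_classes_reported_separately_and_columns_chronological(self):
        expr = self._expr(
            [
                ("c", "s2", 0.2, "susC_like", "laminarin"),
                ("d", "s0", 0.3, "susD_like", "laminarin"),
            ]
        )
        profile = build_substrate_profile(expr, self._meta())
        assert list(profile.susC.columns) == ["s0", "s1", "s2"]
        assert profile.susC.loc["laminarin", "s2"] == pytest.approx(0.2)
        assert profile.susD.loc["laminarin", "s0"] == pytest.approx(0.3)
        assert profile.bloom_phase.loc["s1"] == "mid"

    def test_raising_filter_never_adds_proteins(self):
        expr = self._expr(
            [
                ("p1", "s0", 0.04, "susC_like", "laminarin"),
                ("p2", "s0", 0.5, "susC_like", "alginate"),
            ]
        )
        loose = build_substrate_profile(expr, self._meta(), min_pct_nsaf=0.0)
        strict = build_substrate_profile(expr, self._meta(), min_pct_nsaf=0.1)
        assert set(strict.susC.index) <= set(loose.susC.index)
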