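"""Estimator core: filtering, median rollup, titration inversion, replicate
merging, distribution summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs

from conftest import relative_errors, run_estimation
from parstoich import quantio, simulate as sim, stoichiometry as st
from parstoich.quantio import MixDesign, ReferenceLists


def _rows(*specs):
    """specs: (protein, peptide, mix, rep, ah, al, sh, sl)"""
    return pd.DataFrame(list(specs), columns=quantio.QUANT_COLUMNS)


REFS = ReferenceLists(frozenset({"P1", "P2"}), frozenset({"SITEK"}))


class TestFilter:
    def test_snr_both_mode_requires_both_channels_to_pass(self):
        df = _rows(
            ("P1", "AAK", "1:50", "s1", 10, 100, 4.9, 50.0),
            ("P1", "CCK", "1:50", "s1", 10, 100, 5.1, 50.0),
        )
        kept, report = st.filter_peptides(df, REFS, st.FilterConfig(snr_mode="both"))
        assert list(kept["peptide_seq"]) == ["CCK"]
        assert report.rejected_snr == 1

    def test_snr_either_mode_accepts_one_passing_channel(self):
        df = _rows(("P1", "AAK", "1:50", "s1", 10, 100, 4.9, 50.0))
        kept, _ = st.filter_peptides(df, REFS, st.FilterConfig(snr_mode="either"))
        assert len(kept) == 1

    def test_threshold_is_strict(self):
        df = _rows(("P1", "AAK", "1:50", "s1", 10, 100, 5.0, 5.0))
        kept, _ = st.filter_peptides(df, REFS, st.FilterConfig())
        assert kept.empty

    def test_site_peptides_and_foreign_proteins_removed(self):
        df = _rows(
            ("P1", "SITEK", "1:50", "s1", 10, 100, 50.0, 50.0),
            ("P9", "AAK", "1:50", "s1", 10, 100, 50.0, 50.0),
            ("P2", "AAK", "1:50", "s1", 10, 100, 50.0, 50.0),
        )
        kept, report = st.filter_peptides(df, REFS, st.FilterConfig())
        assert list(kept["protein_id"]) == ["P2"]
        assert report.rejected_site_peptide == 1
        assert report.rejected_not_in_reference == 1

    def test_rows_missing_a_channel_removed(self):
        df = _rows(("P1", "AAK", "1:50", "s1", 10, math.nan, 50.0, math.nan))
        kept, report = st.filter_peptides(df, REFS, st.FilterConfig())
        assert kept.empty and report.rejected_missing_channel == 1

    def test_filter_is_idempotent(self, noiseless_titration, refs_for):
        cfg = st.FilterConfig()
        once, _ = st.filter_peptides(noiseless_titration, refs_for, cfg)
        twice, report = st.filter_peptides(once, refs_for, cfg)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_retained == report.n_input


class TestRollup:
    @pytest.mark.parametrize(
        "ratios,expected",
        [((0.1, 0.2, 0.4), 0.2), ((0.1, 0.3), 0.2), ((0.7,), 0.7)],
    )
    def test_median_conventions(self, ratios, expected):
        df = _rows(
            *(
                ("P1", f"PEP{i}K", "1:50", "s1", r * 100.0, 100.0, 50.0, 50.0)
                for i, r in enumerate(ratios)
            )
        )
        out = st.rollup_protein_ratios(df)
        assert len(out) == 1
        assert out.loc[0, "median_hl"] == pytest.approx(expected, rel=1e-12)
        assert out.loc[0, "n_peptides"] == len(ratios)

    def test_grouping_by_protein_mix_and_replicate(self):
        df = _rows(
            ("P1", "AAK", "1:50", "s1", 10, 100, 50, 50),
            ("P1", "AAK", "1:200", "s1", 10, 100, 50, 50),
            ("P1", "AAK", "1:50", "s2", 10, 100, 50, 50),
            ("P2", "BBK", "1:50", "s1", 10, 100, 50, 50),
        )
        out = st.rollup_protein_ratios(df)
        assert len(out) == 4


class TestInversion:
    def test_identity_case_full_occupancy(self):
        d = MixDesign("1:2000", 5.0, 10_000.0)
        assert st.per_ratio_stoichiometry("1:2000", 1 / 2000, d) == pytest.approx(1.0, rel=1e-12)

    def test_worked_case_two_percent(self):
        d = MixDesign("1:200", 100.0, 20_000.0)
        assert st.per_ratio_stoichiometry("1:200", 0.25, d) == pytest.approx(0.02, rel=1e-12)

    def test_label_mismatch_raises(self):
        d = MixDesign("1:200", 100.0, 20_000.0)
        with pytest.raises(ValueError, match="mismatch"):
            st.per_ratio_stoichiometry("1:50", 0.25, d)

    def test_monotone_decreasing_in_median(self):
        d = MixDesign("1:50", 200.0, 10_000.0)
        values = [st.per_ratio_stoichiometry("1:50", m, d) for m in (0.1, 0.2, 0.5, 2.0)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestFinalize:
    def test_even_count_median(self):
        """Even-count median = arithmetic mean of the two middle values,
        stored at full precision."""
        est = st.finalize_stoichiometry("P1", {"a": 0.019, "b": 0.020, "c": 0.021, "d": 0.024})
        assert est.final == pytest.approx(0.0205, rel=1e-12)
        assert est.n_mix_points == 4 and not est.flags

    def test_single_point_flagged(self):
        est = st.finalize_stoichiometry("P1", {"1:50": 0.004})
        assert est.final == 0.004 and est.flags == {"single_mix_point"}

    def test_exceeds_one_flagged_not_clamped(self):
        est = st.finalize_stoichiometry("P1", {"a": 1.2, "b": 1.1, "c": 1.3})
        assert est.final == pytest.approx(1.2) and "exceeds_one" in est.flags

    def test_no_valid_point_raises(self):
        with pytest.raises(ValueError):
            st.finalize_stoichiometry("P1", {})


class TestReplicates:
    def _est(self, pid, value):
        return st.finalize_stoichiometry(pid, {"1:50": value})

    def test_union_mean(self):
        combined, report = st.combine_replicates(
            {"set1": [self._est("A", 0.02)], "set2": [self._est("A", 0.04)]}
        )
        (a,) = combined
        assert a.final == pytest.approx(0.03) and report.n_overlap == 1
        assert a.replicate_values == {"set1": 0.02, "set2": 0.04}

    def test_disjoint_replicates_have_no_correlation(self):
        combined, report = st.combine_replicates(
            {"set1": [self._est("A", 0.02)], "set2": [self._est("B", 0.04)]}
        )
        assert {e.protein_id for e in combined} == {"A", "B"}
        assert report.n_overlap == 0 and report.pearson_log10 is None

    def test_intersection_mode_drops_singletons(self):
        combined, _ = st.combine_replicates(
            {"set1": [self._est("A", 0.02), self._est("B", 0.01)], "set2": [self._est("A", 0.04)]},
            mode="intersection_mean",
        )
        assert [e.protein_id for e in combined] == ["A"]

    def test_identical_noiseless_replicates_correlate_perfectly(
        self, noiseless_truth, noiseless_cfg, refs_for, truth_map
    ):
        tables = [
            sim.simulate_titration_experiment(noiseless_truth, sim.TABLE1_DESIGN, noiseless_cfg, rep)
            for rep in ("set1", "set2")
        ]
        combined, report = run_estimation(pd.concat(tables, ignore_index=True), refs_for)
        assert report.pearson_log10 == pytest.approx(1.0, abs=1e-12)
        assert report.n_overlap == len(combined)


class TestEndToEnd:
    def test_noiseless_inversion_is_exact(self, noiseless_titration, refs_for, truth_map):
        combined, _ = run_estimation(noiseless_titration, refs_for)
        assert len(combined) == len(truth_map)
        assert relative_errors(combined, truth_map).max() < 1e-9

    def test_scale_invariance_of_estimates(self, noiseless_titration, refs_for):
        combined, _ = run_estimation(noiseless_titration, refs_for)
        scaled = noiseless_titration.copy()
        for col in ("area_heavy", "area_light"):
            scaled[col] *= 37.5
        combined_scaled, _ = run_estimation(scaled, refs_for)
        a = {e.protein_id: e.final for e in combined}
        b = {e.protein_id: e.final for e in combined_scaled}
        assert a.keys() == b.keys()
        assert all(math.isclose(a[p], b[p], rel_tol=1e-12) for p in a)

    @given(
        clean=hs.lists(hs.floats(0.01, 10.0), min_size=3, max_size=9),
        corrupt=hs.lists(hs.floats(1e-6, 1e6), min_size=0, max_size=4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_median_robust_to_minority_corruption(self, clean, corrupt):
        """With 2k+1 ratios, corrupting <= k of them keeps the protein median
        inside the clean ratios' range."""
        if len(corrupt) > (len(clean) + len(corrupt) - 1) // 2:
            corrupt = corrupt[: (len(clean) - 1) // 2]
        ratios = clean + corrupt
        df = _rows(
            *(
                ("P1", f"PEP{i}K", "1:50", "s1", r * 100.0, 100.0, 50.0, 50.0)
                for i, r in enumerate(ratios)
            )
        )
        median = st.rollup_protein_ratios(df).loc[0, "median_hl"]
        assert min(clean) <= median <= max(clean)


class TestSummary:
    def test_small_cohort_summary(self):
        ests = [st.finalize_stoichiometry(p, {"1:50": v}) for p, v in
                [("A", 0.01), ("B", 0.02), ("C", 0.03)]]
        s = st.summarize_distribution(ests)
        assert s.median_percent == pytest.approx(2.0)
        assert s.mean_percent == pytest.approx(2.0)
        assert s.min_percent == pytest.approx(1.0) and s.max_percent == pytest.approx(3.0)

    def test_strict_threshold_buckets(self):
        ests = [st.finalize_stoichiometry(p, {"1:50": v}) for p, v in
                [("A", 0.005), ("B", 0.06), ("C", 0.05), ("D", 0.01)]]
        s = st.summarize_distribution(ests)
        assert s.bucket_counts == {">5%": 1, "<1%": 1}

    def test_synthetic_cohort_matches_truth_sidecar(self, noiseless_titration, refs_for, truth_map):
        combined, _ = run_estimation(noiseless_titration, refs_for)
        s = st.summarize_distribution(combined)
        truth_pct = 100.0 * np.array(list(truth_map.values()))
        assert s.median_percent == pytest.approx(np.median(truth_pct), rel=1e-6)
        assert s.mean_percent == pytest.approx(truth_pct.mean(), rel=1e-6)
        assert s.bucket_counts[">5%"] == int((truth_pct > 5).sum())


def test_estimates_table_roundtrip_columns(tmp_path, noiseless_titration, refs_for):
    combined, _ = run_estimation(noiseless_titration, refs_for)
    path = tmp_path / "est.tsv"
    st.write_estimates_table(combined, path, sim.TABLE1_DESIGN)
    back = pd.read_csv(path, sep="\t")
    assert {"protein_id", "s_final_percent", "n_mix_points", "flags"} <= set(back.columns)
    assert len(back) == len(combined)
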