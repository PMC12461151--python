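"""Cohort summaries, the proportion/location tests and the protein rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splice2nmd.cohort_stats import (
    compare_continuous,
    compare_proportions,
    compare_psi_magnitude,
    export_nmd_false_genes,
    predict_protein_direction,
    summarize_cohort,
)
from splice2nmd.nmd_core import NMDResult
from splice2nmd.whippet_io import DGERecord, SpliceEvent


def chi2_oracle(k1, n1, k2, n2, yates):
    """Closed-form 2x2 chi-square, written from the textbook formula."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    exp = np.outer(row, col) / total
    diff = np.abs(obs - exp)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / exp).sum())
    return stat, float(stats.distributions.chi2.sf(stat, 1))


def _ev(dpsi, gene="G1", node=1):
    return SpliceEvent(gene_id=gene, node=node, chrom="c", start=0, end=10,
                       strand="+", event_type="CE", psi_a=0.5,
                       psi_b=min(1.0, max(0.0, 0.5 + dpsi)), delta_psi=dpsi,
                       probability=0.95)


class TestCompareProportions:
    def test_identical_proportions(self):
        r = compare_proportions(50, 100, 50, 100)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(5, 500, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
                continue
            uncorr, corr = compare_proportions(k1, int(n1), k2, int(n2),
                                               return_both=True)
            s0, p0 = chi2_oracle(k1, n1, k2, n2, yates=False)
            s1, p1 = chi2_oracle(k1, n1, k2, n2, yates=True)
            assert uncorr.statistic == pytest.approx(s0, abs=1e-9)
            assert uncorr.p_value == pytest.approx(p0, abs=1e-9)
            assert corr.statistic == pytest.approx(s1, abs=1e-9)
            assert corr.p_value == pytest.approx(p1, abs=1e-9)

    def test_yates_branch_on_small_expected_counts(self):
        r = compare_proportions(1, 5, 4, 5)
        assert r.test_name == "chi-square (Yates)"
        r = compare_proportions(450, 500, 400, 500)
        assert r.test_name == "chi-square"

    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 5)


class TestComparePsiMagnitude:
    def test_identical_groups(self):
        a = [_ev(d) for d in (0.1, 0.2, 0.3)]
        med_a, med_b, p, _ = compare_psi_magnitude(a, list(a))
        assert med_a == med_b == 0.2
        assert p > 0.9

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(7)
        a = [_ev(round(d, 4)) for d in rng.uniform(0.1, 0.4, 200)]
        b = [_ev(round(-d, 4)) for d in rng.uniform(0.4, 0.7, 200)]
        med_a, med_b, p, details = compare_psi_magnitude(a, b)
        assert med_b > med_a
        assert p < 0.001

    def test_single_element_groups_exact(self):
        med_a, med_b, p, details = compare_psi_magnitude([_ev(0.1)], [_ev(0.2)])
        assert (med_a, med_b) == (0.1, 0.2)
        assert details["method"] == "exact"
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_psi_magnitude([], [_ev(0.1)])


class TestCompareContinuous:
    def test_normal_data_uses_t(self):
        rng = np.random.default_rng(3)
        r = compare_continuous(rng.normal(0, 1, 80), rng.normal(0.1, 1, 80))
        assert r.test_name == "welch-t"

    def test_skewed_data_uses_wilcoxon(self):
        rng = np.random.default_rng(3)
        r = compare_continuous(rng.exponential(1, 80), rng.exponential(2, 80))
        assert r.test_name == "wilcoxon-rank-sum"


def _results_frame(rows):
    return pd.DataFrame(rows, columns=[
        "gene_id", "node", "event_type", "predicted_frame", "ptc_count_f0",
        "ptc_count_f1", "ptc_count_f2", "first_ptc", "last_junction",
        "distance_nt", "nmd", "reason"])


def _row(gene, node, etype, nmd, reason="PTC_UPSTREAM_RULE", ptc=5):
    return dict(gene_id=gene, node=node, event_type=etype, predicted_frame=1,
                ptc_count_f0=ptc, ptc_count_f1=0, ptc_count_f2=0,
                first_ptc=10, last_junction=100, distance_nt=88,
                nmd=nmd, reason=reason)


class TestSummarize:
    def test_rates_and_medians_by_hand(self):
        all_rows = [_row("G1", 1, "ES", True, ptc=37),
                    _row("G2", 2, "ES", True, ptc=36),
                    _row("G3", 3, "ES", True, ptc=38),
                    _row("G4", 4, "RI", False, reason="NO_PTC", ptc=0),
                    _row("G5", 5, "RI", True, ptc=23),
                    _row("G6", 6, "AA", True, ptc=24),
                    _row("G7", 7, "AD", True, ptc=30),
                    _row("G8", 8, "ES", False, reason="PTC_TOO_CLOSE", ptc=2),
                    _row("G9", 9, "ES", True, ptc=40),
                    _row("GA", 10, "ES", True, ptc=41),
                    _row("GB", 11, "TS", False, reason="NOT_ON_CANONICAL")]
        sig_rows = all_rows[:5]
        summary = summarize_cohort(_results_frame(all_rows),
                                   _results_frame(sig_rows))
        base = summary.baseline
        assert base.n_processed == 10  # the TS skip row is excluded
        assert base.nmd_rate == pytest.approx(80.0)
        assert base.ptc_median_by_type["ES"] == 37.5
        assert base.nmd_by_type["RI"] == pytest.approx(50.0)
        shares = base.nmd_share_by_type
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.1)
        assert summary.contrast.nmd_rate == pytest.approx(80.0)
        assert summary.nmd_rate_test is not None

    def test_order_independence(self, cohort100_results):
        df = cohort100_results
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        s1 = summarize_cohort(df, df)
        s2 = summarize_cohort(shuffled, shuffled)
        assert s1.baseline.nmd_rate == s2.baseline.nmd_rate
        assert s1.baseline.ptc_median_by_type == s2.baseline.ptc_median_by_type
        assert s1.baseline.nmd_share_by_type == s2.baseline.nmd_share_by_type

    def test_empty_processed_set_rejected(self):
        df = _results_frame([_row("G", 1, "ES", False,
                                  reason="NOT_ON_CANONICAL")])
        with pytest.raises(ValueError, match="no processed"):
            summarize_cohort(df, df)

    def test_denominator_discipline(self, cohort100, cohort100_results):
        proc = cohort100_results[cohort100_results.reason.isin(
            {"PTC_UPSTREAM_RULE", "NO_PTC", "PTC_IN_LAST_EXON",
             "PTC_TOO_CLOSE", "NO_JUNCTION", "NO_CDS_CHANGE"})]
        summary = summarize_cohort(cohort100_results, cohort100_results)
        assert summary.baseline.nmd_rate == pytest.approx(
            100.0 * proc.nmd.sum() / len(proc))


class TestExportNmdFalse:
    def test_unique_sorted_processed_only(self):
        rows = [_row("GB", 1, "ES", False, reason="NO_PTC"),
                _row("GA", 2, "ES", False, reason="PTC_TOO_CLOSE"),
                _row("GA", 3, "RI", False, reason="NO_PTC"),
                _row("GC", 4, "ES", True),
                _row("GD", 5, "ES", False, reason="NOT_ON_CANONICAL")]
        genes = export_nmd_false_genes(_results_frame(rows))
        assert genes == ["GA", "GB"]

    def test_all_true_gives_empty_file(self, tmp_path):
        rows = [_row("G1", 1, "ES", True)]
        path = tmp_path / "genes.txt"
        genes = export_nmd_false_genes(_results_frame(rows), path)
        assert genes == []
        assert path.read_text() == ""


class TestProteinDirection:
    def _nmd(self, flag):
        return NMDResult(gene_id="GCA", node=1, event_type="ES",
                         predicted_frame=1, nmd=flag,
                         reason="PTC_UPSTREAM_RULE" if flag else "NO_PTC")

    def test_gca_like_case_predicts_higher_protein(self):
        # not differentially expressed, spliced less in the contrast group,
        # event NMD-true: fewer degraded transcripts, more protein
        call = predict_protein_direction(
            DGERecord("GCA", 0.3, 0.8), _ev(-0.3, "GCA"), self._nmd(True))
        assert call.predicted_direction == "higher_in_B"
        assert call.splicing_direction == "less_in_B"

    def test_symmetric_case_predicts_lower(self):
        call = predict_protein_direction(
            DGERecord("GCA", 0.3, 0.8), _ev(0.3, "GCA"), self._nmd(True))
        assert call.predicted_direction == "lower_in_B"

    def test_significant_dge_is_indeterminate(self):
        call = predict_protein_direction(
            DGERecord("GCA", 3.0, 0.001), _ev(-0.3, "GCA"), self._nmd(True))
        assert call.predicted_direction == "indeterminate"
        assert call.dge_significant

    def test_nmd_false_is_indeterminate(self):
        call = predict_protein_direction(
            DGERecord("GCA", 0.3, 0.8), _ev(-0.3, "GCA"), self._nmd(False))
        assert call.predicted_direction == "indeterminate"

    def test_missing_dge_treated_as_non_significant(self):
        call = predict_protein_direction(None, _ev(-0.3, "GCA"),
                                         self._nmd(True))
        assert call.predicted_direction == "higher_in_B"
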