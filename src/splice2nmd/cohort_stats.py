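"""Cohort-level summaries of NMD predictions and the associated tests.

The intended study design compares the NMD rate over *all* quantified
splicing events (the baseline population, playing the control role) against
the rate over the *significant* events (the contrast group, e.g. disease or
non-survivor cohorts).  The summary API makes this explicit:
``summarize_cohort(results_all, results_sig)`` rather than two disjoint
patient-level event sets.

Test selection follows the conventional gates: chi-square for proportions
with Yates' continuity correction when any expected cell count drops below 5;
Shapiro-Wilk normality gating between the t test and the Wilcoxon rank-sum
test for continuous two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .nmd_core import PROCESSED_REASONS, NMDResult
from .whippet_io import DGERecord, SpliceEvent

SPLICING_LABELS = ("ES", "RI", "AA", "AD")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str


@dataclass
class GroupSummary:
    """Per-group NMD summary (one of the two cohorts being compared)."""

    label: str
    n_processed: int
    n_nmd_true: int
    nmd_rate: float  # percent
    event_type_counts: dict[str, int] = field(default_factory=dict)
    event_type_percent: dict[str, float] = field(default_factory=dict)
    nmd_by_type: dict[str, float] = field(default_factory=dict)  # percent per type
    nmd_true_by_type: dict[str, int] = field(default_factory=dict)
    nmd_share_by_type: dict[str, float] = field(default_factory=dict)  # percent of NMD-true
    ptc_median_by_type: dict[str, float] = field(default_factory=dict)
    ptc_counts_by_type: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Two-group comparison of NMD predictions."""

    baseline: GroupSummary
    contrast: GroupSummary
    nmd_rate_test: TestResult | None = None
    nmd_by_type_tests: dict[str, TestResult] = field(default_factory=dict)
    nmd_share_tests: dict[str, TestResult] = field(default_factory=dict)
    ptc_median_tests: dict[str, TestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def grp(g: GroupSummary) -> dict:
            return {
                "label": g.label,
                "n_processed": g.n_processed,
                "n_nmd_true": g.n_nmd_true,
                "nmd_rate": g.nmd_rate,
                "event_type_counts": g.event_type_counts,
                "event_type_percent": g.event_type_percent,
                "nmd_by_type": g.nmd_by_type,
                "nmd_share_by_type": g.nmd_share_by_type,
                "ptc_median_by_type": g.ptc_median_by_type,
            }

        def test(t: TestResult | None):
            if t is None:
                return None
            return {"statistic": t.statistic, "p_value": t.p_value,
                    "test_name": t.test_name}

        return {
            "baseline": grp(self.baseline),
            "contrast": grp(self.contrast),
            "tests": {
                "nmd_rate": test(self.nmd_rate_test),
                "nmd_by_type": {k: test(v) for k, v in self.nmd_by_type_tests.items()},
                "nmd_share_by_type": {k: test(v) for k, v in self.nmd_share_tests.items()},
                "ptc_median_by_type": {k: test(v) for k, v in self.ptc_median_tests.items()},
            },
        }


@dataclass(frozen=True)
class ProteinDirectionCall:
    """Predicted direction of a protein-level change in group B.

    When a gene is not differentially expressed but one of its splicing
    events is significant and NMD-inducing, the psi direction of that event
    predicts the protein: the event *less* frequent in B means fewer
    NMD-degraded transcripts in B, hence a higher protein level in B.
    """

    gene_id: str
    dge_significant: bool
    splicing_direction: str  # more_in_B | less_in_B
    nmd_flag: bool
    predicted_direction: str  # higher_in_B | lower_in_B | indeterminate


def _processed(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["reason"].isin(PROCESSED_REASONS)]


def _ptc_count_translation_frame(df: pd.DataFrame) -> pd.Series:
    # Premature stops in the frame the ribosome reads (frame 0 of the
    # modified transcript).
    return df["ptc_count_f0"]


def _group_summary(df: pd.DataFrame, label: str) -> GroupSummary:
    proc = _processed(df)
    n = len(proc)
    if n == 0:
        raise ValueError(f"group {label!r} has no processed events; "
                         "NMD rate undefined")
    k = int(proc["nmd"].sum())
    counts = {t: int((proc["event_type"] == t).sum()) for t in SPLICING_LABELS}
    percent = {t: 100.0 * c / n for t, c in counts.items()}
    nmd_by_type = {}
    ptc_median = {}
    ptc_lists = {}
    for t in SPLICING_LABELS:
        sub = proc[proc["event_type"] == t]
        nmd_by_type[t] = 100.0 * sub["nmd"].sum() / len(sub) if len(sub) else float("nan")
        vals = _ptc_count_translation_frame(sub).tolist()
        ptc_lists[t] = vals
        ptc_median[t] = float(np.median(vals)) if vals else float("nan")
    true_by_type = {t: int(proc[(proc["event_type"] == t) & proc["nmd"]].shape[0])
                    for t in SPLICING_LABELS}
    total_true = sum(true_by_type.values())
    share = {t: (100.0 * c / total_true if total_true else float("nan"))
             for t, c in true_by_type.items()}
    return GroupSummary(
        label=label, n_processed=n, n_nmd_true=k,
        nmd_rate=100.0 * k / n,
        event_type_counts=counts, event_type_percent=percent,
        nmd_by_type=nmd_by_type, nmd_true_by_type=true_by_type,
        nmd_share_by_type=share,
        ptc_median_by_type=ptc_median, ptc_counts_by_type=ptc_lists)


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int,
    correction: bool | None = None,
    return_both: bool = False,
):
    """Chi-square test of two proportions on the 2x2 table.

    ``correction=None`` selects Yates' continuity correction automatically
    when any expected cell count is below 5 (the conventional small-sample
    rule); pass True/False to force.  With ``return_both`` the corrected and
    uncorrected results are both returned.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        # degenerate: a margin is zero; proportions identical by construction
        return TestResult(0.0, 1.0, "chi-square")

    def run(corr: bool) -> TestResult:
        stat, p, _, _ = stats.chi2_contingency(table, correction=corr)
        name = "chi-square (Yates)" if corr else "chi-square"
        return TestResult(float(stat), float(p), name)

    if return_both:
        return run(False), run(True)
    if correction is None:
        expected = stats.contingency.expected_freq(table)
        correction = bool((expected < 5).any())
    return run(correction)


def compare_psi_magnitude(
    events_a: list[SpliceEvent],
    events_b: list[SpliceEvent],
    exact_max_n: int = 50,
) -> tuple[float, float, float, dict]:
    """Compare |delta psi| magnitudes between two event groups.

    Returns ``(median_a, median_b, p_value, details)``.  Normality of each
    group is assessed with the Anderson-Darling test (reported in
    ``details``); the comparison itself is the Wilcoxon rank-sum test, exact
    for small tie-free samples and normal-approximated (with continuity
    correction) otherwise.
    """
    if not events_a or not events_b:
        raise ValueError("both groups must be non-empty")
    a = np.abs([ev.delta_psi for ev in events_a])
    b = np.abs([ev.delta_psi for ev in events_b])
    details: dict = {}
    for name, x in (("a", a), ("b", b)):
        if len(x) >= 8 and np.ptp(x) > 0:
            ad = stats.anderson(x, dist="norm", method="interpolate")
            details[f"anderson_{name}"] = {
                "statistic": float(ad.statistic),
                "p_value": float(ad.pvalue),
                "normal_at_5pct": bool(ad.pvalue >= 0.05),
            }
        else:
            details[f"anderson_{name}"] = None
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    details["method"] = method
    return (float(np.median(a)), float(np.median(b)),
            float(res.pvalue), details)


def compare_continuous(x, y, alpha: float = 0.05) -> TestResult:
    """Two-group location test gated by Shapiro-Wilk normality at ``alpha``:
    Welch's t test when both groups look normal, else Wilcoxon rank-sum."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon-rank-sum")
    normal = all(
        np.ptp(g) > 0 and stats.shapiro(g).pvalue >= alpha for g in (x, y))
    if normal:
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult(float(res.statistic), float(res.pvalue), "welch-t")
    method = "exact" if (max(len(x), len(y)) <= 50 and
                         len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon-rank-sum")


def summarize_cohort(
    results_all: pd.DataFrame,
    results_sig: pd.DataFrame,
    labels: tuple[str, str] = ("all_events", "significant_events"),
) -> CohortSummary:
    """Build the two-group cohort summary with its statistical tests.

    ``results_all`` is the baseline population (all quantified events),
    ``results_sig`` the contrast (significant events); skip-reason rows are
    excluded from every denominator.
    """
    base = _group_summary(results_all, labels[0])
    cont = _group_summary(results_sig, labels[1])
    summary = CohortSummary(baseline=base, contrast=cont)
    summary.nmd_rate_test = compare_proportions(
        base.n_nmd_true, base.n_processed, cont.n_nmd_true, cont.n_processed)
    for t in SPLICING_LABELS:
        nb = base.event_type_counts[t]
        nc = cont.event_type_counts[t]
        if nb and nc:
            summary.nmd_by_type_tests[t] = compare_proportions(
                base.nmd_true_by_type[t], nb, cont.nmd_true_by_type[t], nc)
        if base.n_nmd_true and cont.n_nmd_true:
            summary.nmd_share_tests[t] = compare_proportions(
                base.nmd_true_by_type[t], base.n_nmd_true,
                cont.nmd_true_by_type[t], cont.n_nmd_true)
        xb = base.ptc_counts_by_type[t]
        xc = cont.ptc_counts_by_type[t]
        if len(xb) >= 1 and len(xc) >= 1:
            summary.ptc_median_tests[t] = compare_continuous(xb, xc)
    return summary


def export_nmd_false_genes(results: pd.DataFrame, path: str | Path | None = None
                           ) -> list[str]:
    """Unique, sorted gene ids of processed events predicted NMD-false.

    Skip-reason rows (NOT_ON_CANONICAL, START_LOST) never contribute.  When
    ``path`` is given the list is also written one gene per line, ready for
    external GO-enrichment tools.
    """
    proc = _processed(results)
    genes = sorted(set(proc.loc[~proc["nmd"], "gene_id"]))
    if path is not None:
        Path(path).write_text("".join(g + "\n" for g in genes))
    return genes


def predict_protein_direction(
    dge: DGERecord | None,
    event: SpliceEvent,
    nmd: NMDResult,
) -> ProteinDirectionCall:
    """Combine DGE, splicing direction and the NMD call into a protein-level
    prediction for group B (the contrast cohort).

    The rule is only informative when transcription is unchanged (DGE not
    significant) and the event triggers NMD: then delta psi < 0 (event rarer
    in B) predicts a higher protein level in B, delta psi > 0 a lower one.
    """
    dge_sig = dge.is_significant() if dge is not None else False
    direction = "less_in_B" if event.delta_psi < 0 else "more_in_B"
    if dge_sig or not nmd.nmd:
        predicted = "indeterminate"
    elif event.delta_psi < 0:
        predicted = "higher_in_B"
    else:
        predicted = "lower_in_B"
    return ProteinDirectionCall(
        gene_id=event.gene_id,
        dge_significant=dge_sig,
        splicing_direction=direction,
        nmd_flag=bool(nmd.nmd),
        predicted_direction=predicted)
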