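"""Group statistics: questionnaire change scoring, median split, exact
Wilcoxon rank-sum tests, Cohen's d, Benjamini-Hochberg correction, and the
per-epoch / whole-task / PSD-map comparisons built from them.

With 9 vs 8 participants the rank-sum null distribution is small enough to
use exactly: for tie-free samples with n1 + n2 <= 25 the two-sided p-value
is computed from the exact null distribution of the rank sum (count DP over
subset rank sums); larger or tied samples fall back to the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .features import EEG_BANDS, band_power

ALPHA = 0.05
EXACT_MAX_N = 25


@dataclass
class GroupAssignment:
    """Participant -> group labels from the questionnaire median split."""

    groups: dict[str, str]  # id -> "anxious" | "non_anxious"
    change_scores: dict[str, float]

    @property
    def anxious(self) -> list[str]:
        return [p for p, g in self.groups.items() if g == "anxious"]

    @property
    def non_anxious(self) -> list[str]:
        return [p for p, g in self.groups.items() if g == "non_anxious"]


@dataclass
class TestResult:
    """One measure's group comparison in the shape of a results-table row."""

    measure: str
    units: str
    rank_sum_statistic: float
    p_two_sided: float
    cohens_d: float
    group_means: dict[str, float]
    group_medians: dict[str, float]
    group_sds: dict[str, float]
    group_ci95: dict[str, tuple[float, float]]
    n_per_group: dict[str, int]
    excluded: list[str] = field(default_factory=list)


@dataclass
class SignificanceMask:
    """Raw/corrected p-values with a boolean mask at alpha."""

    p_raw: np.ndarray
    p_corrected: np.ndarray | None
    mask: np.ndarray
    alpha: float = ALPHA
    labels: list | None = None


def gad7_change(pre_items: np.ndarray, post_items: np.ndarray) -> float:
    """Mean-item change score: mean(post) - mean(pre)."""
    pre_items = np.asarray(pre_items, dtype=float)
    post_items = np.asarray(post_items, dtype=float)
    if pre_items.shape != (7,) or post_items.shape != (7,):
        raise ValueError("GAD-7 requires exactly 7 item scores per occasion")
    return float(post_items.mean() - pre_items.mean())


def median_split(change_scores: dict[str, float]) -> GroupAssignment:
    """Split participants at the median change score.

    Scores above the median are anxious, below non-anxious; for odd n the
    median participant joins the anxious group, which reproduces the 9/8
    split of a 17-participant cohort.  Tied scores are rejected because the
    split would be ambiguous.
    """
    if len(change_scores) < 4:
        raise ValueError("median split needs at least 4 participants")
    vals = np.array(list(change_scores.values()))
    if len(np.unique(vals)) != len(vals):
        raise ValueError(
            "tied change scores: the median split is ambiguous; supply "
            "distinct scores or define a tie policy")
    order = sorted(change_scores, key=change_scores.__getitem__,
                   reverse=True)
    n_anx = (len(order) + 1) // 2
    groups = {p: ("anxious" if i < n_anx else "non_anxious")
              for i, p in enumerate(order)}
    return GroupAssignment({p: groups[p] for p in change_scores},
                           dict(change_scores))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _ranksum_counts(n1: int, n: int) -> np.ndarray:
    """counts[w] = number of size-n1 subsets of ranks {1..n} summing to w."""
    max_w = n1 * n
    dp = np.zeros((n1 + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    return dp[n1]


def _exact_two_sided_p(w: int, n1: int, n2: int) -> float:
    counts = _ranksum_counts(n1, n1 + n2)
    total = comb(n1 + n2, n1)
    lower = counts[: w + 1].sum() / total
    upper = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the sum of the pooled midranks of
    ``x``.  Exact p (2 x the smaller tail of the exact null, capped at 1)
    for tie-free samples with n1 + n2 <= 25; otherwise a normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _st.rankdata(pooled)
    w = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n1 + n2 <= EXACT_MAX_N:
        return w, _exact_two_sided_p(int(round(w)), n1, n2)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return w, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    return w, float(min(1.0, 2.0 * _st.norm.sf(abs(z))))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardized mean difference; NaN when the pooled SD is 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) \
        / (n1 + n2 - 2)
    if s2 <= 0:
        return np.nan
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def bh_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# Measure-level comparisons
# ---------------------------------------------------------------------------

def _split_values(values: pd.Series | dict, assignment: GroupAssignment
                  ) -> tuple[np.ndarray, np.ndarray]:
    values = dict(values)
    x = np.array([values[p] for p in assignment.anxious if p in values])
    y = np.array([values[p] for p in assignment.non_anxious if p in values])
    return x, y


def timecourse_tests(feature_matrix: pd.DataFrame,
                     assignment: GroupAssignment,
                     alpha: float = ALPHA) -> SignificanceMask:
    """Per-epoch rank-sum tests over a participants x epochs matrix.

    P-values are deliberately left uncorrected (exploratory time courses);
    epochs with fewer than 2 valid values in either group get NaN p and a
    False mask entry.
    """
    n_ep = feature_matrix.shape[1]
    p = np.full(n_ep, np.nan)
    for k in range(n_ep):
        col = feature_matrix.iloc[:, k]
        x, y = _split_values(col.dropna(), assignment)
        if len(x) >= 2 and len(y) >= 2:
            _, p[k] = ranksum_test(x, y)
    mask = np.where(np.isnan(p), False, p < alpha)
    return SignificanceMask(p, None, mask, alpha)


def whole_task_test(feature_matrix: pd.DataFrame,
                    assignment: GroupAssignment, measure: str = "",
                    units: str = "") -> TestResult:
    """Average each participant over all epochs, then compare the groups.

    Participants whose every epoch is missing are excluded (and listed in
    the result).  Descriptives per group: mean, median, sample SD and the
    empirical 2.5-97.5 percentile interval.
    """
    means = feature_matrix.mean(axis=1, skipna=True)
    excluded = sorted(means.index[means.isna()])
    means = means.dropna()
    x, y = _split_values(means, assignment)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"measure {measure!r}: fewer than 2 valid "
                         "participants in a group")
    w, p = ranksum_test(x, y)
    desc = {}
    for name, vals in (("anxious", x), ("non_anxious", y)):
        desc[name] = dict(
            mean=float(vals.mean()), median=float(np.median(vals)),
            sd=float(np.std(vals, ddof=1)),
            ci95=(float(np.percentile(vals, 2.5)),
                  float(np.percentile(vals, 97.5))),
            n=len(vals))
    return TestResult(
        measure=measure, units=units, rank_sum_statistic=w, p_two_sided=p,
        cohens_d=cohens_d(x, y),
        group_means={g: d["mean"] for g, d in desc.items()},
        group_medians={g: d["median"] for g, d in desc.items()},
        group_sds={g: d["sd"] for g, d in desc.items()},
        group_ci95={g: d["ci95"] for g, d in desc.items()},
        n_per_group={g: d["n"] for g, d in desc.items()},
        excluded=excluded)


def psd_group_comparison(psd: np.ndarray, freqs: np.ndarray,
                         participant_ids: list[str],
                         assignment: GroupAssignment, level: str,
                         alpha: float = ALPHA) -> SignificanceMask:
    """Group tests over whole-task-averaged power spectra.

    ``level="per_bin_roll"``: psd is participants x epochs x bins; one test
    per 1 Hz bin, BH across bins.  ``level="per_channel_band_eeg"``: psd is
    participants x epochs x channels x bins; band power per channel x band
    cell, one test per cell, BH across all cells.  Masks threshold the
    corrected p-values at alpha.
    """
    psd = np.asarray(psd, dtype=float)
    task_avg = psd.mean(axis=1)  # average over epochs first
    idx = {p: i for i, p in enumerate(participant_ids)}
    ia = [idx[p] for p in assignment.anxious if p in idx]
    inb = [idx[p] for p in assignment.non_anxious if p in idx]
    if level == "per_bin_roll":
        cells = task_avg  # participants x bins
        labels = [float(f) for f in freqs]
    elif level == "per_channel_band_eeg":
        bands = list(EEG_BANDS)
        stacked = np.stack(
            [band_power(task_avg, freqs, EEG_BANDS[b]) for b in bands],
            axis=-1)  # participants x channels x bands
        n_ch = stacked.shape[1]
        cells = stacked.reshape(stacked.shape[0], -1)
        labels = [(c, b) for c in range(n_ch) for b in bands]
    else:
        raise ValueError(f"unknown comparison level {level!r}")
    p_raw = np.empty(cells.shape[1])
    for j in range(cells.shape[1]):
        _, p_raw[j] = ranksum_test(cells[ia, j], cells[inb, j])
    p_corr = bh_correct(p_raw)
    return SignificanceMask(p_raw, p_corr, p_corr < alpha, alpha, labels)


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Assemble TestResults into a descriptive/inferential results table."""
    rows = []
    for r in results:
        rows.append({
            "measure": f"{r.measure} [{r.units}]",
            "mean_anx": r.group_means["anxious"],
            "mean_non_anx": r.group_means["non_anxious"],
            "median_anx": r.group_medians["anxious"],
            "median_non_anx": r.group_medians["non_anxious"],
            "sd_anx": r.group_sds["anxious"],
            "sd_non_anx": r.group_sds["non_anxious"],
            "ci95_lo_anx": r.group_ci95["anxious"][0],
            "ci95_hi_anx": r.group_ci95["anxious"][1],
            "ci95_lo_non_anx": r.group_ci95["non_anxious"][0],
            "ci95_hi_non_anx": r.group_ci95["non_anxious"][1],
            "rank_sum": r.rank_sum_statistic,
            "p_value": r.p_two_sided,
            "cohens_d": r.cohens_d,
        })
    return pd.DataFrame(rows).set_index("measure")
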