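"""Sister-species divergence: per-pair tests, size ratios, and the ANCOVA.

A sister pair is a cherry of the dated phylogeny with a sympatry label
(ranges overlap or not). Character displacement predicts larger body-size
divergence in sympatric pairs. Three complementary analyses:

* per-pair location tests on the individual width measurements — Welch t when
  both species pass a normality screen, two-sample Wilcoxon otherwise — with
  a Bonferroni threshold alpha / (number of pairs);
* the ratio of species mean widths (larger / smaller), compared between
  sympatric and non-sympatric pairs with a pooled-variance t-test;
* an ANCOVA of the absolute standardized contrast |C| of each pair against
  its evolutionary divergence (sum of the two pendant branch lengths, Ma) and
  sympatry status, with interaction — a positive sympatric slope means
  divergence keeps accumulating with time in sympatry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import DatedTree, OccurrenceRecord
from .size_distribution import dagostino_skew_test

__all__ = [
    "SisterPair",
    "TTestResult",
    "AncovaResult",
    "RatioComparison",
    "welch_t",
    "welch_t_from_summary",
    "wilcoxon_rank_sum",
    "read_pair_table",
    "build_sister_pairs",
    "pair_test_battery",
    "ratio_comparison",
    "contrasts_vs_time_ancova",
]

STATUSES = ("sympatric", "non-sympatric")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class SisterPair:
    species_a: str
    species_b: str
    status: str  # sympatric | non-sympatric
    widths_a: tuple[float, ...]
    widths_b: tuple[float, ...]
    sum_branch_lengths: float  # v_a + v_b = 2 x MRCA age on an ultrametric tree

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.widths_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.widths_b))

    @property
    def signed_contrast(self) -> float:
        """(mean_a - mean_b) / sqrt(v_a + v_b), first-listed species first."""
        return (self.mean_a - self.mean_b) / np.sqrt(self.sum_branch_lengths)

    @property
    def abs_contrast(self) -> float:
        return abs(self.signed_contrast)

    @property
    def ratio(self) -> float:
        """Mean width of the larger species over the smaller; always >= 1."""
        a, b = self.mean_a, self.mean_b
        return max(a, b) / min(a, b)


@dataclass(frozen=True)
class RatioComparison:
    mean_ratio_sympatric: float
    mean_ratio_non_sympatric: float
    test: TTestResult


@dataclass(frozen=True)
class AncovaResult:
    F: float
    p_model: float
    adj_r2: float
    slope_sympatric: float
    slope_nonsympatric: float
    p_interaction: float
    p_slope_sym: float
    p_slope_nonsym: float
    intercept_p: float
    contrast_mean: float  # one-sample test of signed contrasts against 0
    contrast_p: float


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Welch t-test from summary statistics (means, SDs, sample sizes)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("summary t-test needs n >= 2 in each group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both variances are zero")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def wilcoxon_rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p for combined n <= 30 without ties; otherwise the normal
    approximation with continuity and tie correction. Returns the rank-sum
    statistic W of the first sample (midranks for ties) and the p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    method = "exact" if (n1 + n2 <= 30 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    W = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U -> rank sum of sample a
    return W, float(res.pvalue)


def read_pair_table(path) -> pd.DataFrame:
    """Read "species_a,species_b,status" (status: sympatric|non-sympatric)."""
    df = pd.read_csv(path)
    expected = ["species_a", "species_b", "status"]
    if list(df.columns) != expected:
        raise ValueError(f"pair table must have columns {expected}, got {list(df.columns)}")
    bad = set(df["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown sympatry status values: {sorted(bad)}")
    return df


def build_sister_pairs(
    pair_table: pd.DataFrame,
    records: Sequence[OccurrenceRecord],
    tree: DatedTree,
) -> list[SisterPair]:
    """Join the pair table with measured widths and tree branch lengths.

    Widths come from records carrying a measurement; branch lengths from the
    pruned two-species subtree (sum of the two pendant branches).
    """
    widths: dict[str, list[float]] = {}
    for r in records:
        if r.width_mm is not None:
            widths.setdefault(r.species, []).append(r.width_mm)
    pairs = []
    cherry_age = {}
    for a, b, age in tree.cherries():
        cherry_age[frozenset((a, b))] = age
    tips = set(tree.tip_names)
    for row in pair_table.itertuples(index=False):
        for sp in (row.species_a, row.species_b):
            if sp not in widths:
                raise ValueError(f"no measured widths for species {sp!r}")
        key = frozenset((row.species_a, row.species_b))
        if key <= tips:
            sub = tree.prune_to(key)
            sbl = sum(lf.edge.length for lf in sub.tree.leaf_node_iter())
        elif key in cherry_age:
            sbl = 2.0 * cherry_age[key]
        else:
            raise ValueError(f"pair {sorted(key)} not resolvable on the tree")
        pairs.append(SisterPair(
            species_a=row.species_a, species_b=row.species_b, status=row.status,
            widths_a=tuple(widths[row.species_a]), widths_b=tuple(widths[row.species_b]),
            sum_branch_lengths=float(sbl),
        ))
    return pairs


def _is_normalish(widths: Sequence[float], alpha: float) -> bool:
    """Normality screen: D'Agostino skewness test (True = no evidence against)."""
    w = np.asarray(widths, dtype=float)
    if w.size <= 8 or np.ptp(w) == 0:
        return True  # too few values to screen; fall through to the t-test
    return dagostino_skew_test(w).p >= alpha


def pair_test_battery(pairs: Sequence[SisterPair], alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair divergence tests with a Bonferroni threshold alpha / n_pairs.

    Each species is screened for normality (D'Agostino skewness at the same
    alpha); the pair gets a Welch t-test when both pass and a two-sample
    Wilcoxon otherwise. The ``significant`` flag compares the test p against
    alpha / n_pairs.
    """
    m = len(pairs)
    if m == 0:
        raise ValueError("no pairs supplied")
    threshold = alpha / m
    rows = []
    for p in pairs:
        normal_a = _is_normalish(p.widths_a, alpha)
        normal_b = _is_normalish(p.widths_b, alpha)
        if normal_a and normal_b:
            res = welch_t(p.widths_a, p.widths_b)
            test, statistic, pval = "welch_t", res.t, res.p
        else:
            statistic, pval = wilcoxon_rank_sum(p.widths_a, p.widths_b)
            test = "wilcoxon"
        rows.append({
            "species_a": p.species_a, "species_b": p.species_b, "status": p.status,
            "mean_a": p.mean_a, "mean_b": p.mean_b, "ratio": p.ratio,
            "normal_a": normal_a, "normal_b": normal_b,
            "test": test, "statistic": statistic, "p": pval,
            "threshold": threshold, "significant": pval < threshold,
        })
    return pd.DataFrame(rows)


def ratio_comparison(pairs: Sequence[SisterPair], equal_var: bool = True) -> RatioComparison:
    """Compare larger/smaller size ratios between sympatry classes.

    Pooled-variance (Student) t by default, so df = n_pairs - 2; Welch
    available via ``equal_var=False``.
    """
    sym = [p.ratio for p in pairs if p.status == "sympatric"]
    non = [p.ratio for p in pairs if p.status == "non-sympatric"]
    if len(sym) < 2 or len(non) < 2:
        raise ValueError("need at least two pairs in each sympatry class")
    res = stats.ttest_ind(sym, non, equal_var=equal_var)
    df = len(sym) + len(non) - 2 if equal_var else float(res.df)
    return RatioComparison(
        mean_ratio_sympatric=float(np.mean(sym)),
        mean_ratio_non_sympatric=float(np.mean(non)),
        test=TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue)),
    )


def contrasts_vs_time_ancova(pairs: Sequence[SisterPair]) -> AncovaResult:
    """OLS of |C| on divergence time, sympatry status and their interaction.

    Also runs the one-sample t-test of the signed contrasts against zero (a
    directional-bias check; contrasts sign convention is first-listed minus
    second-listed species, pair order fixed by the input table).
    """
    statuses = {p.status for p in pairs}
    if statuses != set(STATUSES):
        raise ValueError("ANCOVA needs both sympatric and non-sympatric pairs")
    y = np.array([p.abs_contrast for p in pairs])
    t = np.array([p.sum_branch_lengths for p in pairs])
    sym = np.array([1.0 if p.status == "sympatric" else 0.0 for p in pairs])
    X = sm.add_constant(np.column_stack([t, sym, t * sym]))  # const, time, sym, time:sym
    fit = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    slope_non = fit.params[1]
    slope_sym = fit.params[1] + fit.params[3]
    # p-value of the sympatric slope: t-test on the linear combination b1 + b3
    comb = fit.t_test(np.array([[0.0, 1.0, 0.0, 1.0]]))
    signed = np.array([p.signed_contrast for p in pairs])
    one = stats.ttest_1samp(signed, 0.0)
    return AncovaResult(
        F=float(fit.fvalue), p_model=float(fit.f_pvalue), adj_r2=float(fit.rsquared_adj),
        slope_sympatric=float(slope_sym), slope_nonsympatric=float(slope_non),
        p_interaction=float(fit.pvalues[3]),
        p_slope_sym=float(np.squeeze(comb.pvalue)), p_slope_nonsym=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
        contrast_mean=float(signed.mean()), contrast_p=float(one.pvalue),
    )
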