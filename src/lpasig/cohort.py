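"""Clinical-arm statistics.

Given a cohort of tumor samples with two housekeeping-normalized markers —
the receptor transcript and the candidate biomarker — this module
stratifies the cohort into equal-frequency quartiles of the receptor,
compares the biomarker across quartiles with a tie-corrected
Kruskal-Wallis test followed by Dunn's pairwise post-test, and reports the
tie-corrected Spearman correlation between the two markers.

All tests here are rank-based, so every output is invariant to strictly
increasing transforms of the marker values.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX_DEFAULT = 9


@dataclass
class QuartileAssignment:
    """Rank-based equal-frequency split of a cohort.

    ``labels`` maps each sample to Q1..Qk (Q1 lowest values). With
    ``n = k*q + r`` the r extra samples go to the lowest-labeled groups, so
    group sizes never differ by more than one. Ties are broken by stable
    input order, which makes group sizes reproducible but means a tied
    value can span a boundary (flagged in ``tie_spanning_boundaries``).
    """

    labels: pd.Series
    group_sizes: dict[str, int]
    boundaries: dict[str, tuple[float, float]]  # label -> (min, max) value
    tie_spanning_boundaries: bool = False

    def groups(self, values: pd.Series) -> dict[str, np.ndarray]:
        return {q: values[self.labels == q].to_numpy()
                for q in self.group_sizes}


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus result with Dunn pairwise post-tests."""

    h_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_1, group_2, z, p_unadjusted, p_adjusted
    adjustment: str
    group_sizes: dict[str, int]

    def pair(self, a: str, b: str) -> pd.Series:
        pw = self.pairwise
        m = ((pw.group_1 == a) & (pw.group_2 == b)) | \
            ((pw.group_1 == b) & (pw.group_2 == a))
        return pw[m].iloc[0]


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    method: str  # "t-approximation" | "exact-permutation"


@dataclass
class CohortValidationReport:
    quartiles: QuartileAssignment
    quartile_summary: pd.DataFrame  # per quartile: n, mean, sd, median
    comparison: GroupComparison
    vs_top_quartile: pd.DataFrame  # Dunn rows of each Q against the top Q
    correlation: CorrelationResult
    linear_fit: dict = field(default_factory=dict)  # slope/intercept, no test


def normalize_to_housekeeping(target: pd.Series | np.ndarray,
                              housekeeping: pd.Series | np.ndarray):
    """Elementwise target/housekeeping expression ratio.

    A non-positive housekeeping value makes the ratio meaningless; the
    error names the offending sample(s).
    """
    t = pd.Series(target).astype(float)
    h = pd.Series(housekeeping).astype(float)
    if len(t) != len(h):
        raise ValueError("target and housekeeping vectors differ in length")
    h.index = t.index
    bad = h.index[h <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive housekeeping value at sample(s) {bad}")
    return t / h


def quartile_stratify(values: pd.Series | np.ndarray, k: int = 4
                      ) -> QuartileAssignment:
    """Split a cohort into k equal-frequency groups by one marker."""
    v = pd.Series(values).astype(float)
    n = len(v)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    order = np.argsort(v.to_numpy(), kind="stable")
    base, r = divmod(n, k)
    sizes = [base + 1 if i < r else base for i in range(k)]
    labels = np.empty(n, dtype=object)
    boundaries: dict[str, tuple[float, float]] = {}
    start = 0
    tie_spans = False
    sorted_vals = v.to_numpy()[order]
    for i, size in enumerate(sizes):
        q = f"Q{i + 1}"
        labels[order[start:start + size]] = q
        boundaries[q] = (float(sorted_vals[start]),
                         float(sorted_vals[start + size - 1]))
        if start > 0 and sorted_vals[start] == sorted_vals[start - 1]:
            tie_spans = True
        start += size
    if tie_spans:
        warnings.warn("tied marker values span a quartile boundary; group "
                      "membership there follows stable input order",
                      stacklevel=2)
    return QuartileAssignment(
        labels=pd.Series(labels, index=v.index, name="quartile"),
        group_sizes={f"Q{i + 1}": s for i, s in enumerate(sizes)},
        boundaries=boundaries, tie_spanning_boundaries=tie_spans)


def kruskal_wallis_dunn(groups: dict[str, np.ndarray] | list[np.ndarray],
                        adjust: str = "bonferroni") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post-test.

    Dunn's z for groups i, j uses the pooled mid-ranks over all groups:

        z = (mean_rank_i - mean_rank_j) /
            sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1))  over tie groups of size t.

    Pairwise p-values are two-sided normal and Bonferroni-adjusted across
    all k(k-1)/2 pairs by default (``adjust="none"`` disables adjustment).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        names = [f"group{i + 1}" for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, data):
        if g.size == 0:
            raise ValueError(f"group {name!r} is empty")
    sizes = np.array([g.size for g in data])
    pooled = np.concatenate(data)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least three observations in total")

    if np.ptp(pooled) == 0:
        h, omnibus_p = 0.0, 1.0
    else:
        h, omnibus_p = stats.kruskal(*data)

    ranks = stats.rankdata(pooled)
    bounds = np.cumsum(sizes)
    mean_ranks = [ranks[s - n:s].mean() for s, n in zip(bounds, sizes)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
                if n_total > 1 else 0.0)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:  # all observations tied
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    pw = pd.DataFrame(rows, columns=["group_1", "group_2", "z", "p_unadjusted"])
    n_pairs = len(pw)
    if adjust == "bonferroni":
        pw["p_adjusted"] = np.minimum(pw["p_unadjusted"] * n_pairs, 1.0)
    elif adjust == "none":
        pw["p_adjusted"] = pw["p_unadjusted"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pw["p_adjusted"] = pw["p_adjusted"].clip(lower=np.nextafter(0, 1))
    return GroupComparison(h_statistic=float(h), omnibus_p=float(omnibus_p),
                           pairwise=pw, adjustment=adjust,
                           group_sizes=dict(zip(names, sizes.tolist())))


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_correlation(x, y, exact_n_max: int = EXACT_N_MAX_DEFAULT
                         ) -> CorrelationResult:
    """Tie-corrected Spearman rho with a two-sided p-value.

    For n <= ``exact_n_max`` the p-value is exact: the fraction of all n!
    permutations of y whose |rho| reaches the observed |rho|. Beyond that
    the usual t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees
    of freedom is used (the cohort-scale regime).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = _spearman_rho(x, y)

    if n <= exact_n_max:
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_spearman_rho(x, np.array(perm))) >= obs - 1e-12:
                count += 1
        return CorrelationResult(rho=rho, n=n, p=count / total,
                                 method="exact-permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho=rho, n=n, p=float(p),
                             method="t-approximation")


def run_cohort_validation(cohort: pd.DataFrame, k: int = 4,
                          adjust: str = "bonferroni") -> CohortValidationReport:
    """Full clinical-arm analysis of a two-marker cohort table.

    Stratifies by ``marker_a`` (the receptor), summarises and compares
    ``marker_b`` (the biomarker) across the quartiles with KW + Dunn, and
    computes Spearman(marker_a, marker_b). Mean/SD summaries and the
    rank tests are both emitted; an ordinary least-squares slope/intercept
    is included without any test.
    """
    for col in ("marker_a", "marker_b"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    a = cohort["marker_a"].astype(float)
    b = cohort["marker_b"].astype(float)
    quart = quartile_stratify(a, k=k)
    groups = quart.groups(b)
    summary = pd.DataFrame({
        q: {"n": len(vals), "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            "median": float(np.median(vals))}
        for q, vals in groups.items()
    }).T
    summary.index.name = "quartile"
    comparison = kruskal_wallis_dunn(groups, adjust=adjust)
    top = f"Q{k}"
    pw = comparison.pairwise
    vs_top = pw[(pw.group_1 == top) | (pw.group_2 == top)].reset_index(drop=True)
    corr = spearman_correlation(a.to_numpy(), b.to_numpy())
    slope, intercept = np.polyfit(a.to_numpy(), b.to_numpy(), 1)
    return CohortValidationReport(
        quartiles=quart, quartile_summary=summary, comparison=comparison,
        vs_top_quartile=vs_top, correlation=corr,
        linear_fit={"slope": float(slope), "intercept": float(intercept)})
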