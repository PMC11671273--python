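"""Nonparametric statistics battery for across-session comparisons.

Independent groups (e.g. the three hotspots' dominant frequencies across
sessions) are compared with a Kruskal-Wallis omnibus test; when it is
significant at p < 0.05, Dunn's rank-based pairwise tests identify the
distinct pairs, and for those a one-sided Wilcoxon rank-sum test provides
the reported statistic (direction from the group medians).  Paired data
(per-session condition triplets) use a Friedman omnibus followed by
two-sided Wilcoxon signed-rank tests with Tukey-Kramer (studentized
range) or Bonferroni p-value correction.  Data from two animals are
pooled only when a rank-sum test cannot distinguish them (p > 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "StatsResult",
    "dunn_test",
    "compare_independent_groups",
    "compare_paired_conditions",
    "check_poolability",
    "correlate_session_values",
]

ALPHA = 0.05


@dataclass
class StatsResult:
    """Omnibus test plus an optional post-hoc table."""

    test: str
    statistic: float
    df: int | None
    p: float
    n_per_group: dict[str, int]
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _rank_all(groups: dict[str, np.ndarray]):
    pooled = np.concatenate(list(groups.values()))
    ranks = sst.rankdata(pooled)
    out, i = {}, 0
    for name, g in groups.items():
        out[name] = ranks[i:i + len(g)]
        i += len(g)
    return out, pooled.size, pooled


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank tests (tie-corrected z statistics).

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with T the tie correction sum(t^3 - t) / (12 (N - 1)).  p-values are
    two-sided normal tails without further correction (the gate to the
    subsequent rank-sum stage is at alpha = 0.05).
    """
    ranked, n_total, pooled = _rank_all(groups)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(groups.keys(), 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (ranked[a].mean() - ranked[b].mean()) / se if se > 0 else 0.0
        p = 2.0 * sst.norm.sf(abs(z))
        rows.append({"pair": f"{a}/{b}", "z": z, "p": p,
                     "significant": p < ALPHA})
    return pd.DataFrame(rows)


def compare_independent_groups(groups: dict[str, np.ndarray],
                               alpha: float = ALPHA) -> StatsResult:
    """Kruskal-Wallis omnibus with Dunn's + one-sided rank-sum post-hocs.

    The rank-sum stage runs only for Dunn-significant pairs; its
    one-sided direction is taken from the group medians.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise ValueError("need at least 2 groups with n >= 2 each")
    n_per = {k: len(v) for k, v in groups.items()}
    if len(groups) == 2:
        a, b = groups.values()
        stat, p = sst.ranksums(a, b)
        return StatsResult(test="wilcoxon_ranksum", statistic=float(stat),
                           df=None, p=float(p), n_per_group=n_per)
    vals = list(groups.values())
    if all(np.array_equal(vals[0], v) for v in vals[1:]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sst.kruskal(*vals)
    posthoc = None
    if p < alpha:
        posthoc = dunn_test(groups)
        zs, ps = [], []
        for _, row in posthoc.iterrows():
            if not row["significant"]:
                zs.append(np.nan)
                ps.append(np.nan)
                continue
            a, b = row["pair"].split("/")
            side = ("greater" if np.median(groups[a]) > np.median(groups[b])
                    else "less")
            res = sst.mannwhitneyu(groups[a], groups[b], alternative=side,
                                   method="asymptotic")
            # report the standardized rank-sum z for the chosen direction
            z = sst.norm.isf(res.pvalue)
            zs.append(float(z))
            ps.append(float(res.pvalue))
        posthoc["ranksum_z"] = zs
        posthoc["ranksum_p_one_sided"] = ps
    df = len(groups) - 1
    return StatsResult(test="kruskal_wallis", statistic=float(stat), df=df,
                       p=float(p), n_per_group=n_per, posthoc=posthoc)


def _tukey_kramer_p(z: float, k: int) -> float:
    """Studentized-range correction of a pairwise z among k groups."""
    return float(np.clip(sst.studentized_range.sf(abs(z) * np.sqrt(2.0),
                                                  k, np.inf), 0.0, 1.0))


def compare_paired_conditions(data: np.ndarray,
                              condition_names: list[str] | None = None,
                              correction: str = "tukey-kramer",
                              alpha: float = ALPHA) -> StatsResult:
    """Friedman omnibus + two-sided signed-rank post-hocs (complete cases).

    ``data`` is subjects x conditions.  ``correction`` is
    ``"tukey-kramer"`` (studentized range on the signed-rank z),
    ``"bonferroni"``, or ``"none"``; corrected p-values never fall below
    the raw p.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be subjects x (>=2) conditions")
    if np.isnan(data).any():
        raise ValueError("complete cases only")
    k = data.shape[1]
    names = condition_names or [f"cond{i}" for i in range(k)]
    cols = [data[:, i] for i in range(k)]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        stat, p = 0.0, 1.0
    elif k == 2:
        # Friedman needs >= 3 conditions; two conditions reduce to the
        # signed-rank test directly
        res = sst.wilcoxon(cols[0], cols[1], alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = sst.friedmanchisquare(*cols)
    posthoc = None
    if p < alpha:
        rows = []
        n_pairs = k * (k - 1) // 2
        for i, j in combinations(range(k), 2):
            diff = data[:, i] - data[:, j]
            if np.all(diff == 0):
                w_p, z = 1.0, 0.0
            else:
                res = sst.wilcoxon(data[:, i], data[:, j],
                                   alternative="two-sided",
                                   method="auto")
                w_p = float(res.pvalue)
                z = float(sst.norm.isf(w_p / 2.0) * np.sign(np.median(diff)))
            if correction == "bonferroni":
                p_corr = min(1.0, w_p * n_pairs)
            elif correction == "tukey-kramer":
                p_corr = max(w_p, _tukey_kramer_p(z, k))
            elif correction == "none":
                p_corr = w_p
            else:
                raise ValueError(f"unknown correction {correction!r}")
            rows.append({"pair": f"{names[i]}/{names[j]}", "z": z,
                         "p_raw": w_p, "p_corrected": p_corr,
                         "correction": correction,
                         "significant": p_corr < alpha})
        posthoc = pd.DataFrame(rows)
    return StatsResult(test="friedman", statistic=float(stat), df=k - 1,
                       p=float(p),
                       n_per_group={n: data.shape[0] for n in names},
                       posthoc=posthoc)


def check_poolability(group_a: np.ndarray, group_b: np.ndarray,
                      alpha: float = ALPHA) -> tuple[bool, StatsResult]:
    """Rank-sum check that two animals' data may be pooled (p > alpha)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = sst.ranksums(a, b)
    result = StatsResult(test="wilcoxon_ranksum", statistic=float(stat),
                         df=None, p=float(p),
                         n_per_group={"a": a.size, "b": b.size})
    return bool(p > alpha), result


def correlate_session_values(x: np.ndarray, y: np.ndarray,
                             n_comparisons: int = 3,
                             ) -> tuple[float, float, float]:
    """Pearson correlation with Bonferroni correction over domain pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p), float(min(1.0, p * n_comparisons))
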