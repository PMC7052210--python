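"""Nonparametric group statistics and report writing.

The study's comparisons are all rank-based: Mann-Whitney for two groups,
Kruskal-Wallis for several, Spearman rank correlation for ordinal pairs
(fibrosis stage vs hypertrophy score), with medians and interquartile
ranges as the group summaries.  Exact (permutation / enumeration) p-values
are used at small sample sizes and tie-corrected asymptotic approximations
otherwise; the convention actually used is labeled in the output, since the
original point-and-click analyses do not state theirs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.stats import rankdata

__all__ = [
    "GroupedSeries",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "summarize",
    "significance_stars",
    "write_report",
]

#: Largest n for which the exact permutation Spearman p is enumerated.
SPEARMAN_EXACT_MAX_N = 9
#: Largest pooled n for which the exact Mann-Whitney p is enumerated.
MANN_WHITNEY_EXACT_MAX_N = 12


@dataclass
class GroupedSeries:
    """A numeric vector with a group label per element."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels lengths differ")
        if self.values.size == 0:
            raise ValueError("need at least one observation")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value_col: str = "value", group_col: str = "group"
    ) -> "GroupedSeries":
        return cls(df[value_col].to_numpy(), df[group_col].to_numpy())

    def groups(self) -> dict:
        """Mapping of group label to its value array, in first-seen order."""
        out: dict = {}
        for lab in pd.unique(self.labels):
            out[lab] = self.values[self.labels == lab]
        return out


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman(x, y, method: str = "auto") -> dict:
    """Spearman rank correlation with tie handling by average ranks.

    r is the Pearson correlation of midranks.  The two-sided p-value is
    exact (full permutation enumeration) for n <= 9 under ``method="auto"``
    or ``"exact"``, otherwise from the t approximation
    t = r sqrt((n-2)/(1-r²)) on n-2 degrees of freedom.

    Returns ``{"r", "p", "n", "method"}``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman r undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    r = _rank_correlation(rx, ry)
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    exact = method == "exact" or (method == "auto" and n <= SPEARMAN_EXACT_MAX_N)
    if exact:
        obs = abs(r) - 1e-12
        hits = 0
        total = factorial(n)
        for perm in itertools.permutations(ry):
            if abs(_rank_correlation(rx, np.asarray(perm))) >= obs:
                hits += 1
        p = hits / total
        used = "exact-permutation"
    else:
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = float(2 * _sps.t.sf(abs(t), df=n - 2))
        p = min(p, 1.0)
        used = "t-approximation"
    return {"r": r, "p": p, "n": n, "method": used}


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: wins over b, ties counting one half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b, method: str = "auto") -> dict:
    """Two-sided Mann-Whitney test; U is the smaller of the two U statistics.

    Exact p by enumeration of all group assignments of the pooled values
    when n_a + n_b <= 12 (valid with ties), otherwise the tie-corrected
    normal approximation without continuity correction.

    Returns ``{"U", "p", "n_a", "n_b", "method"}``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    ua = _u_statistic(a, b)
    u = min(ua, na * nb - ua)
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    exact = method == "exact" or (
        method == "auto" and na + nb <= MANN_WHITNEY_EXACT_MAX_N
    )
    if exact:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        hits = 0
        total = comb(na + nb, na)
        obs = u + 1e-9
        for pick in itertools.combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(pick)] = True
            ua_p = _u_statistic(pooled[mask], pooled[~mask])
            if min(ua_p, na * nb - ua_p) <= obs:
                hits += 1
        p = hits / total
        used = "exact-enumeration"
    else:
        pooled = np.concatenate([a, b])
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (ua - na * nb / 2.0) / np.sqrt(var)
            p = float(2 * _sps.norm.sf(abs(z)))
        used = "normal-approximation"
    return {"U": u, "p": min(p, 1.0), "n_a": na, "n_b": nb, "method": used}


def kruskal_wallis(groups) -> dict:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value.

    ``groups`` is a :class:`GroupedSeries` or a sequence of arrays.  When
    every pooled value is identical the statistic degenerates (tie
    correction divides by zero); H = 0 is returned with ``degenerate=True``.

    Returns ``{"H", "p", "df", "n", "degenerate"}``.
    """
    if isinstance(groups, GroupedSeries):
        arrays = list(groups.groups().values())
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    grand = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - grand) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    df = len(arrays) - 1
    if correction == 0:
        return {"H": 0.0, "p": 1.0, "df": df, "n": n, "degenerate": True}
    h /= correction
    p = float(_sps.chi2.sf(h, df))
    return {"H": float(h), "p": p, "df": df, "n": n, "degenerate": False}


def summarize(groups) -> pd.DataFrame:
    """Median and interquartile range per group.

    Quartiles use the linear-interpolation convention (stated in the output
    because IQR values depend on it).
    """
    if not isinstance(groups, GroupedSeries):
        raise TypeError("summarize expects a GroupedSeries")
    rows = []
    for lab, vals in groups.groups().items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": lab,
                "n": vals.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "quantile_convention": "linear-interpolation",
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.005, **** p<0.0005."""
    if p < 0.0005:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def write_report(results: list[dict], path, title: str = "Statistics report") -> None:
    """Write a markdown report from a list of test-result dicts.

    Each dict needs ``name`` (test label) and ``p``; remaining keys are
    rendered as detail columns.  Stars follow :func:`significance_stars`.
    """
    lines = [f"# {title}", ""]
    lines.append("| test | details | p | stars |")
    lines.append("|---|---|---|---|")
    for res in results:
        name = res.get("name", "test")
        p = res["p"]
        detail = ", ".join(
            f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in res.items()
            if k not in ("name", "p")
        )
        lines.append(
            f"| {name} | {detail} | {p:.4g} | {significance_stars(p)} |"
        )
    lines += [
        "",
        "Stars: *p < 0.05; **p < 0.01; ***p < 0.005; ****p < 0.0005.",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
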