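"""Group-comparison statistics: one-way ANOVA, Tukey's HSD, summaries.

These are the tests applied to the per-cell (or per-mouse) regional
measurement sets throughout the pipeline: one-way ANOVA with Tukey's
multiple-comparison test, and mean ± s.e.m. / five-number box summaries.
Unbalanced groups use the Tukey–Kramer form of the studentized-range
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "AnovaResult",
    "TukeyResult",
    "one_way_anova",
    "tukey_hsd",
    "summarize",
]

GroupData = dict[str, "np.ndarray | list[float]"]


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b
    q_statistic: float
    p_adjusted: float


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]

    def p_for(self, a: str, b: str) -> float:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p.p_adjusted
        raise KeyError(f"no pair ({a}, {b})")


def _validate(data: GroupData, min_n: int = 2) -> dict[str, np.ndarray]:
    if len(data) < 2:
        raise ValueError("need at least two groups")
    clean = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) < min_n:
            raise ValueError(f"group {name!r} needs at least {min_n} values")
        clean[name] = arr
    return clean


def _sums_of_squares(groups: dict[str, np.ndarray]) -> tuple[float, float, int, int]:
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    return float(ss_between), float(ss_within), df_between, df_within


def one_way_anova(data: GroupData) -> AnovaResult:
    """F = (SS_between/df_between) / (SS_within/df_within), upper-tail p.

    With two groups this reduces exactly to the square of the pooled-variance
    t statistic.
    """
    groups = _validate(data)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(groups)
    if ss_w == 0 and ss_b == 0:
        raise ValueError("ANOVA undefined: zero between- and within-group variance")
    if ss_w == 0:
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def tukey_hsd(data: GroupData) -> TukeyResult:
    """All-pairs Tukey–Kramer test on the ANOVA within-group mean square.

    q_ij = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)); the
    adjusted p is the upper tail of the studentized-range distribution with
    k groups and the ANOVA within degrees of freedom.
    """
    groups = _validate(data)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(groups)
    if ss_w == 0 and ss_b == 0:
        raise ValueError("Tukey undefined: zero between- and within-group variance")
    ms_w = ss_w / df_w
    k = len(groups)
    names = list(groups)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = float(a.mean() - b.mean())
            if ms_w == 0:
                q = float("inf") if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append(TukeyPair(names[i], names[j], diff, float(q), min(p, 1.0)))
    return TukeyResult(pairs=pairs)


def summarize(data: GroupData) -> dict[str, dict[str, float]]:
    """Per-group mean, s.e.m., n and box-plot five-number summary.

    s.e.m. uses the n-1 sample standard deviation; quartiles use linear
    interpolation; a single-value group reports s.e.m. as NaN (missing).
    """
    out = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) < 1:
            raise ValueError(f"group {name!r} must have at least one value")
        n = len(arr)
        sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
        out[name] = {
            "n": float(n),
            "mean": float(arr.mean()),
            "sem": sem,
            "min": float(arr.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(arr.max()),
        }
    return out
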