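"""Group statistics for metabolite tables.

One-way ANOVA per analyte across sample groups, Benjamini-Hochberg
false-discovery-rate correction across analytes, and Tukey HSD (Tukey-
Kramer for unequal group sizes) post-hoc pairwise comparisons within each
analyte. Adjusted Tukey p-values come from the studentized range
distribution (`scipy.stats.studentized_range`).

Degenerate inputs are handled explicitly: with no variance at all the
ANOVA F is defined as 0 (p = 1); with zero within-group variance but
real between-group differences p is reported as 0 and the result carries a
``degenerate`` flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "bh_adjust",
    "tukey_hsd",
    "analyte_anova_table",
]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in out):
        raise ValueError("each group needs at least 2 replicates")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Standard between/within variance decomposition.

    ``groups`` is a sequence (or mapping) of replicate arrays, one per
    group. Returns the F statistic, its upper-tail p-value and both degrees
    of freedom.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, degenerate=True)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def tukey_hsd(
    groups,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD / Tukey-Kramer comparisons.

    For groups i, j the studentized range statistic is
    ``q = |mean_i - mean_j| / sqrt(MSW * (1/n_i + 1/n_j) / 2)`` with MSW the
    within-group mean square; adjusted p-values come from the studentized
    range distribution with k groups and the within degrees of freedom.

    Returns a DataFrame with one row per pair: group_a, group_b,
    difference (mean_a - mean_b), q_statistic, p_adjusted, significant.
    With MSW = 0 the rows carry ``degenerate = True`` and no p-value.
    """
    gs = _as_groups(groups)
    if isinstance(groups, Mapping) and labels is None:
        labels = list(groups.keys())
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels length must match number of groups")
    k = len(gs)
    n = sum(len(g) for g in gs)
    df_w = n - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = gs[i].mean() - gs[j].mean()
        if msw == 0:
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "difference": diff,
                 "q_statistic": float("nan"), "p_adjusted": float("nan"),
                 "significant": False, "degenerate": True}
            )
            continue
        se = np.sqrt(msw * (1 / len(gs[i]) + 1 / len(gs[j])) / 2)
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "difference": diff,
             "q_statistic": float(q), "p_adjusted": min(p, 1.0),
             "significant": p <= alpha, "degenerate": False}
        )
    return pd.DataFrame(rows)


def analyte_anova_table(
    table: pd.DataFrame,
    analyte_col: str = "analyte",
    group_col: str = "group",
    value_col: str = "value",
    adjust_tukey: bool = False,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-analyte ANOVA with cross-analyte BH correction, plus Tukey tables.

    ``table`` is long format (analyte, group, value). BH runs across all
    analytes' ANOVA p-values; Tukey comparisons are computed per analyte and
    are, by default, not further corrected across analytes
    (``adjust_tukey`` switches a cross-analyte BH on the pairwise p-values).
    """
    anova_rows = []
    tukey_frames = []
    for analyte, sub in table.groupby(analyte_col, sort=True):
        grouped = {g: s[value_col].to_numpy() for g, s in sub.groupby(group_col, sort=True)}
        res = one_way_anova(grouped)
        anova_rows.append(
            {"analyte": analyte, "F": res.f_statistic, "p_value": res.p_value,
             "df_between": res.df_between, "df_within": res.df_within,
             "degenerate": res.degenerate}
        )
        tk = tukey_hsd(grouped, alpha=alpha)
        tk.insert(0, "analyte", analyte)
        tukey_frames.append(tk)
    anova = pd.DataFrame(anova_rows)
    anova["q_value"] = bh_adjust(anova["p_value"].to_numpy())
    tukey = pd.concat(tukey_frames, ignore_index=True)
    if adjust_tukey:
        ok = ~tukey["degenerate"]
        adj = tukey["p_adjusted"].copy()
        adj[ok] = bh_adjust(tukey.loc[ok, "p_adjusted"].to_numpy())
        tukey["p_adjusted_bh"] = adj
        tukey["significant"] = adj <= alpha
    return anova, tukey
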