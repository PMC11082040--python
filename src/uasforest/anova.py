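"""One-way ANOVA with Bonferroni adjustment for stem-map vs UAS comparisons.

Each structure metric (clump counts, basal-area share, height CV, crown
area, opening proportions) is compared between the two data sources with a
classical one-way F test, one test per size class or distance band, and the
p-values are Bonferroni-adjusted by the number of class-level comparisons
within the metric family (capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from uasforest.data import ParameterError

__all__ = [
    "AnovaResult",
    "DEFAULT_K_MAP",
    "one_way_anova",
    "bonferroni_adjust",
    "compare_structure_metrics",
]

#: comparisons per metric family: 5 classes everywhere except height CV,
#: which has no singleton class (CV undefined for one tree)
DEFAULT_K_MAP = {
    "n_clumps": 5,
    "ba_pct": 5,
    "height_cv_pct": 4,
    "crown_area_m2": 5,
    "opening_pct": 5,
}


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    n: int


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA F test from values and group labels."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape or v.ndim != 1:
        raise ParameterError("values and groups must be 1-D and aligned")
    labels = pd.unique(g)
    k = len(labels)
    n = len(v)
    if k < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    if n <= k:
        raise ParameterError("ANOVA needs more observations than groups")
    grand = v.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        gv = v[g == lab]
        ss_between += len(gv) * (gv.mean() - grand) ** 2
        ss_within += ((gv - gv.mean()) ** 2).sum()
    df_b = k - 1
    df_w = n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            f = 0.0
            p = 1.0
        else:
            warnings.warn("zero within-group variance with unequal means; p = 0")
            f = np.inf
            p = 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f_stat=float(f), p_value=p, df_between=df_b, df_within=df_w, n=n)


def bonferroni_adjust(p: float, k: int) -> float:
    """Bonferroni-adjusted p-value min(1, k * p)."""
    if not 0 <= p <= 1:
        raise ParameterError("p must be in [0, 1]")
    if k < 1:
        raise ParameterError("k must be >= 1")
    return min(1.0, k * p)


def compare_structure_metrics(
    stem_metrics: pd.DataFrame,
    uas_metrics: pd.DataFrame,
    k_map: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Stem-map vs UAS ANOVA table over metric x class cells.

    Inputs are long-format frames with columns ``metric``, ``class`` and
    ``value`` (one row per plot or per clump, depending on the metric's
    observation unit).  For every (metric, class) cell present in both
    sources, a one-way ANOVA compares the two; the Bonferroni k is taken from
    ``k_map`` (default :data:`DEFAULT_K_MAP`, falling back to the number of
    classes the metric has in either source).  A cell present in only one
    source is reported with ``comparable=False`` rather than dropped.
    """
    k_map = {**DEFAULT_K_MAP, **(k_map or {})}
    for name, df in (("stem", stem_metrics), ("uas", uas_metrics)):
        missing = {"metric", "class", "value"} - set(df.columns)
        if missing:
            raise ParameterError(f"{name} metrics missing columns {sorted(missing)}")
    rows = []
    metrics = pd.unique(
        pd.concat([stem_metrics["metric"], uas_metrics["metric"]], ignore_index=True)
    )
    for metric in metrics:
        s_m = stem_metrics[stem_metrics["metric"] == metric]
        u_m = uas_metrics[uas_metrics["metric"] == metric]
        classes = pd.unique(pd.concat([s_m["class"], u_m["class"]], ignore_index=True))
        k = k_map.get(metric, len(classes))
        for cls in classes:
            sv = s_m.loc[s_m["class"] == cls, "value"].dropna().to_numpy(float)
            uv = u_m.loc[u_m["class"] == cls, "value"].dropna().to_numpy(float)
            row = {
                "metric": metric,
                "class": cls,
                "n_stem": len(sv),
                "n_uas": len(uv),
                "stem_mean": sv.mean() if len(sv) else np.nan,
                "stem_sd": sv.std(ddof=1) if len(sv) > 1 else np.nan,
                "uas_mean": uv.mean() if len(uv) else np.nan,
                "uas_sd": uv.std(ddof=1) if len(uv) > 1 else np.nan,
                "k": k,
            }
            if len(sv) and len(uv) and len(sv) + len(uv) > 2:
                res = one_way_anova(
                    np.concatenate([sv, uv]),
                    np.array(["stem"] * len(sv) + ["uas"] * len(uv)),
                )
                row.update(
                    comparable=True,
                    f_stat=res.f_stat,
                    p_value=res.p_value,
                    p_adj=bonferroni_adjust(res.p_value, k),
                )
            else:
                row.update(comparable=False, f_stat=np.nan, p_value=np.nan, p_adj=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
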