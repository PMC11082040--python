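"""Tree matching and detection/measurement error assessment.

UAS-detected trees are matched to stem-mapped trees with a greedy rule:
taking UAS trees tallest-first, the unmatched stem-map candidates within
4.0 m are screened for height error under 2.0 m and the candidate with the
smallest height error is paired (ties broken by distance, then field id).
Unmatched UAS trees are false positives; leftover field trees are false
negatives.  Rates and F-scores are summarized over the understory (< 5 m),
intermediate (5-15 m) and overstory (> 15 m) dominance classes, and height /
DBH errors over 5-m height bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from uasforest.data import ParameterError, TreePlot

__all__ = [
    "MatchResult",
    "DetectionRates",
    "DOMINANCE_CLASSES",
    "dominance_class",
    "match_trees",
    "f_score",
    "detection_rates",
    "error_summary",
]

#: dominance-class labels in increasing height order
DOMINANCE_CLASSES = ("understory", "intermediate", "overstory")


def dominance_class(height_m: float) -> str:
    """Height stratum: understory < 5 m, intermediate 5-15 m, overstory > 15 m."""
    if height_m < 5.0:
        return "understory"
    if height_m <= 15.0:
        return "intermediate"
    return "overstory"


@dataclass
class MatchResult:
    """Outcome of greedy UAS-to-field matching."""

    matches: list[tuple[str, str, float, float]] = field(default_factory=list)
    false_positives: list[str] = field(default_factory=list)
    false_negatives: list[str] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


@dataclass
class DetectionRates:
    """Per-dominance-class and overall detection rates and F-scores."""

    per_class: dict[str, dict[str, float]]

    def __getitem__(self, key: str) -> dict[str, float]:
        return self.per_class[key]


def match_trees(
    uas: TreePlot,
    field_plot: TreePlot,
    max_dist_m: float = 4.0,
    max_height_err_m: float = 2.0,
    order: str = "height_desc",
) -> MatchResult:
    """Greedily pair UAS trees with stem-mapped trees.

    Deterministic and invariant to input row order: UAS trees are processed
    in descending height (``order="height_desc"``, the default; ``"id"``
    processes by UAS tree id instead, for order-sensitivity diagnostics).
    """
    if max_dist_m <= 0 or max_height_err_m <= 0:
        raise ParameterError("matching tolerances must be positive")
    uas_trees = sorted(
        uas.trees,
        key=(lambda t: (-t.height_m, t.tree_id))
        if order == "height_desc"
        else (lambda t: t.tree_id),
    )
    field_trees = list(field_plot.trees)
    result = MatchResult()
    if not field_trees:
        result.false_positives = [t.tree_id for t in uas_trees]
        return result
    xy = np.array([(t.x_m, t.y_m) for t in field_trees])
    tree_index = cKDTree(xy)
    unmatched = np.ones(len(field_trees), dtype=bool)
    for u in uas_trees:
        cand = tree_index.query_ball_point([u.x_m, u.y_m], r=max_dist_m)
        best = None  # (|dh|, dist, field_id, idx)
        for i in cand:
            if not unmatched[i]:
                continue
            f = field_trees[i]
            dh = abs(u.height_m - f.height_m)
            if dh >= max_height_err_m:
                continue
            dist = float(np.hypot(u.x_m - f.x_m, u.y_m - f.y_m))
            key = (dh, dist, f.tree_id)
            if best is None or key < best[:3]:
                best = (dh, dist, f.tree_id, i)
        if best is None:
            result.false_positives.append(u.tree_id)
        else:
            dh, dist, fid, i = best
            unmatched[i] = False
            f = field_trees[i]
            result.matches.append((u.tree_id, fid, u.height_m - f.height_m, dist))
    result.false_negatives = [
        field_trees[i].tree_id for i in np.nonzero(unmatched)[0]
    ]
    return result


def f_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of detection precision and recall; 0 when no true positives."""
    if min(tp, fp, fn) < 0:
        raise ParameterError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ParameterError("F-score undefined for all-zero counts")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * (precision * recall) / (precision + recall)


def detection_rates(
    match: MatchResult, uas: TreePlot, field_plot: TreePlot
) -> DetectionRates:
    """TP/FP/FN rates and F-score per dominance class and overall.

    True positives and false negatives are classed by the *field* tree height,
    false positives by the *UAS* height.  An empty class (no trees of either
    kind) is omitted rather than reported as zero.
    """
    field_h = {t.tree_id: t.height_m for t in field_plot.trees}
    uas_h = {t.tree_id: t.height_m for t in uas.trees}
    counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in DOMINANCE_CLASSES}
    for _, fid, _, _ in match.matches:
        counts[dominance_class(field_h[fid])]["tp"] += 1
    for fid in match.false_negatives:
        counts[dominance_class(field_h[fid])]["fn"] += 1
    for uid in match.false_positives:
        counts[dominance_class(uas_h[uid])]["fp"] += 1
    per_class: dict[str, dict[str, float]] = {}
    class_list = list(DOMINANCE_CLASSES) + ["all"]
    totals = {
        "tp": match.tp,
        "fp": match.fp,
        "fn": match.fn,
    }
    for cls in class_list:
        c = totals if cls == "all" else counts[cls]
        tp, fp, fn = c["tp"], c["fp"], c["fn"]
        if tp + fp + fn == 0:
            continue
        entry: dict[str, float] = {"tp": tp, "fp": fp, "fn": fn}
        if tp + fn > 0:
            entry["tp_rate"] = tp / (tp + fn)
            entry["fn_rate"] = fn / (tp + fn)
        if tp + fp > 0:
            entry["fp_rate"] = fp / (tp + fp)
        entry["f_score"] = f_score(tp, fp, fn)
        per_class[cls] = entry
    return DetectionRates(per_class=per_class)


def error_summary(
    match: MatchResult, uas: TreePlot, field_plot: TreePlot
) -> pd.DataFrame:
    """Mean error and RMSE of height and DBH per 5-m field-height class.

    Error convention is UAS minus field.  Bins are [0,5), [5,10), [10,15),
    [15,20), [20,inf) m on the field tree height, plus an "all" row.  DBH
    statistics use only pairs where both sides carry a DBH.
    """
    uas_by_id = {t.tree_id: t for t in uas.trees}
    field_by_id = {t.tree_id: t for t in field_plot.trees}
    rows = []
    for uid, fid, dh, _ in match.matches:
        u, f = uas_by_id[uid], field_by_id[fid]
        ddbh = (
            u.dbh_cm - f.dbh_cm
            if (u.dbh_cm is not None and f.dbh_cm is not None)
            else np.nan
        )
        rows.append({"field_height": f.height_m, "dh": dh, "ddbh": ddbh})
    if not rows:
        return pd.DataFrame(
            columns=["height_class", "n", "height_me_m", "height_rmse_m",
                     "n_dbh", "dbh_me_cm", "dbh_rmse_cm"]
        )
    df = pd.DataFrame(rows)
    edges = [0.0, 5.0, 10.0, 15.0, 20.0, np.inf]
    labels = ["0-5", "5-10", "10-15", "15-20", ">=20"]
    df["height_class"] = pd.cut(
        df["field_height"], bins=edges, labels=labels, right=False
    )
    out = []
    groups = [(lab, sub) for lab, sub in df.groupby("height_class", observed=True)]
    groups.append(("all", df))
    for lab, sub in groups:
        if sub.empty:
            continue
        dbh_err = sub["ddbh"].dropna()
        out.append(
            {
                "height_class": str(lab),
                "n": len(sub),
                "height_me_m": float(sub["dh"].mean()),
                "height_rmse_m": float(np.sqrt((sub["dh"] ** 2).mean())),
                "n_dbh": len(dbh_err),
                "dbh_me_cm": float(dbh_err.mean()) if len(dbh_err) else np.nan,
                "dbh_rmse_cm": float(np.sqrt((dbh_err**2).mean()))
                if len(dbh_err)
                else np.nan,
            }
        )
    return pd.DataFrame(out)
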