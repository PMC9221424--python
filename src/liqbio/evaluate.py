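"""Ground-truth evaluation helpers for synthetic runs.

Detected candidates are matched to planted events by nearest centroid within
a tolerance; the per-class confusion table compares the gated class against
the truth label for matched rare events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import RARE_CLASSES, WBC_LABEL


def match_to_truth(truth: pd.DataFrame, detected: pd.DataFrame,
                   tol_um: float = 4.0) -> pd.DataFrame:
    """Greedy nearest-centroid matching of truth events to detections.

    Both tables need ``frame``, ``x_um``, ``y_um``. Returns the truth table
    with ``matched_event_id`` (detection ``event_id`` or NaN) and, when the
    detection table carries an ``event_class`` column, ``predicted_class``.
    """
    out = truth.copy()
    out["matched_event_id"] = np.nan
    if "event_class" in detected.columns:
        out["predicted_class"] = None
    for f, tsub in truth.groupby("frame"):
        dsub = detected[detected["frame"] == f]
        if dsub.empty:
            continue
        dx = dsub["x_um"].to_numpy()
        dy = dsub["y_um"].to_numpy()
        taken = np.zeros(len(dsub), dtype=bool)
        for ti in tsub.index:
            d2 = (dx - truth.at[ti, "x_um"]) ** 2 + (dy - truth.at[ti, "y_um"]) ** 2
            d2[taken] = np.inf
            j = int(np.argmin(d2))
            if d2[j] <= tol_um**2:
                taken[j] = True
                out.at[ti, "matched_event_id"] = dsub["event_id"].iloc[j]
                if "event_class" in dsub.columns:
                    out.at[ti, "predicted_class"] = dsub["event_class"].iloc[j]
    return out


def rare_confusion(matched: pd.DataFrame) -> pd.DataFrame:
    """Truth-class x predicted-class contingency table over truth-rare events.

    Common WBCs are excluded: their channel signature coincides with the
    CD45/CD31-only rare class, and only the synthetic truth label separates
    the two (in the source assay this separation comes from the upstream
    rarity detection, which is out of scope here).
    """
    rare_names = [c.value for c in RARE_CLASSES]
    sub = matched[matched["true_class"].isin(rare_names)].copy()
    sub["predicted_class"] = sub["predicted_class"].fillna("MISSED")
    table = pd.crosstab(sub["true_class"], sub["predicted_class"])
    return table.reindex(index=[c for c in rare_names if c in table.index])


def confusion_diagonal_fraction(confusion: pd.DataFrame) -> float:
    """Fraction of truth-rare events whose predicted class equals the truth."""
    total = confusion.to_numpy().sum()
    if total == 0:
        return float("nan")
    diag = sum(confusion.at[c, c] for c in confusion.index
               if c in confusion.columns)
    return float(diag) / float(total)


def wbc_detected_count(matched: pd.DataFrame) -> int:
    """Planted common-cell count recovered by detection (the synthetic WBC
    denominator for blood-volume normalization)."""
    wbc = matched[matched["true_class"] == WBC_LABEL]
    return int(wbc["matched_event_id"].notna().sum())
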