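"""Channel positivity calls, the 12-category ontology, and LEV filters.

Each event's four median channel intensities are thresholded into a
:class:`ChannelCall`; the total decision table over the 16 boolean
combinations assigns one of the 8 cellular classes (DAPI-positive), the 4
LEV classes (DAPI-negative, CK-positive) or NOT_RARE. LEVs additionally get a
cell-proximity annotation and a per-frame debris filter: a frame carrying
more than the cap (default 3) is treated as contaminated and contributes no
LEVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CHANNELS,
    CLASS_MARKERS,
    LEV_CLASSES,
    MorphoFeatures,
    RareEventClass,
)

#: Reverse lookup: (dapi, ck, vim, cd) -> rare class, for DAPI+ or DAPI-CK+.
_CALL_TO_CLASS: dict[tuple[bool, bool, bool, bool], RareEventClass] = {
    markers: cls for cls, markers in CLASS_MARKERS.items()
}


@dataclass(frozen=True)
class ChannelCall:
    """Positivity of the four channels for one event."""

    dapi: bool
    ck: bool
    vim: bool
    cd: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.dapi, self.ck, self.vim, self.cd)


@dataclass(frozen=True)
class LEVAnnotation:
    """Proximity and debris-filter state for one LEV event."""

    proximity: str              # "free_floating" | "cell_proximal"
    frame_lev_count: int
    passed_frame_filter: bool


def call_channels(features: MorphoFeatures, thresholds: dict[str, float],
                  kind: str = "nucleated") -> ChannelCall:
    """Threshold median intensities into booleans.

    Positivity is strict (> cutoff); a median exactly at the cutoff is
    negative — conservative rare-event calling. The DAPI call additionally
    requires a nucleated candidate, so vesicles can never be DAPI-positive
    whatever their DAPI-channel background reads.
    """
    missing = [c for c in CHANNELS if c not in thresholds]
    if missing:
        raise ValueError(f"missing thresholds for channels: {missing}")
    if any(thresholds[c] <= 0 for c in CHANNELS):
        raise ValueError("thresholds must be positive")
    return ChannelCall(
        dapi=(kind == "nucleated") and features.median_dapi > thresholds["dapi"],
        ck=features.median_ck > thresholds["ck"],
        vim=features.median_vim > thresholds["vim"],
        cd=features.median_cd > thresholds["cd"],
    )


def classify_event(call: ChannelCall) -> RareEventClass:
    """Total decision table over the 16 channel combinations.

    DAPI-positive events map onto the 8 cellular classes by marker
    combination (CK+Vim−CD− is the epithelial-like CTC; CK+Vim+CD− the
    mesenchymal-like CTC; the rest are named by their positive markers,
    including DAPI only). DAPI-negative CK-positive events map onto the 4 LEV
    classes by their Vim/CD combination; DAPI-negative CK-negative events are
    not rare.
    """
    key = call.as_tuple()
    if key in _CALL_TO_CLASS:
        return _CALL_TO_CLASS[key]
    return RareEventClass.NOT_RARE


def annotate_lev_proximity(centroid_um: tuple[float, float],
                           nucleus_centroids_um: list[tuple[float, float]],
                           radius_um: float = 10.0) -> str:
    """``cell_proximal`` iff the nearest same-frame nucleus centroid lies
    within ``radius_um`` (inclusive); ``free_floating`` otherwise, including
    when the frame has no nuclei."""
    if radius_um <= 0:
        raise ValueError("proximity radius must be positive")
    if not nucleus_centroids_um:
        return "free_floating"
    cx, cy = centroid_um
    d2 = min((cx - nx) ** 2 + (cy - ny) ** 2 for nx, ny in nucleus_centroids_um)
    return "cell_proximal" if d2 <= radius_um**2 else "free_floating"


def filter_lev_frames(classified: pd.DataFrame, max_per_frame: int = 3,
                      mode: str = "drop") -> pd.DataFrame:
    """Apply the per-frame LEV debris cap and return the retained events.

    In ``drop`` mode (default) a frame whose LEV count exceeds the cap is
    treated as contaminated by CK-positive debris and contributes zero LEVs.
    ``cap`` mode instead keeps the ``max_per_frame`` largest-CK LEVs of such a
    frame. Non-LEV rows pass through unchanged; the operation never increases
    counts and is idempotent.
    """
    if mode not in ("drop", "cap"):
        raise ValueError("mode must be 'drop' or 'cap'")
    lev_names = {c.value for c in LEV_CLASSES}
    is_lev = classified["event_class"].isin(lev_names)
    keep = np.ones(len(classified), dtype=bool)
    for _, idx in classified.index[is_lev].to_series().groupby(
            classified.loc[is_lev, "frame"]):
        if len(idx) > max_per_frame:
            if mode == "drop":
                keep[classified.index.get_indexer(idx)] = False
            else:
                order = classified.loc[idx, "median_ck"].sort_values(ascending=False)
                keep[classified.index.get_indexer(order.index[max_per_frame:])] = False
    return classified[keep].copy()


def classify_table(features: pd.DataFrame, thresholds: dict[str, float],
                   proximity_radius_um: float = 10.0,
                   lev_max_per_frame: int = 3,
                   lev_filter_mode: str = "drop",
                   artifact_eccentricity_max: float = 0.95) -> pd.DataFrame:
    """Classify a per-event feature table (detection CSV schema).

    Adds ``dapi_call``/``ck_call``/``vim_call``/``cd_call``, ``event_class``,
    ``lev_proximity`` (LEV rows only, when x/y columns are present) and
    ``passed_frame_filter``. Anucleated rows failing the eccentricity screen
    are labelled ARTIFACT before gating (table-level stand-in for the
    morphology screen applied at detection time on frames).
    """
    df = features.copy()
    calls = []
    classes = []
    for row in df.itertuples(index=False):
        feats = MorphoFeatures(
            cell_area=row.cell_area_um2, cell_eccentricity=row.cell_eccentricity,
            nuclear_area=row.nuclear_area_um2,
            nuclear_eccentricity=row.nuclear_eccentricity,
            median_dapi=row.median_dapi, median_ck=row.median_ck,
            median_vim=row.median_vim, median_cd=row.median_cd)
        call = call_channels(feats, thresholds, kind=row.kind)
        if row.kind == "anucleated" and \
                row.cell_eccentricity > artifact_eccentricity_max:
            cls = RareEventClass.ARTIFACT
        else:
            cls = classify_event(call)
        calls.append(call)
        classes.append(cls.value)
    df["dapi_call"] = [c.dapi for c in calls]
    df["ck_call"] = [c.ck for c in calls]
    df["vim_call"] = [c.vim for c in calls]
    df["cd_call"] = [c.cd for c in calls]
    df["event_class"] = classes

    lev_names = {c.value for c in LEV_CLASSES}
    is_lev = df["event_class"].isin(lev_names)
    if {"frame", "x_um", "y_um"}.issubset(df.columns):
        prox = []
        nuclei_by_frame = {
            f: list(zip(sub.loc[sub["kind"] == "nucleated", "x_um"],
                        sub.loc[sub["kind"] == "nucleated", "y_um"]))
            for f, sub in df.groupby("frame")
        }
        for row in df.itertuples(index=False):
            if row.event_class in lev_names:
                prox.append(annotate_lev_proximity(
                    (row.x_um, row.y_um), nuclei_by_frame.get(row.frame, []),
                    radius_um=proximity_radius_um))
            else:
                prox.append(None)
        df["lev_proximity"] = prox
        retained = filter_lev_frames(df, max_per_frame=lev_max_per_frame,
                                     mode=lev_filter_mode)
        df["passed_frame_filter"] = df.index.isin(retained.index) | ~is_lev
    else:
        df["lev_proximity"] = None
        df["passed_frame_filter"] = True
    return df
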