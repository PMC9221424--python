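"""Shared domain types: frames, features, candidates, and the rare-event ontology.

The ontology follows the channel-type classification used in HD liquid-biopsy
immunofluorescence assays: four fluorescence channels (DAPI nuclear stain,
cytokeratin, vimentin, and a shared CD45/CD31 leukocyte/endothelial channel)
yield 16 positivity combinations that map onto 8 cellular rare classes
(DAPI-positive), 4 large-extracellular-vesicle (LEV) classes (DAPI-negative,
CK-positive), and a not-rare remainder (DAPI-negative, CK-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Channel order used everywhere (TIFF page order, feature columns, calls).
CHANNELS = ("dapi", "ck", "vim", "cd")

#: Human-readable channel names, matching the assay's fluor assignment.
CHANNEL_LABELS = {
    "dapi": "DAPI",
    "ck": "CK",
    "vim": "Vim",
    "cd": "CD45/CD31",
}


class RareEventClass(str, Enum):
    """The 12 rare-event categories plus the two non-rare outcomes.

    Cellular classes require a nuclear DAPI signal; LEV classes require the
    absence of DAPI and the presence of CK. Events negative for both DAPI and
    CK are not rare; detection-stage morphology screens may mark artifacts.
    """

    DAPI_ONLY = "DAPI only"
    VIM_ONLY = "Vim only"
    CD_ONLY = "CD45/CD31 only"
    VIM_CD = "Vim|CD45/CD31"
    EPI_CTC = "epi.CTC"
    MES_CTC = "mes.CTC"
    CK_CD = "CK|CD45/CD31"
    CK_VIM_CD = "CK|Vim|CD45/CD31"
    LEV_CK = "LEV CK only"
    LEV_CK_VIM = "LEV CK|Vim"
    LEV_CK_CD = "LEV CK|CD45/CD31"
    LEV_CK_VIM_CD = "LEV CK|Vim|CD45/CD31"
    NOT_RARE = "NOT_RARE"
    ARTIFACT = "ARTIFACT"


#: The 8 cellular rare classes (nucleated).
CELL_CLASSES: tuple[RareEventClass, ...] = (
    RareEventClass.DAPI_ONLY,
    RareEventClass.VIM_ONLY,
    RareEventClass.CD_ONLY,
    RareEventClass.VIM_CD,
    RareEventClass.EPI_CTC,
    RareEventClass.MES_CTC,
    RareEventClass.CK_CD,
    RareEventClass.CK_VIM_CD,
)

#: The 4 LEV rare classes (anucleated, CK-positive).
LEV_CLASSES: tuple[RareEventClass, ...] = (
    RareEventClass.LEV_CK,
    RareEventClass.LEV_CK_VIM,
    RareEventClass.LEV_CK_CD,
    RareEventClass.LEV_CK_VIM_CD,
)

#: All 12 rare classes, cellular first.
RARE_CLASSES: tuple[RareEventClass, ...] = CELL_CLASSES + LEV_CLASSES

#: Ground-truth marker combination (dapi, ck, vim, cd) defining each rare class.
CLASS_MARKERS: dict[RareEventClass, tuple[bool, bool, bool, bool]] = {
    RareEventClass.DAPI_ONLY: (True, False, False, False),
    RareEventClass.VIM_ONLY: (True, False, True, False),
    RareEventClass.CD_ONLY: (True, False, False, True),
    RareEventClass.VIM_CD: (True, False, True, True),
    RareEventClass.EPI_CTC: (True, True, False, False),
    RareEventClass.MES_CTC: (True, True, True, False),
    RareEventClass.CK_CD: (True, True, False, True),
    RareEventClass.CK_VIM_CD: (True, True, True, True),
    RareEventClass.LEV_CK: (False, True, False, False),
    RareEventClass.LEV_CK_VIM: (False, True, True, False),
    RareEventClass.LEV_CK_CD: (False, True, False, True),
    RareEventClass.LEV_CK_VIM_CD: (False, True, True, True),
}

#: Synthetic truth label for common white blood cells (DAPI+, CD45+): by
#: channel combination alone these are indistinguishable from CD45/CD31-only
#: rare cells; only the ground-truth label keeps them apart.
WBC_LABEL = "WBC"
#: Synthetic truth label for CK-positive optical artifacts (bubbles/halos).
ARTIFACT_LABEL = "artifact"


@dataclass
class ImmunoFrame:
    """One co-registered 4-channel scan frame.

    Attributes
    ----------
    index : frame index within the scan.
    channels : dict of channel name -> 2-D float array (arbitrary units, >= 0).
    um_per_px : isotropic pixel scale in micrometres per pixel.
    """

    index: int
    channels: dict[str, np.ndarray]
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        shapes = {self.channels[c].shape for c in CHANNELS if c in self.channels}
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"frame {self.index} missing channels: {missing}")
        if len(shapes) != 1:
            raise ValueError("all channel rasters must share dimensions")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["dapi"].shape


@dataclass(frozen=True)
class MorphoFeatures:
    """The 8-feature morphometric subset used for embedding and clustering.

    Areas are in square micrometres; eccentricity is the moment-ellipse
    eccentricity sqrt(1 - (minor/major)^2) in [0, 1); intensities are median
    values per channel over the event mask, in arbitrary units. A nuclear area
    of 0 is permitted only for anucleated (LEV) candidates.
    """

    cell_area: float
    cell_eccentricity: float
    nuclear_area: float
    nuclear_eccentricity: float
    median_dapi: float
    median_ck: float
    median_vim: float
    median_cd: float

    def median(self, channel: str) -> float:
        return getattr(self, f"median_{channel}")

    def as_dict(self) -> dict[str, float]:
        return {
            "cell_area_um2": self.cell_area,
            "cell_eccentricity": self.cell_eccentricity,
            "nuclear_area_um2": self.nuclear_area,
            "nuclear_eccentricity": self.nuclear_eccentricity,
            "median_dapi": self.median_dapi,
            "median_ck": self.median_ck,
            "median_vim": self.median_vim,
            "median_cd": self.median_cd,
        }


#: Stable column order for per-event feature tables (CSV schema).
FEATURE_COLUMNS = [
    "cell_area_um2",
    "cell_eccentricity",
    "nuclear_area_um2",
    "nuclear_eccentricity",
    "median_dapi",
    "median_ck",
    "median_vim",
    "median_cd",
]


@dataclass
class EventCandidate:
    """One detected object: location, mask, morphometrics and a kind hint."""

    frame_index: int
    centroid_um: tuple[float, float]  # (x, y), origin at frame top-left
    features: MorphoFeatures
    kind: str  # "nucleated" | "anucleated"
    mask: np.ndarray | None = field(default=None, repr=False)
    solidity: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nucleated", "anucleated"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
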