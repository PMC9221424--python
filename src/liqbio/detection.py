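"""Candidate detection and morphometry on 4-channel frames.

Detection is deliberately simple: nuclei are connected components of the
Otsu-thresholded DAPI raster; anucleated (vesicle) candidates are CK
components that touch no nucleus, screened for round membranous morphology.
Cell features are measured on the nucleus mask dilated by a fixed cytoplasmic
halo, since the assay does not define a whole-cell boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .core import CHANNELS, FEATURE_COLUMNS, EventCandidate, ImmunoFrame, MorphoFeatures

#: Default morphology screen for anucleated candidates: encodes the "round
#: and membranous" criterion; crescents/halos fail solidity or eccentricity.
DEFAULT_SOLIDITY_MIN = 0.7
DEFAULT_ECCENTRICITY_MAX = 0.95


def segment_nuclei(frame: ImmunoFrame, min_area_um2: float = 10.0) -> list[np.ndarray]:
    """Segment nuclei as connected components of the thresholded DAPI raster.

    The threshold is Otsu's bimodal split computed on log-intensities
    (fluorescence populations are log-normal, so the split is found in log
    space); components are 8-connected, and two nuclei whose supra-threshold
    supports touch merge into one mask (the declared merging rule).
    Components below ``min_area_um2`` are dropped. An empty or constant
    raster yields an empty list.
    """
    dapi = frame.channels["dapi"]
    if float(dapi.max()) <= 0 or np.ptp(dapi) == 0:
        return []
    thresh = threshold_otsu(np.log1p(dapi))
    binary = np.log1p(dapi) > thresh
    if not binary.any():
        return []
    labeled = sk_label(binary, connectivity=2)
    min_px = min_area_um2 / frame.um_per_px**2
    masks = []
    for region in regionprops(labeled):
        if region.area >= min_px:
            masks.append(labeled == region.label)
    return masks


def _ck_background_threshold(frame: ImmunoFrame, nuclei_masks: list[np.ndarray],
                             halo_um: float, k: float = 3.0,
                             smooth_sigma: float = 1.0) -> float:
    """Background mean + k·SD of the (lightly smoothed) CK raster over
    nucleus-free regions."""
    ck = ndimage.gaussian_filter(frame.channels["ck"], smooth_sigma)
    exclude = np.zeros(ck.shape, dtype=bool)
    halo_px = max(1, int(round(halo_um / frame.um_per_px)))
    selem = disk(halo_px)
    for m in nuclei_masks:
        exclude |= ndimage.binary_dilation(m, structure=selem)
    bg = ck[~exclude]
    if bg.size == 0:
        bg = ck.ravel()
    # robust cut: the rare CK-positive pixels outside nuclei are excluded by
    # trimming the top tail before estimating background moments
    trimmed = np.sort(bg)[: max(1, int(0.98 * bg.size))]
    return float(trimmed.mean() + k * trimmed.std())


def measure_features(frame: ImmunoFrame, mask: np.ndarray,
                     nucleus_mask: np.ndarray | None = None,
                     intensity_mask: np.ndarray | None = None) -> MorphoFeatures:
    """Morphometrics of one event: areas (µm²), moment-ellipse eccentricities
    and per-channel median intensities.

    ``mask`` is the event (cell or vesicle) support; ``nucleus_mask`` adds the
    nuclear area/eccentricity and is omitted for anucleated candidates.
    Channel medians are taken over the nuclear support when one is given —
    the scan is a 2-D projection, so cytoplasmic markers overlay the nucleus,
    and the nuclear support avoids diluting the median with halo background —
    and over the vesicle mask otherwise.
    """
    if not mask.any():
        raise ValueError("measure_features requires a nonempty mask")
    um2 = frame.um_per_px**2
    props = regionprops(mask.astype(np.uint8))[0]
    if nucleus_mask is not None and nucleus_mask.any():
        nprops = regionprops(nucleus_mask.astype(np.uint8))[0]
        nuc_area, nuc_ecc = nprops.area * um2, float(nprops.eccentricity)
        intensity_support = nucleus_mask
    else:
        nuc_area, nuc_ecc = 0.0, 0.0
        intensity_support = mask
    if intensity_mask is not None and intensity_mask.any():
        intensity_support = intensity_mask
    medians = {c: float(np.median(frame.channels[c][intensity_support]))
               for c in CHANNELS}
    return MorphoFeatures(
        cell_area=props.area * um2,
        cell_eccentricity=float(props.eccentricity),
        nuclear_area=nuc_area,
        nuclear_eccentricity=nuc_ecc,
        median_dapi=medians["dapi"],
        median_ck=medians["ck"],
        median_vim=medians["vim"],
        median_cd=medians["cd"],
    )


def detect_nucleated_candidates(frame: ImmunoFrame,
                                nuclei_masks: list[np.ndarray],
                                halo_um: float = 2.5) -> list[EventCandidate]:
    """One candidate per nucleus; the cell mask is the nucleus dilated by a
    cytoplasmic halo of ``halo_um`` micrometres."""
    halo_px = max(1, int(round(halo_um / frame.um_per_px)))
    selem = disk(halo_px)
    out = []
    for nmask in nuclei_masks:
        cell_mask = ndimage.binary_dilation(nmask, structure=selem)
        feats = measure_features(frame, cell_mask, nucleus_mask=nmask)
        cy, cx = ndimage.center_of_mass(nmask)
        out.append(EventCandidate(
            frame_index=frame.index,
            centroid_um=(cx * frame.um_per_px, cy * frame.um_per_px),
            features=feats, kind="nucleated", mask=cell_mask))
    return out


def detect_anucleated_candidates(frame: ImmunoFrame,
                                 nuclei_masks: list[np.ndarray],
                                 min_area_um2: float = 3.0,
                                 halo_um: float = 2.5,
                                 solidity_min: float = DEFAULT_SOLIDITY_MIN,
                                 eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX,
                                 ) -> list[EventCandidate]:
    """CK-positive components that overlap no nucleus, screened for round
    membranous morphology.

    The CK raster is lightly Gaussian-smoothed (1 px) to suppress
    single-pixel background noise, then thresholded at background mean + 3 SD
    estimated over nucleus-free regions. Components overlapping any nucleus
    mask are part of a cellular event and are not returned; components
    failing the solidity/eccentricity screen are dropped as optical artifacts
    (bubbles, halos, refractions). Intensity medians are measured on the
    original, unsmoothed rasters.
    """
    ck = frame.channels["ck"]
    if np.ptp(ck) == 0:
        return []
    smooth = ndimage.gaussian_filter(ck, 1.0)
    thresh = _ck_background_threshold(frame, nuclei_masks, halo_um)
    # erode by 1 px: smoothing bleeds bright supports past the object edge,
    # which would merge near neighbours and graze nucleus masks
    binary = ndimage.binary_erosion(smooth > thresh)
    if not binary.any():
        return []
    nuc_union = np.zeros(ck.shape, dtype=bool)
    for m in nuclei_masks:
        nuc_union |= m
    labeled = sk_label(binary, connectivity=2)
    min_px = min_area_um2 / frame.um_per_px**2
    out = []
    for region in regionprops(labeled):
        if region.area < min_px:
            continue
        mask = labeled == region.label
        # a component belongs to a cellular event when its interior reaches a
        # nucleus; test the eroded core so a one-pixel boundary graze from
        # smoothing bleed does not discard a free vesicle
        interior = ndimage.binary_erosion(mask)
        if ((interior if interior.any() else mask) & nuc_union).any():
            continue  # belongs to a cellular event
        if region.solidity < solidity_min or region.eccentricity > eccentricity_max:
            continue  # artifact screen
        # intensity medians over the component core: the smoothed support
        # extends past the vesicle edge, so erode before taking medians
        core = ndimage.binary_erosion(mask, iterations=2)
        if not core.any():
            core = ndimage.binary_erosion(mask, iterations=1)
        feats = measure_features(frame, mask, nucleus_mask=None,
                                 intensity_mask=core if core.any() else None)
        cy, cx = region.centroid
        out.append(EventCandidate(
            frame_index=frame.index,
            centroid_um=(cx * frame.um_per_px, cy * frame.um_per_px),
            features=feats, kind="anucleated", mask=mask,
            solidity=float(region.solidity)))
    return out


def detect_events(frame: ImmunoFrame, min_nucleus_area_um2: float = 10.0,
                  halo_um: float = 2.5,
                  solidity_min: float = DEFAULT_SOLIDITY_MIN,
                  eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX,
                  ) -> list[EventCandidate]:
    """Full detection pass on one frame: nucleated then anucleated candidates."""
    nuclei = segment_nuclei(frame, min_area_um2=min_nucleus_area_um2)
    cand = detect_nucleated_candidates(frame, nuclei, halo_um=halo_um)
    cand += detect_anucleated_candidates(
        frame, nuclei, halo_um=halo_um,
        solidity_min=solidity_min, eccentricity_max=eccentricity_max)
    return cand


def candidates_to_table(candidates: list[EventCandidate]) -> pd.DataFrame:
    """Per-event feature CSV schema: frame, event_id, kind, x/y (µm), and the
    eight morphometric feature columns."""
    rows = []
    for i, c in enumerate(candidates):
        rows.append({
            "event_id": i, "frame": c.frame_index, "kind": c.kind,
            "x_um": c.centroid_um[0], "y_um": c.centroid_um[1],
            **c.features.as_dict(),
        })
    return pd.DataFrame(
        rows, columns=["event_id", "frame", "kind", "x_um", "y_um"] + FEATURE_COLUMNS)
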