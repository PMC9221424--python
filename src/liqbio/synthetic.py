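"""Synthetic frames, event tables and cohorts with known ground truth.

Every downstream stage (detection, gating, enumeration, statistics,
clustering) is exercised against data generated here, so each generator is a
pure function of its specification and seed. Three levels are provided:

* :func:`generate_event_table` — per-event morphometric features drawn
  directly from the mixture model (no imaging), with truth labels;
* :func:`generate_frames` — rendered 4-channel frames with planted nuclei,
  marker disks and LEVs, for the imaging pipeline;
* :func:`generate_cohort` — per-sample category counts, blood volumes and a
  clinical covariate table with plantable Spearman correlations.

Scales default to the assay's reported cohort statistics (UTUC rare-cell
rates several-fold above normal-donor rates, WBC counts of a few million per
mL) but at desk-size frame counts; the full 2304-frames-per-slide geometry is
reachable through configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    ARTIFACT_LABEL,
    CELL_CLASSES,
    CHANNELS,
    CLASS_MARKERS,
    FEATURE_COLUMNS,
    LEV_CLASSES,
    RARE_CLASSES,
    WBC_LABEL,
    ImmunoFrame,
    RareEventClass,
)
from .enumeration import SampleMeta


class SpecificationError(ValueError):
    """Raised when a generator specification violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a valid specification cannot be realised (e.g. density)."""


# --------------------------------------------------------------------------
# Mixture specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity populations for one channel.

    ``neg_mu``/``pos_mu`` are natural-log locations; sigma values are
    log-scale spreads. Fluorescence intensities are right-skewed, which the
    log-normal captures; the positive location must strictly exceed the
    negative one so a separating cutoff exists.
    """

    neg_mu: float
    neg_sigma: float
    pos_mu: float
    pos_sigma: float

    def __post_init__(self) -> None:
        if self.pos_mu <= self.neg_mu:
            raise SpecificationError(
                "positive population location must exceed negative location"
            )
        if self.neg_sigma <= 0 or self.pos_sigma <= 0:
            raise SpecificationError("sigma values must be positive")

    @property
    def cutoff(self) -> float:
        """Geometric midpoint of the two population medians."""
        return math.exp(0.5 * (self.neg_mu + self.pos_mu))

    def draw(self, positive: bool, rng: np.random.Generator, size=None):
        mu, sigma = (self.pos_mu, self.pos_sigma) if positive else (self.neg_mu, self.neg_sigma)
        return np.exp(rng.normal(mu, sigma, size=size))


@dataclass(frozen=True)
class MorphologyModel:
    """Cell/nucleus/vesicle geometry in micrometres."""

    nucleus_radius_um: tuple[float, float] = (4.0, 0.5)   # mean, sd
    cell_radius_um: tuple[float, float] = (7.0, 0.8)
    lev_radius_um: tuple[float, float] = (2.5, 0.4)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)

    def __post_init__(self) -> None:
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise SpecificationError("eccentricity range must lie in [0, 1)")


def _default_channels() -> dict[str, ChannelModel]:
    # negative median ~55 a.u., positive median ~800 a.u., well separated
    return {c: ChannelModel(4.0, 0.35, 6.7, 0.35) for c in CHANNELS}


@dataclass(frozen=True)
class EventMixtureSpec:
    """Mixture over the 12 rare categories plus common WBCs and artifacts.

    ``proportions`` keys are the :class:`RareEventClass` values of the 12 rare
    categories plus ``"WBC"`` and ``"artifact"``; they must be nonnegative and
    sum to 1.
    """

    proportions: dict[str, float]
    channels: dict[str, ChannelModel] = field(default_factory=_default_channels)
    morphology: MorphologyModel = field(default_factory=MorphologyModel)

    def __post_init__(self) -> None:
        allowed = {c.value for c in RARE_CLASSES} | {WBC_LABEL, ARTIFACT_LABEL}
        unknown = set(self.proportions) - allowed
        if unknown:
            raise SpecificationError(f"unknown mixture categories: {sorted(unknown)}")
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals < 0).any():
            raise SpecificationError("mixture proportions must be nonnegative")
        if not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
            raise SpecificationError("mixture proportions must sum to 1")
        missing = set(CHANNELS) - set(self.channels)
        if missing:
            raise SpecificationError(f"missing channel models: {sorted(missing)}")

    @classmethod
    def default(cls, rare_fraction: float = 0.05,
                artifact_fraction: float = 0.0) -> "EventMixtureSpec":
        """Equal mixture over the 12 rare categories inside ``rare_fraction``;
        the remainder (minus artifacts) is common WBCs."""
        props = {c.value: rare_fraction / len(RARE_CLASSES) for c in RARE_CLASSES}
        props[ARTIFACT_LABEL] = artifact_fraction
        props[WBC_LABEL] = 1.0 - rare_fraction - artifact_fraction
        return cls(proportions=props)

    def cutoffs(self) -> dict[str, float]:
        """Per-channel gating cutoffs sitting between the two populations."""
        return {c: self.channels[c].cutoff for c in CHANNELS}


def _truth_markers(label: str) -> tuple[bool, bool, bool, bool]:
    if label == WBC_LABEL:
        return (True, False, False, True)
    if label == ARTIFACT_LABEL:
        return (False, True, False, False)
    return CLASS_MARKERS[RareEventClass(label)]


def _is_nucleated(label: str) -> bool:
    return _truth_markers(label)[0]


# --------------------------------------------------------------------------
# Event tables
# --------------------------------------------------------------------------

def generate_event_table(n_events: int, spec: EventMixtureSpec, seed: int) -> pd.DataFrame:
    """Draw per-event features from the mixture model, with truth labels.

    Returns a DataFrame with ``event_id``, ``true_class``, ``kind`` and the
    eight morphometric feature columns. Identical seeds yield identical
    tables.
    """
    if n_events <= 0:
        raise SpecificationError("n_events must be positive")
    rng = np.random.default_rng(seed)
    labels = list(spec.proportions)
    probs = np.array([spec.proportions[k] for k in labels])
    assigned = rng.choice(len(labels), size=n_events, p=probs)

    morph = spec.morphology
    rows = []
    for i, idx in enumerate(assigned):
        label = labels[idx]
        dapi, ck, vim, cd = _truth_markers(label)
        nucleated = _is_nucleated(label)
        if nucleated:
            r_nuc = max(1.0, rng.normal(*morph.nucleus_radius_um))
            r_cell = max(r_nuc + 0.5, rng.normal(*morph.cell_radius_um))
            nuc_area = math.pi * r_nuc**2
            nuc_ecc = rng.uniform(*morph.eccentricity_range)
            kind = "nucleated"
        else:
            r_cell = max(0.8, rng.normal(*morph.lev_radius_um))
            nuc_area = 0.0
            nuc_ecc = 0.0
            kind = "anucleated"
        if label == ARTIFACT_LABEL:
            # halos / light refractions: thin, highly elongated CK shapes
            cell_ecc = rng.uniform(0.96, 0.995)
        else:
            cell_ecc = rng.uniform(*morph.eccentricity_range)
        feats = {
            "cell_area_um2": math.pi * r_cell**2,
            "cell_eccentricity": cell_ecc,
            "nuclear_area_um2": nuc_area,
            "nuclear_eccentricity": nuc_ecc,
            "median_dapi": float(spec.channels["dapi"].draw(dapi, rng)),
            "median_ck": float(spec.channels["ck"].draw(ck, rng)),
            "median_vim": float(spec.channels["vim"].draw(vim, rng)),
            "median_cd": float(spec.channels["cd"].draw(cd, rng)),
        }
        rows.append({"event_id": i, "true_class": label, "kind": kind, **feats})
    return pd.DataFrame(rows, columns=["event_id", "true_class", "kind"] + FEATURE_COLUMNS)


def generate_features_for_counts(counts: dict[str, int], spec: EventMixtureSpec,
                                 seed: int) -> pd.DataFrame:
    """Like :func:`generate_event_table` but with fixed per-category counts."""
    labels = [lab for lab, n in counts.items() for _ in range(int(n))]
    if not labels:
        return pd.DataFrame(columns=["event_id", "true_class", "kind"] + FEATURE_COLUMNS)
    # reuse the table generator with a degenerate mixture per block
    frames = []
    offset = 0
    for j, (lab, n) in enumerate(counts.items()):
        n = int(n)
        if n == 0:
            continue
        sub = replace(spec, proportions={lab: 1.0})
        tab = generate_event_table(n, sub, seed=seed * 1000 + j)
        tab["event_id"] += offset
        offset += n
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Frame rendering
# --------------------------------------------------------------------------

def _render_disk(img: np.ndarray, cx: float, cy: float, radius: float,
                 amplitude: float) -> None:
    """Add a soft-edged disk (1 px linear roll-off) centred at (cx, cy)."""
    h, w = img.shape
    x0, x1 = max(0, int(cx - radius - 2)), min(w, int(cx + radius + 3))
    y0, y1 = max(0, int(cy - radius - 2)), min(h, int(cy + radius + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    img[y0:y1, x0:x1] += amplitude * np.clip(radius - d + 0.5, 0.0, 1.0)


def _render_bar(img: np.ndarray, cx: float, cy: float, length: float,
                width: float, angle: float, amplitude: float) -> None:
    """Add a thin rotated bar (halo/refraction mimic) centred at (cx, cy)."""
    h, w = img.shape
    half = length / 2 + 2
    x0, x1 = max(0, int(cx - half)), min(w, int(cx + half + 1))
    y0, y1 = max(0, int(cy - half)), min(h, int(cy + half + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * math.cos(angle) + (yy - cy) * math.sin(angle)
    v = -(xx - cx) * math.sin(angle) + (yy - cy) * math.cos(angle)
    inside = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    img[y0:y1, x0:x1] += amplitude * inside


@dataclass
class FrameSetSpec:
    """Geometry for rendered synthetic frames."""

    frame_px: tuple[int, int] = (256, 256)
    um_per_px: float = 1.0
    min_separation_um: float = 18.0     # centre-to-centre, keeps nuclei disjoint
    proximity_radius_um: float = 10.0   # LEV cell-proximity annotation radius
    lev_free_floating_prob: float = 0.5
    debris_levs_per_frame: int = 6      # planted on designated debris frames


def generate_frames(n_frames: int, cells_per_frame: float,
                    rare_spec: EventMixtureSpec, seed: int,
                    frame_spec: FrameSetSpec | None = None,
                    n_debris_frames: int = 0,
                    ) -> tuple[list[ImmunoFrame], pd.DataFrame]:
    """Render synthetic 4-channel frames and return them with a truth table.

    Nuclei are soft disks in the DAPI raster; positive markers are larger
    disks in their channel; LEVs are small DAPI-negative CK-positive disks,
    placed either free-floating (well beyond the proximity radius of every
    nucleus) or cell-proximal per a per-event truth flag. The last
    ``n_debris_frames`` frames additionally receive a burst of CK-positive
    debris vesicles to exceed the per-frame LEV cap.

    Truth columns: ``frame``, ``event_id``, ``true_class``, ``kind``,
    ``x_um``, ``y_um``, ``lev_proximal``, ``is_debris_frame``.
    """
    fs = frame_spec or FrameSetSpec()
    if n_debris_frames > n_frames:
        raise SpecificationError("n_debris_frames exceeds n_frames")
    rng = np.random.default_rng(seed)
    h, w = fs.frame_px
    um = fs.um_per_px
    morph = rare_spec.morphology
    margin = (morph.cell_radius_um[0] + 3 * morph.cell_radius_um[1] + 2) / um
    min_sep_px = fs.min_separation_um / um
    # rough packing feasibility check
    usable = max(0.0, (h - 2 * margin)) * max(0.0, (w - 2 * margin))
    if cells_per_frame * min_sep_px**2 > 0.7 * usable:
        raise GenerationError("requested cell density exceeds frame capacity")

    labels = list(rare_spec.proportions)
    probs = np.array([rare_spec.proportions[k] for k in labels])

    frames: list[ImmunoFrame] = []
    truth_rows: list[dict] = []
    event_id = 0
    for f in range(n_frames):
        is_debris = f >= n_frames - n_debris_frames
        chans = {
            c: rare_spec.channels[c].draw(False, rng, size=(h, w)).astype(np.float64)
            for c in CHANNELS
        }
        n_cells = int(rng.poisson(cells_per_frame))
        assigned = [labels[i] for i in rng.choice(len(labels), size=n_cells, p=probs)]
        nucleated = [lab for lab in assigned if _is_nucleated(lab)]
        anucleated = [lab for lab in assigned if not _is_nucleated(lab)]
        if is_debris:
            anucleated = anucleated + [RareEventClass.LEV_CK.value] * fs.debris_levs_per_frame

        # place nucleated events by dart throwing with a separation constraint
        centres: list[tuple[float, float]] = []
        placed_nucleated: list[str] = []
        for lab in nucleated:
            for _ in range(300):
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep_px**2
                       for px, py in centres):
                    centres.append((cx, cy))
                    placed_nucleated.append(lab)
                    break
            else:
                raise GenerationError("could not place nuclei at requested density")

        nuc_radii = []
        cell_radii = []
        marker_radii = []  # marker-disk radius per cell (0 if no marker disk)
        for lab, (cx, cy) in zip(placed_nucleated, centres):
            dapi, ck, vim, cd = _truth_markers(lab)
            r_nuc = max(1.5, rng.normal(*morph.nucleus_radius_um)) / um
            r_cell = max(r_nuc + 1.0, rng.normal(*morph.cell_radius_um) / um)
            nuc_radii.append(r_nuc)
            cell_radii.append(r_cell)
            marker_radii.append(r_cell if (ck or vim or cd) else 0.0)
            _render_disk(chans["dapi"], cx, cy, r_nuc,
                         float(rare_spec.channels["dapi"].draw(True, rng)))
            for name, pos in (("ck", ck), ("vim", vim), ("cd", cd)):
                if pos:
                    _render_disk(chans[name], cx, cy, r_cell,
                                 float(rare_spec.channels[name].draw(True, rng)))
            truth_rows.append({
                "frame": f, "event_id": event_id, "true_class": lab,
                "kind": "nucleated", "x_um": cx * um, "y_um": cy * um,
                "lev_proximal": np.nan, "is_debris_frame": is_debris,
            })
            event_id += 1

        # place LEVs / artifacts
        prox_px = fs.proximity_radius_um / um
        # proximal hosts must be CK-negative cells: a CK-positive host's CK
        # disk would touch the vesicle's CK blob and merge the components
        ck_neg_hosts = [j for j, lab in enumerate(placed_nucleated)
                        if not _truth_markers(lab)[1]]
        lev_pts: list[tuple[float, float, float]] = []  # (x, y, radius)
        for lab in anucleated:
            r_lev = max(1.2, rng.normal(*morph.lev_radius_um)) / um
            proximal = bool(ck_neg_hosts) and rng.random() > fs.lev_free_floating_prob
            pos_xy = None
            for _ in range(300):
                if proximal:
                    host = ck_neg_hosts[rng.integers(len(ck_neg_hosts))]
                    hx, hy = centres[host]
                    # outside the host's marker disks (median-intensity
                    # contamination) and clear of the nucleus support so the
                    # smoothed CK component cannot touch the nucleus mask
                    gap_lo = max(cell_radii[host] + 0.8 * r_lev + 0.5,
                                 nuc_radii[host] + r_lev + 3.5)
                    # stay 1.5 px inside the proximity radius so centroid
                    # localisation error cannot flip the annotation
                    if gap_lo >= prox_px - 1.5:
                        continue
                    d = rng.uniform(gap_lo, prox_px - 1.5)
                    theta = rng.uniform(0, 2 * math.pi)
                    cx, cy = hx + d * math.cos(theta), hy + d * math.sin(theta)
                    # unambiguous nearest nucleus, and clear of every other
                    # cell's marker disk: the smoothed CK supports would merge
                    # and the vesicle medians would read the neighbour's markers
                    ok = all(
                        math.hypot(cx - px, cy - py)
                        > max(prox_px + 2, marker_radii[j] + r_lev + 6.0)
                        for j, (px, py) in enumerate(centres) if j != host)
                else:
                    cx = rng.uniform(margin, w - margin)
                    cy = rng.uniform(margin, h - margin)
                    ok = all(
                        math.hypot(cx - px, cy - py)
                        > max(prox_px + 4, marker_radii[j] + r_lev + 6.0)
                        for j, (px, py) in enumerate(centres))
                ok = ok and all(
                    math.hypot(cx - lx, cy - ly) > r_lev + lr + 5.0
                    for lx, ly, lr in lev_pts)
                if ok and margin <= cx <= w - margin and margin <= cy <= h - margin:
                    pos_xy = (cx, cy)
                    break
            if pos_xy is None and proximal:
                # fall back to free-floating if no proximal slot was found
                proximal = False
                for _ in range(300):
                    cx = rng.uniform(margin, w - margin)
                    cy = rng.uniform(margin, h - margin)
                    clear = all(
                        math.hypot(cx - px, cy - py)
                        > max(prox_px + 4, marker_radii[j] + r_lev + 6.0)
                        for j, (px, py) in enumerate(centres))
                    if clear and all(
                            math.hypot(cx - lx, cy - ly) > r_lev + lr + 5.0
                            for lx, ly, lr in lev_pts):
                        pos_xy = (cx, cy)
                        break
            if pos_xy is None:
                raise GenerationError("could not place LEV at requested density")
            cx, cy = pos_xy
            lev_pts.append((cx, cy, r_lev))
            _, ck, vim, cd = _truth_markers(lab)
            if lab == ARTIFACT_LABEL:
                # halo mimic: thin elongated CK streak, fails the roundness screen
                _render_bar(chans["ck"], cx, cy, length=14.0 / um, width=1.2 / um,
                            angle=rng.uniform(0, math.pi),
                            amplitude=float(rare_spec.channels["ck"].draw(True, rng)))
            else:
                for name, pos in (("ck", ck), ("vim", vim), ("cd", cd)):
                    if pos:
                        _render_disk(chans[name], cx, cy, r_lev,
                                     float(rare_spec.channels[name].draw(True, rng)))
            truth_rows.append({
                "frame": f, "event_id": event_id, "true_class": lab,
                "kind": "anucleated", "x_um": cx * um, "y_um": cy * um,
                "lev_proximal": proximal, "is_debris_frame": is_debris,
            })
            event_id += 1

        frames.append(ImmunoFrame(index=f, channels=chans, um_per_px=um))

    truth = pd.DataFrame(truth_rows, columns=[
        "frame", "event_id", "true_class", "kind", "x_um", "y_um",
        "lev_proximal", "is_debris_frame",
    ])
    return frames, truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

# Per-category mean rates (events/mL) for the tumor cohort; the sums match
# the reported cohort means (219.83 rare cells/mL, 15.05 LEVs/mL).
UTUC_RATES: dict[str, float] = {
    RareEventClass.DAPI_ONLY.value: 11.12,
    RareEventClass.VIM_ONLY.value: 54.50,
    RareEventClass.CD_ONLY.value: 4.37,
    RareEventClass.VIM_CD.value: 89.47,
    RareEventClass.EPI_CTC.value: 1.30,
    RareEventClass.MES_CTC.value: 2.24,
    RareEventClass.CK_CD.value: 5.73,
    RareEventClass.CK_VIM_CD.value: 51.10,
    RareEventClass.LEV_CK.value: 10.36,
    RareEventClass.LEV_CK_VIM.value: 0.20,
    RareEventClass.LEV_CK_CD.value: 4.05,
    RareEventClass.LEV_CK_VIM_CD.value: 0.44,
}

#: Normal-donor rates: per-category UTUC means scaled so cohort totals match
#: the reported donor means (43.21 cells/mL, 4.65 LEVs/mL).
_ND_CELL_SCALE = 43.21 / 219.83
_ND_LEV_SCALE = 4.65 / 15.05
ND_RATES: dict[str, float] = {
    k: v * (_ND_LEV_SCALE if k.startswith("LEV") else _ND_CELL_SCALE)
    for k, v in UTUC_RATES.items()
}


@dataclass(frozen=True)
class CovariateSpec:
    """One clinical covariate with an optional planted rank correlation.

    ``kind`` is ``continuous`` (Gaussian marginal ``params=(mean, sd)``),
    ``ordinal`` (``params=(levels, probs)``) or ``binary``
    (``params=p_positive``). ``target_analyte`` names a rare-event category
    (events/mL) or one of the totals (``total_cells``, ``total_levs``,
    ``total``); ``rho`` is the target Spearman correlation, approached as the
    cohort grows, via a Gaussian-copula rank coupling.
    """

    name: str
    kind: str
    params: tuple
    target_analyte: str | None = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "binary"):
            raise SpecificationError(f"unknown covariate kind {self.kind!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise SpecificationError("correlation target must lie in [-1, 1]")


def default_covariates() -> list[CovariateSpec]:
    """Clinical covariates mirroring a typical UTUC surgical cohort."""
    return [
        CovariateSpec("age", "continuous", (66.5, 10.0),
                      RareEventClass.CK_VIM_CD.value, 0.55),
        CovariateSpec("height", "continuous", (172.0, 9.0),
                      RareEventClass.MES_CTC.value, -0.5),
        CovariateSpec("weight", "continuous", (77.0, 12.0),
                      RareEventClass.MES_CTC.value, -0.5),
        CovariateSpec("bmi", "continuous", (26.0, 4.0)),
        CovariateSpec("gfr", "continuous", (70.0, 15.0),
                      RareEventClass.CK_CD.value, -0.5),
        CovariateSpec("cci_score", "ordinal",
                      ((0, 1, 2, 3), (0.5, 0.25, 0.15, 0.1)),
                      RareEventClass.CK_VIM_CD.value, 0.5),
        CovariateSpec("smoking", "ordinal",
                      (("never", "former", "current"), (0.4, 0.4, 0.2))),
        CovariateSpec("asa_score", "ordinal", ((1, 2, 3, 4), (0.1, 0.4, 0.4, 0.1)),
                      RareEventClass.VIM_CD.value, 0.4),
        CovariateSpec("gender_male", "binary", (0.85,)),
        CovariateSpec("previous_bladder_cancer", "binary", (0.75,),
                      RareEventClass.LEV_CK.value, -0.5),
        CovariateSpec("recurrence", "binary", (0.15,)),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Two-cohort study design: sample counts, rates, blood parameters."""

    n_utuc: int = 20
    n_nd: int = 50
    rates_utuc: dict[str, float] = field(default_factory=lambda: dict(UTUC_RATES))
    rates_nd: dict[str, float] = field(default_factory=lambda: dict(ND_RATES))
    dispersion: float = 1.5           # negative-binomial shape (smaller = wider)
    wbc_per_ml: tuple[float, float, float, float] = (6.0e6, 1.6e6, 2.8e6, 9.8e6)
    wbc_detected_per_slide: tuple[float, float] = (3.9e6, 0.35e6)
    slides_per_test: int = 2
    covariates: tuple[CovariateSpec, ...] = field(
        default_factory=lambda: tuple(default_covariates()))
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.rates_utuc, self.rates_nd):
            if any(v < 0 for v in rates.values()):
                raise SpecificationError("category rates must be nonnegative")
        if self.dispersion <= 0:
            raise SpecificationError("dispersion must be positive")
        if self.n_utuc < 1 or self.n_nd < 1:
            raise SpecificationError("both cohorts need at least one sample")


@dataclass
class CohortSample:
    """Ground-truth per-sample output of the cohort generator."""

    meta: SampleMeta
    counts: dict[str, int]
    volume_ml: float


def _nb_draw(rng: np.random.Generator, mean: float, shape: float) -> int:
    if mean <= 0:
        return 0
    p = shape / (shape + mean)
    return int(rng.negative_binomial(shape, p))


def generate_cohort(spec: CohortSpec) -> tuple[list[CohortSample], pd.DataFrame]:
    """Draw per-sample category counts and the patient clinical table.

    Counts are negative-binomial at cohort-specific per-category rates scaled
    by each sample's analyzed blood volume (WBCs detected by the assay divided
    by the hematology-analyzer WBC concentration). Clinical covariates are
    generated for the tumor cohort with a Gaussian-copula rank coupling to
    their target analyte, so planted Spearman correlations are approached as
    the cohort grows.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[CohortSample] = []
    mu_w, sd_w, lo_w, hi_w = spec.wbc_per_ml
    for cohort, n, rates in (("UTUC", spec.n_utuc, spec.rates_utuc),
                             ("ND", spec.n_nd, spec.rates_nd)):
        for i in range(n):
            wbc_ml = float(np.clip(rng.normal(mu_w, sd_w), lo_w, hi_w))
            detected = float(
                np.sum(rng.normal(*spec.wbc_detected_per_slide,
                                  size=spec.slides_per_test)))
            volume = detected / wbc_ml
            counts = {
                cat: _nb_draw(rng, rate * volume, spec.dispersion)
                for cat, rate in rates.items()
            }
            meta = SampleMeta(
                sample_id=f"{cohort}-{i + 1:03d}", cohort=cohort,
                wbc_per_ml=wbc_ml, slides_per_test=spec.slides_per_test,
                wbcs_detected=detected)
            samples.append(CohortSample(meta=meta, counts=counts, volume_ml=volume))

    clinical = _generate_clinical(
        [s for s in samples if s.meta.cohort == "UTUC"], spec, rng)
    return samples, clinical


def _analyte_vector(samples: list[CohortSample], name: str) -> np.ndarray:
    def per_ml(s: CohortSample, keys) -> float:
        return sum(s.counts[k] for k in keys) / s.volume_ml

    lev_keys = [c.value for c in LEV_CLASSES]
    cell_keys = [c.value for c in CELL_CLASSES]
    if name == "total_cells":
        return np.array([per_ml(s, cell_keys) for s in samples])
    if name == "total_levs":
        return np.array([per_ml(s, lev_keys) for s in samples])
    if name == "total":
        return np.array([per_ml(s, cell_keys + lev_keys) for s in samples])
    return np.array([s.counts[name] / s.volume_ml for s in samples])


def _generate_clinical(samples: list[CohortSample], spec: CohortSpec,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = len(samples)
    out = {"sample_id": [s.meta.sample_id for s in samples]}
    for cov in spec.covariates:
        if cov.target_analyte is not None and abs(cov.rho) > 0 and n > 1:
            a = _analyte_vector(samples, cov.target_analyte)
            ranks = sps.rankdata(a)
            z_a = sps.norm.ppf((ranks - 0.5) / n)
            rho_l = 2 * math.sin(math.pi * cov.rho / 6)  # Spearman -> latent r
            z = rho_l * z_a + math.sqrt(1 - rho_l**2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        u = sps.norm.cdf(z)
        if cov.kind == "continuous":
            mean, sd = cov.params
            vals = sps.norm.ppf(u, loc=mean, scale=sd)
        elif cov.kind == "ordinal":
            levels, probs = cov.params
            edges = np.cumsum(probs)
            idx = np.searchsorted(edges, u, side="right").clip(0, len(levels) - 1)
            vals = np.asarray(levels, dtype=object)[idx]
        else:  # binary
            p = cov.params[0]
            vals = (u > 1 - p).astype(int)
        out[cov.name] = vals
    return pd.DataFrame(out)
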