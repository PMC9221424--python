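"""End-to-end pipeline: simulate -> detect -> classify -> enumerate -> stats
-> cluster, with versioned, reproducible outputs.

Two synthetic arms run in one pass:

* an imaging arm — rendered frames are pushed through detection and gating
  and scored against the planted truth (confusion, LEV proximity and the
  per-frame debris filter);
* a cohort arm — per-sample event tables at the tumor/donor rate scales are
  classified, enumerated into WBC-normalized rates, compared between cohorts
  by rank-sum, correlated against the clinical table, and the pooled cellular
  events are embedded and Ward-clustered.

Every output file name is stable and every run writes a ``report.json``
embedding the tool version, the configuration hash and the seed, so a rerun
with the same configuration reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluate
from .config import PipelineConfig
from .core import CELL_CLASSES
from .enumeration import (
    SampleEnumeration,
    cohort_summary,
    enumerate_sample,
    rates_table,
    save_enumerations,
)
from .gating import classify_table
from .detection import candidates_to_table, detect_events
from .morpho import (
    agglomerate,
    build_feature_matrix,
    clamp_perplexity,
    density_profiles,
    embed_2d,
    profile_summary,
)
from .stats import compare_cohorts, correlate_clinical
from .synthetic import (
    CohortSpec,
    EventMixtureSpec,
    FrameSetSpec,
    generate_cohort,
    generate_features_for_counts,
    generate_frames,
)
from .io import write_frames

log = logging.getLogger("liqbio")


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class ReportBundle:
    """Paths and headline numbers of one pipeline run."""

    output_dir: Path
    report: dict


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "liqbio", "version": __version__,
        "config_hash": config.config_hash(), "seed": config.seed,
    }
    mixture = EventMixtureSpec.default(rare_fraction=config.synthetic.rare_fraction)
    thresholds = config.gating.thresholds or mixture.cutoffs()

    # ---- imaging arm -----------------------------------------------------
    try:
        log.info("stage=simulate-frames n=%d", config.synthetic.n_frames)
        fs = FrameSetSpec(
            frame_px=(config.synthetic.frame_px, config.synthetic.frame_px),
            um_per_px=config.geometry.um_per_px,
            proximity_radius_um=config.gating.proximity_radius_um)
        frames, truth = generate_frames(
            config.synthetic.n_frames, config.synthetic.cells_per_frame,
            mixture, seed=config.seed, frame_spec=fs,
            n_debris_frames=config.synthetic.n_debris_frames)
        truth.to_csv(out / "frame_truth.csv", index=False, float_format="%.10g")
        if config.synthetic.write_frames:
            write_frames(frames, out / "frames")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[simulate] {e}") from e

    try:
        log.info("stage=detect")
        candidates = []
        for fr in frames:
            candidates.extend(detect_events(
                fr, min_nucleus_area_um2=config.detection.min_nucleus_area_um2,
                halo_um=config.detection.halo_um,
                solidity_min=config.detection.solidity_min,
                eccentricity_max=config.detection.eccentricity_max))
        features = candidates_to_table(candidates)
        _write_csv(features, out / "frame_events.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[detect] {e}") from e

    try:
        log.info("stage=classify")
        classified = classify_table(
            features, thresholds,
            proximity_radius_um=config.gating.proximity_radius_um,
            lev_max_per_frame=config.gating.lev_max_per_frame,
            lev_filter_mode=config.gating.lev_filter_mode)
        _write_csv(classified, out / "frame_classified.csv")
        matched = evaluate.match_to_truth(truth, classified)
        confusion = evaluate.rare_confusion(matched)
        confusion.to_csv(out / "frame_confusion.csv")
        report["frame_confusion_diagonal"] = \
            evaluate.confusion_diagonal_fraction(confusion)
        report["frame_wbcs_detected"] = evaluate.wbc_detected_count(matched)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[classify] {e}") from e

    # ---- cohort arm ------------------------------------------------------
    try:
        log.info("stage=simulate-cohort utuc=%d nd=%d",
                 config.synthetic.n_utuc, config.synthetic.n_nd)
        cohort_spec = CohortSpec(
            n_utuc=config.synthetic.n_utuc, n_nd=config.synthetic.n_nd,
            slides_per_test=config.geometry.slides_per_test, seed=config.seed)
        samples, clinical = generate_cohort(cohort_spec)
        _write_csv(clinical, out / "clinical.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[simulate-cohort] {e}") from e

    try:
        log.info("stage=enumerate")
        enums: list[SampleEnumeration] = []
        classified_tables = {}
        for i, sample in enumerate(samples):
            feats = generate_features_for_counts(
                sample.counts, mixture, seed=config.seed * 100 + i)
            ctab = classify_table(feats, thresholds)
            classified_tables[sample.meta.sample_id] = ctab
            enums.append(enumerate_sample(ctab, sample.meta))
        save_enumerations(enums, out / "enumerations.json")
        rates = rates_table(enums)
        _write_csv(rates, out / "sample_rates.csv")
        summary = cohort_summary(enums)
        _write_csv(summary, out / "cohort_summary.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[enumerate] {e}") from e

    try:
        log.info("stage=stats")
        utuc = rates[rates["cohort"] == "UTUC"]
        nd = rates[rates["cohort"] == "ND"]
        comparisons = compare_cohorts(
            utuc, nd, bh_correction=config.stats.bh_correction)
        _write_csv(comparisons, out / "cohort_comparisons.csv")
        var_types = {c.name: c.kind for c in cohort_spec.covariates}
        correlations = correlate_clinical(
            utuc, clinical, var_types, min_group=config.stats.min_group,
            bh_correction=config.stats.bh_correction)
        _write_csv(correlations, out / "clinical_correlations.csv")
        report["total_rare_events_p"] = float(
            comparisons.loc[comparisons["category"] == "total", "p"].iloc[0])
        report["n_significant_categories"] = int(comparisons["significant"].sum())
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[stats] {e}") from e

    try:
        log.info("stage=cluster")
        pooled = pd.concat(
            [classified_tables[s.meta.sample_id] for s in samples
             if s.meta.cohort == "UTUC"], ignore_index=True)
        cellular = pooled[pooled["event_class"].isin(
            [c.value for c in CELL_CLASSES])]
        rng = np.random.default_rng(config.seed)
        if len(cellular) > config.cluster.max_events:
            idx = rng.choice(len(cellular), config.cluster.max_events,
                             replace=False)
            cellular = cellular.iloc[np.sort(idx)]
        Z, classes, dropped = build_feature_matrix(cellular)
        perp = clamp_perplexity(len(Z), config.cluster.perplexity)
        coords = embed_2d(Z, perplexity=perp, seed=config.seed)
        k = min(config.cluster.k, len(Z))
        clusters = agglomerate(Z, k=k)
        emb = pd.DataFrame({
            "tsne_1": coords[:, 0], "tsne_2": coords[:, 1],
            "event_class": classes.to_numpy(), "cluster": clusters.labels,
        })
        _write_csv(emb, out / "embedding.csv")
        profiles = density_profiles(Z, classes)
        # density JSON is large; store peak summary as CSV and full grid JSON
        _write_csv(profile_summary(profiles), out / "density_peaks.csv")
        (out / "density_profiles.json").write_text(json.dumps(
            {cls: {feat: {"n_peaks": d["n_peaks"]}
                   for feat, d in feats.items()}
             for cls, feats in profiles.items()}, indent=1, sort_keys=True))
        report["n_cellular_events_clustered"] = int(len(Z))
        report["dropped_feature_columns"] = dropped
        report["n_clusters"] = int(k)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[cluster] {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    config.to_yaml(out / "config_used.yaml")
    return ReportBundle(output_dir=out, report=report)
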