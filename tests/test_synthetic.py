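"""Generators: determinism, validation, and distributional sanity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from liqbio.core import CHANNELS, RARE_CLASSES, WBC_LABEL
from liqbio.synthetic import (
    ChannelModel,
    CohortSpec,
    CovariateSpec,
    EventMixtureSpec,
    SpecificationError,
    generate_cohort,
    generate_event_table,
    generate_features_for_counts,
    generate_frames,
)


class TestSpecValidation:
    def test_channel_model_requires_separated_locations(self):
        with pytest.raises(SpecificationError):
            ChannelModel(5.0, 0.3, 5.0, 0.3)
        with pytest.raises(SpecificationError):
            ChannelModel(4.0, -0.1, 6.0, 0.3)

    def test_cutoff_lies_between_population_medians(self):
        m = ChannelModel(4.0, 0.35, 6.7, 0.35)
        assert np.exp(4.0) < m.cutoff < np.exp(6.7)

    def test_mixture_must_sum_to_one(self):
        props = {c.value: 0.5 for c in RARE_CLASSES}
        with pytest.raises(SpecificationError):
            EventMixtureSpec(proportions=props)

    def test_mixture_rejects_unknown_category(self):
        with pytest.raises(SpecificationError):
            EventMixtureSpec(proportions={"platelet": 1.0})

    def test_mixture_rejects_negative_proportion(self):
        with pytest.raises(SpecificationError):
            EventMixtureSpec(proportions={WBC_LABEL: 1.1, "epi.CTC": -0.1})

    def test_default_mixture_is_valid_and_rare_fraction_honoured(self):
        spec = EventMixtureSpec.default(rare_fraction=0.12)
        rare = sum(spec.proportions[c.value] for c in RARE_CLASSES)
        assert rare == pytest.approx(0.12)

    def test_cohort_spec_validation(self):
        with pytest.raises(SpecificationError):
            CohortSpec(dispersion=0.0)
        with pytest.raises(SpecificationError):
            CohortSpec(n_utuc=0)
        with pytest.raises(SpecificationError):
            CovariateSpec("x", "continuous", (0, 1), rho=1.5)
        with pytest.raises(SpecificationError):
            CovariateSpec("x", "fuzzy", (0, 1))


class TestEventTable:
    def test_deterministic_under_seed(self):
        spec = EventMixtureSpec.default()
        a = generate_event_table(200, spec, seed=7)
        b = generate_event_table(200, spec, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = generate_event_table(200, spec, seed=8)
        assert not a.equals(c)

    def test_category_counts_within_multinomial_bounds(self):
        spec = EventMixtureSpec.default(rare_fraction=0.3)
        table = generate_event_table(3000, spec, seed=11)
        for label, p in spec.proportions.items():
            n_obs = int((table["true_class"] == label).sum())
            lo = sps.binom.ppf(0.0005, 3000, p)
            hi = sps.binom.ppf(0.9995, 3000, p)
            assert lo <= n_obs <= hi, (label, n_obs)

    def test_kind_matches_nucleation(self):
        spec = EventMixtureSpec.default(rare_fraction=0.5)
        table = generate_event_table(400, spec, seed=3)
        levs = table["true_class"].str.startswith("LEV")
        assert (table.loc[levs, "kind"] == "anucleated").all()
        assert (table.loc[levs, "nuclear_area_um2"] == 0).all()
        cells = table["true_class"] == WBC_LABEL
        assert (table.loc[cells, "kind"] == "nucleated").all()
        assert (table.loc[cells, "nuclear_area_um2"] > 0).all()

    def test_intensities_positive(self):
        table = generate_event_table(500, EventMixtureSpec.default(), seed=5)
        for c in CHANNELS:
            assert (table[f"median_{c}"] > 0).all()

    def test_features_for_counts_exact(self):
        spec = EventMixtureSpec.default()
        counts = {"epi.CTC": 3, "LEV CK only": 2, "WBC": 5}
        table = generate_features_for_counts(counts, spec, seed=4)
        assert len(table) == 10
        assert table["true_class"].value_counts().to_dict() == {
            "WBC": 5, "epi.CTC": 3, "LEV CK only": 2}
        again = generate_features_for_counts(counts, spec, seed=4)
        pd.testing.assert_frame_equal(table, again)


class TestFrames:
    def test_frames_deterministic(self):
        spec = EventMixtureSpec.default()
        f1, t1 = generate_frames(2, 30, spec, seed=42)
        f2, t2 = generate_frames(2, 30, spec, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
        for a, b in zip(f1, f2):
            for c in CHANNELS:
                np.testing.assert_array_equal(a.channels[c], b.channels[c])

    def test_truth_schema_and_bounds(self):
        spec = EventMixtureSpec.default(rare_fraction=0.2)
        frames, truth = generate_frames(3, 40, spec, seed=9, n_debris_frames=1)
        assert set(truth.columns) == {
            "frame", "event_id", "true_class", "kind", "x_um", "y_um",
            "lev_proximal", "is_debris_frame"}
        h, w = frames[0].shape
        assert truth["x_um"].between(0, w).all()
        assert truth["y_um"].between(0, h).all()
        assert truth.loc[truth["frame"] == 2, "is_debris_frame"].all()
        assert not truth.loc[truth["frame"] < 2, "is_debris_frame"].any()

    def test_debris_frames_carry_extra_levs(self):
        spec = EventMixtureSpec.default()
        _, truth = generate_frames(4, 30, spec, seed=2, n_debris_frames=2)
        anuc = truth[truth["kind"] == "anucleated"]
        per_frame = anuc.groupby("frame").size()
        for f in (2, 3):
            assert per_frame.get(f, 0) > 3

    def test_debris_count_cannot_exceed_frames(self):
        with pytest.raises(SpecificationError):
            generate_frames(2, 30, EventMixtureSpec.default(), seed=0,
                            n_debris_frames=3)


class TestCohort:
    def test_cohort_deterministic_and_sized(self):
        spec = CohortSpec(n_utuc=5, n_nd=8, seed=123)
        samples, clinical = generate_cohort(spec)
        samples2, clinical2 = generate_cohort(spec)
        assert [s.meta.sample_id for s in samples] == \
               [s.meta.sample_id for s in samples2]
        assert [s.counts for s in samples] == [s.counts for s in samples2]
        pd.testing.assert_frame_equal(clinical, clinical2)
        assert sum(s.meta.cohort == "UTUC" for s in samples) == 5
        assert sum(s.meta.cohort == "ND" for s in samples) == 8
        # clinical covariates describe the patient cohort only
        assert len(clinical) == 5
        assert clinical["sample_id"].str.startswith("UTUC").all()

    def test_volumes_and_counts_sane(self):
        samples, _ = generate_cohort(CohortSpec(n_utuc=10, n_nd=10, seed=1))
        for s in samples:
            assert s.volume_ml > 0
            assert s.meta.wbc_per_ml >= 2.8e6
            assert all(v >= 0 for v in s.counts.values())

    def test_utuc_rates_exceed_nd_rates_on_average(self):
        samples, _ = generate_cohort(CohortSpec(n_utuc=30, n_nd=30, seed=17))
        def mean_total(cohort):
            sub = [s for s in samples if s.meta.cohort == cohort]
            return np.mean([sum(s.counts.values()) / s.volume_ml for s in sub])
        assert mean_total("UTUC") > 3 * mean_total("ND")

    def test_planted_correlation_sign(self):
        cov = CovariateSpec("age", "continuous", (60.0, 10.0),
                            "Vim|CD45/CD31", 0.7)
        spec = CohortSpec(n_utuc=60, n_nd=1, covariates=(cov,), seed=5)
        samples, clinical = generate_cohort(spec)
        utuc = [s for s in samples if s.meta.cohort == "UTUC"]
        rates = np.array([s.counts["Vim|CD45/CD31"] / s.volume_ml for s in utuc])
        r = sps.spearmanr(clinical["age"].to_numpy(), rates).statistic
        assert r > 0.4
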