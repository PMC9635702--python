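"""Synthetic population generator: distributions, morphology, persistence."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from otoage.pipeline import DatasetTable
from otoage.synthetic import (DEFAULT_AGE_MEANS, DEFAULT_AGE_SDS,
                              DEFAULT_PROPORTIONS, LengthParams,
                              PopulationConfig, RenderParams, count_fingers,
                              expected_finger_count, foreground_mask,
                              measure_core_row, measure_vertical_extent,
                              render_otolith, sample_length,
                              sample_population, write_dataset)


def truncnorm_mean(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.mean(a, b, loc=mean, scale=sd)


class TestPopulationConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationConfig(n_total=10, group_proportions=(0.5, 0.4, 0.2))

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_total=10, group_proportions=(1.2, -0.1, -0.1))

    def test_age_range_lower_bound(self):
        with pytest.raises(ValueError, match="lower bound"):
            PopulationConfig(n_total=10, age_range=(0, 26))

    def test_render_params_validate(self):
        with pytest.raises(ValueError):
            RenderParams(target_height_fraction=0.0)
        with pytest.raises(ValueError):
            RenderParams(fingers_per_year=-1)


class TestSamplePopulation:
    def test_record_count_and_age_range(self, metadata_population):
        assert len(metadata_population) == 10_000
        ages = np.array([r.read_age for r in metadata_population])
        assert ages.min() >= 1 and ages.max() <= 26

    def test_sex_proportions_converge(self, metadata_population):
        sexes = np.array([r.sex for r in metadata_population])
        for sex, p in zip(("male", "female", "unknown"), DEFAULT_PROPORTIONS):
            frac = np.mean(sexes == sex)
            assert abs(frac - p) < 0.01, (sex, frac)

    def test_group_age_means_match_truncnorm_oracle(self, metadata_population):
        """Sample means track the truncated-normal moment (numerical oracle).

        The tolerance is ~3 standard errors of the mean for each group's
        expected sample size, i.e. tightest for the large female group.
        """
        sexes = np.array([r.sex for r in metadata_population])
        ages = np.array([r.read_age for r in metadata_population], dtype=float)
        for i, sex in enumerate(("male", "female", "unknown")):
            expected = truncnorm_mean(DEFAULT_AGE_MEANS[i], DEFAULT_AGE_SDS[i],
                                      1, 26)
            group = ages[sexes == sex]
            tol = max(0.15, 3 * DEFAULT_AGE_SDS[i] / np.sqrt(group.size))
            assert abs(group.mean() - expected) < tol

    def test_determinism(self):
        cfg = PopulationConfig(n_total=5, seed=11,
                               render=RenderParams(canvas_size=32))
        a = sample_population(cfg)
        b = sample_population(cfg)
        for ra, rb in zip(a, b):
            assert ra.read_age == rb.read_age and ra.sex == rb.sex
            assert ra.length == rb.length
            np.testing.assert_array_equal(ra.image, rb.image)

    def test_records_independent_of_population_size(self):
        cfg5 = PopulationConfig(n_total=5, seed=11,
                                render=RenderParams(canvas_size=32))
        cfg9 = PopulationConfig(n_total=9, seed=11,
                                render=RenderParams(canvas_size=32))
        a, b = sample_population(cfg5), sample_population(cfg9)
        np.testing.assert_array_equal(a[3].image, b[3].image)

    def test_lengths_only_for_known_sex_by_default(self, metadata_population):
        for r in metadata_population[:500]:
            assert (r.length is None) == (r.sex == "unknown")


class TestRenderOtolith:
    def test_juvenile_has_no_fingers(self, render_params_128, rng):
        img = render_otolith(2, "male", render_params_128, rng)
        assert count_fingers(img) == 0

    def test_bitwise_determinism(self, render_params_128):
        a = render_otolith(9, "female", render_params_128,
                           np.random.default_rng(5))
        b = render_otolith(9, "female", render_params_128,
                           np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_finger_count_monotone_in_age(self, render_params_128):
        old = render_otolith(20, "male", render_params_128,
                             np.random.default_rng(5))
        young = render_otolith(6, "male", render_params_128,
                               np.random.default_rng(5))
        assert count_fingers(old) >= count_fingers(young)
        assert count_fingers(old) >= 4  # well-developed fingers by age 20

    def test_expected_finger_count_monotone(self, render_params_128):
        counts = [expected_finger_count(a, render_params_128)
                  for a in range(1, 27)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == 0

    @pytest.mark.parametrize("age", [1, 8, 20])
    def test_height_standardization(self, age, render_params_128, rng):
        img = render_otolith(age, "female", render_params_128, rng)
        target = (render_params_128.target_height_fraction
                  * render_params_128.canvas_size)
        assert abs(measure_vertical_extent(img) - target) <= 1.5

    def test_core_drifts_down_with_age(self, render_params_128):
        rows = [measure_core_row(render_otolith(a, "male", render_params_128,
                                                np.random.default_rng(7)))
                for a in (2, 8, 14, 20)]
        assert all(b > a for a, b in zip(rows, rows[1:]))

    def test_area_nondecreasing_with_age(self, render_params_128):
        areas = []
        for age in (2, 8, 14, 20):
            imgs = [render_otolith(age, "female", render_params_128,
                                   np.random.default_rng(100 + k))
                    for k in range(3)]
            areas.append(np.mean([foreground_mask(i).sum() for i in imgs]))
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_intensity_range_and_shape(self, render_params_128, rng):
        img = render_otolith(13, "unknown", render_params_128, rng)
        assert img.shape == (128, 128, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_age_below_one_rejected(self, render_params_128, rng):
        with pytest.raises(ValueError, match="age"):
            render_otolith(0, "male", render_params_128, rng)


class TestSampleLength:
    PARAMS = LengthParams(intercept=8.0, female_slope=4.5,
                          male_slope_delta=-1.0, noise_sd=0.0)

    def test_shared_intercept_at_age_zero(self, rng):
        assert sample_length(0, "male", self.PARAMS, rng) == 8.0
        assert sample_length(0, "female", self.PARAMS, rng) == 8.0

    def test_noiseless_female_strictly_increasing(self, rng):
        lengths = [sample_length(a, "female", self.PARAMS, rng)
                   for a in range(1, 20)]
        assert all(b > a for a, b in zip(lengths, lengths[1:]))

    def test_unknown_sex_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_length(5, "unknown", self.PARAMS, rng)

    def test_noise_sd_recovered(self):
        params = LengthParams(noise_sd=3.0)
        rng = np.random.default_rng(2)
        draws = np.array([sample_length(10, "male", params, rng)
                          for _ in range(5000)])
        assert abs(draws.std(ddof=1) - 3.0) / 3.0 < 0.10


class TestWriteDataset:
    def test_layout_and_round_trip(self, tmp_path):
        cfg = PopulationConfig(n_total=3, seed=4,
                               render=RenderParams(canvas_size=32))
        records = sample_population(cfg)
        manifest = write_dataset(records, tmp_path / "ds")
        assert sorted(p.name for p in (tmp_path / "ds").glob("*.png")) == \
            [f"{r.sample_id}.png" for r in records]
        frame = pd.read_csv(manifest)
        assert len(frame) == 3
        table = DatasetTable.from_manifest(manifest)
        np.testing.assert_array_equal(table.read_ages,
                                      [r.read_age for r in records])
        assert list(table.sex) == [r.sex for r in records]
        # pixel round trip is exact up to the 8-bit quantization done on write
        quantized = np.rint(records[0].image * 255) / 255
        np.testing.assert_allclose(table.images[0], quantized, atol=1e-12)

    def test_missing_length_round_trips_as_absent(self, tmp_path):
        cfg = PopulationConfig(n_total=30, seed=8,
                               render=RenderParams(canvas_size=32))
        records = sample_population(cfg)
        assert any(r.sex == "unknown" for r in records)
        manifest = write_dataset(records, tmp_path / "ds")
        raw = (tmp_path / "ds" / "metadata.csv").read_text().splitlines()
        unknown_line = next(l for l, r in zip(raw[1:], records)
                            if r.sex == "unknown")
        assert unknown_line.endswith(",")  # empty length field
        table = DatasetTable.from_manifest(manifest, load_images=False)
        for r, length in zip(records, table.lengths):
            assert (r.length is None) == bool(np.isnan(length))
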