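"""Phantom generator: grade encoding, geometry, noise and dataset design."""

import numpy as np
import pytest

import scintigrade as sg
from scintigrade.phantom import DEFAULT_GRADE_RATIO_INTERVALS


class TestGradeToRatio:
    def test_draws_stay_inside_the_grade_interval(self):
        rng = np.random.default_rng(0)
        draws = np.array([sg.grade_to_ratio(2, rng) for _ in range(1000)])
        assert (draws >= 0.9).all() and (draws <= 1.1).all()

    def test_grade3_ratio_always_exceeds_one(self):
        rng = np.random.default_rng(1)
        assert all(sg.grade_to_ratio(3, rng) > 1 for _ in range(200))

    def test_degenerate_interval_returns_its_value(self):
        rng = np.random.default_rng(2)
        assert sg.grade_to_ratio(0, rng, {0: (0.0, 0.0)}) == 0.0

    def test_invalid_grade_raises(self):
        with pytest.raises(ValueError, match="grade"):
            sg.grade_to_ratio(7, np.random.default_rng(0))


class TestWholeBody:
    def test_nonzero_rows_span_exactly_the_patient_height(self):
        cfg = sg.PhantomConfig(patient_height_fraction=0.9, seed=7)
        study = sg.generate_whole_body(cfg, grade=2)
        rows = np.nonzero(study.pixels.sum(axis=1))[0]
        assert rows[-1] - rows[0] + 1 == round(0.9 * cfg.image_height)

    def test_seeded_generation_is_bit_identical(self):
        a = sg.generate_whole_body(sg.PhantomConfig(seed=3), 2)
        b = sg.generate_whole_body(sg.PhantomConfig(seed=3), 2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_grade3_cardiac_mean_exceeds_sternum_mean(self, noiseless_config):
        study = sg.generate_whole_body(noiseless_config, grade=3)
        m = study.masks
        assert study.pixels[m["cardiac"]].mean() > study.pixels[m["sternum"]].mean()

    def test_grade0_cardiac_mean_equals_soft_tissue_background(self, noiseless_config):
        study = sg.generate_whole_body(noiseless_config, grade=0)
        m = study.masks
        tissue = m["body"] & ~m["bone"] & ~m["sternum"] & ~m["ribs"] & ~m["cardiac"]
        cardiac_mean = study.pixels[m["cardiac"]].mean()
        assert cardiac_mean == pytest.approx(study.pixels[tissue].mean(), rel=0.01)

    def test_cardiac_mean_is_strictly_increasing_in_grade(self):
        means = []
        for grade, (lo, hi) in DEFAULT_GRADE_RATIO_INTERVALS.items():
            cfg = sg.PhantomConfig(noise_model="none", hotspot_rate=0.0,
                                   cardiac_ratio=(lo + hi) / 2, seed=1)
            study = sg.generate_whole_body(cfg, grade)
            means.append(study.pixels[study.masks["cardiac"]].mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_invalid_dimensions_raise(self):
        with pytest.raises(ValueError, match="dimensions"):
            sg.PhantomConfig(image_height=0)

    def test_intensity_ordering_is_validated(self):
        with pytest.raises(ValueError, match="bone_intensity"):
            sg.PhantomConfig(bone_intensity=5.0, background_intensity=10.0)


class TestPlanarThoracic:
    def test_protocol_label_and_view(self):
        cfg = sg.PhantomConfig(image_height=256, image_width=256, seed=2)
        study = sg.generate_planar_thoracic(cfg, 1)
        assert study.protocol == "planar" and study.view == "AP"

    def test_grade3_cardiac_exceeds_ribs(self):
        cfg = sg.PhantomConfig(image_height=256, image_width=256,
                               noise_model="none", hotspot_rate=0.0, seed=2)
        study = sg.generate_planar_thoracic(cfg, 3)
        m = study.masks
        assert study.pixels[m["cardiac"]].mean() > study.pixels[m["ribs"]].mean()

    def test_seeded_determinism(self):
        cfg = sg.PhantomConfig(image_height=256, image_width=256, seed=9)
        a = sg.generate_planar_thoracic(cfg, 3).pixels
        b = sg.generate_planar_thoracic(cfg, 3).pixels
        assert np.array_equal(a, b)


class TestPoissonNoise:
    def test_expected_total_counts_match_the_noiseless_template(self):
        """Poisson noise conserves counts in expectation: over 100
        replicates the mean total stays within 3 standard errors."""
        base = dict(image_height=256, image_width=128, hotspot_rate=0.0,
                    cardiac_ratio=1.0)
        noisy = np.array([
            sg.generate_whole_body(
                sg.PhantomConfig(noise_model="poisson", seed=s, **base), 2
            ).pixels.sum()
            for s in range(100)
        ])
        # template geometry varies with the seed, so compare each replicate
        # against its own noiseless counterpart
        expected = np.array([
            sg.generate_whole_body(
                sg.PhantomConfig(noise_model="none", seed=s, **base), 2
            ).pixels.sum()
            for s in range(100)
        ])
        # for a sum of independent Poisson pixels, Var(total) = E(total)
        se_of_mean_diff = np.sqrt(expected.mean() / 100)
        assert abs((noisy - expected).mean()) <= 3 * se_of_mean_diff


#: miniature frame so count-contract tests don't pay full rendering cost
TINY = sg.PhantomConfig(image_height=64, image_width=32)


class TestGenerateDataset:
    def test_largest_remainder_rounding_on_the_clinical_cohort(self):
        studies = sg.generate_dataset(1334, (0.743, 0.222, 0.017, 0.018),
                                      seed=0, config=TINY)
        counts = np.bincount([s.grade for s in studies], minlength=4)
        assert counts.tolist() == [991, 296, 23, 24]

    def test_uniform_proportions_give_one_study_per_grade(self):
        studies = sg.generate_dataset(4, (0.25, 0.25, 0.25, 0.25), seed=1)
        assert sorted(s.grade for s in studies) == [0, 1, 2, 3]

    def test_single_class_dataset(self):
        studies = sg.generate_dataset(100, (1.0, 0.0, 0.0, 0.0), seed=2,
                                      config=TINY)
        assert all(s.grade == 0 for s in studies)

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sg.generate_dataset(10, (0.5, 0.5, 0.5, 0.5), seed=0)

    def test_planar_fraction_controls_protocol_mix(self):
        studies = sg.generate_dataset(60, (0.25, 0.25, 0.25, 0.25),
                                      planar_fraction=0.5, seed=3)
        n_planar = sum(s.protocol == "planar" for s in studies)
        assert 15 <= n_planar <= 45
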