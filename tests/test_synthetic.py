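"""Synthetic cohorts, image series, fixtures and exclusion rules."""

import numpy as np
import pytest
from scipy import stats

from deltarad.synthetic import (
    CohortConfig,
    CohortConfigError,
    apply_exclusions,
    cohort_frame,
    exclusion_demo_cohort,
    generate_cohort,
    generate_cohort_tables,
    generate_fixture,
    generate_image_series,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(n_patients=1)
        with pytest.raises(CohortConfigError):
            CohortConfig(n_weeks=1)
        with pytest.raises(CohortConfigError):
            CohortConfig(scanner_fraction=1.5)


class TestFixtures:
    def test_const8_uniform(self):
        img, mask, _ = generate_fixture("const8")
        assert (img == img.flat[0]).all()
        assert mask.all()

    def test_haralick_grid_verbatim(self):
        img, mask, _ = generate_fixture("haralick4x4")
        assert img.shape == (1, 4, 4)
        assert sorted(np.unique(img)) == [1, 2, 3, 4]
        assert img[0, 0, 0] == 1 and img[0, 3, 3] == 4

    def test_sphere_is_digital_ball(self):
        img, mask, _ = generate_fixture("sphere_r10")
        c = np.array(mask.shape) // 2
        zz, yy, xx = np.indices(mask.shape)
        want = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 100
        assert np.array_equal(mask, want)

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            generate_fixture("nope")


class TestCohort:
    def test_determinism_under_fixed_seed(self):
        cfg = CohortConfig(n_patients=15, seed=11)
        a = cohort_frame(generate_cohort(cfg)[0])
        b = cohort_frame(generate_cohort(cfg)[0])
        assert a.equals(b)

    def test_dose_non_decreasing_and_invariants(self, small_cohort):
        _, records, scores = small_cohort
        assert (scores > 0).all()
        for r in records:
            doses = [r.cumulative_dose[w] for w in r.weeks]
            assert all(b >= a for a, b in zip(doses, doses[1:]))
            assert r.scanner in ("A", "B")
            for ep in ("OS", "DM", "LR"):
                assert r.outcome_day[ep] > r.entry_day

    def test_strong_delta_effect_shortens_survival(self):
        """Higher latent response -> higher hazard: Kendall tau between the
        score and uncensored OS time is negative and detectable at n=60."""
        cfg = CohortConfig(n_patients=60, seed=21, delta_coef=1.2, shape_coef=0.0,
                           censoring_rate=0.0)
        records, scores = generate_cohort(cfg)
        times = np.array([r.outcome_day["OS"] - r.entry_day for r in records])
        res = stats.kendalltau(scores, times)
        assert res.statistic < 0
        assert res.pvalue < 0.05

    def test_null_effects_leave_outcomes_independent(self):
        cfg = CohortConfig(n_patients=200, seed=22, delta_coef=0.0, shape_coef=0.0,
                           censoring_rate=0.0)
        records, scores = generate_cohort(cfg)
        times = np.array([r.outcome_day["OS"] - r.entry_day for r in records])
        assert stats.kendalltau(scores, times).pvalue > 0.05


class TestImageSeries:
    def test_zero_score_static_up_to_noise(self, small_cohort):
        cfg, records, _ = small_cohort
        s = generate_image_series(records[0], 0.0, cfg)
        first = s.masks[0]
        for m in s.masks[1:]:
            assert np.array_equal(m, first)
        # week-to-week differences are pure acquisition noise
        diff = s.images[-1][first] - s.images[0][first]
        assert abs(diff.mean()) < 2.0
        assert diff.std() < 4 * np.hypot(4.0, 5.0)

    def test_mask_voxels_non_increasing(self, small_cohort):
        cfg, records, scores = small_cohort
        s = generate_image_series(records[1], float(scores[1]), cfg)
        counts = [m.sum() for m in s.masks]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]  # positive dose, positive score

    def test_scanner_offset_shifts_mean_hu(self, small_cohort):
        cfg, records, _ = small_cohort
        from dataclasses import replace

        rec_a = replace(records[0], scanner="A")
        rec_b = replace(records[0], scanner="B")
        sa = generate_image_series(rec_a, 0.5, cfg, seed=77)
        sb = generate_image_series(rec_b, 0.5, cfg, seed=77)
        m = sa.masks[0]
        delta = sb.images[0][m].mean() - sa.images[0][m].mean()
        assert delta == pytest.approx(cfg.scanner_offset_hu, abs=2.0)

    def test_determinism(self, small_cohort):
        cfg, records, scores = small_cohort
        a = generate_image_series(records[2], float(scores[2]), cfg)
        b = generate_image_series(records[2], float(scores[2]), cfg)
        for ia, ib in zip(a.images, b.images):
            assert np.array_equal(ia, ib)

    def test_nifti_round_trip(self, small_cohort, tmp_path):
        import nibabel as nib

        from deltarad.synthetic import save_series_nifti

        cfg, records, scores = small_cohort
        s = generate_image_series(records[0], float(scores[0]), cfg)
        paths = save_series_nifti(s, tmp_path)
        assert len(paths) == 2 * len(s.weeks)
        img = nib.load(paths[0])
        assert np.allclose(np.abs(np.diag(img.affine)[:3]), s.spacing)
        assert np.allclose(np.asarray(img.dataobj), s.images[0], atol=1e-3)

    def test_texture_homogenizes_with_dose(self, small_cohort):
        cfg, records, _ = small_cohort
        s = generate_image_series(records[3], 2.0, cfg, seed=5)
        sd_first = s.images[0][s.masks[-1]].std()
        sd_last = s.images[-1][s.masks[-1]].std()
        assert sd_last < sd_first


class TestExclusions:
    def test_demo_cohort_tally(self):
        records = exclusion_demo_cohort()
        kept, tally = apply_exclusions(records)
        assert tally == {"small_volume": 18, "protocol": 9, "early_event": 3,
                         "retained": 107}
        assert len(kept) == 107

    def test_boundary_volume_retained(self):
        from dataclasses import replace

        records = exclusion_demo_cohort()
        exactly5 = replace(records[-1], pretx_volume_cm3=5.0)
        kept, tally = apply_exclusions([exactly5])
        assert tally["retained"] == 1

    def test_no_flags_identity(self, small_cohort):
        from dataclasses import replace

        _, records, _ = small_cohort
        clean = [
            replace(r, pretx_volume_cm3=max(r.pretx_volume_cm3, 6.0),
                    protocol_conforming=True,
                    outcome_day={ep: max(d, r.entry_day + 120)
                                 for ep, d in r.outcome_day.items()})
            for r in records
        ]
        kept, tally = apply_exclusions(clean)
        assert len(kept) == len(records)

    def test_missing_volume_raises(self, small_cohort):
        from dataclasses import replace

        _, records, _ = small_cohort
        bad = [replace(records[0], pretx_volume_cm3=float("nan"))]
        with pytest.raises(ValueError):
            apply_exclusions(bad)


class TestCohortTables:
    def test_tables_aligned_and_deterministic(self, table_cohort):
        records, clinical, pretx, longitudinal = table_cohort
        assert set(pretx.index) == set(clinical.index)
        assert set(longitudinal["patient"]) <= set(clinical.index)
        cfg = CohortConfig(n_patients=40, seed=7)
        _, c2, p2, l2 = generate_cohort_tables(cfg)
        assert clinical.equals(c2) and pretx.equals(p2) and longitudinal.equals(l2)

    def test_longitudinal_weeks_start_at_one(self, table_cohort):
        _, _, _, longitudinal = table_cohort
        assert longitudinal["week"].min() >= 1
        assert (longitudinal.groupby("patient")["dose_Gy"].apply(
            lambda s: (s.diff().dropna() >= 0).all())).all()
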