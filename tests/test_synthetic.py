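"""Phantom-generator contracts: parcellation structure, determinism,
planted-effect calibration (Monte-Carlo against the analytic mean shift)
and distributional null behaviour."""

import numpy as np
import pytest
from scipy import stats

from admvnet.synthetic import (DEFAULT_SIGNAL_REGIONS, MultimodalSample,
                               SyntheticConfig, generate_dataset,
                               generate_subject, make_parcellation,
                               regional_profile)


class TestParcellation:
    def test_all_regions_present_and_nonempty(self):
        parc = make_parcellation((24, 24, 24), seed=1)
        assert sorted(np.unique(parc.labels[parc.labels > 0])) == list(range(1, 91))
        assert np.all(parc.region_sizes >= 1)
        assert parc.region_sizes.sum() == (parc.labels > 0).sum()

    def test_deterministic_for_fixed_seed(self):
        a = make_parcellation((16, 16, 16), seed=3)
        b = make_parcellation((16, 16, 16), seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = make_parcellation((16, 16, 16), seed=4)
        assert not np.array_equal(a.labels, c.labels)

    def test_too_small_shape_raises(self):
        # 4^3 = 64 voxels cannot host 90 nonempty regions
        with pytest.raises(ValueError):
            make_parcellation((4, 4, 4))
        with pytest.raises(ValueError):
            make_parcellation((9, 9, 2))


class TestGenerator:
    def test_zero_effect_zero_noise_classes_identical(self, small_parcellation):
        cfg = SyntheticConfig(n_per_class=1, shape=(16, 16, 16),
                              gm_effect=0, wm_effect=0, pet_effect=0,
                              noise_sd=0.0)
        rng = np.random.default_rng(0)
        s0 = generate_subject(0, cfg, small_parcellation, rng)
        s1 = generate_subject(1, cfg, small_parcellation, rng)
        np.testing.assert_array_equal(s0.gm, s1.gm)
        np.testing.assert_array_equal(s0.pet, s1.pet)
        assert np.all(s0.gm[small_parcellation.mask] == 1.0)

    def test_background_is_exactly_zero(self, small_parcellation):
        cfg = SyntheticConfig(n_per_class=1, shape=(16, 16, 16),
                              noise_sd=0.2, site_offset_sd=0.1)
        s = generate_subject(1, cfg, small_parcellation, np.random.default_rng(1))
        outside = ~small_parcellation.mask
        assert np.all(s.gm[outside] == 0) and np.all(s.pet[outside] == 0)

    def test_planted_mean_shift_matches_analytic_value(self):
        """Monte-Carlo: class difference of region-mean GM ~ effect * sd in
        planted regions and ~0 elsewhere (within 3 standard errors)."""
        parc = make_parcellation((12, 12, 12), seed=2)
        cfg = SyntheticConfig(n_per_class=200, shape=(12, 12, 12),
                              signal_regions=(7, 40), gm_effect=2.0,
                              wm_effect=0.0, pet_effect=0.0, noise_sd=0.1, seed=5)
        rng = np.random.default_rng(cfg.seed)
        means = {0: [], 1: []}
        for i in range(2 * cfg.n_per_class):
            cls = i % 2
            s = generate_subject(cls, cfg, parc, rng)
            prof = regional_profile(s)
            means[cls].append(prof[:, 0])  # GM column
        m0 = np.array(means[0])
        m1 = np.array(means[1])
        diff = m0.mean(axis=0) - m1.mean(axis=0)
        se = np.sqrt(m0.var(axis=0, ddof=1) / len(m0) + m1.var(axis=0, ddof=1) / len(m1))
        expected = cfg.gm_effect * cfg.noise_sd  # 0.2
        for r in cfg.signal_regions:
            assert abs(diff[r - 1] - expected) < 3 * se[r - 1]
        others = [r for r in range(1, 91) if r not in cfg.signal_regions]
        inside_3se = np.abs(diff[[r - 1 for r in others]]) < 3 * se[[r - 1 for r in others]]
        assert inside_3se.mean() > 0.95  # 3 sigma: ~99.7% expected

    def test_dataset_balanced_unique_reproducible(self):
        cfg = SyntheticConfig(n_per_class=30, shape=(16, 16, 16), seed=11)
        samples, parc = generate_dataset(cfg)
        assert len(samples) == 60
        labels = [s.label for s in samples]
        assert labels.count(0) == labels.count(1) == 30
        assert len({s.subject_id for s in samples}) == 60
        again, _ = generate_dataset(cfg)
        np.testing.assert_array_equal(samples[13].pet, again[13].pet)
        other, parc2 = generate_dataset(SyntheticConfig(n_per_class=30, shape=(16, 16, 16), seed=12))
        assert not np.array_equal(samples[0].gm, other[0].gm)
        np.testing.assert_array_equal(parc.labels, parc2.labels)  # parc seed fixed

    def test_null_effect_classes_share_marginal_distribution(self):
        """With no planted effect the two classes are exchangeable: the
        voxel distributions pass a two-sample KS test."""
        cfg = SyntheticConfig(n_per_class=50, shape=(12, 12, 12),
                              gm_effect=0, wm_effect=0, pet_effect=0,
                              noise_sd=0.1, seed=3)
        samples, parc = generate_dataset(cfg)
        mask = parc.mask
        rng = np.random.default_rng(0)
        vox0 = np.concatenate([s.gm[mask] for s in samples if s.label == 0])
        vox1 = np.concatenate([s.gm[mask] for s in samples if s.label == 1])
        sub0 = rng.choice(vox0, 2000, replace=False)
        sub1 = rng.choice(vox1, 2000, replace=False)
        assert stats.ks_2samp(sub0, sub1).pvalue > 0.01

    def test_voxelwise_t_statistic_concentrates_in_planted_regions(self):
        cfg = SyntheticConfig(n_per_class=30, shape=(16, 16, 16), seed=9)
        samples, parc = generate_dataset(cfg)
        g0 = np.stack([s.gm for s in samples if s.label == 0])
        g1 = np.stack([s.gm for s in samples if s.label == 1])
        t = stats.ttest_ind(g0, g1, axis=0).statistic
        planted = np.isin(parc.labels, cfg.signal_regions)
        outside = parc.mask & ~planted
        assert np.nanmean(np.abs(t[planted])) > np.nanmean(np.abs(t[outside]))

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            SyntheticConfig(signal_regions=())
        with pytest.raises(ValueError):
            SyntheticConfig(signal_regions=(0,))
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(shape=(6, 24, 24))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_per_class=5, shape=(16, 16, 16), seed=42)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SyntheticConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


def test_regional_profile_recovers_region_means(small_parcellation):
    cfg = SyntheticConfig(n_per_class=1, shape=(16, 16, 16), noise_sd=0.05)
    s = generate_subject(1, cfg, small_parcellation, np.random.default_rng(2))
    prof = regional_profile(s)
    assert prof.shape == (90, 3)
    r = 17
    sel = small_parcellation.labels == r
    assert prof[r - 1, 2] == pytest.approx(float(s.pet[sel].mean()), rel=1e-5)
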