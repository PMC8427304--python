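"""Synthetic cohort generator: trait sampling, photo specs, rendering
and the calibration of planted trait–feature effects."""

import numpy as np
import pandas as pd
import pytest

from phototraits import (
    EMOTIONS,
    PhotoRenderSpec,
    SyntheticCohortConfig,
    extract_pixel_features,
    implied_trait_feature_correlations,
    recode_category,
    render_photo,
    sample_traits,
    simulate_cohort,
    strong_effects,
)
from phototraits.synth import (
    SUBCATEGORY_POOL,
    TRAIT_ORDER,
    sample_channel_levels,
    render_batch,
    render_cohort_images,
)


class TestConfig:
    def test_non_psd_correlation_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 0.8
        bad[0, 2] = bad[2, 0] = 0.8
        bad[1, 2] = bad[2, 1] = -0.8
        with pytest.raises(ValueError):
            SyntheticCohortConfig(trait_corr=bad)

    def test_min_photos_floor(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(photos_per_user=(20, 40))

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(effects=(("charisma", "warm_share", 0.2),))


def test_yaml_config_roundtrip(tmp_path):
    """The shipped example config reproduces the package defaults, and
    partial YAML overrides only what it names."""
    from pathlib import Path

    example = Path(__file__).resolve().parent.parent / "examples/cohort.yaml"
    cfg = SyntheticCohortConfig.from_yaml(example)
    default = SyntheticCohortConfig()
    assert cfg.n_users == default.n_users
    assert cfg.effects == default.effects
    np.testing.assert_allclose(cfg.trait_corr, default.trait_corr)

    partial = tmp_path / "c.yaml"
    partial.write_text("n_users: 12\nphotos_per_user: [30, 31]\n")
    cfg2 = SyntheticCohortConfig.from_yaml(partial)
    assert cfg2.n_users == 12
    assert cfg2.photos_per_user == (30, 31)
    assert cfg2.effects == default.effects


class TestTraits:
    def test_determinism(self):
        cfg = SyntheticCohortConfig(n_users=40)
        a_lat, a_sur = sample_traits(cfg, seed=5)
        b_lat, b_sur = sample_traits(cfg, seed=5)
        pd.testing.assert_frame_equal(a_lat, b_lat)
        pd.testing.assert_frame_equal(a_sur, b_sur)

    def test_latents_bounded_and_total_is_mean(self):
        lat, _ = sample_traits(SyntheticCohortConfig(n_users=200), seed=1)
        for t in TRAIT_ORDER:
            assert lat[t].between(1, 5).all()
        np.testing.assert_allclose(
            lat["loneliness_total"],
            lat[["loneliness_family", "loneliness_social",
                 "loneliness_romantic"]].mean(axis=1), atol=1e-12)

    def test_configured_correlations_recovered(self):
        """At n=5000 the sample trait correlations match the configured
        matrix (clipping is negligible at the default means/sds)."""
        cfg = SyntheticCohortConfig(n_users=5000)
        lat, _ = sample_traits(cfg, seed=3)
        got = lat[list(TRAIT_ORDER)].corr().to_numpy()
        np.testing.assert_allclose(got, cfg.trait_corr, atol=0.05)

    def test_scoring_recovers_latents(self):
        """Scored survey traits track the generating latents closely."""
        from phototraits import score_survey

        cfg = SyntheticCohortConfig(n_users=400, likert_sd=0.3)
        lat, survey = sample_traits(cfg, seed=7)
        scored = score_survey(survey)
        for t in TRAIT_ORDER:
            r = np.corrcoef(lat[t], scored[t])[0, 1]
            assert r > 0.9, (t, r)


class TestRenderSpec:
    def test_from_shares_exact_counts(self):
        spec = PhotoRenderSpec.from_shares(
            {"red": 0.1, "orange": 0.1, "yellow": 0.1, "green": 0.3,
             "blue": 0.3, "violet": 0.1}, size=(10, 10))
        assert sum(spec.color_counts) == 100
        assert spec.warm_share == pytest.approx(0.3)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhotoRenderSpec((4, 4), (16, 0, 0, 0, 0, 1), 50, 200)
        with pytest.raises(ValueError):
            PhotoRenderSpec((4, 4), (16, 0, 0, 0, 0, 0), 0, 200)
        with pytest.raises(ValueError):
            PhotoRenderSpec.from_shares({"red": 0.7}, size=(4, 4))

    def test_render_reproduces_spec_exactly(self):
        spec = PhotoRenderSpec.from_shares(
            {"red": 0.12, "orange": 0.08, "yellow": 0.10, "green": 0.25,
             "blue": 0.25, "violet": 0.20}, size=(20, 20),
            v_lo=90, v_hi=190)
        f = extract_pixel_features(render_photo(spec, seed=4))
        assert f.warm_share == spec.warm_share
        assert f.red_share == spec.color_share["red"]
        assert f.val_var == spec.val_var  # ((190-90)/2)^2
        assert f.val_mean == (190 + 90) / 2

    def test_single_hue_photo(self):
        spec = PhotoRenderSpec.from_shares({"green": 1.0}, size=(8, 8),
                                           v_lo=120, v_hi=120)
        f = extract_pixel_features(render_photo(spec, seed=0))
        assert f.green_share == 1.0
        assert f.warm_share == 0.0
        assert f.val_var == 0.0

    def test_render_determinism(self):
        spec = PhotoRenderSpec.from_shares({"blue": 1.0}, size=(6, 6))
        np.testing.assert_array_equal(render_photo(spec, seed=9),
                                      render_photo(spec, seed=9))


class TestEffects:
    def test_no_effects_implies_zero_correlations(self):
        cfg = SyntheticCohortConfig(effects=())
        assert (implied_trait_feature_correlations(cfg).to_numpy() == 0).all()

    def test_implied_signs_match_configured(self):
        cfg = SyntheticCohortConfig()
        implied = implied_trait_feature_correlations(cfg)
        for trait, ch, beta in cfg.effects:
            assert np.sign(implied.loc[trait, ch]) == np.sign(beta)

    def test_strong_effects_listing(self):
        pairs = strong_effects(SyntheticCohortConfig())
        assert ("narcissism", "people", 1) in pairs
        assert ("loneliness_romantic", "warm_share", -1) in pairs
        assert all(abs(b) >= 0.2 for _, _, b in
                   [(t, f, s) for t, f, s in pairs])

    def test_channel_levels_calibration(self):
        """A single planted effect reproduces its coefficient as the
        latent-level trait–feature correlation."""
        cfg = SyntheticCohortConfig(
            n_users=4000,
            effects=(("narcissism", "val_var", 0.25),))
        lat, _ = sample_traits(cfg, seed=21)
        lev = sample_channel_levels(cfg, lat, seed=21)
        r = np.corrcoef(lat["narcissism"], lev["val_var"])[0, 1]
        assert r == pytest.approx(0.25, abs=0.03)


class TestCohort:
    def test_tables_are_consistent(self, small_cohort):
        c = small_cohort
        assert len(c.manifest) == len(c.specs) == len(c.annotations)
        assert set(c.faces.photo_id) <= set(c.manifest.photo_id)
        assert c.manifest.groupby("user_id").size().min() >= 30
        # every synthetic sub-category recodes into its own category
        for cat, pool in SUBCATEGORY_POOL.items():
            for label in pool:
                assert recode_category(label) == cat

    def test_face_emotions_are_simplex(self, small_cohort):
        em = small_cohort.faces[list(EMOTIONS)].to_numpy()
        if len(em):
            np.testing.assert_allclose(em.sum(axis=1), 1.0, atol=1e-6)
            assert (em >= 0).all() and (em <= 1).all()

    def test_simulation_determinism(self, small_cohort):
        again = simulate_cohort(small_cohort.config, seed=small_cohort.seed)
        pd.testing.assert_frame_equal(small_cohort.manifest, again.manifest)
        pd.testing.assert_frame_equal(small_cohort.faces, again.faces)
        pd.testing.assert_frame_equal(small_cohort.survey, again.survey)
        assert small_cohort.specs == again.specs
        np.testing.assert_array_equal(render_cohort_images(small_cohort),
                                      render_cohort_images(again))

    def test_user_subsets_stable_under_resizing(self):
        """Per-user seeds derive from (master seed, user index), so a
        larger cohort reproduces the smaller one's users verbatim."""
        cfg_small = SyntheticCohortConfig(n_users=4, photos_per_user=(30, 32),
                                          image_size=(16, 16))
        cfg_big = SyntheticCohortConfig(n_users=7, photos_per_user=(30, 32),
                                        image_size=(16, 16))
        a = simulate_cohort(cfg_small, seed=13)
        b = simulate_cohort(cfg_big, seed=13)
        users_a = set(a.manifest.user_id)
        sub = b.manifest[b.manifest.user_id.isin(users_a)].reset_index(
            drop=True)
        pd.testing.assert_frame_equal(a.manifest, sub)

    def test_batch_render_requires_uniform_size(self):
        a = PhotoRenderSpec.from_shares({"red": 1.0}, size=(4, 4))
        b = PhotoRenderSpec.from_shares({"red": 1.0}, size=(6, 6))
        with pytest.raises(ValueError):
            render_batch([a, b], np.random.default_rng(0))
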