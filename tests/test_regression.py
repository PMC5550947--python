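"""Design construction, OLS fitting, cross-validation, coefficient profiles."""
import numpy as np
import pytest

import bbdisp as bb
from bbdisp.basecounts import ConfigError
from bbdisp.regression import (DesignSpec, build_design, coefficient_profile,
                               cross_validated_r2, fit_theta_model)

from conftest import make_obs


class TestDesign:
    def test_indicator_coding_against_reference(self, rng):
        obs = make_obs(10, 2, rng)
        obs.df.loc[0, "context"] = "AG"
        design = build_design(obs, DesignSpec(K=2))
        row = design.X[0]
        cols = dict(zip(design.columns, row))
        assert cols["b1_A"] == 1 and cols["b1_T"] == 0 and cols["b1_C"] == 0
        assert cols["b2_A"] == 0 and cols["b2_T"] == 0 and cols["b2_C"] == 0

    def test_column_counts(self, rng):
        obs = make_obs(300, 80, rng)
        full = build_design(obs, DesignSpec(K=80))
        assert len(full.columns) == 242
        depth_only = build_design(obs, DesignSpec(K=80, include_sequence=False))
        assert depth_only.columns == ["intercept", "log_depth"]

    def test_indicator_row_sums(self, rng):
        """Sequence indicators per row sum to K minus the number of
        reference-base occurrences in the window."""
        K = 10
        obs = make_obs(50, K, rng)
        design = build_design(obs, DesignSpec(K=K, include_depth=False))
        seq_cols = [i for i, c in enumerate(design.columns) if c.startswith("b")]
        sums = design.X[:, seq_cols].sum(axis=1)
        for i in range(50):
            ctx = obs.df.loc[obs.df.index[i], "context"]
            assert sums[i] == K - ctx.count("G")

    def test_missing_and_n_contexts_excluded(self, rng):
        obs = make_obs(20, 4, rng)
        obs.df.loc[3, "context"] = bb.MISSING_CONTEXT
        obs.df.loc[5, "context"] = "ANGT"
        design = build_design(obs, DesignSpec(K=4))
        assert len(design) == 18
        # without sequence terms those rows are kept
        d2 = build_design(obs, DesignSpec(K=4, include_sequence=False))
        assert len(d2) == 20

    def test_context_length_mismatch_is_error(self, rng):
        obs = make_obs(20, 4, rng)
        with pytest.raises(ConfigError):
            build_design(obs, DesignSpec(K=6))

    def test_empty_design_is_error(self, rng):
        obs = make_obs(5, 4, rng)
        obs.df["floored"] = True
        with pytest.raises(ConfigError):
            build_design(obs, DesignSpec(K=4))


class TestFit:
    def test_noise_free_exact_recovery(self, rng):
        beta = {(1, "A"): 0.5, (3, "C"): -0.7}
        obs = make_obs(2000, 4, rng, logD=-2.0, gamma=-0.8, beta=beta,
                       noise_sd=0.0)
        model = fit_theta_model(build_design(obs, DesignSpec(K=4)), "full")
        assert model.logD == pytest.approx(-2.0, abs=1e-8)
        assert model.gamma == pytest.approx(-0.8, abs=1e-8)
        assert model.beta[0, 0] == pytest.approx(0.5, abs=1e-8)   # k=1, A
        assert model.beta[2, 2] == pytest.approx(-0.7, abs=1e-8)  # k=3, C
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_gaussian_noise_recovery(self, rng):
        """gamma recovered within +-0.05 from 50k noisy observations."""
        obs = make_obs(50_000, 4, rng, logD=0.0, gamma=-0.8,
                       beta={(2, "T"): 1.0}, noise_sd=0.3)
        model = fit_theta_model(build_design(obs, DesignSpec(K=4)), "full")
        assert model.gamma == pytest.approx(-0.8, abs=0.05)
        assert model.beta[1, 1] == pytest.approx(1.0, abs=0.05)

    def test_constant_variant_is_mean(self, rng):
        obs = make_obs(500, 4, rng, logD=-3.0, noise_sd=0.5)
        model = fit_theta_model(build_design(
            obs, DesignSpec(K=4, include_depth=False, include_sequence=False)),
            "constant")
        y = np.log(obs.df["theta_hat"])
        assert model.logD == pytest.approx(y.mean(), abs=1e-10)
        assert model.gamma == 0.0 and model.beta is None

    def test_rank_deficiency_flagged(self, rng):
        obs = make_obs(100, 2, rng)
        obs.df["context"] = "AA"  # constant indicators, collinear
        model = fit_theta_model(build_design(obs, DesignSpec(K=2)), "full")
        assert model.rank_deficient

    def test_fewer_rows_than_columns_is_error(self, rng):
        obs = make_obs(5, 6, rng)
        with pytest.raises(ConfigError):
            fit_theta_model(build_design(obs, DesignSpec(K=6)), "full")

    def test_nested_insample_r2_ordering(self, rng):
        obs = make_obs(3000, 4, rng, gamma=-0.8, beta={(1, "A"): 0.3},
                       noise_sd=0.5)
        full = fit_theta_model(build_design(obs, DesignSpec(K=4)), "full")
        pf = fit_theta_model(build_design(obs, DesignSpec(K=4)), "primer_free")
        assert full.r_squared >= pf.r_squared - 1e-12

    def test_variant_constraints_enforced(self):
        with pytest.raises(ConfigError):
            bb.OverdispersionModel(variant="primer_free", logD=0.0,
                                   beta=np.ones((4, 3)), K=4)
        with pytest.raises(ConfigError):
            bb.OverdispersionModel(variant="constant", logD=0.0, gamma=-1.0)


class TestCrossValidation:
    def test_noise_free_r2_is_one(self, rng):
        obs = make_obs(800, 4, rng, gamma=-1.0, noise_sd=0.0)
        cv = cross_validated_r2(obs, DesignSpec(K=4), "primer_free", seed=0)
        assert cv.r_squared == pytest.approx(1.0, abs=1e-8)
        assert cv.r_squared_pred == pytest.approx(1.0, abs=1e-8)
        assert len(cv.per_round) == 50

    def test_deterministic_given_seed(self, rng):
        obs = make_obs(1000, 4, rng, gamma=-1.0, noise_sd=0.5)
        a = cross_validated_r2(obs, DesignSpec(K=4), "primer_free", seed=11)
        b = cross_validated_r2(obs, DesignSpec(K=4), "primer_free", seed=11)
        np.testing.assert_array_equal(a.per_round, b.per_round)

    def test_pure_noise_r2_near_zero(self, rng):
        obs = make_obs(100_000, 2, rng, gamma=0.0, noise_sd=1.0)
        cv = cross_validated_r2(obs, DesignSpec(K=2, include_sequence=False),
                                "primer_free", seed=3)
        assert abs(cv.r_squared_pred) < 0.02
        assert abs(cv.r_squared) < 0.02

    def test_known_population_r2(self, rng):
        """Signal and noise variances matched so the population R^2 is 0.5."""
        obs = make_obs(20_000, 2, rng, gamma=1.0, noise_sd=1.0,
                       depth_median=np.e, depth_sigma=1.0)
        cv = cross_validated_r2(obs, DesignSpec(K=2, include_sequence=False),
                                "primer_free", seed=5)
        assert cv.r_squared_pred == pytest.approx(0.5, abs=0.03)
        assert cv.r_squared == pytest.approx(0.5, abs=0.03)

    def test_full_no_better_than_primer_free_when_beta_zero(self, rng):
        """With no true sequence effect the full model's CV R^2 cannot beat
        the depth-only model by more than noise (confounding restated)."""
        obs = make_obs(8000, 4, rng, gamma=-0.8, noise_sd=0.5)
        full = cross_validated_r2(obs, DesignSpec(K=4), "full", seed=7)
        pf = cross_validated_r2(obs, DesignSpec(K=4), "primer_free", seed=7)
        assert full.r_squared_pred <= pf.r_squared_pred + 0.01

    def test_insufficient_rows_error(self, rng):
        obs = make_obs(20, 4, rng)
        with pytest.raises(ConfigError):
            cross_validated_r2(obs, DesignSpec(K=4), "full", seed=1)


class TestCoefficientProfile:
    def test_offsets_and_row_count(self):
        model = bb.OverdispersionModel(variant="depth_free", logD=0.0,
                                       beta=np.zeros((80, 3)), K=80)
        prof = coefficient_profile(model)
        assert len(prof) == 240
        offs = sorted(prof["offset"].unique())
        assert offs == [o for o in range(-40, 41) if o != 0]
        assert (prof["coefficient"] == 0).all()

    def test_planted_effect_recovered_at_offset(self, rng):
        # K=6: offset +1 is window index k=4
        obs = make_obs(20_000, 6, rng, gamma=-0.5, beta={(4, "A"): 1.0},
                       noise_sd=0.3)
        model = fit_theta_model(build_design(obs, DesignSpec(K=6)), "full")
        prof = coefficient_profile(model)
        cell = prof[(prof.offset == 1) & (prof.base == "A")]["coefficient"].iloc[0]
        assert cell > 0.8

    def test_primer_free_has_no_profile(self):
        model = bb.OverdispersionModel(variant="primer_free", logD=0.0, gamma=-1.0)
        with pytest.raises(ConfigError):
            coefficient_profile(model)

    def test_tsv_roundtrip(self, tmp_path, rng):
        obs = make_obs(2000, 4, rng, gamma=-0.8, beta={(1, "A"): 0.4},
                       noise_sd=0.1)
        model = fit_theta_model(build_design(obs, DesignSpec(K=4)), "full",
                                strand="antisense")
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = bb.OverdispersionModel.from_tsv(path)
        assert back.variant == "full" and back.strand == "antisense"
        assert back.logD == pytest.approx(model.logD, rel=1e-9)
        assert back.gamma == pytest.approx(model.gamma, rel=1e-9)
        np.testing.assert_allclose(back.beta, model.beta, rtol=1e-9)


class TestStrandIndependence:
    def test_fits_on_one_strand_ignore_the_other(self, rng):
        obs_s = make_obs(1000, 4, rng, gamma=-0.8, noise_sd=0.3, strand="sense")
        obs_a = make_obs(1000, 4, rng, gamma=-0.2, noise_sd=0.3,
                         strand="antisense")
        import pandas as pd
        both = bb.ThetaObservations(pd.concat([obs_s.df, obs_a.df],
                                              ignore_index=True))
        m1 = fit_theta_model(build_design(both.subset_strand("sense"),
                                          DesignSpec(K=4)), "primer_free")
        # permute the antisense responses; the sense fit must not move
        both.df.loc[both.df.strand == "antisense", "theta_hat"] = \
            rng.permutation(both.df.loc[both.df.strand == "antisense",
                                        "theta_hat"].to_numpy())
        m2 = fit_theta_model(build_design(both.subset_strand("sense"),
                                          DesignSpec(K=4)), "primer_free")
        assert m1.gamma == m2.gamma and m1.logD == m2.logD
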