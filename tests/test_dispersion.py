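"""Moment estimation of the overdispersion rate and its diagnostics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bbdisp as bb
from bbdisp.basecounts import EstimationError
from bbdisp.dispersion import ThetaObservations, build_theta_observations


def _pc(gene, n, m, strand="sense", ctx=None):
    n = np.asarray(n)
    ctx = np.full(len(n), bb.MISSING_CONTEXT) if ctx is None else np.asarray(ctx)
    return bb.PairedCounts(gene, strand, np.arange(len(n)), n, m, ctx)


class TestProportions:
    def test_neutral_proportion_direct_ratio(self):
        pcs = [_pc("g1", [100, 200], [300, 400])]
        assert bb.neutral_proportion(pcs) == pytest.approx(300 / 1000)

    def test_neutral_proportion_identical_samples(self):
        pcs = [_pc("g1", [5, 7], [5, 7])]
        assert bb.neutral_proportion(pcs) == pytest.approx(0.5)

    def test_neutral_proportion_zero_total_raises(self):
        with pytest.raises(EstimationError):
            bb.neutral_proportion([_pc("g1", [0], [0])])

    @pytest.mark.parametrize("n,m,expected", [
        ([5, 5], [10, 0], 0.5),
        ([0, 0], [1, 2], 0.0),
        ([1], [3], 0.25),
    ])
    def test_gene_proportion(self, n, m, expected):
        assert bb.gene_proportion(_pc("g", n, m)) == pytest.approx(expected)

    def test_gene_proportion_all_zero_is_nan(self):
        assert np.isnan(bb.gene_proportion(_pc("g", [0, 0], [0, 0])))


class TestEstimateTheta:
    def test_hand_arithmetic_single_pair(self):
        # n=8, m=2, p_nr=0.5: sigma=0.09, A=0.36 -> (0.36-0.1)/(1-0.36)
        theta, valid = bb.estimate_theta([[8]], [[2]], [0.5])
        assert valid
        assert theta == pytest.approx(0.40625, abs=1e-12)

    def test_zero_deviation_gives_negative_estimate(self):
        theta, valid = bb.estimate_theta([[5]], [[5]], [0.5])
        assert valid
        assert theta == pytest.approx(-0.1, abs=1e-12)

    def test_invalid_when_denominator_nonpositive(self):
        # sigma/(pq) = (1-0.5)^2/0.25 = 1 -> denominator 0
        theta, valid = bb.estimate_theta([[4]], [[0]], [0.5])
        assert not valid

    def test_swap_invariance(self, rng):
        n = rng.integers(1, 30, (4, 50))
        m = rng.integers(1, 30, (4, 50))
        p = rng.uniform(0.3, 0.7, 4)
        t1, v1 = bb.estimate_theta(n, m, p)
        t2, v2 = bb.estimate_theta(m, n, 1.0 - p)
        np.testing.assert_allclose(t1[v1], t2[v1], rtol=1e-12)

    def test_binomial_null_mean_near_zero(self, rng):
        """theta = 0 truth: the mean estimate converges to zero (the ratio
        estimator's Jensen bias, ~2/t^2 per pair, is negligible at depth
        500)."""
        t = 500
        N = 20000
        n = rng.binomial(t, 0.5, (1, N))
        theta, valid = bb.estimate_theta(n, t - n, [0.5])
        est = theta[valid]
        se = est.std() / np.sqrt(len(est))
        assert abs(est.mean()) < 3 * se + 1e-4

    def test_monte_carlo_consistency(self, rng):
        """Mean of the moment estimate over many positions approaches the
        generating theta (depth 200, theta 0.05, 5 replicate pairs; with a
        single pair the estimator's Jensen bias is ~ +15%)."""
        N = 10000
        R = 5
        t = np.full((R, N), 200)
        n = np.stack([bb.draw_beta_binomial(rng, t[r], 0.5, 0.05)
                      for r in range(R)])
        theta, valid = bb.estimate_theta(n, t - n, np.full(R, 0.5))
        assert theta[valid].mean() == pytest.approx(0.05, rel=0.10)

    def test_zero_depth_pair_raises(self):
        with pytest.raises(EstimationError):
            bb.estimate_theta([[0]], [[0]], [0.5])


class TestBuildObservations:
    def test_flooring_contract_and_flags(self):
        pairs = {("a", "b"): [_pc("g1", [5, 8], [5, 2])]}
        obs = build_theta_observations(pairs, {("a", "b"): 0.5},
                                       bb.FilterConfig(min_depth=1), floor=1e-6)
        df = obs.df.set_index("position")
        assert df.loc[0, "floored"] and df.loc[0, "theta_hat"] == 1e-6
        assert not df.loc[1, "floored"]
        assert df.loc[1, "theta_hat"] == pytest.approx(0.40625)

    def test_min_depth_filters_positions(self):
        pairs = {("a", "b"): [_pc("g1", [5, 1], [5, 1])]}
        obs = build_theta_observations(pairs, {("a", "b"): 0.5},
                                       bb.FilterConfig(min_depth=5))
        assert obs.df["position"].tolist() == [0]

    def test_record_count_matches_simulator_bookkeeping(self, replicate_sim):
        sim = replicate_sim
        pairs = bb.replicate_pairs(sim.sample_ids)
        paired = {pr: bb.build_pairs(sim.counts, sim.genes, *pr, K=8)
                  for pr in pairs}
        p_nr = {pr: bb.neutral_proportion(paired[pr]) for pr in pairs}
        cfg = bb.FilterConfig(min_depth=5)
        obs = build_theta_observations(paired, p_nr, cfg)
        # expected: positions where every pair reaches min_depth
        expected = 0
        for pr in pairs[:1]:
            for pc in paired[pr]:
                T = np.stack([q.depth for qr in pairs
                              for q in paired[qr] if q.gene_id == pc.gene_id])
                expected += int((T >= 5).all(axis=0).sum())
        assert len(obs) == expected

    def test_tsv_roundtrip(self, tmp_path, replicate_sim):
        sim = replicate_sim
        pairs = bb.replicate_pairs(sim.sample_ids)[:1]
        paired = {pr: bb.build_pairs(sim.counts, sim.genes, *pr, K=8)
                  for pr in pairs}
        p_nr = {pr: bb.neutral_proportion(paired[pr]) for pr in pairs}
        obs = build_theta_observations(paired, p_nr, bb.FilterConfig(min_depth=5))
        path = tmp_path / "obs.tsv"
        obs.to_tsv(path)
        back = ThetaObservations.from_tsv(path)
        np.testing.assert_allclose(back.df["theta_hat"], obs.df["theta_hat"])
        assert (back.df["context"] == obs.df["context"]).all()


class TestDepthProfile:
    def _obs_from_sim(self, sim, K=8):
        pairs = bb.replicate_pairs(sim.sample_ids)
        paired = {pr: bb.build_pairs(sim.counts, sim.genes, *pr, K=K)
                  for pr in pairs}
        p_nr = {pr: bb.neutral_proportion(paired[pr]) for pr in pairs}
        return build_theta_observations(paired, p_nr, bb.FilterConfig(min_depth=5))

    def test_slope_recovers_depth_exponent(self, replicate_sim):
        """theta ~ D * t^gamma with gamma=-1: the binned mean log10 theta
        against log10 depth has slope close to -1."""
        obs = self._obs_from_sim(replicate_sim)
        prof = bb.depth_dispersion_profile(obs, n_bins=12)
        ok = prof["count"] > 50
        slope = np.polyfit(prof["bin_mid_log10_depth"][ok],
                           prof["mean_log10_theta"][ok], 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_flat_profile_when_theta_constant(self, rng):
        df = pd.DataFrame({
            "gene_id": "g1", "position": np.arange(500), "strand": "sense",
            "theta_hat": 0.05, "depth": np.exp(rng.uniform(1, 5, 500)),
            "context": bb.MISSING_CONTEXT, "floored": False, "invalid": False})
        prof = bb.depth_dispersion_profile(ThetaObservations(df), n_bins=5)
        assert prof["mean_log10_theta"].std() == pytest.approx(0.0, abs=1e-12)

    def test_motif_columns_empty_without_error(self, rng):
        df = pd.DataFrame({
            "gene_id": "g1", "position": np.arange(50), "strand": "sense",
            "theta_hat": 0.05, "depth": 100.0,
            "context": bb.MISSING_CONTEXT, "floored": False, "invalid": False})
        prof = bb.depth_dispersion_profile(ThetaObservations(df), n_bins=2)
        assert prof["count_gggg"].sum() == 0

    def test_too_few_bins_rejected(self, replicate_sim):
        obs = self._obs_from_sim(replicate_sim)
        with pytest.raises(ValueError):
            bb.depth_dispersion_profile(obs, n_bins=1)


class TestPositionalProfile:
    def _obs(self, theta, L, gene="g1"):
        return ThetaObservations(pd.DataFrame({
            "gene_id": gene, "position": np.arange(L), "strand": "sense",
            "theta_hat": theta, "depth": 50.0, "context": bb.MISSING_CONTEXT,
            "floored": False, "invalid": False}))

    def test_tail_inflated_dispersion_orders_parts(self):
        cfg = bb.SimulationConfig(seed=9, G=30, gene_length=500,
                                  median_depth=100.0, variant="constant",
                                  D=0.05, tail_inflation=3.0, tail_length=200,
                                  K=4)
        sim = bb.simulate_replicates(cfg, 3)
        pairs = bb.replicate_pairs(sim.sample_ids)
        paired = {pr: bb.build_pairs(sim.counts, sim.genes, *pr, K=4)
                  for pr in pairs}
        p_nr = {pr: bb.neutral_proportion(paired[pr]) for pr in pairs}
        obs = build_theta_observations(paired, p_nr, bb.FilterConfig(min_depth=5))
        prof = bb.positional_profile(obs, sim.genes, n_parts=10)
        assert prof.loc[0, "mean_theta"] > prof.loc[9, "mean_theta"]

    def test_uniform_theta_has_no_trend(self, rng):
        L = 2000
        obs = self._obs(rng.lognormal(-3, 0.2, L), L)
        genes = {"g1": bb.GeneModel("g1", length=L)}
        prof = bb.positional_profile(obs, genes, n_parts=10)
        fit = stats.linregress(prof["part"], prof["mean_theta"])
        ci = 2 * fit.stderr
        assert abs(fit.slope) < ci + 1e-9

    def test_single_part_is_overall_mean(self, rng):
        theta = rng.uniform(0.01, 0.1, 100)
        obs = self._obs(theta, 100)
        genes = {"g1": bb.GeneModel("g1", length=100)}
        prof = bb.positional_profile(obs, genes, n_parts=1)
        assert prof.loc[0, "mean_theta"] == pytest.approx(theta.mean())

    def test_fewer_positions_than_parts_raises(self, rng):
        obs = self._obs(np.full(5, 0.05), 5)
        with pytest.raises(EstimationError):
            bb.positional_profile(obs, {"g1": bb.GeneModel("g1", length=5)},
                                  n_parts=10)
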