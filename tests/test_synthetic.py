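"""Generator correctness: documented randomness contract, stationarity,
founder effects, bookkeeping of colony/pedigree/matrix layouts."""

import math

import numpy as np
import pandas as pd
import pytest

from tagen import (ColonyModel, ConfigurationError, ParameterError,
                   TelegraphParams, make_telegraph_population,
                   simulate_colonies, simulate_expression_matrix,
                   simulate_flow_events, simulate_pedigree, telegraph_moments)
from tagen.flow import gate_events


class TestTelegraphParams:
    def test_rejects_nonfinite_and_negative(self):
        with pytest.raises(ParameterError):
            TelegraphParams(k_on=float("nan"))
        with pytest.raises(ParameterError):
            TelegraphParams(cv_intrinsic=-0.1)
        with pytest.raises(ParameterError):
            TelegraphParams(mu_on=5.0, mu_off=5.0)

    def test_zero_rates_while_toggling_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            TelegraphParams(k_on=0.0, k_off=0.0, lock_mode="toggling")

    def test_stationary_probability(self):
        assert TelegraphParams(k_on=1.0, k_off=3.0).p_active == 0.25
        assert TelegraphParams(lock_mode="locked_on").p_active == 1.0
        assert TelegraphParams(lock_mode="locked_off").p_active == 0.0


class TestMakeTelegraphPopulation:
    def test_all_noise_off_gives_constant_intensity(self, noiseless_on):
        cells = make_telegraph_population(noiseless_on, 50, seed=0)
        assert np.all(cells["channel1_intensity"] == 100.0)
        assert (cells["true_state"] == "active").all()

    def test_symmetric_rates_give_half_active(self):
        params = TelegraphParams(k_on=0.2, k_off=0.2)
        cells = make_telegraph_population(params, 100_000, seed=1)
        frac = (cells["true_state"] == "active").mean()
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 100_000)

    def test_stationary_fraction_matches_rates(self):
        params = TelegraphParams(k_on=0.3, k_off=0.1)
        cells = make_telegraph_population(params, 100_000, seed=2)
        p = 0.3 / 0.4
        frac = (cells["true_state"] == "active").mean()
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 100_000)

    def test_deterministic_given_seed(self, default_params):
        a = make_telegraph_population(default_params, 500, seed=9, n_alleles=2)
        b = make_telegraph_population(default_params, 500, seed=9, n_alleles=2)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_first_principles_rederivation(self, default_params):
        """Re-derive intensities from the documented draw order; the
        population CV (and every intensity) must agree to 1e-12."""
        p = default_params
        n = 10_000
        cells = make_telegraph_population(p, n, seed=123)

        rng = np.random.default_rng(123)
        u = rng.random(n)
        states = u < p.k_on / (p.k_on + p.k_off)
        sig_e = p.sigma_extrinsic
        extrinsic = np.exp(sig_e * rng.standard_normal(n) - 0.5 * sig_e**2)
        s_i = math.sqrt(math.log1p(p.cv_intrinsic**2))
        intrinsic = np.exp(s_i * rng.standard_normal((n, 1)) - 0.5 * s_i**2)
        signal = extrinsic[:, None] * np.where(states, p.mu_on, p.mu_off)[:, None] * intrinsic
        pop_mean = 0.5 * (p.mu_on + p.mu_off)
        meas = p.cv_measurement * pop_mean * rng.standard_normal((n, 1))
        expected = np.clip(signal + meas, 0.0, None)[:, 0]

        got = cells["channel1_intensity"].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)
        cv_expected = expected.std(ddof=1) / expected.mean()
        cv_got = got.std(ddof=1) / got.mean()
        assert abs(cv_got - cv_expected) < 1e-12

    def test_two_allele_mode_shares_state_and_extrinsic(self, two_channel_cells):
        # shared extrinsic factor + state => positive inter-channel covariance
        g = two_channel_cells["channel1_intensity"]
        r = two_channel_cells["channel2_intensity"]
        assert np.corrcoef(g, r)[0, 1] > 0.5

    def test_toggling_noisier_than_either_locked_state(self):
        base = dict(k_on=0.1, k_off=0.1, mu_on=100.0, mu_off=5.0,
                    cv_intrinsic=0.1, sigma_extrinsic=0.1, cv_measurement=0.05)
        cvs = {}
        for mode in ("toggling", "locked_on", "locked_off"):
            cells = make_telegraph_population(
                TelegraphParams(lock_mode=mode, **base), 20_000, seed=5)
            x = cells["channel1_intensity"]
            cvs[mode] = x.std(ddof=1) / x.mean()
        assert cvs["toggling"] > cvs["locked_on"]
        assert cvs["toggling"] > cvs["locked_off"]

    def test_closed_form_moments_match_simulation(self, default_params):
        m = telegraph_moments(default_params)
        cells = make_telegraph_population(default_params, 200_000, seed=11)
        x = cells["channel1_intensity"]
        assert x.mean() == pytest.approx(m.mean, rel=0.02)
        assert x.std(ddof=1) / x.mean() == pytest.approx(m.cv, rel=0.03)


class TestSimulateColonies:
    def test_no_switching_preserves_founder_state(self, default_params):
        cm = ColonyModel(n_colonies=8, cells_per_colony=64, generations=6,
                         p_switch_per_division=0.0)
        cells = simulate_colonies(default_params, cm, seed=3)
        per_colony = cells.groupby("colony_id")["true_state"].nunique()
        assert (per_colony == 1).all()

    def test_bookkeeping_six_colonies(self, default_params):
        cm = ColonyModel(n_colonies=6, cells_per_colony=100, generations=8,
                         n_regions_per_colony=2)
        cells = simulate_colonies(default_params, cm, seed=4)
        sizes = cells.groupby("colony_id").size()
        assert len(sizes) == 6 and (sizes == 100).all()
        assert cells.groupby("colony_id")["region_id"].nunique().eq(2).all()

    def test_fast_switching_shrinks_between_colony_variance(self, default_params):
        def colony_mean_var(p_switch, seed):
            cm = ColonyModel(n_colonies=50, cells_per_colony=128, generations=8,
                             p_switch_per_division=p_switch)
            cells = simulate_colonies(default_params, cm, seed=seed)
            return cells.groupby("colony_id")["channel1_intensity"].mean().var(ddof=1)

        assert colony_mean_var(0.5, 10) < colony_mean_var(0.01, 10)

    def test_too_few_cells_for_regions_rejected(self):
        with pytest.raises(ConfigurationError):
            ColonyModel(cells_per_colony=2, n_regions_per_colony=3)


class TestSimulatePedigree:
    def test_bookkeeping(self, default_params):
        cells = simulate_pedigree(default_params, n_pairs=10,
                                  cells_per_population=50, seed=6)
        assert cells["population_id"].nunique() == 20
        assert cells.groupby("population_id").size().eq(50).all()
        assert set(cells["role"]) == {"mother", "daughter"}

    def test_single_pair_rejected(self, default_params):
        with pytest.raises(ConfigurationError):
            simulate_pedigree(default_params, n_pairs=1, seed=0)

    def test_no_switching_no_noise_pairs_identical_means(self, noiseless_on):
        cells = simulate_pedigree(noiseless_on, n_pairs=4,
                                  p_switch_per_division=0.0, seed=7)
        means = cells.groupby("population_id")["channel1_intensity"].mean()
        assert np.allclose(means, 100.0)

    def test_true_pairs_more_similar_than_shuffled(self, default_params):
        """Heritable regime: the mean |difference in mean ln expression| over
        true pairs is below that over label-shuffled pairs (Monte Carlo)."""
        rng = np.random.default_rng(0)
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            cells = simulate_pedigree(default_params, n_pairs=10,
                                      p_switch_per_division=0.02,
                                      generations=10, seed=1000 + rep)
            ln = cells.assign(ln=np.log(cells["channel1_intensity"]
                                        .clip(lower=1e-9)))
            means = ln.groupby("population_id")["ln"].mean()
            m = means[[f"pair{i:02d}_mother" for i in range(10)]].to_numpy()
            d = means[[f"pair{i:02d}_daughter" for i in range(10)]].to_numpy()
            true_stat = np.abs(m - d).mean()
            shuf = np.abs(m - d[rng.permutation(10)]).mean()
            wins += true_stat < shuf
        assert wins > 0.75 * n_rep


class TestSimulateExpressionMatrix:
    def test_layout_160_genes_8_arms(self, default_params):
        matrix, pos = simulate_expression_matrix({1: default_params}, 160,
                                                 n_conditions=3, seed=8)
        assert matrix.shape == (160, 6)
        assert pos["telomere_rank"].value_counts().eq(8).all()
        assert pos["telomere_rank"].max() == 20

    def test_rank_ordering_of_cv(self, default_params):
        slow = default_params
        fast = TelegraphParams(k_on=0.5, k_off=0.5, mu_on=100.0, mu_off=5.0,
                               cv_intrinsic=0.1, sigma_extrinsic=0.1,
                               cv_measurement=0.1)
        from tagen import gene_condition_cv

        matrix, pos = simulate_expression_matrix({1: slow, 4: fast}, 320, seed=9)
        cvs = gene_condition_cv(matrix)["mean_cv"]
        merged = pos.set_index("gene_id").join(cvs)
        rank_mean = merged.groupby("telomere_rank")["mean_cv"].mean()
        assert rank_mean.loc[1] > rank_mean.loc[8]

    def test_empty_rank_params_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_expression_matrix({}, 10, seed=0)


class TestSimulateFlowEvents:
    def test_no_debris_all_events_gated(self, default_params):
        events = simulate_flow_events(default_params, n_events=5_000,
                                      frac_debris=0.0, seed=10)
        assert len(gate_events(events)) == 5_000

    def test_debris_fraction_removed(self, default_params):
        n = 100_000
        events = simulate_flow_events(default_params, n_events=n,
                                      frac_debris=0.1, seed=11)
        frac = len(gate_events(events)) / n
        assert abs(frac - 0.9) < 3 * math.sqrt(0.09 / n)

    def test_locked_noiseless_fl1_constant(self, noiseless_on):
        events = simulate_flow_events(noiseless_on, n_events=200,
                                      frac_debris=0.0, seed=12)
        assert np.all(events["fl1"] == 100.0)

    def test_invalid_debris_fraction(self, default_params):
        with pytest.raises(ParameterError):
            simulate_flow_events(default_params, 100, frac_debris=1.5, seed=0)
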