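"""Transition enumeration, dwell MLE, CHESS, thermodynamics, statistics."""

import numpy as np
import pytest
from scipy import stats

from hexkin import kinetics as K
from hexkin.hmm import IdealizedTrace, MonomerCalibration

MEANS = np.array([20.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0])


def ideal_from_states(states, trace_id=0, video_id=0):
    states = np.asarray(states, int)
    return IdealizedTrace(states=states, idealized_photons=MEANS[states],
                          residuals=np.zeros(len(states)), loglik=0.0,
                          converged=True, trace_id=trace_id,
                          video_id=video_id)


class TestExtractTransitions:
    def test_constant_trace_has_no_transitions(self):
        recs, clusters = K.extract_transitions([ideal_from_states([2] * 50)])
        assert recs == [] and clusters == {}

    def test_fixture_enumeration(self):
        # S1 x10, S2 x20, S4 x5, S2 x7 frames
        states = [1] * 10 + [2] * 20 + [4] * 5 + [2] * 7
        recs, clusters = K.extract_transitions([ideal_from_states(states)])
        keys = [(r.state_before, r.state_after) for r in recs]
        assert keys == [(1, 2), (2, 4), (4, 2)]
        # first segment censored: S1 dwell not usable for rates
        assert recs[0].censored_entry
        assert clusters[(1, 2)].dwells.size == 0
        assert clusters[(1, 2)].density == 1
        np.testing.assert_allclose(clusters[(2, 4)].dwells, [3.0])
        np.testing.assert_allclose(clusters[(4, 2)].dwells, [0.75])

    def test_background_transitions_excluded(self):
        states = [1] * 10 + [0] * 10 + [2] * 10 + [3] * 10
        recs, clusters = K.extract_transitions([ideal_from_states(states)])
        assert [(r.state_before, r.state_after) for r in recs] == [(2, 3)]

    def test_photon_levels_recorded(self):
        recs, _ = K.extract_transitions([ideal_from_states([1] * 20 + [2] * 20)])
        assert recs[0].photon_before == 50.0
        assert recs[0].photon_after == 100.0


class TestDwellFit:
    def test_mle_is_inverse_mean(self):
        c = K.DwellCluster((2, 1), np.array([1.0, 1.0, 1.0]),
                           np.zeros(3, int), density=3)
        fit = K.fit_dwell(c)
        assert fit.rate == pytest.approx(1.0)

    def test_consistency_against_exponential_sample(self):
        rng = np.random.default_rng(20)
        d = rng.exponential(5.0, 10_000)  # true rate 0.2 /s
        d = d[d <= 75.0]
        c = K.DwellCluster((2, 1), d, np.zeros(len(d), int), density=len(d))
        fit = K.fit_dwell(c, seed=1)
        assert abs(fit.rate - 0.2) < 3 * fit.bootstrap_se

    def test_cutoff_excludes_long_dwells(self):
        c = K.DwellCluster((2, 1), np.array([2.0, 100.0]),
                           np.zeros(2, int), density=2)
        fit = K.fit_dwell(c)
        assert not fit.defined  # one retained dwell is not fittable
        assert fit.n_excluded == 1

    def test_low_n_flag(self):
        c = K.DwellCluster((2, 1), np.full(6, 2.0), np.zeros(6, int),
                           density=6)
        assert K.fit_dwell(c).low_n_flag

    def test_per_cluster_rates_report_total_exit(self):
        # two competing channels: each cluster's dwell sample follows the
        # total-exit exponential; the corrected rates split it by counts
        rng = np.random.default_rng(21)
        k_a, k_b = 0.3, 0.1
        total = k_a + k_b
        n = 5000
        dwells = rng.exponential(1 / total, n)
        channel = rng.random(n) < k_a / total
        clusters = {
            (2, 3): K.DwellCluster((2, 3), dwells[channel],
                                   np.zeros(channel.sum(), int),
                                   density=int(channel.sum())),
            (2, 1): K.DwellCluster((2, 1), dwells[~channel],
                                   np.zeros((~channel).sum(), int),
                                   density=int((~channel).sum())),
        }
        for c in clusters.values():
            fit = K.fit_dwell(c, seed=2)
            assert fit.rate == pytest.approx(total, rel=0.1)
        corrected = K.competing_risks_rates(clusters)
        assert corrected[(2, 3)] == pytest.approx(k_a, rel=0.1)
        assert corrected[(2, 1)] == pytest.approx(k_b, rel=0.1)
        assert sum(corrected.values()) == pytest.approx(total, rel=0.1)


class TestSolutionComposition:
    CAL = MonomerCalibration(mu=46.0, sigma=16.0, n_particles=100)

    def test_pure_monomer_steps(self):
        rng = np.random.default_rng(22)
        steps = rng.normal(46, 16, 500)
        comp = K.estimate_solution_composition(steps, self.CAL, 10e-9)
        assert comp.weights[1] > 0.99
        assert comp.concentrations[1] == pytest.approx(10e-9, rel=0.02)

    def test_weight_recovery(self):
        rng = np.random.default_rng(23)
        w_true = np.array([0.8, 0.15, 0.03, 0.015, 0.005])
        comp_idx = rng.choice(5, size=20_000, p=w_true)
        m = comp_idx + 1
        steps = rng.normal(m * 46.0, np.sqrt(m) * 16.0)
        comp = K.estimate_solution_composition(steps, self.CAL, 10e-9)
        for i, w in enumerate(w_true, start=1):
            se = np.sqrt(w * (1 - w) / 20_000)
            assert abs(comp.weights[i] - w) < max(3 * se, 0.01)

    def test_monomer_equivalent_conservation(self):
        # w = (0.5, 0.5, 0, 0, 0) at 10 nM: C_N = 10/1.5 nM, c1 = c2 = 3.33 nM
        comp = K.SolutionComposition(
            weights={1: 0.5, 2: 0.5, 3: 0.0, 4: 0.0, 5: 0.0},
            concentrations={1: 10e-9 / 3, 2: 10e-9 / 3, 3: 0.0, 4: 0.0, 5: 0.0},
            total_monomer_equiv=10e-9)
        total = sum(m * c for m, c in comp.concentrations.items())
        assert total == pytest.approx(10e-9)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            K.estimate_solution_composition(np.full(50, 46.0), self.CAL, 1e-8)


def monomer_composition(c1=1e-9):
    return K.SolutionComposition(
        weights={1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        concentrations={1: c1, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        total_monomer_equiv=c1)


class TestChess:
    def test_assembly_rate_divided_by_concentration(self):
        # decay 0.01 /s with added species at 1 nM -> 1e7 /M/s
        rng = np.random.default_rng(24)
        d = rng.exponential(100.0, 5000)
        d = d[d <= 75.0]
        # large-sample MLE of the truncated sample, then exact arithmetic
        c = K.DwellCluster((1, 2), d, np.zeros(len(d), int), density=len(d))
        fit = K.fit_dwell(c)
        chess = K.build_chess({(1, 2): c}, monomer_composition(1e-9))
        row = chess.iloc[0]
        assert row["rate_constant"] == pytest.approx(fit.rate / 1e-9)
        assert row["kind"] == "assembly"

    def test_low_n_triangle_flag(self):
        c = K.DwellCluster((2, 1), np.full(6, 1.0), np.zeros(6, int), density=6)
        chess = K.build_chess({(2, 1): c}, monomer_composition())
        assert bool(chess.iloc[0]["low_n_flag"])

    def test_missing_species_concentration_flagged(self):
        c = K.DwellCluster((2, 4), np.full(20, 1.0), np.zeros(20, int),
                           density=20)
        chess = K.build_chess({(2, 4): c}, monomer_composition())
        assert bool(chess.iloc[0]["unconvertible"])

    def test_density_conservation_exact(self, kinetics_recovery):
        _, records, clusters, chess = kinetics_recovery
        assert int(chess["density"].sum()) == len(records)

    def test_full_recovery_of_planted_constants(self, kinetics_recovery):
        from conftest import KIN_K12, KIN_K21

        _, _, _, chess = kinetics_recovery
        by_key = {(r.state_before, r.state_after): r for r in chess.itertuples()}
        up, down = by_key[(1, 2)], by_key[(2, 1)]
        assert up.n_dwells >= 1500 and down.n_dwells >= 1500
        assert up.rate_constant == pytest.approx(KIN_K12, rel=0.10)
        assert down.rate_constant == pytest.approx(KIN_K21, rel=0.10)


class TestOccupancy:
    def test_single_state(self):
        rng = np.random.default_rng(25)
        x = rng.normal(50, 25, 4000)
        occ, _ = K.occupancy(x, n_boot=2, seed=0)
        assert occ[1] > 0.99
        assert occ.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_state_even_split(self):
        rng = np.random.default_rng(26)
        x = np.concatenate([rng.normal(50, 25, 5000),
                            rng.normal(100, 35, 5000)])
        occ, err = K.occupancy(x, n_boot=5, seed=1)
        se = np.sqrt(0.25 / 10_000)
        assert abs(occ[1] - 0.5) < max(3 * err[1], 5 * se)
        assert abs(occ[2] - 0.5) < max(3 * err[2], 5 * se)


class TestThermodynamics:
    def test_unit_equilibrium_zero_energy(self):
        assert K.free_energy(1.0) == 0.0

    def test_printed_equilibrium_case(self):
        # K = 0.96e8 /M at 298 K -> about -45.5 kJ/mol
        dg = K.free_energy(K.equilibrium_constant(0.96e8, 1.0))
        assert dg / 1e3 == pytest.approx(-45.5, abs=0.1)

    def test_activation_energy_identities(self):
        c = K.CONSTANTS
        k_ref = c.k_B * c.T / c.h
        assert K.activation_energy(k_ref) == pytest.approx(0.0, abs=1e-9)
        assert K.activation_energy(1.0) / 1e3 == pytest.approx(73.0, abs=0.1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            K.equilibrium_constant(0.0, 1.0)
        with pytest.raises(ValueError):
            K.free_energy(-1.0)
        with pytest.raises(ValueError):
            K.activation_energy(0.0)


class TestStatistics:
    def test_identical_groups_not_significant(self):
        t, p, stars = K.compare_conditions(1.0, 0.2, 5, 1.0, 0.2, 5)
        assert t == 0.0 and p == pytest.approx(1.0) and stars == ""

    def test_welch_matches_direct_formula(self):
        m1, s1, n1 = 10.0, 2.0, 5
        m2, s2, n2 = 12.0, 3.0, 5
        t, p, _ = K.compare_conditions(m1, s1, n1, m2, s2, n2)
        v1, v2 = s1**2 / n1, s2**2 / n2
        t_ref = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_star_mapping(self):
        cases = [
            ((1.0, 0.1, 6, 1.2, 0.1, 6), "*"),
        ]
        _, p, stars = K.compare_conditions(*cases[0][0])
        assert (p < 0.05) == (stars != "")

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            K.compare_conditions(1.0, 0.1, 1, 2.0, 0.1, 5)

    def test_fold_ratio_printed_case(self):
        # dimer->tetramer vs dimer->trimer: 4.0e8 / 8.9e6 -> 45-fold
        r, _ = K.fold_ratio(4.0e8, 0.4e8, 8.9e6, 0.07e6, sig_figs=2)
        assert r == 45.0

    def test_fold_ratio_error_propagation(self):
        r, e = K.fold_ratio(10.0, 1.0, 5.0, 0.5, sig_figs=3)
        assert r == pytest.approx(2.0)
        assert e == pytest.approx(2.0 * np.sqrt(0.01 + 0.01), rel=0.01)
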