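"""Unit and property tests for the energy-landscape module."""

import heapq

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from tmslandscape import landscape as ls
from tmslandscape.localize import RoiSeries
from tmslandscape.networks import NetworkDefinition
from tmslandscape.synthetic import sample_ising_series


def random_model(rng, m, scale=0.5):
    h = rng.normal(0, scale, m)
    J = np.triu(rng.normal(0, scale, (m, m)), 1)
    J = J + J.T
    return ls.MaxEntModel(h=h, J=J)


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------


class TestBinarize:
    def _series(self, values, names):
        return RoiSeries(values=values, roi_names=names, subject_id="s1")

    def test_mean_threshold_is_strict(self):
        net = NetworkDefinition("toy", ("a", "b"))
        # region a: [1,2,3] (mean 2) -> [-1,-1,+1]; exact ties map to -1
        values = np.array([[1.0, 2.0, 3.0, 0, 0, 0], [5.0, 5.0, 5.0, 0, 0, 0]])
        bp = ls.binarize(self._series(values, ("a", "b")), net, "pre")
        assert np.array_equal(bp.patterns[:, 0], [-1, -1, 1])

    def test_constant_region_is_all_inactive(self):
        net = NetworkDefinition("toy", ("a", "b"))
        values = np.tile([[4.0], [7.0]], (1, 10))
        bp = ls.binarize(self._series(values, ("a", "b")), net, "post")
        assert np.all(bp.patterns == -1)

    def test_matches_independent_oracle(self, rng):
        net = NetworkDefinition("toy", ("r0", "r1", "r2"))
        values = rng.normal(size=(3, 40))
        series = self._series(values, ("r0", "r1", "r2"))
        for window, sl in (("pre", slice(0, 20)), ("post", slice(20, 40))):
            bp = ls.binarize(series, net, window)
            x = values[:, sl]
            oracle = (x > x.mean(axis=1, keepdims=True)).T * 2.0 - 1.0
            assert np.array_equal(bp.patterns, oracle)

    def test_missing_region_named_in_error(self):
        net = NetworkDefinition("toy", ("a", "missing_region"))
        series = self._series(np.zeros((1, 4)), ("a",))
        with pytest.raises(KeyError, match="missing_region"):
            ls.binarize(series, net, "pre")


# ---------------------------------------------------------------------------
# energy / boltzmann
# ---------------------------------------------------------------------------


class TestEnergy:
    def test_hand_computed_value(self):
        model = ls.MaxEntModel(h=[1.0, -1.0], J=[[0.0, 0.5], [0.5, 0.0]])
        assert ls.energy(model, [1.0, 1.0]) == pytest.approx(-0.5)

    def test_zero_model_zero_energy_everywhere(self):
        model = ls.MaxEntModel(h=np.zeros(4), J=np.zeros((4, 4)))
        assert np.allclose(ls.energies_all(model), 0.0)
        assert np.allclose(ls.boltzmann(model), 1.0 / 16.0)

    def test_wrong_length_raises(self):
        model = ls.MaxEntModel(h=np.zeros(3), J=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ls.energy(model, [1.0, -1.0])

    @given(hst.integers(0, 2**5 - 1), hst.integers(0, 10_000))
    def test_global_sign_flip_symmetry_without_fields(self, code, seed):
        rng = np.random.default_rng(seed)
        J = np.triu(rng.normal(0, 1, (5, 5)), 1)
        model = ls.MaxEntModel(h=np.zeros(5), J=J + J.T)
        sigma = ls.code_to_spins(code, 5)
        assert ls.energy(model, sigma) == pytest.approx(ls.energy(model, -sigma))

    def test_boltzmann_normalized_and_monotone(self, rng):
        model = random_model(rng, 6)
        p = ls.boltzmann(model)
        e = ls.energies_all(model)
        assert p.sum() == pytest.approx(1.0)
        assert np.argmax(p) == np.argmin(e)
        # extreme parameters must not overflow
        big = ls.MaxEntModel(h=np.full(8, 50.0), J=np.zeros((8, 8)))
        assert np.isfinite(ls.boltzmann(big)).all()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitMaxent:
    def test_uniform_data_gives_zero_parameters(self):
        m = 4
        codes = np.arange(2**m)
        patterns = np.where((codes[:, None] >> np.arange(m)) & 1, 1.0, -1.0)
        fit = ls.fit_maxent(patterns)
        assert np.abs(fit.h).max() < 1e-6
        assert np.abs(fit.J).max() < 1e-6

    def test_recovers_known_model(self, rng):
        truth = random_model(rng, 4, scale=0.4)
        patterns = sample_ising_series(truth, 50_000, rng)
        fit = ls.fit_maxent(patterns)
        assert np.abs(fit.h - truth.h).max() < 0.1
        assert np.abs(fit.J - truth.J).max() < 0.1

    def test_two_region_closed_form(self, rng):
        """For M=2 the three moments invert analytically; the gradient fit
        must agree with the log-odds closed form."""
        truth = ls.MaxEntModel(h=[0.3, -0.2], J=[[0.0, 0.4], [0.4, 0.0]])
        patterns = sample_ising_series(truth, 100_000, rng)
        fit = ls.fit_maxent(patterns)
        codes = (patterns > 0) @ (2 ** np.arange(2))
        p = np.bincount(codes.astype(int), minlength=4) / len(patterns)
        j_cf = 0.25 * np.log(p[3] * p[0] / (p[1] * p[2]))
        h0_cf = 0.25 * np.log(p[3] * p[1] / (p[2] * p[0]))
        h1_cf = 0.25 * np.log(p[3] * p[2] / (p[1] * p[0]))
        assert fit.J[0, 1] == pytest.approx(j_cf, abs=1e-6)
        assert fit.h[0] == pytest.approx(h0_cf, abs=1e-6)
        assert fit.h[1] == pytest.approx(h1_cf, abs=1e-6)

    def test_gradient_descent_agrees_with_lbfgs(self, rng):
        truth = random_model(rng, 3, scale=0.3)
        patterns = sample_ising_series(truth, 5000, rng)
        a = ls.fit_maxent(patterns, method="lbfgs")
        b = ls.fit_maxent(patterns, method="gd", tol_moment=1e-6, max_iter=100_000)
        assert np.abs(a.h - b.h).max() < 1e-2
        assert np.abs(a.J - b.J).max() < 1e-2

    def test_constant_region_warns_and_clips(self):
        patterns = np.column_stack(
            [np.ones(50), np.where(np.arange(50) % 2, 1.0, -1.0)]
        )
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = ls.fit_maxent(patterns, theta_max=20.0)
        # the boundary moment is unattainable; the field saturates at a
        # large but bounded value instead of diverging
        assert 5.0 < fit.h[0] <= 20.0
        assert abs(fit.h[1]) < 1.0

    def test_moment_matching_at_convergence(self, rng):
        truth = random_model(rng, 5, scale=0.3)
        patterns = sample_ising_series(truth, 20_000, rng)
        fit = ls.fit_maxent(patterns, tol_moment=1e-4)
        m_emp, c_emp = ls.empirical_moments(patterns)
        m_fit, c_fit = ls.model_moments(fit)
        assert np.abs(m_fit - m_emp).max() <= 1e-4
        assert np.abs(c_fit - c_emp).max() <= 1e-4

    def test_enumeration_limit(self):
        with pytest.raises(ValueError, match="enumeration"):
            ls.fit_maxent(np.ones((5, 13)))


# ---------------------------------------------------------------------------
# landscape enumeration oracles
# ---------------------------------------------------------------------------


def brute_force_minima(energies, m):
    return [
        c
        for c in range(2**m)
        if all(energies[c] <= energies[c ^ (1 << i)] for i in range(m))
    ]


def minimax_barrier(energies, m, a, b):
    """Independent oracle: Dijkstra-style widest (minimax) path search."""
    best = {a: energies[a]}
    heap = [(energies[a], a)]
    done = set()
    while heap:
        cost, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == b:
            return cost
        for i in range(m):
            v = u ^ (1 << i)
            c2 = max(cost, energies[v])
            if c2 < best.get(v, np.inf):
                best[v] = c2
                heapq.heappush(heap, (c2, v))
    raise AssertionError("hypercube is connected; unreachable")


class TestStableStates:
    def test_separable_model_has_unique_minimum(self, rng):
        h = rng.normal(0, 1, 6)
        h[np.abs(h) < 0.1] = 0.5  # keep fields clearly nonzero
        model = ls.MaxEntModel(h=h, J=np.zeros((6, 6)))
        scape = ls.EnergyLandscape.from_model(model)
        expected = ls.spins_to_code(np.sign(h))
        assert ls.find_stable_states(scape) == [expected]

    def test_ferromagnet_has_two_uniform_minima(self):
        m = 5
        J = 0.6 * (1 - np.eye(m))
        scape = ls.EnergyLandscape.from_model(ls.MaxEntModel(h=np.zeros(m), J=J))
        minima = ls.find_stable_states(scape)
        assert sorted(minima) == [0, 2**m - 1]
        assert scape.energies[0] == pytest.approx(scape.energies[2**m - 1])

    @pytest.mark.parametrize("m", [2, 4, 6, 8])
    def test_minima_match_brute_force(self, m, rng):
        for _ in range(10):
            scape = ls.EnergyLandscape.from_model(random_model(rng, m))
            assert sorted(scape.local_minima.tolist()) == brute_force_minima(
                scape.energies, m
            )

    def test_truncation_and_energy_ranking(self, rng):
        scape = ls.EnergyLandscape.from_model(random_model(rng, 6))
        ranked = ls.find_stable_states(scape)
        energies = scape.energies[ranked]
        assert np.all(np.diff(energies) >= 0)
        assert ls.find_stable_states(scape, k=1) == ranked[:1]


class TestDisconnectivity:
    def test_single_minimum_trivial_tree(self):
        model = ls.MaxEntModel(h=[2.0, 2.0], J=np.zeros((2, 2)))
        scape = ls.EnergyLandscape.from_model(model)
        dg = ls.disconnectivity_graph(scape)
        assert len(dg.minima) == 1
        assert dg.merges == []

    def test_barriers_match_minimax_oracle(self, rng):
        for _ in range(15):
            m = int(rng.integers(3, 7))
            scape = ls.EnergyLandscape.from_model(random_model(rng, m, scale=0.8))
            dg = ls.disconnectivity_graph(scape)
            for i, a in enumerate(dg.minima):
                for b in dg.minima[i + 1 :]:
                    oracle = minimax_barrier(scape.energies, m, a, b)
                    assert dg.barrier(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_barrier_dominates_both_minima(self, rng):
        scape = ls.EnergyLandscape.from_model(random_model(rng, 6, scale=0.8))
        dg = ls.disconnectivity_graph(scape)
        for (a, b), level in dg.barriers.items():
            assert level >= max(scape.energies[a], scape.energies[b]) - 1e-12


# ---------------------------------------------------------------------------
# subject energies
# ---------------------------------------------------------------------------


def _roi_series_from_patterns(patterns, names, subject_id, group):
    """Embed a +-1 pattern sequence as a two-window ROI series whose
    binarization recovers the patterns exactly (values 0/1, mean strictly
    between them whenever both occur)."""
    n, m = patterns.shape
    values = np.concatenate([patterns.T, patterns.T], axis=1) * 0.5 + 0.5
    return RoiSeries(
        values=values, roi_names=names, subject_id=subject_id, group=group, site="x"
    )


class TestSubjectEnergies:
    def test_shape_and_determinism(self, rng):
        net = NetworkDefinition("toy", ("a", "b", "c"))
        truth = random_model(rng, 3, scale=0.3)
        pats = sample_ising_series(truth, 400, rng)
        series = [
            _roi_series_from_patterns(pats, net.regions, f"s{i}", "controls")
            for i in range(2)
        ]
        df = ls.subject_energies(series, net, [0, 7], fit_kwargs={"l2": 0.01})
        assert len(df) == 2 * 2 * 2  # subjects x conditions x patterns
        s0 = df[df.subject == "s0"].drop(columns="subject").reset_index(drop=True)
        s1 = df[df.subject == "s1"].drop(columns="subject").reset_index(drop=True)
        pd.testing.assert_frame_equal(s0, s1)  # identical inputs, identical rows

    def test_consistency_with_group_model_at_large_n(self, rng):
        net = NetworkDefinition("toy", ("a", "b", "c", "d"))
        truth = random_model(rng, 4, scale=0.3)
        pats = sample_ising_series(truth, 30_000, rng)
        series = [_roi_series_from_patterns(pats, net.regions, "s0", "controls")]
        codes = [0, 5, 15]
        df = ls.subject_energies(series, net, codes)
        for code in codes:
            expected = ls.energy(truth, ls.code_to_spins(code, 4))
            got = df[(df.pattern_code == code) & (df.condition == "pre")].energy.iloc[0]
            assert got == pytest.approx(expected, abs=0.15)

    def test_group_model_mode(self, rng):
        net = NetworkDefinition("toy", ("a", "b"))
        model = random_model(rng, 2, scale=0.2)
        pats = sample_ising_series(model, 100, rng)
        series = [_roi_series_from_patterns(pats, net.regions, "s0", "controls")]
        df = ls.subject_energies(
            series,
            net,
            [3],
            per_subject_model=False,
            group_models={("controls", "pre"): model, ("controls", "post"): model},
        )
        expected = ls.energy(model, ls.code_to_spins(3, 2))
        assert np.allclose(df.energy, expected)

    def test_group_fit_invariant_to_subject_order(self, rng):
        truth = random_model(rng, 3, scale=0.4)
        chunks = [sample_ising_series(truth, 500, rng) for _ in range(4)]
        a = ls.fit_maxent(np.vstack(chunks))
        b = ls.fit_maxent(np.vstack(chunks[::-1]))
        assert np.allclose(a.h, b.h, atol=1e-8)
        assert np.allclose(a.J, b.J, atol=1e-8)
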