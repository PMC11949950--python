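"""ELA core: binarization, exact PMEM fitting, landscapes vs brute force."""
import heapq
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elanull.datatypes import PmemModel, RoiTimeSeries
from elanull.ela import (binarize, boltzmann_probabilities, build_landscape,
                         empirical_moments, encode_states, energy,
                         energies_all, fit_pmem, landscape_correlation,
                         same_basin_structure, states_matrix)
from elanull.errors import (ConvergenceError, DegenerateStatisticError,
                            ValidityError)
from elanull.simulate import simulate_ising
from conftest import random_pmem


class TestBinarize:
    def test_mean_threshold_with_tie_to_minus(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 4.0]])
        out = binarize(x)
        # channel 0: mean 2, value 2 ties -> -1
        assert out[:, 0].tolist() == [-1, -1, 1]

    def test_constant_channel_rejected(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValidityError):
            binarize(x)

    def test_plus_fraction_near_half_for_symmetric_noise(self):
        rng = np.random.default_rng(0)
        b = binarize(rng.normal(size=(100_000, 3)))
        assert np.abs((b > 0).mean(axis=0) - 0.5).max() < 0.01

    @given(gain=st.floats(0.1, 10.0), offset=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(200, 3))
        assert np.array_equal(binarize(x), binarize(gain * x + offset))


class TestEnergy:
    def test_zero_model_zero_energy(self):
        model = PmemModel(np.zeros(3), np.zeros((3, 3)))
        assert np.array_equal(energies_all(model), np.zeros(8))

    def test_two_channel_arithmetic(self):
        model = PmemModel(np.array([0.5, -0.5]),
                          np.array([[0.0, 1.0], [1.0, 0.0]]))
        state_pp = encode_states(np.array([[1, 1]]))[0]
        assert energy(model, state_pp) == pytest.approx(-1.0)

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            model = random_pmem(4, 1.0, rng)
            assert boltzmann_probabilities(model).sum() == pytest.approx(1.0)

    def test_out_of_range_state(self):
        model = PmemModel(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValidityError):
            energy(model, 4)


class TestFitPmem:
    def test_uniform_data_gives_zero_parameters(self):
        b = states_matrix(3).astype(int)  # every state exactly once
        model, info = fit_pmem(b, tol=1e-8)
        assert np.abs(model.h).max() < 1e-8
        assert np.abs(model.J).max() < 1e-8

    def test_parameter_recovery_from_exact_samples(self):
        rng = np.random.default_rng(3)
        truth = random_pmem(4, 0.5, rng)
        b = simulate_ising(truth, 100_000, seed=4)
        model, _ = fit_pmem(b, tol=1e-6)
        assert np.abs(model.h - truth.h).max() < 0.05
        assert np.abs(model.J - truth.J).max() < 0.05

    def test_fitted_moments_match_empirical(self, hcp_series):
        b = binarize(hcp_series[0])
        model, info = fit_pmem(b, tol=1e-6)
        m1, m2 = empirical_moments(b)
        p = boltzmann_probabilities(model)
        s = states_matrix(model.n_channels)
        mm1 = p @ s
        mm2 = (s * p[:, None]).T @ s
        off = ~np.eye(7, dtype=bool)
        assert np.abs(mm1 - m1).max() < 1e-6
        assert np.abs((mm2 - m2)[off]).max() < 1e-6
        assert info.discrepancy < 1e-6

    def test_boundary_moments_raise(self):
        b = np.array([[1, 1, 1], [-1, -1, -1]] * 50)
        with pytest.raises(ConvergenceError):
            fit_pmem(b, tol=1e-6, max_iter=3000)

    def test_shuffle_invariance_is_bit_exact(self, hcp_series):
        x = hcp_series[0].data[:4000]
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(x))
        m_a, _ = fit_pmem(binarize(x))
        m_b, _ = fit_pmem(binarize(x[perm]))
        assert np.array_equal(m_a.h, m_b.h)
        assert np.array_equal(m_a.J, m_b.J)


def brute_force_landscape(model: PmemModel):
    """Independent oracle: explicit neighbour checks, per-state descent
    loops, and minimax-path barriers via best-first search."""
    n = model.n_channels
    size = 2 ** n
    e = np.array([energy(model, s) for s in range(size)])
    neighbours = [[s ^ (1 << i) for i in range(n)] for s in range(size)]
    minima = [s for s in range(size)
              if all(e[s] < e[t] for t in neighbours[s])]

    def descend(s):
        while True:
            lower = [t for t in neighbours[s] if e[t] < e[s]]
            if not lower:
                return s
            best = min(e[t] for t in lower)
            s = min(t for t in lower if e[t] == best)

    basin = np.array([descend(s) for s in range(size)])

    def minimax_barrier(a, b):
        # Dijkstra-like search minimizing the maximum energy along the path
        best = np.full(size, np.inf)
        best[a] = e[a]
        heap = [(e[a], a)]
        while heap:
            val, s = heapq.heappop(heap)
            if s == b:
                return val
            if val > best[s]:
                continue
            for t in neighbours[s]:
                cand = max(val, e[t])
                if cand < best[t]:
                    best[t] = cand
                    heapq.heappush(heap, (cand, t))
        raise AssertionError("unreachable")

    barriers = np.full((len(minima), len(minima)), np.nan)
    for i, a in enumerate(minima):
        barriers[i, i] = e[a]
        for j in range(i + 1, len(minima)):
            barriers[i, j] = barriers[j, i] = minimax_barrier(a, minima[j])
    return np.array(minima), basin, barriers


class TestBuildLandscape:
    def test_two_channel_ferromagnet(self):
        model = PmemModel(np.zeros(2), np.array([[0.0, 1.0], [1.0, 0.0]]))
        ls = build_landscape(model)
        assert ls.minima.tolist() == [0, 3]
        assert ls.barriers[0, 1] == pytest.approx(1.0)

    def test_strong_fields_single_minimum(self):
        model = PmemModel(np.full(3, 2.0), np.zeros((3, 3)))
        ls = build_landscape(model)
        assert ls.minima.tolist() == [7]
        assert np.all(ls.basin_of == 7)

    @pytest.mark.parametrize("n_channels", [2, 3, 4])
    def test_matches_brute_force_oracle(self, n_channels):
        rng = np.random.default_rng(n_channels)
        for _ in range(10):
            model = random_pmem(n_channels, 1.0, rng)
            ls = build_landscape(model)
            minima, basin, barriers = brute_force_landscape(model)
            assert np.array_equal(ls.minima, minima)
            assert np.array_equal(ls.basin_of, basin)
            assert np.array_equal(ls.barriers, barriers)

    def test_barriers_are_ultrametric(self):
        rng = np.random.default_rng(9)
        model = random_pmem(5, 0.8, rng)
        ls = build_landscape(model)
        b = ls.barriers
        k = len(ls.minima)
        for i, j, m in itertools.permutations(range(k), 3):
            assert b[i, j] <= max(b[i, m], b[m, j]) + 1e-12

    def test_descent_reaches_strictly_lower_energy(self):
        rng = np.random.default_rng(10)
        model = random_pmem(5, 0.8, rng)
        ls = build_landscape(model)
        non_min = np.setdiff1d(np.arange(32), ls.minima)
        assert np.all(ls.energies[ls.basin_of[non_min]]
                      < ls.energies[non_min])

    def test_shuffle_invariant_landscape(self, hcp_series):
        x = hcp_series[0].data[:4000]
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(x))
        ls_a = build_landscape(fit_pmem(binarize(x))[0])
        ls_b = build_landscape(fit_pmem(binarize(x[perm]))[0])
        assert np.array_equal(ls_a.energies, ls_b.energies)
        assert np.array_equal(ls_a.minima, ls_b.minima)
        assert np.array_equal(ls_a.basin_of, ls_b.basin_of)


class TestLandscapeComparison:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(12)
        ls = build_landscape(random_pmem(4, 0.5, rng))
        assert landscape_correlation(ls, ls) == pytest.approx(1.0)

    def test_negated_energies_anticorrelate(self):
        rng = np.random.default_rng(13)
        model = random_pmem(4, 0.5, rng)
        ls = build_landscape(model)
        flipped = build_landscape(PmemModel(-model.h, -model.J))
        assert landscape_correlation(ls, flipped) == pytest.approx(-1.0)

    def test_independent_landscapes_decorrelated(self):
        rng = np.random.default_rng(14)
        values = [landscape_correlation(build_landscape(random_pmem(7, 0.3, rng)),
                                        build_landscape(random_pmem(7, 0.3, rng)))
                  for _ in range(10)]
        assert abs(np.mean(values)) < 0.15

    def test_zero_variance_rejected(self):
        flat = build_landscape(PmemModel(np.array([2.0, 0.1]),
                                         np.zeros((2, 2))))
        zero = PmemModel(np.zeros(2), np.zeros((2, 2)))
        from elanull.datatypes import EnergyLandscape
        degenerate = EnergyLandscape(
            n_channels=2, energies=np.zeros(4),
            minima=flat.minima, basin_of=flat.basin_of)
        with pytest.raises(DegenerateStatisticError):
            landscape_correlation(flat, degenerate)

    def test_same_basin_structure_modes(self):
        rng = np.random.default_rng(15)
        model = random_pmem(4, 0.8, rng)
        ls = build_landscape(model)
        assert same_basin_structure(ls, ls, mode="strict")
        # same minima, one boundary state reassigned
        tweaked_basin = ls.basin_of.copy()
        boundary = next(int(s) for s in range(16)
                        if s not in ls.minima and len(set(
                            ls.basin_of[[s ^ (1 << i) for i in range(4)]])) > 1)
        other = next(m for m in ls.minima if m != ls.basin_of[boundary])
        tweaked_basin[boundary] = other
        from elanull.datatypes import EnergyLandscape
        tweaked = EnergyLandscape(n_channels=4, energies=ls.energies,
                                  minima=ls.minima, basin_of=tweaked_basin)
        assert not same_basin_structure(ls, tweaked, mode="strict")
        assert same_basin_structure(ls, tweaked, mode="minima")
        # different minima counts
        single = build_landscape(PmemModel(np.full(4, 2.0), np.zeros((4, 4))))
        assert not same_basin_structure(ls, single, mode="minima")
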