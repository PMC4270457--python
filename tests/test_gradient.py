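"""Steady-state ParA gradient: closed form vs finite-difference oracle."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from parspace.gradient import (
    GradientParams,
    equal_spacing_positions,
    flux_imbalance_relaxation,
    solve_steady_state,
)


def fd_oracle(L, R, D, plasmids, kB=math.inf, n=20_001):
    """Dense finite-difference solve of D·A'' + R = 0, no-flux edges.

    Plasmids are the grid nodes nearest their positions; kB=inf imposes
    A=0 there, finite kB adds a point sink kB·A(x_i)/h at the node.
    Returns (x, A, fluxes) with fluxes estimated by one-sided differences.
    """
    x = np.linspace(0.0, L, n)
    h = x[1] - x[0]
    idx = [int(round(p / h)) for p in plasmids]
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    A_mat = sp.diags([off, main, off], [-1, 0, 1], format="lil") * (D / h**2)
    rhs = np.full(n, -R)
    # reflecting ends: ghost-node elimination A_{-1}=A_1
    A_mat[0, 1] = 2 * D / h**2
    A_mat[-1, -2] = 2 * D / h**2
    for i in idx:
        if math.isinf(kB):
            A_mat[i, :] = 0.0
            A_mat[i, i] = 1.0
            rhs[i] = 0.0
        else:
            A_mat[i, i] -= kB / h
    sol = spla.spsolve(sp.csr_matrix(A_mat), rhs)
    fluxes = []
    for i in idx:
        jm = -D * (sol[i] - sol[i - 1]) / h
        jp = D * (sol[i + 1] - sol[i]) / h
        fluxes.append((jm, jp))
    return x, sol, np.asarray(fluxes)


class TestSolveSteadyState:
    def test_single_central_plasmid_absorbing(self):
        p = GradientParams(L=2, R=1, D=1, plasmid_positions=[1.0])
        sol = solve_steady_state(p)
        np.testing.assert_allclose(sol.fluxes[0], [1.0, 1.0], rtol=1e-12)
        assert sol.profile(np.array([0.0]))[0] == pytest.approx(0.5)
        # cross-check against the finite-difference oracle
        _, _, fd_flux = fd_oracle(2, 1, 1, [1.0])
        np.testing.assert_allclose(sol.fluxes, fd_flux, rtol=1e-3)

    def test_offcenter_plasmid_fluxes(self):
        p = GradientParams(L=2, R=1, D=1, plasmid_positions=[0.5])
        sol = solve_steady_state(p)
        np.testing.assert_allclose(sol.fluxes[0], [0.5, 1.5], rtol=1e-12)
        _, _, fd_flux = fd_oracle(2, 1, 1, [0.5])
        np.testing.assert_allclose(sol.fluxes, fd_flux, rtol=1e-3)

    def test_zero_source_gives_zero_profile(self):
        p = GradientParams(L=3, R=0, D=0.5, plasmid_positions=[1.0, 2.0])
        sol = solve_steady_state(p)
        x = np.linspace(0, 3, 50)
        np.testing.assert_allclose(sol.profile(x), 0.0, atol=1e-14)
        np.testing.assert_allclose(sol.fluxes, 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_params_match_fd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.uniform(1, 5)
        R = rng.uniform(0.1, 10)
        D = rng.uniform(0.1, 5)
        n_p = rng.integers(1, 4)
        pos = np.sort(rng.uniform(0.1 * L, 0.9 * L, n_p))
        while np.any(np.diff(pos) < 0.05 * L):
            pos = np.sort(rng.uniform(0.1 * L, 0.9 * L, n_p))
        sol = solve_steady_state(GradientParams(L=L, R=R, D=D, plasmid_positions=pos))
        x, a_fd, fd_flux = fd_oracle(L, R, D, pos)
        a = sol.profile(x)
        scale = max(a_fd.max(), 1e-12)
        assert np.max(np.abs(a - a_fd)) / scale < 1e-4
        np.testing.assert_allclose(sol.fluxes, fd_flux, rtol=1e-3, atol=1e-6 * R * L)

    def test_finite_kb_matches_fd_oracle(self):
        L, R, D, kB = 2.0, 1.0, 1.0, 5.0
        sol = solve_steady_state(
            GradientParams(L=L, R=R, D=D, kB=kB, plasmid_positions=[0.7])
        )
        x, a_fd, fd_flux = fd_oracle(L, R, D, [0.7], kB=kB)
        assert np.max(np.abs(sol.profile(x) - a_fd)) / a_fd.max() < 1e-3
        np.testing.assert_allclose(sol.fluxes, fd_flux, rtol=1e-2)
        # sink balance holds exactly in the closed form
        assert sol.total_flux == pytest.approx(
            kB * sol.plasmid_concentrations[0], rel=1e-10
        )

    def test_finite_kb_converges_to_absorbing_limit(self):
        p_inf = GradientParams(L=1, R=1, D=1, plasmid_positions=[0.4])
        sol_inf = solve_steady_state(p_inf)
        sol_big = solve_steady_state(
            GradientParams(L=1, R=1, D=1, kB=1e9, plasmid_positions=[0.4])
        )
        rel = np.abs(sol_big.fluxes - sol_inf.fluxes) / sol_inf.fluxes
        assert np.max(rel) < 1e-6

    def test_flux_conservation_and_positivity(self):
        # everything bound must be released: sum of fluxes = R·L exactly
        for pos in ([0.3], [0.5, 1.1], [0.2, 0.9, 1.7]):
            sol = solve_steady_state(
                GradientParams(L=2, R=3.7, D=0.8, plasmid_positions=pos)
            )
            assert sol.total_flux == pytest.approx(3.7 * 2, rel=1e-12)
            x = np.linspace(0, 2, 400)
            assert np.all(sol.profile(x) >= -1e-12)

    def test_single_plasmid_imbalance_identity(self):
        # J+ - J- = R(L - 2 x1) for any interior single-plasmid position
        L, R, D = 2.0, 1.3, 0.9
        for x1 in np.linspace(0.1, 1.9, 9):
            sol = solve_steady_state(
                GradientParams(L=L, R=R, D=D, plasmid_positions=[x1])
            )
            jm, jp = sol.fluxes[0]
            assert jp - jm == pytest.approx(R * (L - 2 * x1), rel=1e-10, abs=1e-10)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            GradientParams(L=2, R=1, D=1, plasmid_positions=[0.0])
        with pytest.raises(ValueError):
            GradientParams(L=2, R=1, D=1, plasmid_positions=[2.5])
        with pytest.raises(ValueError):
            GradientParams(L=2, R=1, D=1, plasmid_positions=[1.0, 0.5])
        with pytest.raises(ValueError):
            GradientParams(L=2, R=1, D=1, kB=-3, plasmid_positions=[1.0])


class TestEqualSpacing:
    def test_known_configurations(self):
        np.testing.assert_allclose(equal_spacing_positions(3, 1), [1.5])
        np.testing.assert_allclose(equal_spacing_positions(2, 2), [0.5, 1.5])
        np.testing.assert_allclose(
            equal_spacing_positions(4, 4), [0.5, 1.5, 2.5, 3.5]
        )

    def test_flux_balance_at_fixed_point(self):
        for n_p in (1, 2, 4):
            pos = equal_spacing_positions(4, n_p)
            sol = solve_steady_state(
                GradientParams(L=4, R=1, D=1, plasmid_positions=pos)
            )
            np.testing.assert_allclose(sol.fluxes[:, 0], sol.fluxes[:, 1], rtol=1e-10)

    def test_spacing_is_half_length_for_two_plasmids(self):
        # inter-plasmid distance L/2 across lengths: slope 0.5 of spacing vs L
        lengths = np.linspace(1.5, 3.0, 7)
        spacings = [np.diff(equal_spacing_positions(L, 2))[0] for L in lengths]
        slope = np.polyfit(lengths, spacings, 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_rejects_zero_plasmids(self):
        with pytest.raises(ValueError):
            equal_spacing_positions(2, 0)


class TestRelaxation:
    def test_single_plasmid_converges_to_center(self):
        p = GradientParams(L=2, R=1, D=1, plasmid_positions=[0.2])
        traj = flux_imbalance_relaxation(p)
        assert traj[-1][0] == pytest.approx(1.0, abs=1e-6)

    def test_two_plasmids_converge_to_quartiles(self):
        p = GradientParams(L=2, R=1, D=1, plasmid_positions=[0.3, 0.5])
        traj = flux_imbalance_relaxation(p)
        np.testing.assert_allclose(
            traj[-1], equal_spacing_positions(2, 2), atol=1e-6
        )

    def test_fixed_point_is_stationary(self):
        pos = equal_spacing_positions(3, 3)
        p = GradientParams(L=3, R=1, D=1, plasmid_positions=pos)
        traj = flux_imbalance_relaxation(p)
        assert len(traj) == 1
        np.testing.assert_allclose(traj[-1], pos)

    def test_oversized_step_raises(self):
        p = GradientParams(L=2, R=1, D=1, plasmid_positions=[0.3])
        with pytest.raises(RuntimeError):
            flux_imbalance_relaxation(p, step=1.8)
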