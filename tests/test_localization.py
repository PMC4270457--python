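"""Nucleoid edges, positioning nulls, asymmetry, harmonic and colocalization."""

import numpy as np
import pytest
import scipy.stats

from parspace.localization import (
    IntensityStack,
    asymmetry_measure,
    colocalize,
    count_lobes,
    first_harmonic_score,
    mind_reference,
    nucleoid_edges,
    random_position_null,
    relative_positions,
    select_focus_planes,
)


class TestNucleoidEdges:
    def test_triangular_profile(self):
        x = np.linspace(0, 2, 401)
        y = np.clip(1 - np.abs(x - 1), 0, None)
        left, right, length = nucleoid_edges(x, y)
        assert left == pytest.approx(0.5, abs=1e-9)
        assert right == pytest.approx(1.5, abs=1e-9)
        assert length == pytest.approx(1.0, abs=1e-9)

    def test_rectangular_profile(self):
        x = np.linspace(0, 3, 301)
        y = np.where((x >= 1.0) & (x <= 2.0), 5.0, 0.0)
        dx = x[1] - x[0]
        left, right, _ = nucleoid_edges(x, y)
        assert abs(left - 1.0) <= dx
        assert abs(right - 2.0) <= dx

    def test_two_lobed_profile_outermost_crossings(self):
        x = np.linspace(0, 4, 801)
        y = (np.exp(-0.5 * ((x - 1.0) / 0.25) ** 2)
             + np.exp(-0.5 * ((x - 3.0) / 0.25) ** 2))
        left, right, _ = nucleoid_edges(x, y)
        assert left < 1.0 < 3.0 < right
        assert count_lobes(x, y) == 2

    def test_flat_zero_profile_raises(self):
        with pytest.raises(ValueError):
            nucleoid_edges(np.linspace(0, 1, 10), np.zeros(10))


class TestRelativePositions:
    def test_mid_focus(self):
        out = relative_positions([1.0], (0.0, 2.0))
        assert out["rel"][0] == pytest.approx(0.5)
        assert out["label"][0] == 1

    def test_rank_labels(self):
        out = relative_positions([1.5, 0.5], (0.0, 2.0))
        np.testing.assert_allclose(out["rel"], [0.25, 0.75])
        np.testing.assert_array_equal(out["label"], [1, 2])

    def test_equal_spacing_prediction_three_plasmids(self):
        from parspace.gradient import equal_spacing_positions
        L = 2.4
        foci = equal_spacing_positions(L, 3)
        out = relative_positions(foci, (0.0, L))
        np.testing.assert_allclose(out["rel"], [1 / 6, 3 / 6, 5 / 6])

    def test_outside_flag(self):
        out = relative_positions([-0.2, 1.0], (0.0, 2.0))
        assert out["outside"][0] and not out["outside"][1]


class TestRandomPositionNull:
    def test_single_plasmid_uniform(self):
        samples, hists, _ = random_position_null(1, n_datasets=40_000, seed=0)
        expected = samples.shape[0] / hists.shape[1]
        chi2 = ((hists[0] - expected) ** 2 / expected).sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=hists.shape[1] - 1)

    @pytest.mark.parametrize("n_p", [2, 3, 4])
    def test_order_statistic_means(self, n_p):
        samples, _, _ = random_position_null(n_p, n_datasets=50_000, seed=1)
        means = samples.mean(axis=0)
        expect = np.arange(1, n_p + 1) / (n_p + 1)
        se = samples.std(axis=0) / np.sqrt(samples.shape[0])
        assert np.all(np.abs(means - expect) < 4 * se)


class TestAsymmetry:
    x = np.linspace(0, 2, 2001)

    def test_uniform_profile_gives_zero(self):
        for focus in (0.3, 1.0, 1.7):
            res = asymmetry_measure(self.x, np.ones_like(self.x), focus,
                                    (0.0, 2.0))
            assert res.asymmetry < 5e-3

    def test_one_sided_profile_gives_one(self):
        y = np.where(self.x < 1.0, 1.0, 0.0)
        res = asymmetry_measure(self.x, y, 1.0, (0.0, 2.0))
        assert res.asymmetry == pytest.approx(1.0, abs=1e-6)

    def test_three_to_one_density_ratio(self):
        y = np.where(self.x <= 1.0, 1.0, 3.0)
        res = asymmetry_measure(self.x, y, 1.0, (0.0, 2.0))
        assert res.asymmetry == pytest.approx(0.5, abs=5e-3)

    def test_scale_invariance_and_range(self):
        rng = np.random.default_rng(0)
        y = rng.random(len(self.x))
        a1 = asymmetry_measure(self.x, y, 0.7, (0.0, 2.0)).asymmetry
        a2 = asymmetry_measure(self.x, 17.3 * y, 0.7, (0.0, 2.0)).asymmetry
        assert a1 == pytest.approx(a2)
        assert 0.0 <= a1 <= 1.0

    def test_focus_at_pole_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_measure(self.x, np.ones_like(self.x), 0.0, (0.0, 2.0))


class TestMindReference:
    def test_zero_amplitude(self):
        assert np.all(mind_reference(0.0, 100, seed=0) == 0.0)

    def test_max_and_mean(self):
        s = mind_reference(0.6, 20_000, seed=1)
        assert s.max() == pytest.approx(0.6, abs=1e-3)
        assert s.mean() == pytest.approx(0.6 * 2 / np.pi, abs=5e-3)


class TestFocusPlaneSelection:
    def test_unimodal_window_centred_at_peak(self):
        z = np.arange(21)
        imax = np.exp(-0.5 * ((z - 10) / 3.0) ** 2)
        stack = IntensityStack(x=np.arange(5.0), I=np.outer(imax, np.ones(5)))
        planes = select_focus_planes(stack, 9)
        assert planes[4] == 10  # centre of the 9-window at the peak

    def test_constant_ties_to_first_window(self):
        stack = IntensityStack(x=np.arange(4.0), I=np.ones((15, 4)))
        np.testing.assert_array_equal(select_focus_planes(stack, 9),
                                      np.arange(9))

    def test_known_in_focus_band_recovered(self):
        from parspace.synthetic import SynthCellSpec, generate_cell_stack
        spec = SynthCellSpec(in_focus_start=7, seed=3)
        stack_a, _, truth = generate_cell_stack(spec)
        np.testing.assert_array_equal(select_focus_planes(stack_a, 9),
                                      truth["in_focus_planes"])

    def test_too_few_planes_rejected(self):
        stack = IntensityStack(x=np.arange(4.0), I=np.ones((5, 4)))
        with pytest.raises(ValueError):
            select_focus_planes(stack, 9)


class TestFirstHarmonic:
    x = np.linspace(0.0, 2.0, 201)

    def half_sine_stack(self, n_planes=9):
        prof = np.sin(np.pi * self.x / 2.0)
        return IntensityStack(x=self.x, I=np.tile(prof, (n_planes, 1)))

    def test_exact_half_sine_scores_zero(self):
        # with the true support supplied as edges, a half-sine profile is
        # reproduced exactly by its own first harmonic
        res = first_harmonic_score(self.half_sine_stack(),
                                   edges_per_z=[(0.0, 2.0)] * 9)
        assert res.SE_cell == pytest.approx(0.0, abs=1e-12)

    def test_half_sine_with_halfmax_edges_matches_closed_form(self):
        # automatic edges sit at the sin = 1/2 crossings (u = 1/6, 5/6);
        # the residual of the re-fitted harmonic has a closed-form mean:
        # mean over u in [1/6, 5/6] of (sin(pi u) - sin(pi (u-1/6)/(2/3)))^2
        import scipy.integrate
        expected, _ = scipy.integrate.quad(
            lambda u: (np.sin(np.pi * u)
                       - np.sin(np.pi * (u - 1 / 6) / (2 / 3))) ** 2,
            1 / 6, 5 / 6,
        )
        expected /= 2 / 3
        res = first_harmonic_score(self.half_sine_stack())
        assert res.SE_cell == pytest.approx(expected, abs=2e-3)

    def test_uniform_profile_closed_form(self):
        # flat profile at I_max between its own edges: SE_cell equals
        # the mean of (1 - sin(pi u))^2 over u in [0, 1] = 3/2 - 4/pi
        stack = IntensityStack(x=self.x, I=np.ones((9, len(self.x))))
        res = first_harmonic_score(stack)
        assert res.SE_cell == pytest.approx(1.5 - 4 / np.pi, abs=5e-3)
        assert res.SE_cell > 0

    def test_helical_scores_higher_than_flat(self):
        from parspace.synthetic import SynthCellSpec, generate_cell_stack
        flat, _, _ = generate_cell_stack(SynthCellSpec(seed=0))
        helical, _, _ = generate_cell_stack(
            SynthCellSpec(modulation_amplitude=0.5, seed=0)
        )
        s_flat = first_harmonic_score(flat).SE_cell
        s_helical = first_harmonic_score(helical).SE_cell
        assert s_helical > s_flat


class TestColocalize:
    def random_stack(self, seed, shape=(9, 40)):
        rng = np.random.default_rng(seed)
        return IntensityStack(x=np.arange(shape[1], dtype=float),
                              I=rng.random(shape))

    def test_threshold_zero_gives_unit_overlap(self):
        res = colocalize(self.random_stack(0), self.random_stack(1))
        assert res.M_A[0] == pytest.approx(1.0)
        assert res.M_B[0] == pytest.approx(1.0)

    def test_identical_stacks(self):
        a = self.random_stack(2)
        res = colocalize(a, a)
        assert res.r_P == pytest.approx(1.0)
        np.testing.assert_allclose(res.M_A, res.M_B)

    def test_disjoint_channels_vanishing_overlap(self):
        x = np.arange(40, dtype=float)
        a = np.zeros((3, 40))
        b = np.zeros((3, 40))
        a[:, :20] = 1.0
        b[:, 20:] = 1.0
        res = colocalize(IntensityStack(x=x, I=a), IntensityStack(x=x, I=b),
                         thresholds=np.array([0.0, 0.5]))
        assert res.M_A[1] == 0.0 and res.M_B[1] == 0.0

    def test_manders_curves_non_increasing(self):
        res = colocalize(self.random_stack(3), self.random_stack(4),
                         thresholds=np.linspace(0, 1, 21))
        assert np.all(np.diff(res.M_A) <= 1e-12)
        assert np.all(np.diff(res.M_B) <= 1e-12)

    def test_nested_channel_overlaps_more(self):
        # ParA support strictly inside the nucleoid support: the nested
        # channel's overlap coefficient dominates at positive thresholds
        from parspace.synthetic import SynthCellSpec, generate_cell_stack
        nucleoid, parA, _ = generate_cell_stack(
            SynthCellSpec(channel_b="nested", nested_shrink=0.4, seed=5)
        )
        thr = np.linspace(0.0, 0.9, 10)
        res = colocalize(nucleoid, parA, thresholds=thr)
        # M_B: fraction of nested (ParA) intensity where nucleoid is high
        assert np.all(res.M_B[1:] >= res.M_A[1:])
        assert res.M_B[1:5].mean() > res.M_A[1:5].mean()

    def test_zero_variance_channel_flagged(self):
        a = self.random_stack(6)
        flat = IntensityStack(x=a.x, I=np.ones_like(a.I))
        with pytest.warns(UserWarning):
            res = colocalize(a, flat)
        assert np.isnan(res.r_P)
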