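"""Rate laws, right-hand side, and the fixed-step RK4 integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmbsim import (
    ModelParameters,
    TissueState,
    degradation_rate,
    integrate,
    production_rate,
    rhs,
)
from fmbsim.model import IntegrationError, laplacian


class TestRateLaws:
    @pytest.mark.parametrize(
        "func, j, z, expected",
        [
            (production_rate, 1, 0.0, 2.1),  # full production at zero repressor
            (production_rate, 1, 1.0, 1.1),  # half-saturation point (z = K_f)
            (degradation_rate, 2, 0.0, 0.1),  # basal degradation at zero inducer
            (degradation_rate, 2, 1.0, 1.1),  # half-saturation point (z = K_g)
        ],
    )
    def test_reference_values(self, defaults, func, j, z, expected):
        assert func(j, z, defaults) == pytest.approx(expected, abs=1e-12)

    def test_limits(self, defaults):
        # production decays to the basal rate, degradation saturates at d + c
        assert production_rate(1, 1e6, defaults) == pytest.approx(0.1, abs=1e-6)
        assert production_rate(1, 1e6, defaults) > 0.1
        assert degradation_rate(2, 1e6, defaults) == pytest.approx(2.1, abs=1e-5)
        assert degradation_rate(2, 1e6, defaults) < 2.1

    @pytest.mark.parametrize("func", [production_rate, degradation_rate])
    def test_invalid_arguments(self, defaults, func):
        with pytest.raises(ValueError):
            func(3, 1.0, defaults)
        with pytest.raises(ValueError):
            func(1, -0.5, defaults)

    @given(st.floats(min_value=0.0, max_value=50.0), st.floats(min_value=1e-6, max_value=50.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, z, dz):
        """Production strictly decreases, degradation strictly increases, and
        both stay inside their asymptotic ranges for all z >= 0."""
        p = ModelParameters()
        f0, f1 = production_rate(1, z, p), production_rate(1, z + dz, p)
        g0, g1 = degradation_rate(1, z, p), degradation_rate(1, z + dz, p)
        assert f0 > f1
        assert g0 < g1
        assert p.p1 < f0 <= p.p1 + p.r1
        assert p.d1 <= g0 < p.d1 + p.c1


class TestParameters:
    def test_rejects_nonpositive_required_fields(self):
        with pytest.raises(ValueError):
            ModelParameters(p1=0.0)
        with pytest.raises(ValueError):
            ModelParameters(d2=-0.1)
        with pytest.raises(ValueError):
            ModelParameters(D_AD=-1e-9)
        with pytest.raises(ValueError):
            ModelParameters(n_f=0)

    def test_degenerate_repression_free_set_is_legal(self):
        p = ModelParameters(r1=0.0, r2=0.0, c1=0.0, c2=0.0, D_AD=0.0, D_AB=0.0)
        assert p.r1 == 0.0

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_mapping({"p1": 0.1, "bogus": 1.0})

    def test_swapped_roles(self, defaults):
        asym = defaults.replace(r2=1.8, D_AD=0.2)
        sw = asym.swapped()
        assert (sw.r1, sw.r2, sw.D_AB) == (1.8, 2.0, 0.2)
        assert defaults.is_symmetric and not asym.is_symmetric


class TestRHS:
    def test_uniform_tissue_has_no_diffusion_contribution(self, defaults):
        uniform = TissueState([2.0] * 5, [0.3] * 5)
        single = TissueState([2.0], [0.3])
        dAD, dAB = rhs(uniform, defaults)
        dAD1, dAB1 = rhs(single, defaults)
        assert np.allclose(dAD, dAD1[0]) and np.allclose(dAB, dAB1[0])

    def test_two_cell_gradient_conserves_mass(self):
        p = ModelParameters(D_AD=0.1, D_AB=0.1)
        state = TissueState([1.0, 0.0], [0.0, 0.0])
        dAD, _ = rhs(state, p)
        # subtract the reaction part (evaluated cell by cell, no diffusion)
        p0 = ModelParameters(D_AD=0.0, D_AB=0.0)
        rAD, _ = rhs(state, p0)
        assert np.allclose(dAD - rAD, [-0.1, +0.1])

    def test_diffusion_mass_balance_random_states(self, rng):
        """Summed diffusive contributions vanish to machine precision."""
        for n in (2, 3, 7, 25):
            u = rng.uniform(0, 10, n)
            assert abs(laplacian(u).sum()) < 1e-12 * max(1.0, np.abs(u).max()) * n


class TestIntegrate:
    def test_pure_decay_matches_closed_form(self):
        """r=c=D=0 reduces each variable to linear production-decay with the
        closed form AD(t) = p/d + (AD0 - p/d) e^{-dt}."""
        p = ModelParameters(r1=0.0, r2=0.0, c1=0.0, c2=0.0, D_AD=0.0, D_AB=0.0)
        ad0 = 5.0
        traj = integrate(TissueState([ad0], [ad0]), p, t_end=10.0, dt=0.2, record_stride=1)
        expected = p.p1 / p.d1 + (ad0 - p.p1 / p.d1) * np.exp(-p.d1 * traj.times)
        assert np.max(np.abs(traj.AD[:, 0] - expected) / expected) <= 1e-6

    def test_rk4_global_error_is_fourth_order(self):
        """Halving dt shrinks the pure-decay global error ~16x."""
        p = ModelParameters(r1=0.0, r2=0.0, c1=0.0, c2=0.0, D_AD=0.0, D_AB=0.0)
        ad0, t_end = 5.0, 10.0
        exact = p.p1 / p.d1 + (ad0 - p.p1 / p.d1) * np.exp(-p.d1 * t_end)
        errs = []
        for dt in (0.5, 0.25, 0.125):
            traj = integrate(TissueState([ad0], [ad0]), p, t_end, dt=dt, record_stride=10**6)
            errs.append(abs(traj.AD[-1, 0] - exact))
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(10.0 < r < 22.0 for r in ratios)

    def test_steady_state_is_preserved(self, defaults, default_steady_states):
        ss = default_steady_states.ad_expressing
        init = TissueState([ss.AD] * 4, [ss.AB] * 4)
        traj = integrate(init, defaults, t_end=100.0)
        assert np.max(np.abs(traj.AD - ss.AD)) < 1e-8
        assert np.max(np.abs(traj.AB - ss.AB)) < 1e-8

    def test_final_time_within_dt(self, defaults, default_steady_states):
        ss = default_steady_states.ad_expressing
        init = TissueState([ss.AD] * 2, [ss.AB] * 2)
        traj = integrate(init, defaults, t_end=10.1, dt=0.2, record_stride=3)
        assert traj.times[0] == 0.0
        assert abs(traj.times[-1] - 10.1) <= 0.2
        assert np.all(np.diff(traj.times) > 0)

    def test_rejects_bad_arguments(self, defaults):
        state = TissueState([1.0], [1.0])
        with pytest.raises(ValueError):
            integrate(state, defaults, t_end=0.0)
        with pytest.raises(ValueError):
            integrate(state, defaults, t_end=1.0, dt=-0.1)

    def test_nonnegativity_across_regimes(self, rng):
        """No negative concentrations arise in randomly perturbed bistable
        regimes (the integrator asserts rather than clamps)."""
        for _ in range(5):
            factors = rng.uniform(0.7, 1.3, 8)
            p = ModelParameters(
                p1=0.1 * factors[0], p2=0.1 * factors[1],
                r1=2.0 * factors[2], r2=2.0 * factors[3],
                d1=0.1 * factors[4], d2=0.1 * factors[5],
                c1=2.0 * factors[6], c2=2.0 * factors[7],
            )
            init = TissueState(rng.uniform(0, 10, 6), rng.uniform(0, 10, 6))
            traj = integrate(init, p, t_end=50.0)
            assert traj.AD.min() >= 0 and traj.AB.min() >= 0

    def test_pinned_cell_is_clamped(self, defaults, default_steady_states):
        hi = default_steady_states.ad_expressing
        lo = default_steady_states.ab_expressing
        init = TissueState([hi.AD, lo.AD], [hi.AB, lo.AB])
        traj = integrate(init, defaults, t_end=50.0, pinned={0: (hi.AD, hi.AB)})
        assert np.all(traj.AD[:, 0] == hi.AD)
        assert np.all(traj.AB[:, 0] == hi.AB)


class TestEquivariance:
    def test_role_swap_and_reflection_map_trajectories_exactly(self):
        """Swapping gene roles (params 1<->2), swapping the AD/AB fields and
        reversing the cell order maps a trajectory onto the corresponding
        trajectory bitwise (same dt, same steps)."""
        p = ModelParameters(r2=1.8)
        init = TissueState([9.5, 9.5, 9.5, 0.06, 0.06, 0.06],
                           [0.06, 0.06, 0.06, 9.5, 9.5, 9.5])
        traj = integrate(init, p, t_end=200.0, dt=0.2, record_stride=5)

        mapped_init = TissueState(init.AB[::-1].copy(), init.AD[::-1].copy())
        mapped = integrate(mapped_init, p.swapped(), t_end=200.0, dt=0.2, record_stride=5)
        assert np.array_equal(traj.AD, mapped.AB[:, ::-1])
        assert np.array_equal(traj.AB, mapped.AD[:, ::-1])

    def test_reflection_alone_maps_exactly(self, defaults):
        init = TissueState([1.0, 2.0, 3.0, 0.5], [0.2, 0.1, 4.0, 1.0])
        a = integrate(init, defaults, t_end=50.0)
        b = integrate(TissueState(init.AD[::-1].copy(), init.AB[::-1].copy()),
                      defaults, t_end=50.0)
        assert np.array_equal(a.AD, b.AD[:, ::-1])
        assert np.array_equal(a.AB, b.AB[:, ::-1])


class TestTrajectoryIO:
    def test_tidy_csv_roundtrip(self, tmp_path, defaults, default_steady_states):
        import pandas as pd

        ss = default_steady_states.ad_expressing
        traj = integrate(TissueState([ss.AD] * 3, [ss.AB] * 3), defaults, t_end=5.0)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "cell_index", "AD", "AB"]
        assert len(df) == len(traj.times) * 3
        assert np.allclose(
            df.pivot(index="time", columns="cell_index", values="AD").to_numpy(),
            traj.AD,
        )
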