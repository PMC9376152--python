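"""Fixed points, Jacobians, stability and the transcritical bifurcation."""

import math

import numpy as np
import pytest

from crawlby.equilibria import (
    LABEL_CARRYING_CAPACITY,
    LABEL_COEXISTENCE_HIGH,
    LABEL_COEXISTENCE_LOW,
    LABEL_EXTINCTION,
    bifurcation_value,
    carrying_capacity,
    catalog,
    coexistence_pair,
    jacobian,
    lambda1,
)
from crawlby.model import ParameterError, State, step, step_resource_only


def fd_jacobian(s: State, params, h_scale=1e-6) -> np.ndarray:
    """Central finite differences of the map: the definitional oracle."""
    out = np.empty((2, 2))
    for j, coord in enumerate(("p", "n")):
        base = getattr(s, coord)
        h = h_scale * max(1.0, abs(base))
        lo = {"p": s.p, "n": s.n}
        hi = dict(lo)
        hi[coord] = base + h
        lo[coord] = max(base - h, 0.0)
        s_hi = step(State(**hi), params)
        s_lo = step(State(**lo), params)
        dx = hi[coord] - lo[coord]
        out[0, j] = (s_hi.p - s_lo.p) / dx
        out[1, j] = (s_hi.n - s_lo.n) / dx
    return out


class TestCarryingCapacity:
    def test_closed_form_matches_iteration_oracle(self, base_params):
        n = 1.0
        for _ in range(10_000):
            n = step_resource_only(n, base_params)
        assert carrying_capacity(base_params) == pytest.approx(n, rel=1e-12)
        assert carrying_capacity(base_params) == pytest.approx(9.0, rel=1e-14)

    def test_simple_value(self, base_params):
        assert carrying_capacity(base_params.replace(delta_n=0.5, R=1.0)) == pytest.approx(1.0)

    def test_vanishes_at_replenishment_boundary(self, base_params):
        eps = 1e-9
        params = base_params.replace(R=(1 - base_params.delta_n) + eps)
        assert 0 < carrying_capacity(params) < 1e-8

    def test_error_without_replenishment(self, base_params):
        with pytest.raises(ParameterError):
            carrying_capacity(base_params.replace(R=0.1))


class TestBifurcation:
    def test_baseline_value(self, base_params):
        # (1 - 0.9) * (1 + 2.67 * 81) / 9
        assert bifurcation_value(base_params) == pytest.approx(2.4141111111111111, rel=1e-12)

    def test_sigma_zero_reduction(self, base_params):
        params = base_params.replace(sigma=0.0)
        assert bifurcation_value(params) == pytest.approx((1 - 0.9) / 9.0, rel=1e-12)

    def test_lambda1_is_one_at_bifurcation(self, base_params):
        params = base_params.replace(gamma_p=bifurcation_value(base_params))
        assert lambda1(params) == pytest.approx(1.0, abs=1e-14)

    def test_lambda1_above_bifurcation(self, cycling_params):
        lam = lambda1(cycling_params)
        assert lam == pytest.approx(0.9 + 3.0 * 9.0 / (1 + 2.67 * 81), rel=1e-12)
        assert lam > 1

    def test_lambda1_equals_consumer_jacobian_eigenvalue(self, cycling_params):
        n_star = carrying_capacity(cycling_params)
        J = fd_jacobian(State(0.0, n_star), cycling_params)
        assert lambda1(cycling_params) == pytest.approx(J[0, 0], rel=1e-5)

    def test_stability_switch_located_by_bisection(self, base_params):
        """The carrying-capacity state flips from stable to non-stable
        exactly at the analytic bifurcation value."""
        n_star = carrying_capacity(base_params)

        def stable_at(gp: float) -> bool:
            # raw spectral radius, without the nonhyperbolic tolerance band
            J = jacobian(State(0.0, n_star), base_params.replace(gamma_p=gp))
            return bool(np.max(np.abs(np.linalg.eigvals(J))) < 1.0)

        lo, hi = 2.0, 3.0
        assert stable_at(lo) and not stable_at(hi)
        while hi - lo > 1e-10:
            mid = 0.5 * (lo + hi)
            if stable_at(mid):
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(bifurcation_value(base_params), abs=1e-9)


class TestCoexistencePair:
    def test_sigma_zero_empty(self, base_params):
        assert coexistence_pair(base_params.replace(sigma=0.0)) == []

    def test_negative_discriminant_empty(self, base_params):
        # gamma_p < 2 sqrt(sigma) (1 - delta_p) ~ 0.327
        assert coexistence_pair(base_params.replace(gamma_p=0.1)) == []

    def test_ghost_parameters_pair_are_fixed_points(self, base_params):
        gamma_p = 0.9912 * bifurcation_value(base_params)
        params = base_params.replace(gamma_p=gamma_p)
        pair = coexistence_pair(params)
        assert len(pair) == 2
        for s in pair:
            nxt = step(s, params)
            assert abs(nxt.p - s.p) < 1e-10 and abs(nxt.n - s.n) < 1e-10

    def test_matches_newton_grid_scan_oracle(self, base_params):
        """Independent oracle: 2-D Newton refinement seeded from a dense
        grid scan of the positive quadrant finds the same interior fixed
        points, and no others."""
        gamma_p = 0.9912 * bifurcation_value(base_params)
        params = base_params.replace(gamma_p=gamma_p)

        def newton(p, n):
            for _ in range(60):
                s = State(max(p, 1e-14), max(n, 1e-14))
                F = np.array([step(s, params).p - s.p, step(s, params).n - s.n])
                J = fd_jacobian(s, params, h_scale=1e-7) - np.eye(2)
                try:
                    d = np.linalg.solve(J, F)
                except np.linalg.LinAlgError:
                    return None
                p, n = s.p - d[0], s.n - d[1]
                if np.max(np.abs(d)) < 1e-13:
                    return p, n
            return None

        found: list[tuple[float, float]] = []
        for p0 in np.linspace(0.05, 2.0, 12):
            for n0 in np.linspace(0.05, 9.5, 12):
                root = newton(p0, n0)
                if root is None:
                    continue
                p, n = root
                if p > 1e-8 and n > 1e-8 and not any(
                        abs(p - q) < 1e-6 and abs(n - m) < 1e-6 for q, m in found):
                    found.append((p, n))
        pair = coexistence_pair(params)
        assert len(found) == len(pair) == 2
        for s in pair:
            assert any(abs(s.p - q) < 1e-8 and abs(s.n - m) < 1e-8 for q, m in found)

    def test_single_low_branch_above_bifurcation(self, cycling_params):
        """Above the bifurcation the upper branch leaves the first
        quadrant; only the low-resource saddle remains."""
        pair = coexistence_pair(cycling_params)
        assert len(pair) == 1
        assert pair[0].n < 1.0 / math.sqrt(cycling_params.sigma)

    def test_unstable_below_bifurcation(self, base_params):
        cat = catalog(base_params)
        for label in (LABEL_COEXISTENCE_LOW, LABEL_COEXISTENCE_HIGH):
            eq = cat.get(label)
            assert eq is not None
            assert eq.stability in ("saddle", "unstable")


class TestJacobian:
    def test_triangular_at_carrying_capacity(self, base_params):
        n_star = carrying_capacity(base_params)
        J = jacobian(State(0.0, n_star), base_params)
        assert J[0, 1] == 0.0
        assert J[0, 0] == pytest.approx(lambda1(base_params), rel=1e-14)
        expected = base_params.delta_n + base_params.R / (1 + n_star) ** 2
        assert J[1, 1] == pytest.approx(expected, rel=1e-14)

    def test_eigenvalues_at_origin(self, base_params):
        J = jacobian(State(0.0, 0.0), base_params)
        eig = sorted(np.linalg.eigvals(J).real)
        assert eig[0] == pytest.approx(base_params.delta_p, rel=1e-14)
        assert eig[1] == pytest.approx(base_params.delta_n + base_params.R, rel=1e-14)

    def test_agrees_with_finite_differences(self, base_params, param_sampler):
        rng = np.random.default_rng(7)
        for _ in range(25):
            params = param_sampler(rng)
            s = State(rng.uniform(0.01, 10.0), rng.uniform(0.01, 10.0))
            np.testing.assert_allclose(jacobian(s, params), fd_jacobian(s, params),
                                       rtol=1e-5, atol=1e-8)


class TestCatalog:
    def test_below_bifurcation_carrying_capacity_stable(self, base_params):
        cat = catalog(base_params)
        assert cat.get(LABEL_CARRYING_CAPACITY).stability == "stable"
        assert cat.gamma_p_star == bifurcation_value(base_params)
        assert cat.lambda_1 == lambda1(base_params)

    def test_above_bifurcation_no_stable_fixed_point(self, cycling_params):
        cat = catalog(cycling_params)
        assert not cat.has_stable
        assert cat.get(LABEL_CARRYING_CAPACITY).stability in ("saddle", "unstable")

    def test_extinction_never_stable_when_replenishing(self, base_params, param_sampler):
        rng = np.random.default_rng(11)
        for _ in range(25):
            cat = catalog(param_sampler(rng))
            assert cat.get(LABEL_EXTINCTION).stability in ("saddle", "unstable")

    def test_all_entries_are_fixed_points(self, base_params):
        cat = catalog(base_params)
        assert len(cat.equilibria) == 4
        for eq in cat.equilibria:
            assert eq.residual(base_params) < 1e-10
            assert eq.in_first_quadrant
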