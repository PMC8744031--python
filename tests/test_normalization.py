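"""Maximal-inequality benchmark and normalized indices."""

import numpy as np
import pytest

import lifeineq as li
from conftest import random_distribution
from test_indices import brute_force_aid

DIST_INDICES = ("AID", "G", "sigma", "CV")


class TestBenchmark:
    def test_symmetric_case(self):
        bm = li.max_inequality_distribution(61.0, 122.0)
        assert bm.s1 == pytest.approx(0.5)

    def test_quarter_share(self):
        bm = li.max_inequality_distribution(91.5, 122.0)
        assert bm.s1 == pytest.approx(0.25)

    def test_mean_identity_random(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            omega = rng.uniform(10.0, 500.0)
            e0 = rng.uniform(0.01, 0.999) * omega
            bm = li.max_inequality_distribution(e0, omega)
            assert bm.dist.e0 == pytest.approx(e0, rel=1e-12)

    @pytest.mark.parametrize("e0,omega", [(122.0, 122.0), (130.0, 122.0), (0.0, 122.0), (-5.0, 122.0)])
    def test_domain_errors(self, e0, omega):
        with pytest.raises(li.LifeTableError):
            li.max_inequality_distribution(e0, omega)


class TestMaxAid:
    def test_closed_form_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            omega = rng.uniform(10.0, 500.0)
            e0 = rng.uniform(0.05, 0.95) * omega
            bm = li.max_inequality_distribution(e0, omega)
            assert li.max_aid(e0, omega) == pytest.approx(
                brute_force_aid(bm.dist), abs=1e-10
            )
            assert li.max_aid(e0, omega) == pytest.approx(li.aid(bm.dist), abs=1e-12)

    def test_peak_at_half_omega(self):
        grid = np.linspace(0.5, 121.5, 1211)
        values = [li.max_aid(e0, 122.0) for e0 in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(61.0)
        assert li.max_aid(61.0, 122.0) == pytest.approx(30.5)

    def test_boundary_limits(self):
        assert li.max_aid(1e-9, 122.0) == pytest.approx(0.0, abs=1e-8)
        assert li.max_aid(122.0 - 1e-9, 122.0) == pytest.approx(0.0, abs=1e-8)


class TestClosedFormDenominators:
    """Each closed form equals direct evaluation of its index on M(e0, omega)."""

    @pytest.mark.parametrize("name", DIST_INDICES)
    def test_distribution_indices(self, name):
        rng = np.random.default_rng(11)
        for _ in range(200):
            omega = rng.uniform(50.0, 300.0)
            e0 = rng.uniform(0.05, 0.95) * omega
            bm = li.max_inequality_distribution(e0, omega)
            direct = li.compute_index(name, bm.dist)
            assert li.max_index_value(name, e0, omega) == pytest.approx(direct, rel=1e-10)

    def test_edagger_and_entropy_on_two_point_table(self):
        # the life-table realization of the benchmark: e-dagger_max = e0(w-e0)/w
        s1 = 0.35
        mx = np.zeros(91)
        mx[0] = s1 / (1 - s1)
        mx[-1] = 1e9
        ax = np.full(91, 0.5)
        ax[0] = 0.0
        lt = li.build_lifetable_from_mx(mx, ax)
        dist = li.deaths_distribution(lt)
        omega = dist.max_xbar
        e0 = dist.e0
        assert li.max_index_value("edagger", e0, omega) == pytest.approx(
            li.e_dagger(lt), rel=1e-6
        )
        assert li.max_index_value("H", e0, omega) == pytest.approx(
            li.entropy(lt), rel=1e-6
        )


class TestNormalizedIndex:
    @pytest.mark.parametrize("name", DIST_INDICES)
    def test_self_normalization_is_one(self, name):
        bm = li.max_inequality_distribution(70.0, 122.0)
        assert li.normalized_index(name, bm.dist, 122.0) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_is_zero(self, fx):
        dist = fx["degenerate"](80.0)
        for name in DIST_INDICES:
            assert li.normalized_index(name, dist, 122.0) == 0.0

    def test_gstar_algebra(self):
        # G = 0.1 at e0 = 61, omega = 122: G* = 0.1 / (61/122) = 0.2
        g = 0.1
        e0 = 61.0
        assert g / li.max_index_value("G", e0, 122.0) == pytest.approx(0.2)

    def test_mass_above_omega_rejected(self, fx):
        dist = fx["two_point"](61.0, 122.0)
        with pytest.raises(li.LifeTableError, match="exceeds omega"):
            li.normalized_index("G", dist, 100.0)

    def test_aid_star_equals_g_star(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            dist = random_distribution(rng)
            if dist.e0 <= 0:
                continue
            a = li.normalized_aid(dist, 122.0)
            g = li.normalized_gini(dist, 122.0)
            assert abs(a - g) < 1e-12

    def test_maximality_and_unit_range(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            dist = random_distribution(rng)
            e0 = dist.e0
            for name in DIST_INDICES:
                value = li.compute_index(name, dist)
                assert value <= li.max_index_value(name, e0, 122.0) * (1 + 1e-9)
                istar = li.normalized_index(name, dist, 122.0)
                assert -1e-12 <= istar <= 1 + 1e-9

    def test_limit_to_classical_gini(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            dist = random_distribution(rng)
            g = li.gini(dist)
            if g == 0:
                continue
            omega_big = 1e5 * dist.e0
            gstar = li.normalized_gini(dist, omega_big)
            assert abs(gstar - g) / g < 1e-3

    def test_strictly_decreasing_in_omega(self):
        rng = np.random.default_rng(23)
        dist = random_distribution(rng)
        omegas = np.linspace(122.0, 5000.0, 50)
        values = [li.normalized_gini(dist, w) for w in omegas]
        assert np.all(np.diff(values) < 0)
        assert values[-1] > li.gini(dist)
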