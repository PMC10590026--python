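"""Band Option 3 collision model against Monte Carlo blade-interception
oracles, plus the farm-configuration and comparison machinery."""

import numpy as np
import pandas as pd
import pytest

from altiflight import crm
from altiflight.crm import (
    BirdParams,
    TurbineConfig,
    compare_collisions,
    make_farm_configs,
    monthly_collisions,
    option3_collision_integral,
    single_transit_risk,
)
from altiflight.heights import HeightDistribution

from crm_oracles import mc_farm_month, mc_transit_risk


def fixture_turbines():
    """Three turbines spanning the 12-config size range."""
    farms = make_farm_configs()
    return [farms[0].turbine, farms[5].turbine, farms[11].turbine]


def skewed_distribution(shift_m: float = 0.0) -> HeightDistribution:
    """Low-altitude-skewed gamma(2, 20) band distribution, optionally
    shifted upward."""
    from scipy import stats

    edges = np.arange(0.0, 501.0)
    props = stats.gamma.cdf(edges[1:] - shift_m, 2.0, scale=20.0) - stats.gamma.cdf(
        edges[:-1] - shift_m, 2.0, scale=20.0
    )
    props = np.clip(props, 0, None)
    return HeightDistribution(edges, props / props.sum(), n=0)


class TestSingleTransit:
    def test_zero_for_stationary_blades_and_point_bird(self):
        t = TurbineConfig(hub_height_m=100.0, rotor_radius_m=50.0, rotation_rpm=0.0, max_chord_m=0.0)
        b = BirdParams(wingspan_m=1e-12, length_m=1e-12)
        assert single_transit_risk(t, b, 10.0) < 1e-9

    def test_nondecreasing_in_rotation_speed(self):
        b = BirdParams()
        risks = [
            single_transit_risk(
                TurbineConfig(hub_height_m=100.0, rotor_radius_m=50.0, rotation_rpm=rpm), b, 10.0
            )
            for rpm in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(risks, risks[1:]))

    def test_outside_disk_rejected(self):
        t = TurbineConfig(hub_height_m=100.0, rotor_radius_m=50.0)
        with pytest.raises(ValueError):
            single_transit_risk(t, BirdParams(), 51.0)

    @pytest.mark.parametrize("iturb", [0, 1, 2])
    @pytest.mark.parametrize("y_frac", [-0.6, 0.1, 0.8])
    def test_matches_monte_carlo_oracle(self, iturb, y_frac):
        turbine = fixture_turbines()[iturb]
        bird = BirdParams()
        y = y_frac * turbine.rotor_radius_m
        analytic = single_transit_risk(turbine, bird, y)
        mc = mc_transit_risk(turbine, bird, y, n=1_000_000, seed=17 + iturb)
        assert mc == pytest.approx(analytic, rel=0.01)


class TestOption3Integral:
    def test_distribution_below_rotor_gives_zero(self):
        t = TurbineConfig(hub_height_m=150.0, rotor_radius_m=50.0)
        edges = np.arange(0.0, 501.0)
        props = np.zeros(500)
        props[:50] = 1 / 50  # all mass below 50 m, lower tip at 100 m
        d = HeightDistribution(edges, props, n=0)
        integral, q = option3_collision_integral(t, BirdParams(), d)
        assert integral == 0.0 and q == 0.0

    def test_uniform_distribution_recovers_disk_average(self):
        turbine = fixture_turbines()[1]
        bird = BirdParams()
        R = turbine.rotor_radius_m
        hub = turbine.hub_height_m
        # fine bands so the tip-band discretization (sqrt edge of the disk)
        # does not dominate the comparison
        edges = np.arange(0.0, 500.01, 0.125)
        props = np.zeros(len(edges) - 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        span = (mids > hub - R) & (mids < hub + R)
        props[span] = 1.0 / span.sum()
        d = HeightDistribution(edges, props, n=0)
        integral, q = option3_collision_integral(turbine, bird, d)

        # independent disk average by polar quadrature
        from numpy.polynomial.legendre import leggauss

        ru, wu = leggauss(64)
        r = (ru + 1) / 2 * R
        th, wt = leggauss(64)
        theta = (th + 1) * np.pi
        acc = 0.0
        for ri, wri in zip(r, wu):
            x = ri * np.cos(theta)
            y = ri * np.sin(theta)
            p = crm._point_risk(turbine, bird, x, y)
            acc += wri * ri * np.sum(wt * p)
        disk_avg = acc * (R / 2) * np.pi / (np.pi * R**2)
        assert integral / q == pytest.approx(disk_avg, rel=2e-3)

    def test_upward_shift_toward_hub_increases_integral(self):
        turbine = fixture_turbines()[0]
        base = skewed_distribution()
        shifted = skewed_distribution(shift_m=11.0)
        i0, _ = option3_collision_integral(turbine, BirdParams(), base)
        i1, _ = option3_collision_integral(turbine, BirdParams(), shifted)
        assert i1 > i0

    def test_unnormalized_rejected(self):
        t = fixture_turbines()[0]
        d = skewed_distribution()
        d.proportions = d.proportions * 0.9
        with pytest.raises(ValueError):
            option3_collision_integral(t, BirdParams(), d)

    def test_band_refinement_invariance(self):
        from scipy import stats as st

        turbine = fixture_turbines()[1]
        bird = BirdParams()
        results = []
        for band in (1.0, 0.5):
            edges = np.arange(0.0, 500.0 + band / 2, band)
            props = st.gamma.cdf(edges[1:], 2.0, scale=20.0) - st.gamma.cdf(edges[:-1], 2.0, scale=20.0)
            d = HeightDistribution(edges, props / props.sum(), n=0)
            integral, _ = option3_collision_integral(turbine, bird, d)
            results.append(integral)
        assert results[1] == pytest.approx(results[0], rel=0.005)


class TestMonthlyCollisions:
    def test_zero_density_zero_collisions(self):
        farm = make_farm_configs()[0]
        est = monthly_collisions(farm, BirdParams(), 0.0, "June", skewed_distribution())
        assert est.collisions == 0.0

    def test_linear_in_density_and_avoidance(self):
        farm = make_farm_configs()[0]
        d = skewed_distribution()
        c1 = monthly_collisions(farm, BirdParams(), 1.0, "June", d).collisions
        c2 = monthly_collisions(farm, BirdParams(), 2.0, "June", d).collisions
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        b_half = BirdParams(avoidance=0.99)
        c3 = monthly_collisions(farm, b_half, 1.0, "June", d).collisions
        assert c3 == pytest.approx(2 * c1, rel=1e-9)  # (1-A) doubles

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            monthly_collisions(make_farm_configs()[0], BirdParams(), -1.0, "June", skewed_distribution())

    @pytest.mark.parametrize("ifarm", [0, 5, 11])
    def test_matches_end_to_end_monte_carlo(self, ifarm):
        farm = make_farm_configs()[ifarm]
        bird = BirdParams()
        d = skewed_distribution()
        est = monthly_collisions(farm, bird, 2.0, "June", d).collisions
        mc = mc_farm_month(farm, bird, d, 2.0, crm.MONTH_HOURS["June"], n=4_000_000, seed=5 + ifarm)
        assert mc == pytest.approx(est, rel=0.02)


class TestFarmConfigs:
    def test_per_turbine_capacity_rounding(self):
        farms = make_farm_configs(capacity_coef_mw_per_m2=3.58 / 40.0**2, radius_range=(40.0, 110.0))
        assert farms[0].n_turbines == round(430.0 / 3.58) == 120

    def test_counts_decrease_with_size(self):
        farms = make_farm_configs()
        counts = [f.n_turbines for f in farms]
        assert counts == sorted(counts, reverse=True)
        assert farms[-1].n_turbines < farms[0].n_turbines

    def test_total_capacity(self):
        for f in make_farm_configs():
            assert f.n_turbines * f.turbine.rated_mw == pytest.approx(430.0, abs=1.0)

    def test_lower_tip_above_sea(self):
        for f in make_farm_configs():
            assert f.turbine.hub_height_m > f.turbine.rotor_radius_m

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            make_farm_configs(total_mw=1.0, capacity_coef_mw_per_m2=1.0)


class TestQualitativePatterns:
    """The method-difference patterns reported for Option 3 CRMs."""

    def setup_method(self):
        self.farms = make_farm_configs()
        self.bird = BirdParams()
        self.base = skewed_distribution()
        self.shifted = skewed_distribution(shift_m=11.0)

    def _totals(self, dist):
        return np.array(
            [monthly_collisions(f, self.bird, 2.0, "June", dist).collisions for f in self.farms]
        )

    def test_upward_shift_raises_collisions_everywhere(self):
        # rotor bands all sit above the ~20 m distribution mode
        base, shifted = self._totals(self.base), self._totals(self.shifted)
        assert np.all(shifted > base)

    def test_totals_decrease_with_turbine_size(self):
        totals = self._totals(self.base)
        assert np.all(np.diff(totals) < 0)

    def test_method_gap_narrows_with_turbine_size(self):
        gap = self._totals(self.shifted) - self._totals(self.base)
        assert gap[-1] < gap[0]
        # overall trend downward: late-sequence gaps below early-sequence
        assert gap[8:].mean() < gap[:4].mean()


class TestCompareCollisions:
    def _frame(self, deltas, sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, delta in deltas.items():
            vals = delta + rng.normal(0, sd, 48)
            for v in vals:
                rows.append({"group": g, "collisions": v})
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        df = self._frame({"a": 10.0, "b": 10.0}, sd=0.5)
        out = compare_collisions(df)
        assert abs(out["mean_difference"].iloc[0]) < 0.3
        assert out["p_adjusted"].iloc[0] > 0.2

    def test_separated_groups(self):
        df = self._frame({"a": 10.0, "b": 15.0}, sd=0.01)
        out = compare_collisions(df)
        assert out["mean_difference"].iloc[0] == pytest.approx(-5.0, abs=0.1)
        assert out["p_adjusted"].iloc[0] < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_collisions(self._frame({"a": 1.0}))

    def test_familywise_error_calibrated(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "group": np.repeat(["a", "b", "c"], 20),
                    "collisions": rng.normal(0, 1, 60),
                }
            )
            out = compare_collisions(df)
            hits += (out["p_adjusted"] < 0.05).any()
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)
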