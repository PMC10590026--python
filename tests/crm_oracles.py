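"""Monte Carlo blade-interception oracles shared by the CRM tests.

Event-based simulation of the same transit geometry as the production
integrator: each blade's rotation delay to the bird's angular window
decides the hit, so overlapping windows and the p = 1 cap are handled
naturally rather than by the analytic min(1, .) formula.
"""

import numpy as np

from altiflight.crm import BirdParams, TurbineConfig


def _window(x, y, half_span):
    a1 = np.arctan2(y, x - half_span)
    a2 = np.arctan2(y, x + half_span)
    d = np.mod(a2 - a1, 2.0 * np.pi)
    theta_a = np.where(d <= np.pi, a1, a2)
    width = np.where(d <= np.pi, d, 2.0 * np.pi - d)
    return theta_a, width


def mc_hits(turbine: TurbineConfig, bird: BirdParams, x, y, phase):
    """Boolean hit per simulated transit at in-plane position (x, y)."""
    R = turbine.rotor_radius_m
    r = np.clip(np.hypot(x, y), 1e-9, R)
    depth = turbine.chord_at(r / R) * np.sin(turbine.pitch_rad)
    tau = (depth + bird.length_m) / bird.speed_ms
    theta_a, width = _window(x, y, bird.wingspan_m / 2.0)
    hit = np.zeros(len(np.atleast_1d(x)), dtype=bool)
    for k in range(turbine.n_blades):
        blade0 = phase + 2.0 * np.pi * k / turbine.n_blades
        delay = np.mod(theta_a - blade0, 2.0 * np.pi)
        inside_initially = delay >= 2.0 * np.pi - width
        reaches = delay <= turbine.omega * tau
        hit |= inside_initially | reaches
    return hit


def mc_transit_risk(turbine, bird, y, n, seed):
    """Chord- and phase-averaged transit risk at height y above hub."""
    rng = np.random.default_rng(seed)
    half_chord = np.sqrt(turbine.rotor_radius_m**2 - y**2)
    x = rng.uniform(-half_chord, half_chord, n)
    phase = rng.uniform(0.0, 2.0 * np.pi, n)
    return mc_hits(turbine, bird, x, np.full(n, y), phase).mean()


def mc_farm_month(farm, bird, dist, density_per_km2, month_hours, n, seed):
    """End-to-end Monte Carlo: birds drawn from the height distribution
    crossing a gate of rotor-diameter width at one farm for one month."""
    rng = np.random.default_rng(seed)
    turbine = farm.turbine
    R = turbine.rotor_radius_m
    edges = dist.band_edges
    total_hit = 0
    done = 0
    while done < n:
        m = min(1_000_000, n - done)
        band = rng.choice(len(dist.proportions), size=m, p=dist.proportions)
        y = rng.uniform(edges[band], edges[band + 1]) - turbine.hub_height_m
        x = rng.uniform(-R, R, m)
        inside = x**2 + y**2 <= R**2
        if inside.any():
            phase = rng.uniform(0, 2 * np.pi, int(inside.sum()))
            total_hit += mc_hits(turbine, bird, x[inside], y[inside], phase).sum()
        done += m
    p_hit = total_hit / n
    density_m2 = density_per_km2 / 1e6
    transits = density_m2 * bird.speed_ms * month_hours * 3600.0 * 2.0 * R
    op = turbine.monthly_operation.get("June", 1.0)
    return (
        farm.n_turbines * transits * p_hit * op * bird.nocturnal_activity * (1 - bird.avoidance)
    )
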