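"""Young--Laplace solver, hysteresis state machine and flatness/coverage metrics."""

import math

import numpy as np
import pytest

from hydraplate import meniscus as mn
from hydraplate.meniscus import MM, UL, UM


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def test_cap_oracle_zero_volume_identity():
    assert mn.spherical_cap_oracle(0.0, 1 * MM) == (0.0, 0.0)


@pytest.mark.parametrize("theta", [10.0, 30.0, 60.0, 90.0])
def test_cap_oracle_round_trip(theta):
    """V(h) then h(V) must invert to the starting angle to 1e-9 relative."""
    rc = 1 * MM
    h = rc * math.tan(math.radians(theta / 2))
    volume = (math.pi * h / 6) * (3 * rc**2 + h**2)
    h_back, theta_back = mn.spherical_cap_oracle(volume, rc)
    assert theta_back == pytest.approx(theta, rel=1e-9)
    assert h_back == pytest.approx(h, rel=1e-9)


def test_cap_oracle_hemisphere_volume():
    rc = 1 * MM
    _, theta = mn.spherical_cap_oracle((2 / 3) * math.pi * rc**3, rc)
    assert theta == pytest.approx(90.0, rel=1e-9)


def test_cap_oracle_rejects_superhemispherical():
    rc = 1 * MM
    with pytest.raises(ValueError):
        mn.spherical_cap_oracle(0.8 * math.pi * rc**3, rc)


# ---------------------------------------------------------------------------
# pinned-cap solver
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("theta", [8.0, 25.0, 45.0, 70.0, 88.0])
def test_zero_gravity_matches_oracle(fluid_g0, theta):
    """Without gravity the solver must reproduce the spherical cap to 0.5%."""
    rc = 2 * MM
    h = rc * math.tan(math.radians(theta / 2))
    volume = (math.pi * h / 6) * (3 * rc**2 + h**2)
    profile = mn.solve_cap_profile(volume, rc, fluid_g0)
    assert profile.apparent_angle == pytest.approx(theta, rel=5e-3)
    assert profile.z[0] == pytest.approx(h, rel=5e-3)


def test_volume_conservation(fluid):
    """Water-like drop, 12 uL pinned at 2.5 mm: volume closed to 0.1%."""
    profile = mn.solve_cap_profile(12 * UL, 2.5 * MM, fluid)
    assert profile.integrate_volume() == pytest.approx(12 * UL, rel=1e-3)
    assert profile.volume == pytest.approx(12 * UL, rel=1e-3)


def test_angle_monotone_in_volume(fluid):
    rc = 2.0 * MM
    angles = [mn.solve_cap_profile(v * UL, rc, fluid).apparent_angle
              for v in (1.0, 2.0, 4.0, 7.0)]
    assert np.all(np.diff(angles) > 0)


def test_profile_contract(fluid):
    p = mn.solve_cap_profile(5 * UL, 2 * MM, fluid)
    assert p.r[0] == 0.0 and p.r[-1] == pytest.approx(2 * MM)
    assert np.all(np.diff(p.r) > 0)
    assert np.all(p.z >= 0)
    assert len(p.r) >= 400


def test_solver_rejects_bad_inputs(fluid):
    with pytest.raises(ValueError):
        mn.solve_cap_profile(-1 * UL, 2 * MM, fluid)
    with pytest.raises(ValueError):
        mn.solve_cap_profile(float("nan"), 2 * MM, fluid)


# ---------------------------------------------------------------------------
# wall meniscus
# ---------------------------------------------------------------------------


def test_wall_meniscus_flat_limit(fluid, well):
    """90 deg wall angle: the interface is a flat disk at V / (pi Rw^2)."""
    volume = 15 * UL
    p = mn.solve_wall_meniscus(volume, well, fluid, theta_wall=90.0)
    expected = volume / (math.pi * well.radius**2)
    assert np.allclose(p.z, expected, rtol=1e-6, atol=1e-9)
    assert mn.flatness_metric(p, well) == pytest.approx(100.0)


def test_wall_meniscus_full_coverage(fluid, well, wetting):
    p = mn.solve_wall_meniscus(20 * UL, well, fluid, wetting.theta_wall)
    assert mn.coverage_metric(p, well) == 100.0
    assert p.wall_contact
    assert p.integrate_volume() == pytest.approx(20 * UL, rel=1e-3)


def test_wall_meniscus_infeasible_volume(fluid, well, wetting):
    with pytest.raises(mn.InfeasibleConfigurationError):
        mn.solve_wall_meniscus(0.5 * UL, well, fluid, wetting.theta_wall)


def test_wall_meniscus_flatness_volume_invariant(fluid, well, wetting):
    """The slope profile is volume-independent; flatness must not move."""
    f1 = mn.flatness_metric(
        mn.solve_wall_meniscus(15 * UL, well, fluid, wetting.theta_wall), well)
    f2 = mn.flatness_metric(
        mn.solve_wall_meniscus(30 * UL, well, fluid, wetting.theta_wall), well)
    assert f1 == pytest.approx(f2, abs=0.5)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_flatness_flat_profile(well):
    r = np.linspace(0, well.radius, 401)
    p = mn.InterfaceProfile(r=r, z=np.full_like(r, 30 * UM),
                            contact_radius=well.radius,
                            volume=math.pi * well.radius**2 * 30 * UM,
                            wall_contact=True, apparent_angle=0.0)
    assert mn.flatness_metric(p, well) == pytest.approx(100.0)


def test_flatness_hemisphere_geometry(well):
    """Hemisphere spanning the well: planar extent is R*sin(3 deg) ~ 5.23%."""
    R = well.radius
    r = np.linspace(0, R * (1 - 1e-9), 2001)
    z = np.sqrt(R**2 - r**2)
    p = mn.InterfaceProfile(r=r, z=z, contact_radius=R,
                            volume=(2 / 3) * math.pi * R**3,
                            wall_contact=False, apparent_angle=90.0)
    assert mn.flatness_metric(p, well) == pytest.approx(100 * math.sin(math.radians(3)),
                                                        rel=0.05)


def test_coverage_ratio(fluid, well):
    p = mn.solve_cap_profile(2 * UL, well.radius / 2, fluid)
    assert mn.coverage_metric(p, well) == pytest.approx(50.0, abs=1e-9)
    bigger = mn.InterfaceProfile(r=np.linspace(0, 2 * well.radius, 5),
                                 z=np.ones(5) * UM, contact_radius=2 * well.radius,
                                 volume=1e-9, wall_contact=False, apparent_angle=1.0)
    with pytest.raises(ValueError):
        mn.coverage_metric(bigger, well)


def test_flatness_bounded_by_coverage(fluid, well):
    """Planar extent of a cap cannot exceed its footprint."""
    for v in (2.0, 6.0, 12.0):
        p = mn.solve_cap_profile(v * UL, 2.5 * MM, fluid)
        assert mn.flatness_metric(p, well) <= mn.coverage_metric(p, well) + 1e-6


# ---------------------------------------------------------------------------
# protocol state machine
# ---------------------------------------------------------------------------


def test_empty_protocol(fluid, well, wetting):
    res = mn.simulate_protocol(mn.DispenseProtocol(steps=()), well, fluid, wetting)
    assert res.empty and res.coverage == 0.0 and res.flatness == 0.0
    assert res.final_profile is None


def test_dispense_24ul_wets_wall(fluid, well, wetting, solver):
    proto = mn.DispenseProtocol(steps=(("dispense", 24 * UL),))
    res = mn.simulate_protocol(proto, well, fluid, wetting, solver=solver)
    assert res.wall_contact_ever
    assert res.coverage == 100.0


def test_dispense_12ul_stays_off_wall(fluid, well, wetting, solver):
    proto = mn.DispenseProtocol(steps=(("dispense", 12 * UL),))
    res = mn.simulate_protocol(proto, well, fluid, wetting, solver=solver)
    assert not res.wall_contact_ever
    assert res.coverage < 100.0
    assert res.final_profile.apparent_angle == pytest.approx(
        wetting.theta_advancing, abs=1.0)


def test_aspiration_pins_footprint(fluid, well, wetting, solver):
    """A small re-aspiration leaves the contact line pinned (hysteresis)."""
    proto = mn.DispenseProtocol(
        steps=(("dispense", 12 * UL), ("aspirate", 3 * UL)),
        residual_volume=0.0)
    res = mn.simulate_protocol(proto, well, fluid, wetting, solver=solver)
    traj = res.trajectory
    rc_dispense_end = traj[traj.volume <= 12 * UL].contact_radius.iloc[-1]
    assert res.final_profile.contact_radius == pytest.approx(rc_dispense_end,
                                                             rel=1e-6)
    asp = traj.iloc[-5:]
    assert asp.pinned.all()


def test_no_hysteresis_removes_path_dependence(fluid, well):
    """theta_adv == theta_rec: dispensing 2V equals dispensing V twice."""
    wet = mn.WettingParams(theta_advancing=50.0, theta_receding=50.0)
    solver = mn.CapSolver(fluid)
    one = mn.simulate_protocol(mn.DispenseProtocol(steps=(("dispense", 8 * UL),)),
                               well, fluid, wet, solver=solver)
    two = mn.simulate_protocol(
        mn.DispenseProtocol(steps=(("dispense", 4 * UL), ("dispense", 4 * UL))),
        well, fluid, wet, solver=solver)
    assert one.coverage == pytest.approx(two.coverage, abs=0.5)


def test_volume_step_validation(fluid, well, wetting):
    proto = mn.DispenseProtocol(steps=(("dispense", 2 * UL),))
    with pytest.raises(ValueError):
        mn.simulate_protocol(proto, well, fluid, wetting, volume_step=2 * UL)


def test_protocol_validation():
    with pytest.raises(ValueError):
        mn.DispenseProtocol(steps=(("sip", 1 * UL),))
    with pytest.raises(ValueError):
        mn.DispenseProtocol(steps=(("dispense", -1 * UL),))


def test_sweep_no_perturbation_matches_nominal(fluid, well, wetting):
    table = mn.robustness_sweep([6 * UL], 0.0, [], well, fluid, wetting)
    assert len(table) == 1
    res = mn.simulate_protocol(mn.hydra_protocol(6 * UL), well, fluid, wetting)
    assert table.flatness_pct.iloc[0] == pytest.approx(res.flatness, abs=1e-6)
    assert table.coverage_pct.iloc[0] == pytest.approx(res.coverage, abs=1e-6)


def test_wetting_params_validation():
    with pytest.raises(ValueError):
        mn.WettingParams(theta_advancing=10.0, theta_receding=20.0)
    with pytest.raises(ValueError):
        mn.WettingParams(theta_wall=0.0)
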