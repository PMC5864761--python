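import dataclasses

import numpy as np
import pytest

from dualmode import synthetic_data as synth
from dualmode.cg_dynamics import (
    BreakTracker,
    ForceExtensionCurve,
    LangevinSettings,
    PullingSettings,
    classify_trajectory,
    default_threshold,
    integrate,
    native_state_stats,
    pull,
    scenario_report,
    unfolding_times,
)
from dualmode.cg_model import (
    CGTopology,
    build_topology,
    native_lj_energy,
    total_energy,
)
from dualmode.contact_map import native_contacts

from conftest import make_two_bead_contact


def single_bead_topology():
    return CGTopology(
        positions=np.zeros((1, 3)),
        chain_of=np.array([0]),
        bonds=np.zeros((0, 2), int),
        bond_lengths=np.zeros(0),
        contacts=np.zeros((0, 2), int),
        contact_sigma=np.zeros(0),
        contact_class=[],
        chirality_quads=np.zeros((0, 4), int),
        chirality_native=np.zeros(0),
    )


@pytest.fixture(scope="module")
def hairpin_top(hairpin):
    return build_topology(hairpin, native_contacts(hairpin))


class TestIntegrator:
    def test_identical_seeds_identical_trajectories(self, hairpin_top):
        st = LangevinSettings(temperature=0.5, steps=2000, sample_stride=100, seed=7)
        a = integrate(hairpin_top, st)
        b = integrate(hairpin_top, st)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_different_seeds_differ(self, hairpin_top):
        st = LangevinSettings(temperature=0.5, steps=2000, sample_stride=100, seed=7)
        a = integrate(hairpin_top, st)
        b = integrate(hairpin_top, dataclasses.replace(st, seed=8))
        assert not np.array_equal(a.positions, b.positions)

    def test_energy_conserved_without_thermostat(self):
        """Gamma = 0, T = 0: the deterministic dynamics conserves E."""
        s = synth.make_helix(10)
        top = build_topology(s, native_contacts(s))
        rng = np.random.default_rng(5)
        x0 = top.positions + rng.normal(0, 0.02, top.positions.shape)
        st = LangevinSettings(temperature=0.0, gamma=1.0, steps=10_000, sample_stride=100)
        st = dataclasses.replace(st, gamma=0.0)
        traj = integrate(top, st, coords0=x0)
        E = [
            total_energy(top, x).total + 0.5 * np.sum(v**2)
            for x, v in zip(traj.positions, traj.velocities)
        ]
        assert max(E) - min(E) < 1e-4

    @pytest.mark.parametrize("integrator", ["gear5", "verlet"])
    def test_harmonic_well_position_variance(self, integrator):
        """Stationary variance in a harmonic well equals k_B T / k."""
        k, T = 2.0, 0.4
        estimates = []
        for seed in (5, 6, 7):
            st = LangevinSettings(
                temperature=T, steps=100_000, equilibration_steps=10_000,
                sample_stride=100, seed=seed, integrator=integrator,
            )
            traj = integrate(
                single_bead_topology(), st, extra_force=lambda x, t: -k * x
            )
            estimates.append(float(np.var(traj.positions)))
        assert np.mean(estimates) == pytest.approx(T / k, rel=0.08)

    def test_equipartition_on_helix(self, helix20):
        top = build_topology(helix20, native_contacts(helix20))
        T = 0.3
        st = LangevinSettings(
            temperature=T, steps=20_000, equilibration_steps=4_000,
            sample_stride=100, seed=11,
        )
        traj = integrate(top, st)
        ke_per_dof = 0.5 * float(np.mean(traj.velocities**2))
        n_samples = traj.velocities.size
        se = (T / 2) * np.sqrt(2.0 / (n_samples / 4))  # ~4-frame correlation
        assert abs(ke_per_dof - T / 2) < 3 * se + 0.02 * T

    def test_blowup_detected(self, hairpin_top):
        bad = hairpin_top.positions + np.array([1e7, 0, 0])
        with pytest.raises(Exception):
            integrate(
                hairpin_top,
                LangevinSettings(temperature=0.1, steps=200, sample_stride=50),
                coords0=bad * 1e3,
            )


class TestThermalStability:
    def test_frozen_native_state(self, hairpin_top):
        res = native_state_stats(
            hairpin_top, [0.02], n_traj=2,
            settings=LangevinSettings(temperature=0, steps=2_000,
                                      equilibration_steps=500, sample_stride=200),
        )
        assert res.P0[0] == pytest.approx(1.0)
        assert res.Q[0] == pytest.approx(1.0)

    def test_melted_at_high_temperature(self, hairpin_top):
        res = native_state_stats(
            hairpin_top, [2.5], n_traj=2,
            settings=LangevinSettings(temperature=0, steps=4_000,
                                      equilibration_steps=1_000, sample_stride=200),
        )
        assert res.P0[0] < 0.1

    def test_p0_bounded_by_q_and_monotone_in_t(self, hairpin_top):
        res = native_state_stats(
            hairpin_top, [0.05, 0.8, 2.2], n_traj=3,
            settings=LangevinSettings(temperature=0, steps=4_000,
                                      equilibration_steps=1_000, sample_stride=200, seed=3),
        )
        assert np.all(res.P0 <= res.Q + 1e-12)
        assert res.Q[0] >= res.Q[-1]
        assert res.P0[0] >= res.P0[-1]

    def test_t0_crossing_interpolated(self, hairpin_top):
        from dualmode.cg_dynamics import ThermalStabilityResult

        res = ThermalStabilityResult(
            temperatures=np.array([0.2, 0.4, 0.6]),
            P0=np.array([0.9, 0.6, 0.2]),
            Q=np.array([0.95, 0.8, 0.5]),
            n_trajectories=10,
        )
        assert 0.4 < res.T0 < 0.6


class TestUnfolding:
    def test_no_nonlocal_contacts_unfold_immediately(self):
        s = synth.make_helix(6)  # only (i, i+3)/(i, i+4) local contacts
        top = build_topology(s, native_contacts(s))
        assert len(top.nonlocal_contact_indices()) == 0
        res = unfolding_times(top, [1.0], n_traj=2)
        assert np.all(res.times[0] == 0.0)

    def test_median_unfolding_time_decreases_with_temperature(self, hairpin_top):
        res = unfolding_times(
            hairpin_top, [1.2, 1.9], n_traj=7,
            settings=LangevinSettings(temperature=1, steps=40_000,
                                      sample_stride=50, seed=13),
        )
        assert res.unfolded_fraction[0] > 0.5
        assert res.unfolded_fraction[1] > 0.5
        assert res.t_u[1] < res.t_u[0]

    def test_censored_trajectories_reported(self, hairpin_top):
        res = unfolding_times(
            hairpin_top, [0.4], n_traj=2,
            settings=LangevinSettings(temperature=1, steps=1_000, sample_stride=100),
        )
        assert res.unfolded_fraction[0] == 0.0
        assert np.isinf(res.t_u[0])


class TestPulling:
    def test_single_peak_near_quasi_static_bond_strength(self, two_bead_contact):
        """The rupture peak approaches the maximal attractive LJ force."""
        sigma = two_bead_contact.contact_sigma[0]
        r = np.linspace(3.8, 3 * 3.8, 30_000)
        _, F = native_lj_energy(r, sigma)
        f_quasi_static = float(np.max(-F))
        curve = pull(
            two_bead_contact,
            PullingSettings(spring_constant=1.0, speed=5e-3, fixed_bead=0,
                            pulled_bead=1, max_displacement=4.0, window=0.25),
            LangevinSettings(temperature=0.01, seed=2, sample_stride=20, dt=0.02),
        )
        assert curve.f_max == pytest.approx(f_quasi_static, rel=0.20)
        assert np.isfinite(curve.dissociation_d)
        assert 0 in curve.last_break

    def test_free_bead_feels_only_viscous_drag(self):
        top = CGTopology(
            positions=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
            chain_of=np.array([0, 1]),
            bonds=np.zeros((0, 2), int),
            bond_lengths=np.zeros(0),
            contacts=np.zeros((0, 2), int),
            contact_sigma=np.zeros(0),
            contact_class=[],
            chirality_quads=np.zeros((0, 4), int),
            chirality_native=np.zeros(0),
        )
        vp, gamma = 0.01, 2.0
        curve = pull(
            top,
            PullingSettings(spring_constant=0.5, speed=vp, fixed_bead=0,
                            pulled_bead=1, max_displacement=6.0),
            LangevinSettings(temperature=0.0, seed=1, sample_stride=20, dt=0.01),
        )
        # after the transient the spring tension settles at gamma * v_p
        tail = curve.force[len(curve.force) // 2:]
        assert np.mean(tail) == pytest.approx(gamma * vp, rel=0.2)

    def test_peak_force_non_decreasing_in_speed(self):
        f_maxes = []
        for vp in (2e-3, 8e-3, 2e-2):
            curve = pull(
                make_two_bead_contact(),
                PullingSettings(spring_constant=1.0, speed=vp, fixed_bead=0,
                                pulled_bead=1, max_displacement=4.0, window=0.25),
                LangevinSettings(temperature=0.01, seed=4, sample_stride=20, dt=0.02),
            )
            f_maxes.append(curve.f_max)
        assert f_maxes[0] <= f_maxes[1] + 0.05
        assert f_maxes[1] <= f_maxes[2] + 0.05

    def test_same_bead_attachment_rejected(self):
        with pytest.raises(ValueError):
            PullingSettings(fixed_bead=3, pulled_bead=3)

    def test_interface_breaks_precede_dissociation(self, two_body):
        s, _ = two_body
        top = build_topology(s, native_contacts(s))
        chain_b_start = int(np.flatnonzero(top.chain_of == 1)[0])
        curve = pull(
            top,
            PullingSettings(spring_constant=0.5, speed=0.02, fixed_bead=0,
                            pulled_bead=chain_b_start, max_displacement=25.0),
            LangevinSettings(temperature=0.05, seed=6, sample_stride=50),
        )
        interface = set(int(i) for i in top.interface_contact_indices())
        broken_interface = interface & set(curve.last_break)
        assert broken_interface  # interface contacts appear in the break log
        if np.isfinite(curve.dissociation_d):
            assert all(
                curve.last_break[i] <= curve.dissociation_d + 1e-9
                for i in broken_interface
            )


class TestBreakTracker:
    def test_last_break_overwrites_earlier_breaks(self):
        tracker = BreakTracker(np.array([True, True]))
        tracker.update(np.array([False, True]), 10.0)  # contact 0 breaks
        tracker.update(np.array([True, True]), 12.0)  # re-forms
        tracker.update(np.array([False, False]), 20.0)  # both break
        assert tracker.last_break == {0: 20.0, 1: 20.0}

    def test_never_broken_contact_absent(self):
        tracker = BreakTracker(np.array([True]))
        tracker.update(np.array([True]), 5.0)
        assert tracker.last_break == {}


def fake_curve(diss_d: float) -> ForceExtensionCurve:
    return ForceExtensionCurve(
        displacement=np.arange(0.25, diss_d, 0.5),
        force=np.full(max(1, int(diss_d / 0.5)), 1.0),
        last_break={},
        dissociation_d=diss_d,
        complete=True,
    )


class TestClassification:
    def test_short_below_threshold(self):
        assert classify_trajectory(fake_curve(10.0), threshold_d=100.0) == "short"

    def test_all_long_when_threshold_below_everything(self):
        curves = [fake_curve(d) for d in (50.0, 60.0, 70.0)]
        assert all(classify_trajectory(c, 10.0) == "long" for c in curves)

    def test_default_threshold_splits_two_modes(self):
        rng = np.random.default_rng(0)
        diss = np.concatenate([rng.normal(80, 5, 40), rng.normal(200, 8, 60)])
        thr = default_threshold(diss)
        assert 100 < thr < 180

    def test_bimodal_ensemble_fractions_recovered(self):
        """The classifier recovers the generator's mixing weights."""
        rng = np.random.default_rng(1)
        n, p_long = 200, 0.66
        labels = rng.random(n) < p_long
        diss = np.where(labels, rng.normal(200, 10, n), rng.normal(80, 8, n))
        curves = [fake_curve(float(d)) for d in diss]
        top = make_two_bead_contact()
        rep = scenario_report(curves, top, threshold_d=140.0)
        assert rep.fraction_long == pytest.approx(labels.mean(), abs=1e-12)
        assert rep.ci_low < p_long < rep.ci_high

    def test_identical_curves_fraction_one(self):
        curves = [fake_curve(150.0)] * 5
        top = make_two_bead_contact()
        rep = scenario_report(curves, top, threshold_d=100.0)
        assert rep.fraction_long == 1.0
        assert rep.n_total == 5

    def test_break_order_table_matches_manual_aggregation(self):
        curves = []
        for shift in (0.0, 2.0):
            c = fake_curve(50.0)
            c.last_break = {0: 10.0 + shift, 1: 30.0 + shift}
            curves.append(c)
        top = make_two_bead_contact()
        rep = scenario_report(
            curves, top, threshold_d=10.0,
            class_labels={0: "interface", 1: "intra"},
        )
        assert rep.median_last_break == {"interface": 11.0, "intra": 31.0}
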