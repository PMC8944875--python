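"""Model assembly, integration oracles and stride-level behaviour."""
import dataclasses

import numpy as np
import pytest

from carposim.contact import GroundParams
from carposim.dynamics import (
    ForelimbModel,
    ModelConfig,
    assemble_forelimb,
    energy_audit,
    free_body_state,
    hold_drive,
    simulate_stride,
    step,
)
from carposim.errors import AssemblyError, InputError, IntegrationError, ParameterError
from carposim.geometry import BodySegment


def _minimal_model(mass=1.0, com=(0.0, 0.0, 0.05), plane=None, dt_max=1e-5):
    seg = BodySegment("Cr", mass, np.eye(3) * 1e-4 * mass, np.asarray(com, float))
    return ForelimbModel(
        segments={"Cr": seg},
        free_bodies=("Cr",),
        contacts={},
        plane_contacts={"Cr": plane} if plane else {},
        config=ModelConfig(dt_max=dt_max),
    )


class TestAssembly:
    def test_default_component_counts(self):
        model = assemble_forelimb()
        rep = model.validation_report()
        assert rep["n_segments"] == 11
        assert rep["n_hinges"] == 4
        assert rep["n_ligaments"] == 9
        assert rep["n_bushings"] >= 6
        assert rep["n_contact_pairs"] == 4
        assert rep["free_dof"] == 18

    def test_missing_carpal_suspension_is_an_assembly_error(self):
        from carposim.force_elements import default_carpal_bushings, default_carpal_ligaments

        bushings = [b for b in default_carpal_bushings() if b.child != "Cr"]
        with pytest.raises(AssemblyError):
            assemble_forelimb(force_element_set=(default_carpal_ligaments(), bushings))

    def test_assembly_is_deterministic(self):
        m1 = assemble_forelimb()
        m2 = assemble_forelimb()
        for b1, b2 in zip(m1.ligaments, m2.ligaments):
            assert b1.slack_length == b2.slack_length
            assert np.array_equal(b1.origin, b2.origin)
        for a, b in zip(m1.bushings, m2.bushings):
            assert np.array_equal(a.K_t, b.K_t) and np.array_equal(a.frame.p, b.frame.p)
        for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu"):
            assert m1.contacts[pid].stiffness == m2.contacts[pid].stiffness
            assert np.array_equal(m1.contacts[pid].surfA.mesh.vertices, m2.contacts[pid].surfA.mesh.vertices)


class TestStepOracles:
    def test_free_fall_matches_closed_form(self):
        model = _minimal_model(com=(0.0, 0.0, 1.0))
        drive = hold_drive(T=0.2)
        state = free_body_state(model)
        dt = 1e-5
        for i in range(10_000):
            step(model, state, i * dt, dt, drive)
        drop = 1.0 - state.com["Cr"][2]
        assert drop == pytest.approx(0.5 * 9.81 * 0.1**2, abs=1e-6)

    def test_bouncing_on_undamped_contact_conserves_energy(self):
        m, k = 1.0, 1e4
        plane = GroundParams(stiffness=k, exponent=1.0, max_damping=0.0, friction_mu=0.0)
        model = _minimal_model(mass=m, plane=plane)
        drive = hold_drive(T=0.2)
        state = free_body_state(model, com={"Cr": np.array([0.0, 0.0, 0.02])})
        dt = 1e-5

        def energy():
            z = state.com["Cr"][2]
            u = 0.5 * k * min(z, 0.0) ** 2
            return 0.5 * m * state.vel["Cr"] @ state.vel["Cr"] + m * 9.81 * z + u

        e0 = energy()
        worst = 0.0
        for i in range(1_000):  # 10 ms spanning several contact events
            step(model, state, i * dt, dt, drive)
            worst = max(worst, abs(energy() - e0))
        assert worst < 1e-3 * abs(m * 9.81 * 0.02)

    def test_halving_dt_changes_final_pose_below_micron(self):
        plane = GroundParams(stiffness=1e4, exponent=1.0, max_damping=20.0, damping_depth=1e-3, friction_mu=0.0)
        finals = []
        for dt in (1e-5, 5e-6):
            model = _minimal_model(plane=plane, com=(0.0, 0.0, 0.002))
            drive = hold_drive(T=0.02)
            state = free_body_state(model, com={"Cr": np.array([0.0, 0.0, 0.002])})
            for i in range(int(round(0.01 / dt))):
                step(model, state, i * dt, dt, drive)
            finals.append(state.com["Cr"].copy())
        assert np.linalg.norm(finals[0] - finals[1]) < 1e-6

    def test_dt_above_dt_max_rejected(self):
        model = _minimal_model()
        with pytest.raises(ParameterError):
            step(model, free_body_state(model), 0.0, 1e-3, hold_drive())

    def test_divergence_names_the_largest_force_element(self):
        plane = GroundParams(stiffness=1e308, exponent=1.0, max_damping=0.0, friction_mu=0.0)
        model = _minimal_model(plane=plane, com=(0.0, 0.0, -10.0))
        drive = hold_drive(T=0.1)
        state = free_body_state(model, com={"Cr": np.array([0.0, 0.0, -10.0])})
        with pytest.raises(IntegrationError, match="plane_Cr"):
            for i in range(1000):
                step(model, state, i * 1e-5, 1e-5, drive)


class TestEnergyAudit:
    def _conservative(self, dt):
        plane = GroundParams(stiffness=1e4, exponent=1.0, max_damping=0.0, friction_mu=0.0)
        seg = BodySegment("Cr", 1.0, np.eye(3) * 1e-4, np.array([0.0, 0.0, 0.01]))
        cfg = ModelConfig(dt=dt, dt_max=dt, T=0.08, output_dt=1e-4)
        model = ForelimbModel(segments={"Cr": seg}, free_bodies=("Cr",), contacts={}, plane_contacts={"Cr": plane}, config=cfg)
        return simulate_stride(model, hold_drive(T=0.1))

    def test_conservative_configuration_residual_below_1e3(self):
        res = self._conservative(1e-5)
        _, frac = energy_audit(res)
        assert frac < 1e-3

    def test_doubling_dt_grows_the_residual(self):
        r1, _ = energy_audit(self._conservative(1e-5))
        r2, _ = energy_audit(self._conservative(2e-5))
        assert r2 > r1

    def test_dissipated_energy_is_monotone(self, stride_sim):
        d = stride_sim["result"].energy["dissipated"]
        assert np.all(np.diff(d) >= -1e-12)


class TestPresetStride:
    def test_prescribed_hinge_angles_reproduce_the_drive_exactly(self, stride_sim):
        from carposim.dynamics import _prescribed_poses

        model, drive = stride_sim["model"], stride_sim["drive"]
        rng = np.random.default_rng(5)
        for t in rng.uniform(0.0, 0.103, 20):
            vals = {k: float(drive.at(k, t)) for k in drive.interpolants}
            poses = _prescribed_poses(model, vals, 0.0, 0.0)
            rel = poses["metacarpus"].R.T @ poses["radius"].R
            theta = np.degrees(np.arctan2(-rel[2, 0], rel[0, 0]))
            assert 180.0 + theta == pytest.approx(vals["carpus"], abs=1e-9)
            rel_f = poses["metacarpus"].R.T @ poses["phalanx_prox_mid"].R
            theta_f = np.degrees(np.arctan2(-rel_f[2, 0], rel_f[0, 0]))
            assert 180.0 + theta_f == pytest.approx(vals["fetlock"], abs=1e-9)

    def test_action_reaction_closure(self, stride_sim):
        assert stride_sim["result"].closure.max() < 1e-9

    def test_all_three_carpal_surfaces_contact_after_hoof_strike(self, stride_sim):
        res = stride_sim["result"]
        k = np.searchsorted(res.t, res.events["hoof_on"] + 7e-3)
        for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu"):
            assert res.traces[pid].force[k] > 0.0

    def test_contact_forces_decrease_when_swing_begins(self, stride_sim):
        res = stride_sim["result"]
        off = res.events["hoof_off"]
        early_swing = (res.t > off) & (res.t < off + 8e-3)
        for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu"):
            tr = res.traces[pid]
            assert tr.force[early_swing].max() < 0.2 * tr.force.max()

    def test_peak_force_ordering_medial_to_lateral(self, stride_sim):
        res = stride_sim["result"]
        peaks = {pid: res.traces[pid].force.max() for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu")}
        assert peaks["Ra_Cr"] > peaks["Ra_Ci"] > peaks["Ra_Cu"]

    def test_swing_flexion_peak_stays_below_the_stance_peak(self, stride_sim):
        ev = stride_sim["result"].events
        assert ev["swing_peak_Ra_Cr"] > 0.0
        assert ev["swing_peak_Ra_Cr"] < ev["stance_peak_Ra_Cr"]

    def test_coc_migrates_dorsal_palmar_dorsal(self, stride_sim):
        res = stride_sim["result"]
        phi = res.traces["Ra_Cr"].coc_phi
        fin = np.flatnonzero(np.isfinite(phi))
        t_min = res.t[fin[np.argmin(phi[fin])]]
        assert 0.030 <= t_min <= 0.050  # palmar-most near 40 ms
        assert phi[fin[0]] > np.nanmin(phi) + 0.3  # starts clearly dorsal
        assert phi[fin[-1]] > np.nanmin(phi) + 0.3  # returns dorsal by stride end

    def test_static_drive_holds_rest_forces_and_no_events(self):
        cfg = dataclasses.replace(ModelConfig(), T=0.02, resolution=8)
        model = assemble_forelimb(config=cfg)
        res = simulate_stride(model, hold_drive(T=0.05))
        assert res.events["hoof_on"] is None
        for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu"):
            assert np.allclose(res.traces[pid].force, 0.0, atol=1e-9)

    def test_drive_shorter_than_horizon_rejected(self):
        model = assemble_forelimb(config=dataclasses.replace(ModelConfig(), T=0.103, resolution=8))
        with pytest.raises(InputError):
            simulate_stride(model, hold_drive(T=0.05))


def _short_sim(medial_sign):
    cfg = dataclasses.replace(ModelConfig(), T=0.045, resolution=8, medial_sign=medial_sign)
    from carposim.kinematics import build_drive
    from carposim.synthetic_data import asti_2015_preset

    scenario, metrics, _ = asti_2015_preset()
    drive = build_drive(metrics, scenario, T=0.103)
    model = assemble_forelimb(config=cfg)
    return simulate_stride(model, drive)


def test_mirror_symmetry_of_the_stride():
    """A sagittally mirrored model under the mirrored drive yields mirrored
    traces: identical force magnitudes, negated medio-lateral CoC."""
    res_a = _short_sim(+1.0)
    res_b = _short_sim(-1.0)
    for pid in ("Ra_Cr", "Ra_Ci", "Ra_Cu"):
        fa, fb = res_a.traces[pid].force, res_b.traces[pid].force
        assert np.allclose(fa, fb, rtol=0.0, atol=1e-9 * max(fa.max(), 1.0))
        ca, cb = res_a.traces[pid].coc, res_b.traces[pid].coc
        fin = np.isfinite(ca[:, 1]) & np.isfinite(cb[:, 1])
        assert np.allclose(ca[fin, 1], -cb[fin, 1], atol=1e-9)
        assert np.allclose(ca[fin, 0], cb[fin, 0], atol=1e-9)
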