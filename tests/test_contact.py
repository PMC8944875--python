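"""Penalty contact: detection, force law, CoC, ground reaction."""
import numpy as np
import pytest

from carposim.contact import (
    ContactPair,
    ContactState,
    GroundParams,
    center_of_contact,
    contact_force,
    detect_penetration,
    ground_reaction,
)
from carposim.errors import ParameterError
from carposim.geometry import make_radiocarpal_geometry
from carposim.rigid import Pose


@pytest.fixture(scope="module")
def small_pair():
    rad, carp = make_radiocarpal_geometry(cartilage_gap=1.0e-3, resolution=8)
    assert len(rad[2].mesh.faces) <= 500
    return ContactPair(id="Ra_Cu", surfA=rad[2], surfB=carp[2], stiffness=1e7, cth=1.0e-3)


def _brute_force_distances(pair, poseA, poseB):
    """Exhaustive all-pairs point-triangle distance oracle."""
    pts = poseA.transform(pair.surfA.mesh.triangles_center)
    tris = poseB.transform(pair.surfB.mesh.vertices.reshape(-1, 3)).reshape(-1)
    tri = pair.surfB.mesh.triangles
    tri_w = np.array([poseB.transform(t) for t in tri])  # (m, 3, 3)
    out = np.full(len(pts), np.inf)
    for a, b, c in tri_w:
        ab, ac = b - a, c - a
        ap = pts - a
        d1 = ap @ ab
        d2 = ap @ ac
        nn = np.cross(ab, ac)
        # project every point on this triangle's plane and clamp barycentric
        for i, p in enumerate(pts):
            out[i] = min(out[i], _point_tri_dist(p, a, b, c))
    return out


def _point_tri_dist(p, a, b, c):
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


class TestDetectPenetration:
    def test_no_contact_when_separation_exceeds_cartilage(self):
        # contact onset is at separation = C.Th: with the bone surfaces a
        # full cartilage gap apart and a thinner cartilage map, no face may
        # register (mesh sagitta stays well below the margin)
        rad, carp = make_radiocarpal_geometry(cartilage_gap=1.0e-3, resolution=8)
        pair = ContactPair(id="Ra_Cu", surfA=rad[2], surfB=carp[2], stiffness=1e7, cth=0.9e-3)
        assert detect_penetration(pair, Pose.identity(), Pose.identity()) == []

    def test_translation_produces_expected_penetration(self, small_pair):
        # move the radius facet 0.1 mm outward (toward the carpal cup)
        poseA = Pose(np.array([0.0, 0.0, -1.0e-4]))
        hits = detect_penetration(small_pair, poseA, Pose.identity())
        assert hits
        deltas = np.array([h[1] for h in hits])
        edge = 1e-4  # sagitta-scale mesh tolerance at this resolution
        assert deltas.max() == pytest.approx(1.0e-4, abs=edge)

    def test_matches_exhaustive_closest_point_oracle(self, small_pair):
        poseA = Pose(np.array([0.0, 0.0, -1.5e-4]))
        poseB = Pose.identity()
        hits = detect_penetration(small_pair, poseA, poseB)
        dist = _brute_force_distances(small_pair, poseA, poseB)
        delta_oracle = small_pair.cth_at_faces(len(dist)) - dist
        active_oracle = set(np.flatnonzero(delta_oracle > 0))
        assert {h[0] for h in hits} == active_oracle
        for face, delta, _, _ in hits:
            assert delta == pytest.approx(delta_oracle[face], abs=1e-9)

    def test_swap_is_symmetric_with_flipped_normals(self):
        rad, carp = make_radiocarpal_geometry(cartilage_gap=1.0e-3, resolution=8)
        fwd = ContactPair(id="Ra_Cu", surfA=rad[2], surfB=carp[2], stiffness=1e7, cth=1e-3)
        rev = ContactPair(id="Ra_Cu", surfA=carp[2], surfB=rad[2], stiffness=1e7, cth=1e-3)
        poseA = Pose(np.array([0.0, 0.0, -1.5e-4]))
        hits_f = detect_penetration(fwd, poseA, Pose.identity())
        hits_r = detect_penetration(rev, Pose.identity(), poseA)
        df = np.max([h[1] for h in hits_f])
        dr = np.max([h[1] for h in hits_r])
        assert df == pytest.approx(dr, abs=2e-5)  # within mesh resolution
        n_f = hits_f[np.argmax([h[1] for h in hits_f])][2]
        n_r = hits_r[np.argmax([h[1] for h in hits_r])][2]
        assert float(n_f @ n_r) < 0.0


class TestContactForce:
    def test_zero_penetration_zero_force(self):
        assert contact_force(0.0, 0.0, 1e7) == 0.0

    def test_linear_law_evaluation(self):
        # e = 1, k = 1e7 N/m, delta = 0.2 mm -> 2000 N
        assert contact_force(2e-4, 0.0, 1e7, exponent=1.0) == pytest.approx(2000.0, rel=1e-12)

    def test_rapid_withdrawal_clamps_to_no_adhesion(self):
        f = contact_force(1e-4, -10.0, 1e7, exponent=1.5, max_damping=5e3, damping_depth=1e-4)
        assert f == 0.0

    def test_no_adhesion_over_random_inputs(self, rng):
        deltas = rng.uniform(0, 2e-3, 5000)
        rates = rng.normal(0, 1.0, 5000)
        f = contact_force(deltas, rates, 5e7, 1.5, 2e3, 2e-4)
        assert np.all(f >= 0.0)


class TestCenterOfContact:
    def _state(self, points, forces):
        n = len(points)
        return ContactState(
            pair_id="Ra_Cr",
            faces=np.arange(n),
            penetration=np.full(n, 1e-4),
            penetration_rate=np.zeros(n),
            normals=np.tile([0.0, 0.0, 1.0], (n, 1)),
            points=np.asarray(points, float),
            normal_forces=np.asarray(forces, float),
        )

    def test_equal_forces_give_midpoint(self):
        st = self._state([[0, 0, 0], [2, 0, 0]], [10.0, 10.0])
        assert np.allclose(center_of_contact(st), [1, 0, 0])

    def test_single_point_is_its_own_centroid(self):
        st = self._state([[0.3, -0.2, 0.1]], [5.0])
        assert np.allclose(center_of_contact(st), [0.3, -0.2, 0.1])

    def test_matches_exhaustive_weighted_sum(self, rng):
        pts = rng.normal(0, 0.01, (50, 3))
        f = rng.uniform(0, 100, 50)
        st = self._state(pts, f)
        expect = (f[:, None] * pts).sum(axis=0) / f.sum()
        assert np.allclose(center_of_contact(st), expect, atol=1e-15)

    def test_no_active_region_returns_none(self):
        st = self._state(np.zeros((0, 3)), np.zeros(0))
        assert center_of_contact(st) is None


class TestGroundReaction:
    def test_hoof_above_ground_is_unloaded(self):
        assert np.allclose(ground_reaction([0, 0, 0.01], [0, 0, 0]), 0.0)

    def test_static_penetration_normal_only(self):
        gp = GroundParams(stiffness=1e6, exponent=1.0)
        f = ground_reaction([0, 0, -1e-3], [0, 0, 0], gp)
        assert f[2] == pytest.approx(1000.0, rel=1e-12)
        assert np.allclose(f[:2], 0.0)

    def test_coulomb_limit_opposes_sliding(self):
        gp = GroundParams(stiffness=1e6, exponent=1.0, friction_mu=0.55, v_eps=0.05)
        f = ground_reaction([0, 0, -1e-3], [2.0, 0, 0], gp)
        assert f[0] == pytest.approx(-0.55 * 1000.0, rel=1e-3)
        assert f[1] == 0.0


def test_quasi_static_settling_matches_closed_form():
    """A mass resting on a flat e = 1 penalty contact settles to mg/k."""
    from carposim.dynamics import ForelimbModel, ModelConfig, free_body_state, hold_drive, step
    from carposim.geometry import BodySegment

    m, k = 2.0, 1e5
    seg = BodySegment("Cr", m, np.eye(3) * 1e-4, np.zeros(3))
    model = ForelimbModel(
        segments={"Cr": seg},
        free_bodies=("Cr",),
        contacts={},
        plane_contacts={"Cr": GroundParams(stiffness=k, exponent=1.0, max_damping=50.0, damping_depth=1e-4, friction_mu=0.0)},
        config=ModelConfig(),
    )
    drive = hold_drive(T=1.0)
    state = free_body_state(model, com={"Cr": np.array([0.0, 0.0, 1e-5])})
    dt = 1e-5
    for i in range(50_000):
        step(model, state, i * dt, dt, drive)
    expect = m * 9.81 / k
    assert -state.com["Cr"][2] == pytest.approx(expect, rel=0.01)


def test_friction_must_be_zero_for_articular_pairs():
    rad, carp = make_radiocarpal_geometry(resolution=8)
    with pytest.raises(ParameterError):
        ContactPair(id="Ra_Cr", surfA=rad[0], surfB=carp[0], stiffness=1e7, friction_mu=0.3)
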