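"""Driven forelimb multibody model and stride integration.

Structure of the model: the gross limb kinematics (trunk, radius,
metacarpus + fused distal carpal row, phalanges) are position-driven from a
:class:`~carposim.kinematics.DriveSignal`; only the three proximal carpal
bones (Cr, Ci, Cu) are dynamic, each a free 6-DOF rigid body intercalated
between the radius above and the fused distal row below.  They are loaded
by gravity, tension-only ligament branches, six-component bushings, and
penalty contact against the radius trochlear facets; the hoof additionally
contacts the ground plane.  The elbow, carpus, fetlock and distal
interphalangeal joints are sagittal-plane hinges (axis +y) whose angles are
prescribed; P1-P2, C2-C3-C4 and distal row-metacarpus are fixed.

Integration is kick-drift-kick (leapfrog) velocity Verlet with one force
evaluation per step and a velocity predictor for the damping terms: exact
on free fall, symplectic on the stiff penalty-contact springs (bounded
energy oscillation, no drift) at dt = 1e-5 s.  Quaternions are renormalised
every step.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh

from . import force_elements as fe
from .contact import (
    ContactPair,
    GroundParams,
    calibrate_contact_stiffness,
    ground_reaction,
    smooth_step,
)
from .errors import AssemblyError, InputError, IntegrationError, ParameterError
from .geometry import (
    ArticularSurfacePatch,
    BodySegment,
    MaterialParams,
    make_radiocarpal_geometry,
)
from .kinematics import DriveSignal
from .rigid import (
    Pose,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    quat_to_matrix,
    rot_x,
    rot_y,
    rotvec_from_matrix,
)

__all__ = [
    "ModelConfig",
    "ForelimbModel",
    "SimState",
    "SimulationResult",
    "ContactTrace",
    "assemble_forelimb",
    "free_body_state",
    "step",
    "simulate_stride",
    "energy_audit",
    "hold_drive",
]

FREE_BODIES = ("Cr", "Ci", "Cu")
HINGES = (
    ("humerus", "radius", "elbow"),
    ("radius", "distal_row", "carpus"),
    ("metacarpus", "phalanx_prox_mid", "fetlock"),
    ("phalanx_prox_mid", "phalanx_distal", "coffin"),
)
FIXED_JOINTS = (("phalanx_prox_mid",), ("distal_row",), ("distal_row", "metacarpus"))


@dataclass
class ModelConfig:
    """Assembly-time parameters of the forelimb model (SI units)."""

    trunk_mass: float = 500.0
    material: MaterialParams = field(default_factory=MaterialParams)
    facet_radii: tuple = (0.035, 0.035, 0.035)
    facet_widths: tuple = (0.030, 0.025, 0.015)
    cartilage_gap: float = 1.0e-3
    resolution: int = 12
    contact_exponent: float = 1.5
    contact_max_damping: float = 2.0e3
    contact_damping_depth: float = 2.0e-4
    ground: GroundParams = field(default_factory=GroundParams)
    gravity: tuple = (0.0, 0.0, -9.81)
    dt: float = 1.0e-5
    dt_max: float = 1.0e-5
    output_dt: float = 5.0e-4
    T: float = 0.103
    reference_strain: float = 0.0
    event_threshold: float = 5.0  # N, hoof-on/off detection
    metacarpus_length: float = 0.25  # fetlock -> carpus [m]
    pastern_length: float = 0.12  # hoof -> fetlock [m]
    radius_length: float = 0.40  # carpus -> elbow [m]
    trunk_height: float = 1.30
    lean_sign: float = 1.0  # +1 leans toward +y (medial)
    medial_sign: float = 1.0  # -1 builds the sagittal mirror image


@dataclass
class ForelimbModel:
    """Assembled model: segments, joints, force elements and contacts."""

    segments: Dict[str, BodySegment]
    hinges: tuple = HINGES
    fixed_joints: tuple = FIXED_JOINTS
    free_bodies: tuple = FREE_BODIES
    ligaments: List[fe.LigamentBranch] = field(default_factory=list)
    bushings: List[fe.BushingElement] = field(default_factory=list)
    contacts: dict = field(default_factory=dict)  # pair id -> ContactPair | GroundParams
    plane_contacts: dict = field(default_factory=dict)  # free body -> GroundParams
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -9.81]))
    config: ModelConfig = field(default_factory=ModelConfig)
    carpal_y: Dict[str, float] = field(default_factory=dict)
    drive: Optional[DriveSignal] = None

    def validation_report(self) -> dict:
        return {
            "n_segments": len(self.segments),
            "n_hinges": len(self.hinges),
            "n_ligaments": len(self.ligaments),
            "n_bushings": len(self.bushings),
            "n_contact_pairs": len(self.contacts),
            "free_dof": 6 * len(self.free_bodies),
            "prescribed_coordinates": [
                "trunk translation",
                "hoof trajectory",
                "elbow",
                "carpus",
                "fetlock",
                "coffin",
                "limb inclination",
            ],
        }


def _box_segment(seg_id: str, extents, com, density: float) -> BodySegment:
    from .geometry import inertia_from_mesh

    mesh = trimesh.creation.box(extents=extents)
    mass, _, inertia = inertia_from_mesh(mesh, density)
    return BodySegment(seg_id, mass, inertia, np.asarray(com, float))


def _analytic_segment(seg_id: str, mass: float, gyr: float, com=(0, 0, 0)) -> BodySegment:
    return BodySegment(seg_id, mass, np.eye(3) * mass * gyr**2, np.asarray(com, float))


def _carpal_centers(widths, medial_sign: float) -> Dict[str, float]:
    total = sum(widths)
    edges = np.concatenate([[total / 2.0], total / 2.0 - np.cumsum(widths)])
    centers = (edges[:-1] + edges[1:]) / 2.0
    return {b: medial_sign * float(c) for b, c in zip(FREE_BODIES, centers)}


def _mirror_patch(patch: ArticularSurfacePatch) -> ArticularSurfacePatch:
    """Sagittal mirror (y -> -y) of a facet patch, preserving normal sense."""
    v = patch.mesh.vertices.copy()
    v[:, 1] = -v[:, 1]
    mesh = trimesh.Trimesh(vertices=v, faces=patch.mesh.faces[:, ::-1], process=False)
    cyl = patch.cylinder
    if cyl is not None:
        cyl = replace(cyl, y_range=(-cyl.y_range[1], -cyl.y_range[0]))
    return ArticularSurfacePatch(
        mesh=mesh, facet_label=patch.facet_label, dorsal_axis=patch.dorsal_axis, cylinder=cyl
    )


_MIRROR_NAMES = {"l-MCL": "l-LCL", "s-MCL": "s-LCL", "l-MR": "l-LR", "s-MR": "s-LR", "palmar_carpal": "palmar_carpal"}
_MIRROR_NAMES.update({v: k for k, v in _MIRROR_NAMES.items() if v != k})
_MIRROR_BODIES = {"Cr": "Cu", "Cu": "Cr"}


def _mirror_ligament(br: fe.LigamentBranch) -> fe.LigamentBranch:
    flip = np.array([1.0, -1.0, 1.0])
    return replace(
        br,
        name=_MIRROR_NAMES[br.name],
        parent=_MIRROR_BODIES.get(br.parent, br.parent),
        child=_MIRROR_BODIES.get(br.child, br.child),
        origin=br.origin * flip,
        insertion=br.insertion * flip,
    )


def _mirror_bushing(b: fe.BushingElement) -> fe.BushingElement:
    return replace(
        b,
        parent=_MIRROR_BODIES.get(b.parent, b.parent),
        child=_MIRROR_BODIES.get(b.child, b.child),
        frame=Pose(b.frame.p * np.array([1.0, -1.0, 1.0]), b.frame.q.copy()),
    )


def assemble_forelimb(
    geometry_set=None,
    force_element_set=None,
    contact_set=None,
    config: ModelConfig = None,
    validate: bool = True,
) -> ForelimbModel:
    """Build the forelimb model from geometry, force elements and contacts.

    Any argument left ``None`` is built from the shipped defaults for the
    given config.  Deterministic: two assemblies from the same config carry
    bit-identical parameter tables.  Raises :class:`AssemblyError` when a
    free carpal bone is not suspended by bushings both from the radius and
    from the distal row.
    """
    cfg = config or ModelConfig()
    density = cfg.material.bone_density

    if geometry_set is None:
        radius_patches, carpal_patches = make_radiocarpal_geometry(
            cfg.facet_radii, cfg.facet_widths, cfg.cartilage_gap, cfg.resolution
        )
        if cfg.medial_sign < 0:
            radius_patches = [_mirror_patch(p) for p in radius_patches]
            carpal_patches = [_mirror_patch(p) for p in carpal_patches]
    else:
        radius_patches, carpal_patches = geometry_set

    carpal_y = _carpal_centers(cfg.facet_widths, cfg.medial_sign)

    if force_element_set is None:
        ligaments = fe.default_carpal_ligaments()
        # carpal_y is already mirrored, so the bushing frames come out on the
        # correct side; ligament attachments are y-flipped in place (each bone
        # keeps its own branches -- in the mirror image the medial side is -y)
        bushings = fe.default_carpal_bushings(carpal_y=carpal_y)
        if cfg.medial_sign < 0:
            flip = np.array([1.0, -1.0, 1.0])
            ligaments = [replace(b, origin=b.origin * flip, insertion=b.insertion * flip) for b in ligaments]
    else:
        ligaments, bushings = force_element_set

    if contact_set is None:
        contacts = {}
        for pid, ra, ca in zip(("Ra_Cr", "Ra_Ci", "Ra_Cu"), radius_patches, carpal_patches):
            k_c = calibrate_contact_stiffness(
                cfg.material.cartilage_modulus, ra.area, cfg.cartilage_gap, cfg.contact_exponent
            )
            contacts[pid] = ContactPair(
                id=pid,
                surfA=ra,
                surfB=ca,
                stiffness=k_c,
                exponent=cfg.contact_exponent,
                max_damping=cfg.contact_max_damping,
                damping_depth=cfg.contact_damping_depth,
                cth=cfg.cartilage_gap,
            )
        contacts["hoof_ground"] = cfg.ground
    else:
        contacts = dict(contact_set)

    # --- body segments -----------------------------------------------------
    from .geometry import inertia_from_mesh

    trunk_mesh = trimesh.creation.cylinder(radius=0.30, height=1.60, sections=64)
    _, _, trunk_inertia_unit = inertia_from_mesh(trunk_mesh, 1.0)
    trunk_inertia = trunk_inertia_unit * (cfg.trunk_mass / trunk_mesh.volume)
    segments = {
        "trunk": BodySegment("trunk", cfg.trunk_mass, trunk_inertia, np.zeros(3)),
        "humerus": _analytic_segment("humerus", 3.0, 0.08),
        "ulna": _analytic_segment("ulna", 0.5, 0.05),
        "radius": _analytic_segment("radius", 2.5, 0.10, com=(0, 0, cfg.radius_length / 2)),
        "distal_row": _analytic_segment("distal_row", 0.6, 0.03, com=(0, 0, -0.05)),
        "metacarpus": _analytic_segment("metacarpus", 0.8, 0.07, com=(0, 0, -cfg.metacarpus_length / 2)),
        "phalanx_prox_mid": _analytic_segment("phalanx_prox_mid", 0.35, 0.04),
        "phalanx_distal": _analytic_segment("phalanx_distal", 0.25, 0.03),
    }
    for bone, width in zip(FREE_BODIES, cfg.facet_widths):
        segments[bone] = _box_segment(bone, (0.045, width, 0.030), (0.0, carpal_y[bone], -0.030), density)

    model = ForelimbModel(
        segments=segments,
        ligaments=ligaments,
        bushings=bushings,
        contacts=contacts,
        gravity=np.asarray(cfg.gravity, float),
        config=cfg,
        carpal_y=carpal_y,
    )

    if validate:
        for bone in model.free_bodies:
            parents = {b.parent for b in bushings if b.child == bone}
            if "radius" not in parents or "distal_row" not in parents:
                raise AssemblyError(
                    f"free body {bone} must be suspended by bushings from both the radius and the distal row"
                )
        for br in ligaments:
            for seg_id in (br.parent, br.child):
                if seg_id not in segments:
                    raise AssemblyError(f"ligament {br.name} references missing segment {seg_id}")

    # slack lengths tuned at the reference (rest) pose: all frames coincident
    rest = {sid: Pose.identity() for sid in segments}
    model.ligaments = fe.tune_slack_lengths(model.ligaments, rest, cfg.reference_strain)
    return model


# ---------------------------------------------------------------------------
# prescribed kinematics
# ---------------------------------------------------------------------------


def _prescribed_poses(model: ForelimbModel, vals: dict, hoof_x: float, trunk_x: float) -> Dict[str, Pose]:
    """Poses of the driven segments from instantaneous drive values."""
    cfg = model.config
    lam = np.deg2rad(90.0 - vals["inclination_deg"]) * cfg.lean_sign * cfg.medial_sign
    R_mc = rot_x(-lam)
    m_hat = R_mc[:, 2]
    hoof = np.array([hoof_x, 0.0, vals["hoof_height"]])
    fetlock_pt = hoof + cfg.pastern_length * m_hat
    carpus_pt = hoof + (cfg.pastern_length + cfg.metacarpus_length) * m_hat

    theta_f = np.deg2rad(180.0 - vals["carpus"])
    tilt = vals["frontal_tilt"] * cfg.lean_sign * cfg.medial_sign
    R_rad = R_mc @ rot_y(-theta_f) @ rot_x(-tilt)
    u_hat = R_rad[:, 2]  # proximal, along the radius shaft
    d_hat = R_rad[:, 0]  # dorsal
    p_rad = carpus_pt - vals["squeeze"] * u_hat + vals["shear"] * d_hat

    R_p1 = R_mc @ rot_y(-np.deg2rad(180.0 - vals["fetlock"]))
    R_pd = R_p1 @ rot_y(-np.deg2rad(180.0 - vals["coffin"]))
    R_hum = R_rad @ rot_y(-np.deg2rad(180.0 - vals["elbow"]))
    elbow_pt = p_rad + cfg.radius_length * u_hat

    poses = {
        "radius": Pose.from_matrix(R_rad, p_rad),
        "distal_row": Pose.from_matrix(R_mc, carpus_pt),
        "metacarpus": Pose.from_matrix(R_mc, carpus_pt),
        "phalanx_prox_mid": Pose.from_matrix(R_p1, fetlock_pt),
        "phalanx_distal": Pose.from_matrix(R_pd, hoof),
        "trunk": Pose(np.array([trunk_x, 0.0, cfg.trunk_height])),
        "humerus": Pose.from_matrix(R_hum, elbow_pt),
        "ulna": Pose.from_matrix(R_hum, elbow_pt),
    }
    return {k: v for k, v in poses.items() if k in model.segments}


def hold_drive(T: float = 0.05, hoof_height: float = 0.05, carpus_angle: float = 180.0, n: int = 51) -> DriveSignal:
    """A constant drive holding the limb static above the ground."""
    from scipy.interpolate import PchipInterpolator

    t = np.linspace(0.0, T, n)
    const_vals = {
        "trunk_speed": 0.0,
        "hoof_speed": 0.0,
        "hoof_height": hoof_height,
        "carpus": carpus_angle,
        "elbow": 150.0,
        "fetlock": 205.0,
        "coffin": 180.0,
        "inclination_deg": 90.0,
        "squeeze": 0.0,
        "shear": 0.0,
        "frontal_tilt": 0.0,
    }
    interpolants = {k: PchipInterpolator([0.0, max(T, 1.0)], [v, v]) for k, v in const_vals.items()}
    zero = np.zeros_like(t)
    return DriveSignal(
        t=t,
        trunk_velocity=np.zeros((n, 3)),
        hoof_speed=zero,
        hoof_height=np.full(n, hoof_height),
        hinge_angles={k: np.full(n, const_vals[k]) for k in ("elbow", "carpus", "fetlock", "coffin")},
        inclination_deg=np.full(n, 90.0),
        squeeze=zero,
        shear=zero,
        frontal_tilt=zero,
        impact_time=T / 2,
        interpolants=interpolants,
    )


# ---------------------------------------------------------------------------
# state and integration
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Integrator state: COM-centric free-body coordinates plus caches.

    ``vel``/``omega`` are full-step velocities synchronised with ``com``;
    between steps the integrator keeps the half-step (leapfrog) velocities
    and the last accelerations to complete each kick-drift-kick update.
    """

    t: float
    com: Dict[str, np.ndarray]
    quat: Dict[str, np.ndarray]
    vel: Dict[str, np.ndarray]
    omega: Dict[str, np.ndarray]
    vel_half: Optional[Dict[str, np.ndarray]] = None
    omega_half: Optional[Dict[str, np.ndarray]] = None
    prev_acc: dict = field(default_factory=dict)
    prev_delta: dict = field(default_factory=dict)
    work_in: float = 0.0
    dissipated: float = 0.0

    def body_pose(self, model: ForelimbModel, body: str) -> Pose:
        R = quat_to_matrix(self.quat[body])
        pose = Pose(self.com[body] - R @ model.segments[body].com, self.quat[body].copy())
        pose._R = R
        return pose


def free_body_state(model: ForelimbModel, com: Dict[str, np.ndarray] = None, vel=None) -> SimState:
    """A quiescent state with free bodies at given COM positions."""
    com = com or {}
    vel = vel or {}
    return SimState(
        t=0.0,
        com={b: np.asarray(com.get(b, model.segments[b].com), float).copy() for b in model.free_bodies},
        quat={b: np.array([1.0, 0.0, 0.0, 0.0]) for b in model.free_bodies},
        vel={b: np.asarray(vel.get(b, np.zeros(3)), float).copy() for b in model.free_bodies},
        omega={b: np.zeros(3) for b in model.free_bodies},
    )


def _initial_state(model: ForelimbModel, drive: DriveSignal) -> SimState:
    """Free carpal bones seated on the distal row, moving with it."""
    dt = model.config.dt
    vals0 = {k: float(drive.at(k, 0.0)) for k in drive.interpolants}
    vals1 = {k: float(drive.at(k, dt)) for k in drive.interpolants}
    poses0 = _prescribed_poses(model, vals0, 0.0, 0.0)
    poses1 = _prescribed_poses(model, vals1, vals0["hoof_speed"] * dt, vals0["trunk_speed"] * dt)
    anchor = "distal_row" if "distal_row" in poses0 else None
    com, quat, vel, omega = {}, {}, {}, {}
    for bone in model.free_bodies:
        seg = model.segments[bone]
        if anchor is not None:
            com[bone] = poses0[anchor].transform(seg.com)
            quat[bone] = poses0[anchor].q.copy()
            vel[bone] = (poses1[anchor].p - poses0[anchor].p) / dt
        else:
            com[bone] = seg.com.copy()
            quat[bone] = np.array([1.0, 0.0, 0.0, 0.0])
            vel[bone] = np.zeros(3)
        omega[bone] = np.zeros(3)
    return SimState(t=0.0, com=com, quat=quat, vel=vel, omega=omega)


class _Integrator:
    """Precomputes drive samples on the step grid and advances the state."""

    def __init__(self, model: ForelimbModel, drive: DriveSignal, dt: float, T: float):
        if drive.duration() < T - 1e-12:
            raise InputError(f"drive ({drive.duration():.4f} s) shorter than horizon {T} s")
        self.model = model
        self.drive = drive
        self.dt = dt
        self.n_steps = int(round(T / dt))
        tgrid = np.arange(self.n_steps + 2) * dt
        self.vals = {k: np.asarray(drive.at(k, tgrid), float) for k in drive.interpolants}
        from scipy.integrate import cumulative_trapezoid

        self.hoof_x = cumulative_trapezoid(self.vals["hoof_speed"], tgrid, initial=0.0)
        self.trunk_x = cumulative_trapezoid(self.vals["trunk_speed"], tgrid, initial=0.0)
        self._pose_memo = (-1, None)
        self.pair_cache = {}
        for pid, pair in model.contacts.items():
            if not isinstance(pair, ContactPair):
                continue
            mesh = pair.surfA.mesh
            areas = mesh.area_faces
            self.pair_cache[pid] = {
                "centroids": np.ascontiguousarray(mesh.triangles_center),
                "normals": np.ascontiguousarray(mesh.face_normals),
                "k_face": pair.stiffness * areas / areas.sum(),
                "c_face": pair.max_damping * areas / areas.sum(),
                "cth": pair.cth_at_faces(len(mesh.faces)),
                "cyl_B": pair.surfB.cylinder,
                "cyl_A": pair.surfA.cylinder,
                "child": pid.split("_")[1],
            }

    def poses_at(self, i: int) -> Dict[str, Pose]:
        if self._pose_memo[0] == i:
            return self._pose_memo[1]
        vals = {k: float(v[i]) for k, v in self.vals.items()}
        poses = _prescribed_poses(self.model, vals, float(self.hoof_x[i]), float(self.trunk_x[i]))
        self._pose_memo = (i, poses)
        return poses

    def advance(self, state: SimState, i: int, record: Optional[dict] = None) -> None:
        model, dt = self.model, self.dt
        poses = self.poses_at(i)
        self._pose_memo = (-1, None)  # memo holds one entry; keep (i+1) for the next step
        poses_next = self.poses_at(i + 1)
        vels = {
            sid: (
                (poses_next[sid].p - poses[sid].p) / dt,
                rotvec_from_matrix(poses_next[sid].R @ poses[sid].R.T) / dt,
            )
            for sid in poses
        }

        F = {b: np.zeros(3) for b in model.free_bodies}
        T = {b: np.zeros(3) for b in model.free_bodies}
        closure_f = np.zeros(3)
        closure_t = np.zeros(3)  # about the world origin
        work_in = 0.0
        dissipated = 0.0
        elastic = 0.0
        forces_log = {}

        free_poses = {b: state.body_pose(model, b) for b in model.free_bodies}
        # velocity predictor: complete the pending half-kick with the last
        # step's acceleration (only damping terms feel the O(dt) lag)
        if state.vel_half is not None:
            free_vel = {
                b: (
                    state.vel_half[b] + 0.5 * dt * state.prev_acc[b][0],
                    state.omega_half[b] + 0.5 * dt * state.prev_acc[b][1],
                )
                for b in model.free_bodies
            }
        else:
            free_vel = {b: (state.vel[b], state.omega[b]) for b in model.free_bodies}

        for b in model.free_bodies:
            F[b] += model.segments[b].mass * model.gravity

        # --- ligaments ------------------------------------------------------
        lig_t = {}
        for br in model.ligaments:
            pp = poses.get(br.parent) or free_poses.get(br.parent)
            pc = poses.get(br.child) or free_poses.get(br.child)
            if pp is None or pc is None:
                continue
            o_w = pp.transform(br.origin)
            i_w = pc.transform(br.insertion)
            d = i_w - o_w
            L = float(np.linalg.norm(d))
            u = d / L
            vp, wp = vels[br.parent] if br.parent in vels else free_vel[br.parent]
            vc, wc = vels[br.child] if br.child in vels else free_vel[br.child]
            ref_p = state.com[br.parent] if br.parent in free_vel else poses[br.parent].p
            ref_c = state.com[br.child] if br.child in free_vel else poses[br.child].p
            v_o = vp + np.cross(wp, o_w - ref_p)
            v_i = vc + np.cross(wc, i_w - ref_c)
            rate = float(u @ (v_i - v_o))
            tension = fe.ligament_tension(br, L, rate)
            lig_t[br.name] = tension
            f_child = -tension * u
            f_parent = tension * u
            if br.child in F:
                F[br.child] += f_child
                T[br.child] += np.cross(i_w - state.com[br.child], f_child)
            else:
                work_in += -(f_child @ v_i) * dt
            if br.parent in F:
                F[br.parent] += f_parent
                T[br.parent] += np.cross(o_w - state.com[br.parent], f_parent)
            else:
                work_in += -(f_parent @ v_o) * dt
            closure_f += f_child + f_parent
            closure_t += np.cross(i_w, f_child) + np.cross(o_w, f_parent)
            if tension > 0:
                dissipated += br.damping * max(rate, 0.0) * rate * dt
            elastic += fe.ligament_elastic_energy(br, L)

        # --- bushings ---------------------------------------------------------
        for b in model.bushings:
            pp = poses.get(b.parent) or free_poses.get(b.parent)
            pc = poses.get(b.child) or free_poses.get(b.child)
            if pp is None or pc is None:
                continue
            vel_p = vels[b.parent] if b.parent in vels else free_vel[b.parent]
            vel_c = vels[b.child] if b.child in vels else free_vel[b.child]
            ref_p = poses[b.parent].p if b.parent in poses else state.com[b.parent]
            ref_c = poses[b.child].p if b.child in poses else state.com[b.child]
            f_c, tau_c, p_att, rel = _bushing_world(b, pp, pc, vel_p, vel_c, ref_p, ref_c)
            f_p, tau_p = -f_c, -tau_c
            if b.child in F:
                F[b.child] += f_c
                T[b.child] += tau_c + np.cross(p_att - state.com[b.child], f_c)
            else:
                v_att = vel_c[0] + np.cross(vel_c[1], p_att - ref_c)
                work_in += -(f_c @ v_att + tau_c @ vel_c[1]) * dt
            if b.parent in F:
                F[b.parent] += f_p
                T[b.parent] += tau_p + np.cross(p_att - state.com[b.parent], f_p)
            else:
                v_att = vel_p[0] + np.cross(vel_p[1], p_att - ref_p)
                work_in += -(f_p @ v_att + tau_p @ vel_p[1]) * dt
            closure_f += f_c + f_p
            closure_t += np.cross(p_att, f_c) + np.cross(p_att, f_p) + tau_c + tau_p
            d, theta, v_rel, w_rel = rel
            dissipated += float((b.C_t * v_rel) @ v_rel + (b.C_r * w_rel) @ w_rel) * dt
            elastic += 0.5 * float((b.K_t * d) @ d + (b.K_r * theta) @ theta)

        # --- articular contacts (cylinder fast path) -------------------------
        rad_pose = poses.get("radius")
        rad_vel = vels.get("radius")
        for pid, cache in self.pair_cache.items():
            pair: ContactPair = model.contacts[pid]
            child = cache["child"]
            if rad_pose is None or child not in free_poses:
                continue
            pose_c = free_poses[child]
            pw = rad_pose.transform(cache["centroids"])
            p_b = pose_c.inverse_transform(pw)
            cyl = cache["cyl_B"]
            relp = p_b - np.asarray(cyl.axis_point)
            rho = np.hypot(relp[:, 0], relp[:, 2])
            delta = cache["cth"] - (cyl.radius - rho)
            phi = np.arctan2(relp[:, 0], -relp[:, 2])
            y_lo, y_hi = cyl.y_range
            phi_lo, phi_hi = cyl.phi_range
            active = (relp[:, 1] >= y_lo) & (relp[:, 1] <= y_hi) & (phi >= phi_lo) & (phi <= phi_hi)
            prev = state.prev_delta.get(pid)
            rate = (delta - prev) / dt if prev is not None else np.zeros_like(delta)
            state.prev_delta[pid] = delta
            dpos = np.where(active, np.maximum(delta, 0.0), 0.0)
            ramp = smooth_step(dpos, 0.0, 0.0, pair.damping_depth, 1.0)
            f_el = cache["k_face"] * dpos**pair.exponent
            f_face = np.maximum(f_el + cache["c_face"] * ramp * rate * (dpos > 0), 0.0)
            total = float(f_face.sum())
            n_w = rad_pose.rotate(cache["normals"])
            fvec = n_w * f_face[:, None]
            f_child = fvec.sum(axis=0)
            F[child] += f_child
            T[child] += np.cross(pw - state.com[child], fvec).sum(axis=0)
            # equal-and-opposite on the radius at the same points: the
            # internal-wrench closure contribution is identically zero;
            # the prescribed radius feeds energy into the contact
            if rad_vel is not None:
                v_pts = rad_vel[0] + np.cross(np.broadcast_to(rad_vel[1], pw.shape), pw - rad_pose.p)
                work_in += float((fvec * v_pts).sum()) * dt
            dissipated += float(((f_face - f_el) * rate).sum()) * dt
            elastic += float((cache["k_face"] * dpos ** (pair.exponent + 1.0)).sum() / (pair.exponent + 1.0))
            forces_log[pid] = total
            if record is not None:
                record.setdefault("pairs", {})[pid] = (total, f_face, pw, dpos)

        # --- plane contacts on free bodies (verification scenarios) ----------
        for body, gp in model.plane_contacts.items():
            v_body = free_vel[body][0]
            f = ground_reaction(state.com[body], v_body, gp)
            F[body] += f
            forces_log[f"plane_{body}"] = float(np.linalg.norm(f))
            deltap = max(-state.com[body][2], 0.0)
            elastic += gp.stiffness * deltap ** (gp.exponent + 1.0) / (gp.exponent + 1.0)
            f_el_p = gp.stiffness * deltap**gp.exponent
            if deltap > 0 and np.isfinite(f_el_p):
                dissipated += float((f[2] - f_el_p) * (-v_body[2])) * dt

        # --- hoof-ground (prescribed hoof): recorded for event detection -----
        ground_f = np.zeros(3)
        if "hoof_ground" in model.contacts and "phalanx_distal" in poses:
            ground_f = ground_reaction(
                poses["phalanx_distal"].p, vels["phalanx_distal"][0], model.contacts["hoof_ground"]
            )

        # --- integrate free bodies (kick-drift-kick velocity Verlet) ---------
        acc = {}
        for b in model.free_bodies:
            seg = model.segments[b]
            a = F[b] / seg.mass
            R = quat_to_matrix(state.quat[b])
            I_w = R @ seg.inertia @ R.T
            w = free_vel[b][1]
            a_rot = np.linalg.solve(I_w, T[b] - np.cross(w, I_w @ w))
            acc[b] = (a, a_rot)
            # complete the previous step's second half-kick: velocities are
            # now synchronised with the current positions
            if state.vel_half is not None:
                state.vel[b] = state.vel_half[b] + 0.5 * dt * a
                state.omega[b] = state.omega_half[b] + 0.5 * dt * a_rot

        if record is not None:
            ke = 0.0
            for b in model.free_bodies:
                seg = model.segments[b]
                R = quat_to_matrix(state.quat[b])
                ke += 0.5 * seg.mass * float(state.vel[b] @ state.vel[b])
                ke += 0.5 * float(state.omega[b] @ (R @ seg.inertia @ R.T @ state.omega[b]))
            pe = sum(-model.segments[b].mass * float(model.gravity @ state.com[b]) for b in model.free_bodies)
            record.update(
                ground=ground_f,
                lig=lig_t,
                poses=poses,
                elastic=elastic,
                kinetic=ke,
                potential=pe,
                work_in=state.work_in,
                dissipated=state.dissipated,
                closure=float(max(np.linalg.norm(closure_f), np.linalg.norm(closure_t))),
                forces=forces_log,
            )

        if state.vel_half is None:
            state.vel_half, state.omega_half = {}, {}
        for b in model.free_bodies:
            a, a_rot = acc[b]
            vh = state.vel[b] + 0.5 * dt * a
            state.com[b] = state.com[b] + vh * dt
            state.vel_half[b] = vh
            wh = state.omega[b] + 0.5 * dt * a_rot
            state.quat[b] = quat_normalize(quat_multiply(quat_from_rotvec(wh * dt), state.quat[b]))
            state.omega_half[b] = wh
            state.prev_acc[b] = acc[b]
            if not (np.all(np.isfinite(state.com[b])) and np.all(np.isfinite(vh))):
                biggest = max(forces_log.items(), key=lambda kv: abs(kv[1]), default=("unknown", 0.0))
                raise IntegrationError(
                    f"NaN in state of {b} at t={state.t:.6f}s; largest force element: {biggest[0]} ({biggest[1]:.1f} N)"
                )

        state.t += dt
        state.work_in += work_in
        state.dissipated += dissipated


def _bushing_world(b, pose_p, pose_c, vel_p, vel_c, ref_p, ref_c):
    att_p = pose_p.compose(b.frame)
    att_c = pose_c.compose(b.frame)  # child marker coincides with the frame at rest
    R_b = att_p.R
    d = R_b.T @ (att_c.p - att_p.p)
    theta = rotvec_from_matrix(R_b.T @ att_c.R)
    vp, wp = vel_p
    vc, wc = vel_c
    v_att_p = vp + np.cross(wp, att_p.p - ref_p)
    v_att_c = vc + np.cross(wc, att_c.p - ref_c)
    v_rel = R_b.T @ (v_att_c - v_att_p)
    w_rel = R_b.T @ (np.asarray(wc) - np.asarray(wp))
    wrench_c, _ = fe.bushing_wrench(b, (d, theta), (v_rel, w_rel))
    return R_b @ wrench_c[:3], R_b @ wrench_c[3:], att_p.p, (d, theta, v_rel, w_rel)


def step(model: ForelimbModel, state: SimState, t: float, dt: float, drive: DriveSignal = None) -> SimState:
    """Advance the model one step of size ``dt`` from time ``t``.

    Prescribed bodies follow the drive exactly (kinematic enforcement);
    free bodies advance by the semi-implicit Newton-Euler update.
    """
    if dt > model.config.dt_max + 1e-15:
        raise ParameterError(f"dt={dt} exceeds dt_max={model.config.dt_max}")
    drive = drive if drive is not None else model.drive
    if drive is None:
        raise InputError("no drive signal attached to the model")
    cache = getattr(model, "_step_cache", None)
    if cache is None or cache[0] is not drive or cache[1] != dt:
        integ = _Integrator(model, drive, dt, drive.duration())
        model._step_cache = (drive, dt, integ)
    else:
        integ = cache[2]
    i = int(round(t / dt))
    if i + 1 >= len(integ.hoof_x):
        raise InputError("prescribed trajectories not defined beyond the drive horizon")
    state.t = t
    integ.advance(state, i)
    return state


@dataclass
class ContactTrace:
    """Force magnitude and center-of-contact location of one pair vs time."""

    force: np.ndarray  # (N,) [N]
    coc: np.ndarray  # (N, 3) world [m], NaN rows when no contact
    coc_phi: np.ndarray  # (N,) trochlear angle of the CoC on the radius
    # facet [rad], positive dorsal, NaN when no contact


@dataclass
class SimulationResult:
    t: np.ndarray
    traces: Dict[str, ContactTrace]
    ground_force: np.ndarray  # (N, 3)
    free_poses: Dict[str, np.ndarray]  # (N, 7): com xyz + quat wxyz
    ligament_tension: Dict[str, np.ndarray]
    trunk_speed: np.ndarray
    metacarpus_inclination: np.ndarray  # deg to ground
    events: dict
    energy: Dict[str, np.ndarray]
    closure: np.ndarray  # internal-wrench residual per sample [N]

    @property
    def stance_duration(self):
        return self.events.get("stance_duration")


def simulate_stride(model: ForelimbModel, drive: DriveSignal) -> SimulationResult:
    """Integrate one stride and collect traces, events and the energy audit.

    Traces are sampled every ``config.output_dt`` (default 0.5 ms); hoof-on
    and hoof-off are the first crossings of the ground normal force above /
    back below the event threshold (default 5 N), detected at integration
    resolution.
    """
    cfg = model.config
    model.drive = drive
    integ = _Integrator(model, drive, cfg.dt, cfg.T)
    state = _initial_state(model, drive)

    # preliminary-simulation slack tuning: re-reference the ligament slack
    # lengths to the limb posture at stride start, so every branch carries
    # exactly the reference strain when integration begins
    ref_poses = dict(integ.poses_at(0))
    for b in model.free_bodies:
        ref_poses[b] = state.body_pose(model, b)
    model.ligaments = fe.tune_slack_lengths(model.ligaments, ref_poses, cfg.reference_strain)

    every = max(1, int(round(cfg.output_dt / cfg.dt)))
    sample_steps = list(range(0, integ.n_steps, every))
    n_out = len(sample_steps)
    pair_ids = [pid for pid, p in model.contacts.items() if isinstance(p, ContactPair)]
    t_out = np.zeros(n_out)
    force_tr = {pid: np.zeros(n_out) for pid in pair_ids}
    coc_tr = {pid: np.full((n_out, 3), np.nan) for pid in pair_ids}
    phi_tr = {pid: np.full(n_out, np.nan) for pid in pair_ids}
    ground_tr = np.zeros((n_out, 3))
    free_tr = {b: np.zeros((n_out, 7)) for b in model.free_bodies}
    lig_tr = {br.name: np.zeros(n_out) for br in model.ligaments}
    trunk_tr = np.zeros(n_out)
    incl_tr = np.zeros(n_out)
    energy = {k: np.zeros(n_out) for k in ("kinetic", "potential", "elastic", "dissipated", "work_in", "residual")}
    closure_tr = np.zeros(n_out)

    # ground normal force on the step grid (prescribed hoof trajectory):
    # events are detected at integration resolution, finer than output_dt
    hoof_on = hoof_off = None
    if "hoof_ground" in model.contacts:
        from .contact import contact_force as _cf

        gp = model.contacts["hoof_ground"]
        z = integ.vals["hoof_height"][: integ.n_steps]
        vz = np.gradient(integ.vals["hoof_height"], cfg.dt)[: integ.n_steps]
        fn_series = np.where(
            z < 0,
            _cf(-z, -vz, gp.stiffness, gp.exponent, gp.max_damping, gp.damping_depth),
            0.0,
        )
        above = fn_series > cfg.event_threshold
        idx_on = np.flatnonzero(above)
        if len(idx_on):
            hoof_on = idx_on[0] * cfg.dt
            idx_off = np.flatnonzero(~above[idx_on[0] :])
            if len(idx_off):
                hoof_off = (idx_on[0] + idx_off[0]) * cfg.dt

    e0 = None
    k_out = 0
    for i in range(integ.n_steps):
        want = i % every == 0
        rec = {} if want else None
        integ.advance(state, i, record=rec)
        if want:
            t_i = i * cfg.dt
            t_out[k_out] = t_i
            rad_pose = rec["poses"].get("radius")
            for pid in rec.get("pairs", {}):
                total, f_face, pw, dpos = rec["pairs"][pid]
                force_tr[pid][k_out] = total
                if total > 0:
                    centroid = (f_face[:, None] * pw).sum(axis=0) / f_face.sum()
                    cyl_a = integ.pair_cache[pid]["cyl_A"]
                    if cyl_a is not None and rad_pose is not None:
                        pl = rad_pose.inverse_transform(centroid) - np.asarray(cyl_a.axis_point)
                        rho = float(np.hypot(pl[0], pl[2]))
                        if rho > 0:
                            scale = cyl_a.radius / rho
                            centroid = rad_pose.transform(
                                np.array([pl[0] * scale, pl[1], pl[2] * scale]) + np.asarray(cyl_a.axis_point)
                            )
                        phi_tr[pid][k_out] = float(np.arctan2(pl[0], -pl[2]))
                    coc_tr[pid][k_out] = centroid
            ground_tr[k_out] = rec["ground"]
            for b in model.free_bodies:
                free_tr[b][k_out, :3] = state.com[b]
                free_tr[b][k_out, 3:] = state.quat[b]
            for name, val in rec["lig"].items():
                lig_tr[name][k_out] = val
            trunk_tr[k_out] = float(integ.vals["trunk_speed"][i])
            mc_pose = rec["poses"].get("metacarpus")
            if mc_pose is not None:
                incl_tr[k_out] = float(np.degrees(np.arcsin(np.clip(mc_pose.R[2, 2], -1.0, 1.0))))
            if e0 is None:
                e0 = rec["kinetic"] + rec["potential"] + rec["elastic"]
            energy["kinetic"][k_out] = rec["kinetic"]
            energy["potential"][k_out] = rec["potential"]
            energy["elastic"][k_out] = rec["elastic"]
            energy["dissipated"][k_out] = rec["dissipated"]
            energy["work_in"][k_out] = rec["work_in"]
            energy["residual"][k_out] = (
                rec["kinetic"] + rec["potential"] + rec["elastic"] + rec["dissipated"] - e0 - rec["work_in"]
            )
            closure_tr[k_out] = rec["closure"]
            k_out += 1

    events = {
        "hoof_on": hoof_on,
        "hoof_off": hoof_off,
        "stance_duration": (hoof_off - hoof_on) if (hoof_on is not None and hoof_off is not None) else None,
        "stride_duration": cfg.T,
    }
    if hoof_off is not None:
        swing = t_out[:k_out] > hoof_off + 2e-3
        for pid in pair_ids:
            f = force_tr[pid][:k_out]
            if np.any(swing) and np.any(~swing):
                events[f"stance_peak_{pid}"] = float(f[~swing].max())
                events[f"swing_peak_{pid}"] = float(f[swing].max())

    traces = {
        pid: ContactTrace(force_tr[pid][:k_out], coc_tr[pid][:k_out], phi_tr[pid][:k_out]) for pid in pair_ids
    }
    return SimulationResult(
        t=t_out[:k_out],
        traces=traces,
        ground_force=ground_tr[:k_out],
        free_poses={b: free_tr[b][:k_out] for b in model.free_bodies},
        ligament_tension={k: v[:k_out] for k, v in lig_tr.items()},
        trunk_speed=trunk_tr[:k_out],
        metacarpus_inclination=incl_tr[:k_out],
        events=events,
        energy={k: v[:k_out] for k, v in energy.items()},
        closure=closure_tr[:k_out],
    )


def energy_audit(result: SimulationResult) -> Tuple[float, float]:
    """Maximum energy-balance residual over the stride.

    Returns ``(residual [J], residual as a fraction of the peak energy
    turnover)``; the turnover scale is the larger of the mechanical-energy
    excursion and the work input.
    """
    e = result.energy
    res = float(np.max(np.abs(e["residual"])))
    # turnover scale: peak energy actually exchanged between the stores
    # (the gravitational reference offset cancels out)
    scale = float(
        np.max(e["kinetic"])
        + np.max(e["elastic"])
        + np.max(np.abs(e["potential"] - e["potential"][0]))
        + np.max(np.abs(e["work_in"]))
        + np.max(e["dissipated"])
    )
    return res, (res / scale if scale > 0 else 0.0)
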