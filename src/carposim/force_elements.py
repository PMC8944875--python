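"""Ligament branches and intercarpal bushing elements.

Ligaments are non-linear tension-only springs with a quadratic toe region
blending C1-continuously into a linear region (the standard ligament
constitutive form), with slack lengths tuned at a reference pose.  The
constraining effect of the intercarpal ligaments and peri-articular soft
tissue is lumped into six-component bushing elements: a diagonal linear
spring-damper producing three forces and three torques proportional to the
relative linear/angular displacement and velocity of two bones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, ParameterError
from .rigid import Pose, rotvec_from_matrix

__all__ = [
    "LIGAMENT_NAMES",
    "LigamentBranch",
    "BushingElement",
    "ligament_tension",
    "ligament_elastic_energy",
    "tune_slack_lengths",
    "bushing_wrench",
    "evaluate_bushing",
    "default_carpal_ligaments",
    "default_carpal_bushings",
]

log = logging.getLogger(__name__)

LIGAMENT_NAMES = (
    "l-MCL",
    "s-MCL",
    "l-LCL",
    "s-LCL",
    "l-MR",
    "s-MR",
    "l-LR",
    "s-LR",
    "palmar_carpal",
)


@dataclass
class LigamentBranch:
    """One ligament branch between a parent and a child body.

    ``stiffness`` is expressed per unit strain (N at strain 1 in the linear
    region); ``toe_strain`` is the strain at which the quadratic toe region
    ends; ``damping`` acts only while the branch is taut and lengthening.
    """

    name: str
    parent: str
    child: str
    origin: np.ndarray  # parent-frame attachment [m]
    insertion: np.ndarray  # child-frame attachment [m]
    slack_length: float  # L0 [m]
    stiffness: float  # k [N per unit strain]
    toe_strain: float = 0.03
    damping: float = 0.0  # c [N·s/m]

    def __post_init__(self):
        if self.name not in LIGAMENT_NAMES:
            raise ParameterError(f"unknown ligament branch name {self.name!r}")
        self.origin = np.asarray(self.origin, float)
        self.insertion = np.asarray(self.insertion, float)
        if not self.slack_length > 0:
            raise ParameterError(f"{self.name}: slack length must be positive")
        if not self.stiffness > 0:
            raise ParameterError(f"{self.name}: stiffness must be positive")
        if not 0 < self.toe_strain < 0.1:
            raise ParameterError(f"{self.name}: toe_strain must lie in (0, 0.1)")
        if self.damping < 0:
            raise ParameterError(f"{self.name}: damping must be >= 0")


def ligament_tension(branch: LigamentBranch, length: float, lengthening_rate: float = 0.0) -> float:
    """Tension [N] of a branch at the given length and lengthening rate.

    Piecewise law in strain eps = (L - L0)/L0:

    * slack (eps <= 0):            F = 0
    * toe (0 < eps <= eps_t):      F = k/(2 eps_t) * eps^2
    * linear (eps > eps_t):        F = k (eps - eps_t/2)

    plus viscous damping c * max(rate, 0) applied only while taut; the
    result is clamped to be non-negative (tension-only element).
    """
    if not length > 0:
        raise ParameterError("ligament length must be positive")
    eps = (length - branch.slack_length) / branch.slack_length
    if eps <= 0.0:
        return 0.0
    if eps <= branch.toe_strain:
        f = branch.stiffness / (2.0 * branch.toe_strain) * eps * eps
    else:
        f = branch.stiffness * (eps - branch.toe_strain / 2.0)
    f += branch.damping * max(lengthening_rate, 0.0)
    return max(f, 0.0)


def ligament_elastic_energy(branch: LigamentBranch, length: float) -> float:
    """Stored elastic energy [J] of the branch (damping excluded)."""
    L0, k, et = branch.slack_length, branch.stiffness, branch.toe_strain
    eps = (length - L0) / L0
    if eps <= 0.0:
        return 0.0
    if eps <= et:
        return k / (6.0 * et) * eps**3 * L0
    # integral of the toe up to et plus the linear part beyond
    u_toe = k / (6.0 * et) * et**3
    u_lin = k * (0.5 * (eps**2 - et**2) - 0.5 * et * (eps - et))
    return (u_toe + u_lin) * L0


def tune_slack_lengths(
    branches: Sequence[LigamentBranch],
    reference_pose: Mapping[str, Pose],
    reference_strain: float = 0.0,
) -> list:
    """Set each branch's slack length so its strain at the reference pose
    equals ``reference_strain``.

    This mirrors tuning slack lengths from the modelled ligament lengths at
    the joint's resting position.  Deterministic; returns new branch objects.
    """
    if not 0.0 <= reference_strain <= 0.05:
        raise ParameterError("reference_strain must lie in [0, 0.05]")
    tuned = []
    for br in branches:
        o = reference_pose[br.parent].transform(br.origin)
        i = reference_pose[br.child].transform(br.insertion)
        d = float(np.linalg.norm(i - o))
        if d < 1e-9:
            raise GeometryError(f"{br.name}: origin and insertion coincide at reference pose")
        tuned.append(replace(br, slack_length=d / (1.0 + reference_strain)))
    return tuned


@dataclass
class BushingElement:
    """Six-component spring-damper between two bones.

    ``frame`` is the bushing attachment frame on the parent body (parent
    body frame); at zero relative displacement and twist the wrench is
    exactly zero.  The law is diagonal linear: each translational/rotational
    component responds only to its own displacement/velocity component,
    expressed in the bushing frame.
    """

    parent: str
    child: str
    frame: Pose = field(default_factory=Pose.identity)
    K_t: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N/m
    K_r: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N·m/rad
    C_t: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N·s/m
    C_r: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N·m·s/rad

    def __post_init__(self):
        for name in ("K_t", "K_r", "C_t", "C_r"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (3,):
                raise ParameterError(f"bushing {name} must be a 3-vector")
            if np.any(v < 0):
                raise ParameterError(f"bushing {name} components must be >= 0")
            setattr(self, name, v)


_SMALL_ANGLE_BOUND = 0.35  # rad


def bushing_wrench(b: BushingElement, rel_pose, rel_twist):
    """Wrench of a bushing given relative displacement/rotation and twist.

    Parameters
    ----------
    rel_pose : (displacement 3-vector [m], small-rotation 3-vector [rad])
        of the child attachment relative to the parent attachment, expressed
        in the bushing frame.
    rel_twist : (linear velocity [m/s], angular velocity [rad/s]) of the
        child relative to the parent, in the bushing frame.

    Returns
    -------
    (wrench_child, wrench_parent) : 6-vectors (force, torque) in the bushing
        frame; exactly equal and opposite about the common attachment point.
    """
    d, theta = (np.asarray(v, float) for v in rel_pose)
    v, omega = (np.asarray(v, float) for v in rel_twist)
    ang = np.linalg.norm(theta)
    if ang > _SMALL_ANGLE_BOUND:
        log.warning(
            "bushing %s-%s rotation %.3f rad exceeds small-angle bound %.2f",
            b.parent,
            b.child,
            ang,
            _SMALL_ANGLE_BOUND,
        )
    force = -b.K_t * d - b.C_t * v
    torque = -b.K_r * theta - b.C_r * omega
    wrench_child = np.concatenate([force, torque])
    return wrench_child, -wrench_child


def evaluate_bushing(
    b: BushingElement,
    pose_parent: Pose,
    pose_child: Pose,
    vel_parent,
    vel_child,
    child_rest: Pose,
):
    """World-frame bushing forces on both bodies.

    ``child_rest`` is the child attachment frame in the child body frame
    (coincident with ``b.frame`` on the parent at the rest configuration).
    ``vel_*`` are (linear COM velocity, angular velocity) world-frame pairs;
    linear attachment velocities include the omega x r term.

    Returns ``(f_child, tau_child_about_att, f_parent, tau_parent_about_att,
    p_att)`` with the attachment point taken as the parent-frame bushing
    origin in the world (common point for action-reaction bookkeeping).
    """
    att_parent = pose_parent.compose(b.frame)
    att_child = pose_child.compose(child_rest)
    R_b = att_parent.R
    d_world = att_child.p - att_parent.p
    d = R_b.T @ d_world
    R_rel = R_b.T @ att_child.R
    theta = rotvec_from_matrix(R_rel)

    vp, wp = (np.asarray(a, float) for a in vel_parent)
    vc, wc = (np.asarray(a, float) for a in vel_child)
    v_att_p = vp + np.cross(wp, att_parent.p - pose_parent.p)
    v_att_c = vc + np.cross(wc, att_child.p - pose_child.p)
    v_rel = R_b.T @ (v_att_c - v_att_p)
    w_rel = R_b.T @ (wc - wp)

    wc6, wp6 = bushing_wrench(b, (d, theta), (v_rel, w_rel))
    f_child = R_b @ wc6[:3]
    tau_child = R_b @ wc6[3:]
    return f_child, tau_child, -f_child, -tau_child, att_parent.p


def default_carpal_ligaments(
    joint_half_width: float = 0.038,
    stiffness_collateral: float = 3.0e4,
    stiffness_retinaculum: float = 1.5e3,
    stiffness_palmar: float = 1.0e5,
    toe_strain: float = 0.03,
    damping: float = 50.0,
) -> list:
    """The nine shipped ligament branches of the carpal model.

    Attachment coordinates are in the body frames used by the dynamics
    module (radius/carpal frames with the trochlea axis through the origin,
    +y medial, +x dorsal, +z proximal).  Long collateral and retinacular
    branches and the palmar carpal ligament span radius -> distal row; the
    short collateral/retinacular branches insert on the adjacent proximal
    carpal bone (Cr medially, Cu laterally).  Slack lengths are nominal and
    are re-tuned at assembly time.
    """
    y = joint_half_width
    # attachments are kept close to the flexion axis: the real collateral
    # ligaments straddle it (small length change over the motion arc) and
    # the dorsal retinaculum wraps over the joint, which a straight-line
    # element cannot do -- near-axis anchoring bounds its spurious strain
    branches = [
        # long/short medial collateral
        LigamentBranch("l-MCL", "radius", "distal_row", (0.000, y, 0.050), (0.000, y - 0.004, -0.035), 0.08, stiffness_collateral, toe_strain, damping),
        LigamentBranch("s-MCL", "radius", "Cr", (0.000, y, 0.022), (0.004, y - 0.010, -0.006), 0.04, stiffness_collateral, toe_strain, damping),
        # long/short lateral collateral
        LigamentBranch("l-LCL", "radius", "distal_row", (0.000, -y, 0.050), (0.000, -(y - 0.004), -0.035), 0.08, stiffness_collateral, toe_strain, damping),
        LigamentBranch("s-LCL", "radius", "Cu", (0.000, -y, 0.022), (0.004, -(y - 0.010), -0.006), 0.04, stiffness_collateral, toe_strain, damping),
        # dorsal retinaculum, medial and lateral, long and short branches
        LigamentBranch("l-MR", "radius", "distal_row", (0.018, 0.018, 0.040), (0.020, 0.015, -0.030), 0.07, stiffness_retinaculum, toe_strain, damping),
        LigamentBranch("s-MR", "radius", "Cr", (0.012, 0.018, 0.012), (0.018, 0.020, -0.004), 0.03, stiffness_retinaculum, toe_strain, damping),
        LigamentBranch("l-LR", "radius", "distal_row", (0.018, -0.018, 0.040), (0.020, -0.015, -0.030), 0.07, stiffness_retinaculum, toe_strain, damping),
        LigamentBranch("s-LR", "radius", "Cu", (0.012, -0.018, 0.012), (0.018, -0.020, -0.004), 0.03, stiffness_retinaculum, toe_strain, damping),
        # palmar carpal ligament: counterbalances the flexor-tendon side
        LigamentBranch("palmar_carpal", "radius", "distal_row", (-0.030, 0.0, 0.025), (-0.030, 0.0, -0.030), 0.06, stiffness_palmar, toe_strain, damping),
    ]
    return branches


def default_carpal_bushings(
    carpal_y: Mapping[str, float] = None,
    K_row: float = 2.0e7,
    C_row: float = 8.0e2,
    K_rad: float = 5.0e5,
    C_rad: float = 1.5e2,
    Kr_rad: float = 80.0,
    Kr_row: float = 10.0,
    K_inter: float = 1.0e6,
    C_inter: float = 1.0e2,
) -> list:
    """The shipped bushing set: each proximal carpal bone is suspended
    between the radius (above) and the fused distal row (below), plus the
    intercarpal Cr-Ci and Ci-Cu couplings.

    The distal-row bushing is stiff (it stands in for the midcarpal
    articulation through which stance load is transmitted); the radius-side
    bushing is a soft capsular restraint whose rotational stiffness keeps
    each bone angularly aligned with the radius facet it articulates with.
    """
    if carpal_y is None:
        carpal_y = {"Cr": 0.0, "Ci": 0.0, "Cu": 0.0}
    bushings = []
    for bone in ("Cr", "Ci", "Cu"):
        y = carpal_y[bone]
        bushings.append(
            BushingElement(
                "radius",
                bone,
                frame=Pose(np.array([0.0, y, -0.01])),
                K_t=np.full(3, K_rad),
                K_r=np.full(3, Kr_rad),
                C_t=np.full(3, C_rad),
                C_r=np.full(3, 0.05),
            )
        )
        # attached at the carpal COM plane: the stiff seat constrains
        # translation without adding a large lever-arm rotational stiffness
        bushings.append(
            BushingElement(
                "distal_row",
                bone,
                frame=Pose(np.array([0.0, y, -0.030])),
                K_t=np.full(3, K_row),
                K_r=np.full(3, Kr_row),
                C_t=np.full(3, C_row),
                C_r=np.full(3, 0.05),
            )
        )
    for a, b in (("Cr", "Ci"), ("Ci", "Cu")):
        bushings.append(
            BushingElement(
                a,
                b,
                frame=Pose(np.array([0.0, 0.0, -0.03])),
                K_t=np.full(3, K_inter),
                K_r=np.full(3, 5.0),
                C_t=np.full(3, C_inter),
                C_r=np.full(3, 0.02),
            )
        )
    return bushings
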