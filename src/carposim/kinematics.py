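"""Stride measurement computations and construction of the drive signal.

This module reproduces the measurement chain of the live experiment:
segmentation of strides from carpus-mounted IMU signals, carpal angle
metrics by gyroscope integration, galloping speed from ground-marker
crossing times, the lean predicted by curve dynamics, and finally the
smooth drive signal (trunk speed, hoof trajectory, hinge angles, limb
inclination and radio-carpal micro-motion) that the dynamics module
consumes in place of the proprietary motion-capture pipeline.

Angle convention: the carpus angle is 180 deg at full extension (straight
limb) and decreases with flexion.  Limb inclination is measured from the
ground plane: 90 deg is a vertical metacarpus, smaller values mean a more
leaned limb; "maximal inclination" refers to the most-leaned configuration
(the minimum of the inclination-to-ground series), quantified by its
inclination-to-ground value as in field practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .errors import DetectionError, InputError, ParameterError

__all__ = [
    "ImuRecord",
    "StrideMetrics",
    "CurveScenario",
    "DriveSignal",
    "SegmentationParams",
    "segment_strides",
    "carpus_angle_metrics",
    "speed_from_markers",
    "predicted_lean",
    "build_drive",
]

G = 9.81  # m/s^2


@dataclass
class ImuRecord:
    """A carpus-mounted IMU recording (triaxial accelerometer + gyroscope)."""

    sample_rate: float = 200.0  # Hz
    accel: np.ndarray = None  # (N, 3) [m/s^2]
    gyro: np.ndarray = None  # (N, 3) [rad/s]
    placement: str = "left_carpus"

    def __post_init__(self):
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")
        if self.placement not in ("left_carpus", "right_carpus"):
            raise ParameterError(f"unknown placement {self.placement!r}")
        self.accel = np.asarray(self.accel, float)
        self.gyro = np.asarray(self.gyro, float)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise InputError("accel and gyro must be equal-length (N, 3) series")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.accel)) / self.sample_rate


@dataclass
class StrideMetrics:
    """Per-stride temporal and angular metrics imported into the model."""

    stride_duration: float  # s
    stance_duration: float  # s
    swing_duration: float  # s
    carpus_angle_at_impact: float  # deg
    angle_max_extension: float  # deg
    angle_max_flexion: float  # deg
    range_of_motion: float  # deg
    lead: str = "lead"

    def __post_init__(self):
        if self.lead not in ("lead", "trail"):
            raise ParameterError("lead must be 'lead' or 'trail'")
        if abs(self.stride_duration - (self.stance_duration + self.swing_duration)) > 0.01:
            raise InputError("stride duration must equal stance + swing (within one sample)")
        if abs(self.range_of_motion - abs(self.angle_max_extension - self.angle_max_flexion)) > 1e-9:
            raise InputError("range of motion must equal |max extension - max flexion|")


@dataclass
class CurveScenario:
    """Geometry and speed of the curve where the accident occurred."""

    curve_radius: float = 28.0  # m
    speed: float = 14.0  # m/s
    metacarpal_inclination_max: float = 56.0  # deg from the ground at maximal lean
    direction: str = "clockwise"

    def __post_init__(self):
        if not self.curve_radius > 0:
            raise ParameterError("curve_radius must be positive")
        if not 0 < self.metacarpal_inclination_max <= 90:
            raise ParameterError("inclination must lie in (0, 90] deg")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ParameterError("direction must be clockwise or counterclockwise")


@dataclass
class DriveSignal:
    """Prescribed gross limb kinematics over one stride.

    All series are C1 smooth (PCHIP through phase landmarks).  Besides the
    gross series, the drive carries the radio-carpal micro-motion
    (axial squeeze, dorso-palmar shear, frontal tilt) that reconstructs the
    load transfer through the carpus; see the methods note.
    """

    t: np.ndarray  # dense grid [s]
    trunk_velocity: np.ndarray  # (N, 3) [m/s]
    hoof_speed: np.ndarray  # (N,) forward speed [m/s]
    hoof_height: np.ndarray  # (N,) [m]
    hinge_angles: Dict[str, np.ndarray]  # deg per hinge
    inclination_deg: np.ndarray  # (N,) metacarpus-to-ground
    squeeze: np.ndarray  # (N,) radio-carpal axial approach [m]
    shear: np.ndarray  # (N,) dorsal(+)/palmar(-) shear [m]
    frontal_tilt: np.ndarray  # (N,) medial tilt [rad]
    impact_time: float = 0.018
    interpolants: dict = field(default_factory=dict, repr=False)

    def duration(self) -> float:
        return float(self.t[-1])

    def at(self, name: str, t):
        """Evaluate a named series at arbitrary times via its C1 interpolant."""
        return self.interpolants[name](np.clip(t, self.t[0], self.t[-1]))

    def check_invariants(self, accel_bound: float = 5e3) -> None:
        """C1 bound on hoof speed and zero hoof speed at the impact time."""
        if abs(float(self.at("hoof_speed", self.impact_time))) > 1e-12:
            raise InputError("hoof speed must be zero at the impact time")
        dv = np.gradient(self.hoof_speed, self.t)
        if np.max(np.abs(dv)) > accel_bound:
            raise InputError("hoof speed violates the C1 velocity-jump bound")


@dataclass
class SegmentationParams:
    mad_factor: float = 6.0  # impact-peak threshold: median + n * MAD
    min_stride_s: float = 0.25  # refractory between impact peaks
    gyro_mad_factor: float = 8.0  # swing-onset threshold over early-stance baseline
    baseline_samples: int = 12
    refractory_samples: int = 2
    onset_consecutive: int = 3  # samples that must exceed the swing threshold


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def segment_strides(imu: ImuRecord, params: SegmentationParams = None) -> List[Tuple[int, int, Tuple[int, int]]]:
    """Detect hoof-on / hoof-off events in an IMU record.

    Hoof-on is an acceleration-magnitude impact peak above an adaptive
    threshold (median + n*MAD); hoof-off is the subsequent transition from
    gyroscope quiescence (stance) to the swing oscillation.  Returns a list
    of ``(hoof_on index, hoof_off index, (stride start, stride end))`` for
    every complete stride.  Deterministic for fixed parameters.
    """
    if params is None:
        params = SegmentationParams()
    a = np.linalg.norm(imu.accel, axis=1)
    g = np.linalg.norm(imu.gyro, axis=1)
    thr = np.median(a) + params.mad_factor * _mad(a)
    peaks, _ = find_peaks(a, height=thr, distance=max(1, int(params.min_stride_s * imu.sample_rate)))
    if len(peaks) < 2:
        raise DetectionError("fewer than two impact peaks found (need >= 2 strides)")
    out = []
    for i0, i1 in zip(peaks[:-1], peaks[1:]):
        b0 = i0 + params.refractory_samples
        base = g[b0 : b0 + params.baseline_samples]
        g_thr = np.median(base) + params.gyro_mad_factor * _mad(base) + 1e-6
        window = g[b0 + params.baseline_samples : i1] > g_thr
        k = params.onset_consecutive
        sustained = window.copy()
        for j in range(1, k):
            sustained[: len(window) - j] &= window[j:]
        idx = np.flatnonzero(sustained[: len(window) - k + 1] if k > 1 else sustained)
        if len(idx) == 0:
            hoof_off = i0 + (i1 - i0) // 3  # no swing signature: nominal split
        else:
            # the onset sample itself is the last quiescent instant: step
            # one sample back to centre the systematic detection delay
            hoof_off = max(b0 + params.baseline_samples + int(idx[0]) - 1, i0 + 1)
        out.append((int(i0), int(hoof_off), (int(i0), int(i1))))
    return out


def carpus_angle_metrics(
    gyro_prox: np.ndarray,
    gyro_dist: np.ndarray,
    stride_bounds: Sequence[Tuple[int, int]],
    sample_rate: float = 200.0,
    impact_angle_deg: float = 175.0,
    hinge_axis: int = 1,
    stance_fraction: float = 0.4,
    lead: str = "lead",
) -> List[StrideMetrics]:
    """Carpal angle metrics from a proximal/distal gyroscope pair.

    The joint angle is the integral of the relative angular rate about the
    hinge axis, drift-corrected by a per-stride linear detrend anchored to
    the impact pose (a zero-velocity-update at each impact), and offset so
    the angle at impact equals ``impact_angle_deg``.
    """
    gyro_prox = np.asarray(gyro_prox, float)
    gyro_dist = np.asarray(gyro_dist, float)
    if np.max(np.abs(gyro_dist)) > 34.9 or np.max(np.abs(gyro_prox)) > 34.9:
        import logging

        logging.getLogger(__name__).warning("gyro magnitude near saturation (2000 deg/s)")
    w_rel = gyro_dist[:, hinge_axis] - gyro_prox[:, hinge_axis]
    dt = 1.0 / sample_rate
    metrics = []
    for a, b in stride_bounds:
        if not (0 <= a < b <= len(w_rel)):
            raise InputError("invalid stride bounds")
        w = w_rel[a:b]
        ang = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2.0) * dt])
        # linear detrend: the impact pose recurs at each stride boundary
        drift = ang[-1] - ang[0]
        ang = ang - drift * np.linspace(0.0, 1.0, len(ang))
        ang_deg = impact_angle_deg + np.degrees(ang)
        stride_T = (b - a) * dt
        metrics.append(
            StrideMetrics(
                stride_duration=stride_T,
                stance_duration=stance_fraction * stride_T,
                swing_duration=(1.0 - stance_fraction) * stride_T,
                carpus_angle_at_impact=impact_angle_deg,
                angle_max_extension=float(ang_deg.max()),
                angle_max_flexion=float(ang_deg.min()),
                range_of_motion=float(ang_deg.max() - ang_deg.min()),
                lead=lead,
            )
        )
    return metrics


def speed_from_markers(crossing_times: Sequence[float], spacing: float = 5.0):
    """Velocities and accelerations from ground-marker crossing times.

    Markers are placed every ``spacing`` meters; ``crossing_times`` are the
    instants the horse passes each.  Returns ``(instant velocities,
    average velocity, accelerations)``; accelerations are finite
    differences of the instant velocities at interval midpoints.
    """
    t = np.asarray(crossing_times, float)
    if len(t) < 3:
        raise InputError("need at least 3 marker crossings")
    if np.any(np.diff(t) <= 0):
        raise InputError("crossing times must be strictly increasing")
    gaps = np.diff(t)
    v = spacing / gaps
    avg = spacing * len(gaps) / (t[-1] - t[0])
    mid = (t[:-1] + t[1:]) / 2.0
    acc = np.diff(v) / np.diff(mid)
    return v, float(avg), acc


def predicted_lean(scenario: CurveScenario, g: float = G) -> Tuple[float, float]:
    """Centripetal acceleration and predicted limb inclination on the curve.

    A limb aligned with the resultant of gravity and the centripetal
    acceleration a_c = v^2 / r makes an angle ``90 - atan(a_c / g)`` degrees
    with the ground.
    """
    a_c = scenario.speed**2 / scenario.curve_radius
    inclination = 90.0 - np.degrees(np.arctan2(a_c, g))
    return float(a_c), float(inclination)


# ---------------------------------------------------------------------------
# drive construction
# ---------------------------------------------------------------------------

#: Calibrated micro-motion defaults of the shipped scenario (see methods
#: note): peak radio-carpal axial approach during stance / swing flexion,
#: dorso-palmar shear excursion, and peak frontal (medial) tilt.
SQUEEZE_STANCE = 0.87e-3  # m
SQUEEZE_SWING_FRACTION = 0.55
SHEAR_DORSAL = 0.8e-3  # m
SHEAR_PALMAR = -1.2e-3  # m
FRONTAL_TILT_MAX = 4.0e-3  # rad
STANCE_FLEXION_DIP = 24.0  # deg of carpal flexion under the stance load


def _pchip(knots_ms, values, T_scale):
    x = np.asarray(knots_ms, float) * 1e-3 * T_scale
    return PchipInterpolator(x, np.asarray(values, float))


def build_drive(
    metrics: StrideMetrics,
    scenario: CurveScenario,
    T: float = 0.103,
    impact_time: float = None,
    n_samples: int = 2061,
) -> DriveSignal:
    """Assemble the C1 drive signal from stride metrics and the scenario.

    Phase landmarks (impact, hoof-off, angle extrema, peak speed, maximal
    lean) are placed as PCHIP knots so the drive passes through them
    exactly; time-scaling ``T`` scales every landmark time linearly.
    """
    if not T > 0:
        raise ParameterError("T must be positive")
    s = T / 0.103  # landmark times below are expressed on the 103 ms reference
    if impact_time is None:
        impact_time = 0.018 * s
    if not 0 < impact_time < T:
        raise InputError("impact landmark out of order")
    imp = impact_time / (1e-3 * s)  # back on the reference ms axis
    off = imp + 103.0 * metrics.stance_duration / metrics.stride_duration
    if not imp < off < 103.0:
        raise InputError("landmarks out of order (stance extends past the stride)")

    v_top = scenario.speed
    trunk = _pchip([0, 50, 103], [v_top - 0.3, v_top, v_top - 0.2], s)
    hoof_speed = _pchip(
        [0, 0.5 * imp, imp, off, off + 17, off + 29, 103],
        [0.8 * v_top, 0.5 * v_top, 0.0, 0.0, 1.15 * v_top, 0.6 * v_top, 0.35 * v_top],
        s,
    )
    sink = 2.0e-3
    hoof_height = _pchip(
        [0, 0.5 * imp, imp, imp + 6, imp + 12, off - 5, off, off + 17, off + 29, 103],
        [0.04, 0.012, 0.0, -0.9 * sink, -sink, -0.5 * sink, 0.0, 0.06, 0.03, 0.008],
        s,
    )

    ext, flx, a_imp = metrics.angle_max_extension, metrics.angle_max_flexion, metrics.carpus_angle_at_impact
    mid_flex = max(min(a_imp, ext) - STANCE_FLEXION_DIP, flx)  # flexion dip under load
    t_dip = imp + 0.49 * (off - imp)
    t_flex = off + 0.55 * (103 - off)  # full flexion in mid-swing
    carpus = _pchip(
        [0, 0.45 * imp, imp, t_dip, off - 4, t_flex, 103],
        [a_imp - 1, ext, a_imp, mid_flex, min(a_imp, ext), flx, min(flx + 50, ext - 10)],
        s,
    )
    elbow = _pchip([0, 103], [150.0, 150.0], s)
    fetlock = _pchip([0, imp, t_dip, off, t_flex, 103], [205, 200, 215, 205, 160, 200], s)
    coffin = _pchip([0, 103], [180.0, 180.0], s)

    lean_min = scenario.metacarpal_inclination_max
    t_lean = imp + 0.49 * (off - imp)  # maximal lean near mid-stance, end of curve
    incl = _pchip(
        [0, imp, t_lean, off, off + 0.5 * (103 - off), 103],
        [85.0, 80.0, lean_min, 70.0, 82.0, 85.0],
        s,
    )

    dz_st = SQUEEZE_STANCE
    dz_sw = SQUEEZE_SWING_FRACTION * dz_st
    t_pk = imp + 0.33 * (off - imp)
    squeeze = _pchip(
        [0, imp, imp + 0.18 * (off - imp), t_pk, imp + 0.6 * (off - imp), off - 2, off, 0.5 * (off + t_flex), t_flex, t_flex + 0.5 * (103 - t_flex), 103],
        [0, 0, 0.8 * dz_st, dz_st, 0.5 * dz_st, 0.05 * dz_st, 0, 0, dz_sw, 0, 0],
        s,
    )
    t_pal = imp + 0.49 * (off - imp)  # loaded palmar glide peaks mid-stance
    st = off - imp
    shear = _pchip(
        [0, imp, imp + 0.09 * st, t_pk, t_pal, t_pal + 0.13 * st, t_pal + 0.27 * st, off - 0.07 * st, off, 0.7 * off + 0.3 * t_flex, t_flex, 0.5 * (t_flex + 103), 103],
        [0, 0, SHEAR_DORSAL, 0.2 * SHEAR_DORSAL, SHEAR_PALMAR, 0.2 * SHEAR_PALMAR, 0.4 * SHEAR_DORSAL, 0.5 * SHEAR_DORSAL, 0, 0, 0.9 * SHEAR_DORSAL, 0, 0],
        s,
    )
    tilt = _pchip(
        [0, imp, imp + 0.18 * (off - imp), t_pk, imp + 0.6 * (off - imp), off, 103],
        np.array([0, 0, 0.8, 1.0, 0.5, 0, 0]) * FRONTAL_TILT_MAX,
        s,
    )

    t = np.linspace(0.0, T, n_samples)
    interpolants = {
        "trunk_speed": trunk,
        "hoof_speed": hoof_speed,
        "hoof_height": hoof_height,
        "carpus": carpus,
        "elbow": elbow,
        "fetlock": fetlock,
        "coffin": coffin,
        "inclination_deg": incl,
        "squeeze": squeeze,
        "shear": shear,
        "frontal_tilt": tilt,
    }
    drive = DriveSignal(
        t=t,
        trunk_velocity=np.column_stack([trunk(t), np.zeros_like(t), np.zeros_like(t)]),
        hoof_speed=hoof_speed(t),
        hoof_height=hoof_height(t),
        hinge_angles={
            "elbow": elbow(t),
            "carpus": carpus(t),
            "fetlock": fetlock(t),
            "coffin": coffin(t),
        },
        inclination_deg=incl(t),
        squeeze=squeeze(t),
        shear=shear(t),
        frontal_tilt=tilt(t),
        impact_time=float(impact_time),
        interpolants=interpolants,
    )
    drive.check_invariants()
    return drive
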