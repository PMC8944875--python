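"""Seeded generators for every input the analysis pipeline consumes.

The analysis needs CT/micro-CT scans, carpus-mounted IMU recordings and
race video that do not exist in public form, so this module generates the
stand-ins: IMU
stride records with the signal structure the segmentation relies on,
analytic morphometry phantoms carrying their reference values, and the
shipped accident-scenario preset with its documented constants.

Every generator is a pure function of (config, seed); a single global seed
fans out to independent per-generator substreams (``spawn_key`` on the seed
sequence), so adding a generator never perturbs existing fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError
from .kinematics import CurveScenario, ImuRecord, StrideMetrics
from .microct_morphometry import VoxelVolume

__all__ = [
    "GeneratorConfig",
    "synth_imu",
    "asti_2015_preset",
    "phantom",
    "PHANTOM_SHAPES",
]

_STREAMS = {"imu": 0, "phantom": 1, "scenario": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic IMU stride generator."""

    seed: int = 0
    n_strides: int = 6
    stride_duration: float = 0.45  # s
    stance_fraction: float = 0.30
    sample_rate: float = 200.0  # Hz
    noise_accel: float = 0.5  # m/s^2
    noise_gyro: float = 0.05  # rad/s
    impact_amplitude: float = 80.0  # m/s^2 spike at hoof-on
    swing_gyro_amplitude: float = 5.0  # rad/s
    lead_in: float = 0.25  # s of quiet signal before the first impact
    gyro_bias: float = 0.0  # rad/s constant bias (drift injection, default off)
    placement: str = "left_carpus"

    def __post_init__(self):
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance fraction must lie in (0, 1)")
        if self.n_strides < 2:
            raise ParameterError("need at least 2 strides")


def synth_imu(config: GeneratorConfig) -> ImuRecord:
    """An IMU record with impact spikes at hoof-on and a swing oscillation.

    Impacts are placed at integer sample indices every stride; the
    gyroscope is quiescent during stance and carries a half-sine
    flexion-extension burst during swing; Gaussian sensor noise is added at
    the configured levels.  Deterministic per seed.
    """
    rng = _rng(config.seed, "imu")
    fs = config.sample_rate
    stride_n = int(round(config.stride_duration * fs))
    stance_n = int(round(config.stance_fraction * config.stride_duration * fs))
    lead_n = int(round(config.lead_in * fs))
    total = lead_n + config.n_strides * stride_n + lead_n
    accel = np.zeros((total, 3))
    gyro = np.zeros((total, 3))
    accel[:, 2] = 9.81
    for k in range(config.n_strides):
        i_on = lead_n + k * stride_n
        accel[i_on, 2] += config.impact_amplitude
        if i_on + 1 < total:
            accel[i_on + 1, 2] += 0.35 * config.impact_amplitude
        i_off = i_on + stance_n
        i_next = i_on + stride_n
        swing = np.arange(i_off, min(i_next, total))
        phase = (swing - i_off) / max(i_next - i_off, 1)
        gyro[swing, 1] += config.swing_gyro_amplitude * np.sin(np.pi * phase)
    accel += rng.normal(0.0, config.noise_accel, size=accel.shape)
    gyro += rng.normal(0.0, config.noise_gyro, size=gyro.shape)
    gyro += config.gyro_bias
    return ImuRecord(sample_rate=fs, accel=accel, gyro=gyro, placement=config.placement)


def asti_2015_preset():
    """The shipped accident-scenario constants.

    Curve radius 28 m, trunk mass 500 kg, peak curve speed 14 m/s, maximal
    metacarpal inclination 56 deg, stride 103 ms with hoof strike at 18 ms,
    bone density 1590 kg/m^3.  The carpal angle landmarks (impact angle,
    maximal extension/flexion) are not available as measurements; the
    values here are documented placeholders consistent with galloping
    carpal kinematics.

    Returns ``(scenario, metrics, model_config)``.
    """
    from .dynamics import ModelConfig

    scenario = CurveScenario(
        curve_radius=28.0,
        speed=14.0,
        metacarpal_inclination_max=56.0,
        direction="clockwise",
    )
    metrics = StrideMetrics(
        stride_duration=0.103,
        stance_duration=0.045,
        swing_duration=0.058,
        carpus_angle_at_impact=182.0,  # placeholder (stance hyperextension)
        angle_max_extension=183.0,  # placeholder
        angle_max_flexion=120.0,  # placeholder
        range_of_motion=63.0,
        lead="lead",
    )
    model = ModelConfig(trunk_mass=500.0, T=0.103)
    assert model.material.bone_density == 1590.0
    return scenario, metrics, model


PHANTOM_SHAPES = ("plate", "rod", "sphere", "isotropic_spheres", "cartilage_layer", "wedge_layer")


def phantom(shape: str, params: Optional[dict] = None, seed: int = 0) -> VoxelVolume:
    """Voxelise an analytic phantom; analytic reference values are attached
    as ``metadata`` for direct consumption by the morphometry tests.

    Shapes and their parameters (all lengths in voxels unless noted):

    * ``plate``: parallel slabs, ``thickness`` (default 8), ``gap`` (24);
      refs: TbTh, TbSp.
    * ``rod``: a cylinder spanning z, ``diameter`` (12); ref: TbTh.
    * ``sphere``: centered ball, ``radius`` (12); ref: BVTV.
    * ``isotropic_spheres``: seeded random balls, ``n_spheres`` (40),
      ``radius`` (5); isotropic by construction (DA ref approx 0).
    * ``cartilage_layer``: uniform sheet, ``thickness`` (e.g. 300 um /
      voxel size); refs: CTh mean/min/max.
    * ``wedge_layer``: thickness ramp ``t0`` -> ``t1`` along x; refs CTh.

    Common params: ``size`` (cube edge, default 64), ``voxel_size_um``
    (default 17.5).
    """
    if shape not in PHANTOM_SHAPES:
        raise ParameterError(f"unknown phantom shape {shape!r}")
    p = dict(params or {})
    n = int(p.get("size", 64))
    vx = float(p.get("voxel_size_um", 17.5))
    data = np.zeros((n, n, n), bool)
    meta = {"shape": shape, "seed": seed}
    phase = "bone"

    if shape == "plate":
        t = int(p.get("thickness", 8))
        gap = int(p.get("gap", 24))
        if t <= 0 or gap < 0 or t + gap > n:
            raise ParameterError("plate thickness/gap exceed the volume")
        z = 0
        while z < n:
            data[:, :, z : min(z + t, n)] = True
            z += t + gap
        meta.update(TbTh_ref_um=t * vx, TbSp_ref_um=gap * vx, DA_ref="anisotropic")
    elif shape == "rod":
        d = int(p.get("diameter", 12))
        if d > n:
            raise ParameterError("rod diameter exceeds the volume")
        r = d / 2.0
        c = (n - 1) / 2.0
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disk = (xx - c) ** 2 + (yy - c) ** 2 <= r**2
        data[:] = disk[:, :, None]
        meta.update(TbTh_ref_um=d * vx, SMI_ref=3.0)
    elif shape == "sphere":
        r = float(p.get("radius", 12))
        if 2 * r > n:
            raise ParameterError("sphere exceeds the volume")
        c = (n - 1) / 2.0
        g = np.arange(n)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        data = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= r**2
        meta.update(BVTV_ref_percent=100.0 * (4.0 / 3.0) * np.pi * r**3 / n**3, SMI_ref=4.0)
    elif shape == "isotropic_spheres":
        rng = _rng(seed, "phantom")
        n_sph = int(p.get("n_spheres", 40))
        r = float(p.get("radius", 5))
        g = np.arange(n)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        for _ in range(n_sph):
            c = rng.uniform(r, n - 1 - r, size=3)
            data |= (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r**2
        meta.update(DA_ref=0.0)
    elif shape in ("cartilage_layer", "wedge_layer"):
        phase = "cartilage"
        z0 = max(2, n // 8)  # keep the sheet clear of the volume border
        if shape == "cartilage_layer":
            t = int(p.get("thickness", 17))
            if z0 + t > n:
                raise ParameterError("layer thicker than the volume")
            data[:, :, z0 : z0 + t] = True
            meta.update(CTh_ref_um=t * vx)
        else:
            t0 = int(p.get("t0", 6))
            t1 = int(p.get("t1", 34))
            if z0 + max(t0, t1) > n:
                raise ParameterError("wedge exceeds the volume")
            thick = np.rint(np.linspace(t0, t1, n)).astype(int)
            for i, ti in enumerate(thick):
                data[i, :, z0 : z0 + ti] = True
            meta.update(CTh_min_ref_um=min(t0, t1) * vx, CTh_max_ref_um=max(t0, t1) * vx)

    return VoxelVolume(data=data, voxel_size=vx, phase_label=phase, metadata=meta)
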