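"""Dynamic numerical thorax phantom for first-pass myocardial perfusion.

The phantom is the ground-truth "patient" that the acquisition simulator
samples: an analytic thorax (elliptic body, lungs, liver below a mobile
diaphragm) containing a tilted left ventricle modelled as an ellipsoidal
blood pool inside an ellipsoidal epicardial shell, plus a right-ventricular
blood pool.  Contrast passage is a gamma-variate arterial input with a
delayed, dispersed tissue curve; respiration is a diaphragm foot-head trace
that the heart follows with a fixed scaling (the quantity a navigator
tracking factor tries to match).

All geometry is evaluated analytically at arbitrary (continuous) foot-head
positions, so sampling a slice at ``prescribed + heart_displacement``
reproduces the motion-free image exactly -- the property that makes
perfect prospective tracking testable to machine precision.

Axes: index order is (x, y, z) with z the foot-head axis, positive toward
the head.  In-plane slice images have shape ``(nx, ny)``; y is the
phase-encode direction of the simulated acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TissueSpec",
    "PhantomSpec",
    "BolusModel",
    "MotionConfig",
    "BreathEvent",
    "MotionTrace",
    "CoilMaps",
    "DynamicPhantom",
    "GeometryError",
    "make_phantom",
    "gamma_variate_concentration",
    "t1_with_contrast",
    "make_motion_trace",
    "make_coil_maps",
    "sample_slices",
]

# Tissue label ids.  Label 0 is air/background outside the body.
AIR = 0
LUNG = 1
BODY = 2
LIVER = 3
MYOCARDIUM = 4
LV_BLOOD = 5
RV_BLOOD = 6


class GeometryError(ValueError):
    """Raised for degenerate phantom geometry (non-positive radii, LV outside grid)."""


@dataclass(frozen=True)
class TissueSpec:
    """Relaxation and enhancement parameters of one tissue class.

    ``kinetics`` selects the contrast curve: ``"none"`` (no enhancement),
    ``"blood"`` (arterial input function) or ``"tissue"`` (delayed,
    dispersed, amplitude-reduced curve).
    """

    label: int
    name: str
    t1_ms: float
    proton_density: float
    kinetics: str = "none"


def default_tissues() -> tuple[TissueSpec, ...]:
    # Baseline T1 values approximate 1.5 T literature values.
    return (
        TissueSpec(AIR, "air", 1000.0, 0.0),
        TissueSpec(LUNG, "lung", 1200.0, 0.05),
        TissueSpec(BODY, "body", 900.0, 0.7),
        TissueSpec(LIVER, "liver", 580.0, 1.0),
        TissueSpec(MYOCARDIUM, "myocardium", 950.0, 0.8, kinetics="tissue"),
        TissueSpec(LV_BLOOD, "lv_blood", 1550.0, 0.95, kinetics="blood"),
        TissueSpec(RV_BLOOD, "rv_blood", 1550.0, 0.95, kinetics="blood"),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Static anatomy of the numerical thorax.

    Lengths are millimetres; the grid origin is at voxel (0, 0, 0) and voxel
    ``i`` is centred at ``i * voxel_size``.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 2.0)
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_tissues)

    # Heart geometry (mm).  The LV long axis is tilted: the cross-section
    # centre at height z is lv_center_xy + lv_tilt * (z - lv_center_z), as
    # for oblique short-axis slices, so through-plane motion also displaces
    # the in-plane centre of mass.
    lv_center: tuple[float, float, float] = (100.0, 130.0, 110.0)
    lv_blood_radii: tuple[float, float] = (22.0, 32.0)  # (in-plane, FH half-length)
    lv_outer_radii: tuple[float, float] = (32.0, 42.0)
    # Tilt signs are chosen so the through-plane COM shift and the optional
    # in-plane heart translation add rather than cancel (oblique motion).
    lv_tilt: tuple[float, float] = (0.30, -0.20)  # mm in-plane per mm FH
    rv_offset: tuple[float, float, float] = (-30.0, 8.0, 5.0)
    rv_radii: tuple[float, float] = (16.0, 30.0)

    # Thorax (mm).
    thorax_center: tuple[float, float] = (121.6, 121.6)
    thorax_radii: tuple[float, float] = (110.0, 88.0)
    chest_wall_mm: float = 15.0
    diaphragm_z: float = 55.0

    slice_thickness_mm: float = 10.0
    seed: int = 0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size))

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise GeometryError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel_size must be positive")
        ab, cb = self.lv_blood_radii
        ao, co = self.lv_outer_radii
        if min(ab, cb, ao, co) <= 0:
            raise GeometryError("LV radii must be positive")
        if not (ab < ao and cb < co):
            raise GeometryError(
                "LV blood pool must lie strictly inside the epicardial shell "
                f"(blood radii {self.lv_blood_radii}, outer {self.lv_outer_radii})"
            )
        ex, ey, ez = self.extent_mm
        cx, cy, cz = self.lv_center
        if not (0 < cx < ex and 0 < cy < ey and 0 < cz < ez):
            raise GeometryError(f"LV centre {self.lv_center} outside grid extent {self.extent_mm}")
        if not 0 < self.diaphragm_z < ez:
            raise GeometryError("diaphragm_z outside grid extent")

    def tissue_table(self) -> dict[int, TissueSpec]:
        return {t.label: t for t in self.tissues}


@dataclass(frozen=True)
class BolusModel:
    """Gamma-variate first-pass contrast model.

    The arterial concentration is the peak-normalised gamma-variate

        C(t) = A * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)

    for t > t0 and zero before arrival; its maximum A occurs at
    t0 + alpha*beta.  Tissue (myocardial) enhancement reuses the same family
    with a later arrival (``tissue_delay``), broader time scale
    (``tissue_dispersion`` added to beta) and a reduced amplitude.
    """

    t0_s: float = 5.0
    alpha: float = 2.5
    beta_s: float = 1.5
    peak_amplitude_mmol: float = 4.0
    tissue_delay_s: float = 4.0
    tissue_dispersion_s: float = 2.0
    tissue_fraction: float = 0.25
    r1_per_mmol_s: float = 4.5

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("gamma-variate needs alpha > 0 and beta > 0")
        if self.peak_amplitude_mmol < 0:
            raise ValueError("peak amplitude must be non-negative")

    def concentration(self, t, kinetics: str = "blood"):
        if kinetics == "none":
            return np.zeros_like(np.asarray(t, dtype=float))
        if kinetics == "blood":
            return gamma_variate_concentration(t, self)
        if kinetics == "tissue":
            shifted = replace(
                self,
                t0_s=self.t0_s + self.tissue_delay_s,
                beta_s=self.beta_s + self.tissue_dispersion_s,
                peak_amplitude_mmol=self.peak_amplitude_mmol * self.tissue_fraction,
            )
            return gamma_variate_concentration(t, shifted)
        raise ValueError(f"unknown kinetics {kinetics!r}")


def gamma_variate_concentration(t, model: BolusModel):
    """Arterial input concentration (mmol/L) at time ``t`` seconds."""
    model.validate()
    t = np.asarray(t, dtype=float)
    dt = t - model.t0_s
    out = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / (model.alpha * model.beta_s)
    out[pos] = model.peak_amplitude_mmol * x**model.alpha * np.exp(
        model.alpha - dt[pos] / model.beta_s
    )
    return out if out.ndim else float(out)


def t1_with_contrast(t10_ms: float, r1_per_mmol_s: float, concentration_mmol):
    """Fast-exchange relaxivity model: 1/T1 = 1/T10 + r1 * C (seconds scale)."""
    if t10_ms <= 0:
        raise ValueError("baseline T1 must be positive")
    if r1_per_mmol_s < 0:
        raise ValueError("relaxivity must be non-negative")
    c = np.asarray(concentration_mmol, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    rate = 1.0 / (t10_ms / 1000.0) + r1_per_mmol_s * c
    t1 = 1000.0 / rate
    return float(t1) if t1.ndim == 0 else t1


@dataclass(frozen=True)
class BreathEvent:
    onset_s: float
    duration_s: float
    extra_mm: float


@dataclass(frozen=True)
class MotionConfig:
    amplitude_mm: float = 7.0
    period_s: float = 4.0
    drift_mm_per_s: float = 0.05
    events: tuple[BreathEvent, ...] = ()
    heart_scale: float = 0.42
    inplane_scale: float = 0.15  # heart y-translation per mm of diaphragm motion


@dataclass(frozen=True)
class MotionTrace:
    """Respiratory trace: diaphragm foot-head displacement d(t) in mm.

    The heart follows the diaphragm with a fixed ratio ``heart_scale``
    (foot-head) and, optionally, a small in-plane (y) translation
    ``inplane_scale * d(t)`` that prospective foot-head tracking cannot
    correct.  Deep-breath events are smooth compactly-supported sin^2 bumps.
    """

    times_s: np.ndarray
    displacement_mm: np.ndarray
    config: MotionConfig = field(default_factory=MotionConfig)
    seed: int = 0

    def diaphragm(self, t):
        c = self.config
        t = np.asarray(t, dtype=float)
        d = np.zeros_like(t)
        if c.period_s <= 0:
            raise ValueError("period must be positive")
        d = c.amplitude_mm * np.sin(2.0 * np.pi * t / c.period_s) + c.drift_mm_per_s * t
        for ev in c.events:
            u = (t - ev.onset_s) / ev.duration_s
            inside = (u > 0) & (u < 1)
            d = d + np.where(inside, ev.extra_mm * np.sin(np.pi * np.clip(u, 0, 1)) ** 2, 0.0)
        return float(d) if d.ndim == 0 else d

    def heart_fh(self, t):
        return self.config.heart_scale * self.diaphragm(t)

    def heart_inplane_y(self, t):
        return self.config.inplane_scale * self.diaphragm(t)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])


def make_motion_trace(config: MotionConfig, duration_s: float, seed: int = 0,
                      dt_s: float = 0.02) -> MotionTrace:
    """Build a motion trace covering ``duration_s`` seconds.

    The trace is deterministic given (config, seed); the seed is carried for
    provenance and for derived stochastic consumers (navigator noise).
    """
    if config.period_s <= 0:
        raise ValueError("period must be positive")
    times = np.arange(0.0, duration_s + dt_s, dt_s)
    trace = MotionTrace(times_s=times, displacement_mm=np.empty(0), config=config, seed=seed)
    d = trace.diaphragm(times)
    return MotionTrace(times_s=times, displacement_mm=d, config=config, seed=seed)


@dataclass(frozen=True)
class CoilMaps:
    """Complex receive sensitivities, shape (n_coils, n_slices, nx, ny)."""

    maps: np.ndarray
    slice_positions_mm: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def sos(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def make_coil_maps(spec: PhantomSpec, slice_positions_mm: Sequence[float],
                   n_coils: int = 8, seed: int = 0) -> CoilMaps:
    """Smooth Gaussian-lobe coil sensitivities around the thorax.

    Coil centres sit on a ring around the chest at two foot-head levels with
    per-coil complex phase ramps, so sensitivities vary both along the
    phase-encode direction and between the two simultaneously excited
    slices -- the variation the extended-FOV parallel-imaging separation
    relies on.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC011]))
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_size
    x = (np.arange(nx) * dx)[:, None]
    y = (np.arange(ny) * dy)[None, :]
    cx, cy = spec.thorax_center
    rx, ry = spec.thorax_radii
    zs = np.asarray(slice_positions_mm, dtype=float)
    z_lo, z_hi = zs.min() - 20.0, zs.max() + 20.0

    maps = np.zeros((n_coils, len(zs), nx, ny), dtype=np.complex128)
    angles = 2.0 * np.pi * np.arange(n_coils) / n_coils + rng.uniform(-0.2, 0.2, n_coils)
    z_levels = np.where(np.arange(n_coils) % 2 == 0, z_lo, z_hi)
    sigma_xy = 0.85 * min(rx, ry)
    sigma_z = 45.0
    for c in range(n_coils):
        ccx = cx + 1.15 * rx * np.cos(angles[c])
        ccy = cy + 1.15 * ry * np.sin(angles[c])
        r2 = (x - ccx) ** 2 + (y - ccy) ** 2
        phase_ramp = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-0.02, 0.02) * (x - cx)
            + rng.uniform(-0.02, 0.02) * (y - cy)
        )
        for s, z in enumerate(zs):
            amp = 0.05 + np.exp(-r2 / (2 * sigma_xy**2)) * np.exp(
                -((z - z_levels[c]) ** 2) / (2 * sigma_z**2)
            )
            maps[c, s] = amp * np.exp(1j * phase_ramp)
    return CoilMaps(maps=maps, slice_positions_mm=zs)


@dataclass(frozen=True)
class DynamicPhantom:
    """Ground-truth world: anatomy + contrast kinetics + motion + coils."""

    spec: PhantomSpec
    bolus: BolusModel
    motion: MotionTrace
    coils: CoilMaps | None = None
    rr_s: float = 1.0
    labels: np.ndarray | None = None  # (nx, ny, nz) label volume at t = 0

    def check_timeline(self, n_dynamics: int) -> None:
        needed = n_dynamics * self.rr_s
        if self.motion.duration_s < needed:
            raise ValueError(
                f"motion trace covers {self.motion.duration_s:.1f} s "
                f"but the acquisition needs {needed:.1f} s"
            )

    def tissue_weights(self, t_s: float, ts_ms: float) -> dict[int, float]:
        """Per-tissue signal weight PD * (1 - exp(-TS/T1(t))) at time t."""
        from .sequence import saturation_recovery_weight

        weights = {}
        for tis in self.spec.tissues:
            c = self.bolus.concentration(t_s, tis.kinetics)
            t1 = t1_with_contrast(tis.t1_ms, self.bolus.r1_per_mmol_s, c)
            weights[tis.label] = tis.proton_density * saturation_recovery_weight(t1, ts_ms)
        return weights


def _label_cross_section(spec: PhantomSpec, z_mm, heart_dz: float = 0.0,
                         heart_dy: float = 0.0, liver_dz: float = 0.0) -> np.ndarray:
    """Analytic tissue-label image (nx, ny) of the axial plane at height z.

    ``heart_dz``/``heart_dy`` translate the heart (foot-head / in-plane y);
    ``liver_dz`` translates the diaphragm edge.
    """
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_size
    x = (np.arange(nx) * dx)[:, None]
    y = (np.arange(ny) * dy)[None, :]

    labels = np.full((nx, ny), AIR, dtype=np.uint8)

    cx, cy = spec.thorax_center
    rx, ry = spec.thorax_radii
    thorax = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    labels[thorax] = BODY

    rxi, ryi = rx - spec.chest_wall_mm, ry - spec.chest_wall_mm
    inner = ((x - cx) / rxi) ** 2 + ((y - cy) / ryi) ** 2 <= 1.0
    if z_mm < spec.diaphragm_z + liver_dz:
        labels[inner] = LIVER
    else:
        labels[inner] = LUNG

    hx, hy, hz = spec.lv_center
    tx, ty = spec.lv_tilt
    dz_rel = z_mm - hz - heart_dz
    ex = hx + tx * dz_rel
    ey = hy + ty * dz_rel + heart_dy

    # RV blood pool (painted first; the septum is overwritten by myocardium).
    rvx, rvy, rvz = spec.rv_offset
    arv, crv = spec.rv_radii
    uz = (dz_rel - rvz) / crv
    if abs(uz) < 1.0:
        s = np.sqrt(1.0 - uz**2)
        rv = (x - (ex + rvx)) ** 2 + (y - (ey + rvy)) ** 2 <= (arv * s) ** 2
        labels[rv & inner] = RV_BLOOD

    ao, co = spec.lv_outer_radii
    uo = dz_rel / co
    if abs(uo) < 1.0:
        s = np.sqrt(1.0 - uo**2)
        outer = (x - ex) ** 2 + (y - ey) ** 2 <= (ao * s) ** 2
        labels[outer & inner] = MYOCARDIUM
        ab, cb = spec.lv_blood_radii
        ub = dz_rel / cb
        if abs(ub) < 1.0:
            sb = np.sqrt(1.0 - ub**2)
            blood = (x - ex) ** 2 + (y - ey) ** 2 <= (ab * sb) ** 2
            labels[blood & inner] = LV_BLOOD
    return labels


def _lv_mask_cross_section(spec: PhantomSpec, z_mm: float, heart_dz: float = 0.0,
                           heart_dy: float = 0.0) -> np.ndarray:
    """Ground-truth epicardial (outer LV) mask at height z."""
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_size
    x = (np.arange(nx) * dx)[:, None]
    y = (np.arange(ny) * dy)[None, :]
    hx, hy, hz = spec.lv_center
    tx, ty = spec.lv_tilt
    dz_rel = z_mm - hz - heart_dz
    ao, co = spec.lv_outer_radii
    uo = dz_rel / co
    if abs(uo) >= 1.0:
        return np.zeros((nx, ny), dtype=bool)
    s = np.sqrt(1.0 - uo**2)
    ex = hx + tx * dz_rel
    ey = hy + ty * dz_rel + heart_dy
    return (x - ex) ** 2 + (y - ey) ** 2 <= (ao * s) ** 2


def make_phantom(spec: PhantomSpec, bolus: BolusModel | None = None,
                 motion: MotionTrace | None = None, rr_s: float = 1.0,
                 duration_s: float | None = None) -> DynamicPhantom:
    """Rasterise the label volume and assemble the dynamic phantom scaffold.

    Deterministic for a fixed spec/seed.  Coil maps are attached later by the
    acquisition layer (they depend on the prescribed slice positions).
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    dz = spec.voxel_size[2]
    labels = np.empty((nx, ny, nz), dtype=np.uint8)
    for iz in range(nz):
        labels[:, :, iz] = _label_cross_section(spec, iz * dz)
    if motion is None:
        motion = make_motion_trace(MotionConfig(), duration_s or 90.0, seed=spec.seed)
    if bolus is None:
        bolus = BolusModel()
    return DynamicPhantom(spec=spec, bolus=bolus, motion=motion, rr_s=rr_s, labels=labels)


def sample_slices(phantom: DynamicPhantom, t_s: float,
                  slice_positions_mm: Sequence[float],
                  weights: Mapping[int, float],
                  applied_offset_mm: float = 0.0,
                  n_profile_taps: int = 5):
    """Sample axial slices at time t with a boxcar slice profile.

    The scanner samples at ``position + applied_offset`` (the prospective
    tracking shift); the heart has moved by ``heart_scale * d(t)`` foot-head
    and ``inplane_scale * d(t)`` in y, the liver by ``d(t)``.  Returns
    ``(images, masks)`` with shapes (n_slices, nx, ny); masks are the
    ground-truth epicardial LV masks at the slice-profile centre.
    """
    spec = phantom.spec
    ez = spec.extent_mm[2]
    d = phantom.motion.diaphragm(t_s)
    heart_dz = phantom.motion.config.heart_scale * d
    heart_dy = phantom.motion.config.inplane_scale * d

    wtable = np.zeros(max(weights) + 1)
    for lab, w in weights.items():
        wtable[lab] = w

    taps = np.linspace(-spec.slice_thickness_mm / 2.0, spec.slice_thickness_mm / 2.0,
                       n_profile_taps)
    nx, ny, _ = spec.grid_shape
    images = np.zeros((len(slice_positions_mm), nx, ny))
    masks = np.zeros((len(slice_positions_mm), nx, ny), dtype=bool)
    for i, pos in enumerate(slice_positions_mm):
        zc = pos + applied_offset_mm
        if not (0.0 <= zc <= ez):
            raise GeometryError(f"slice position {zc:.1f} mm outside grid extent [0, {ez:.1f}]")
        acc = np.zeros((nx, ny))
        for tap in taps:
            lab = _label_cross_section(spec, zc + tap, heart_dz=heart_dz,
                                       heart_dy=heart_dy, liver_dz=d)
            acc += wtable[lab]
        images[i] = acc / len(taps)
        masks[i] = _lv_mask_cross_section(spec, zc, heart_dz=heart_dz, heart_dy=heart_dy)
    return images, masks


def default_slice_positions(spec: PhantomSpec, n_slices: int = 6,
                            spacing_mm: float = 10.0) -> np.ndarray:
    """Prescribed short-axis stack, base (toward head) first."""
    zc = spec.lv_center[2]
    offs = (np.arange(n_slices) - (n_slices - 1) / 2.0) * spacing_mm
    return zc + offs[::-1]
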