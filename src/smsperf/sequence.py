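"""ECG-triggered SMS-bSSFP saturation-recovery acquisition simulator.

Each heartbeat contains three saturation-recovery blocks; each block excites
two slices simultaneously (multiband 2), so six short-axis slices are
acquired per beat.  Slice pairs are separated with CAIPIRINHA RF phase
cycling, which shifts the second band by half of a two-fold extended
phase-encode field of view; the combined multiband-2 x N-fold in-plane
acceleration problem is thereby recast as a single 2N-fold one-dimensional
acceleration over the doubled FOV, and a time-interleaved (TGRAPPA)
undersampling scheme staggers the acquired lines across dynamics.

Conventions: k-space is stored in centred (DC at row n/2) order with
orthonormal FFTs; phase-encode is the last array axis.  Band phases are
indexed by the absolute (centred) phase-encode line, which keeps the
half-FOV inter-band shift identical in every dynamic regardless of the
TGRAPPA line offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .phantom import CoilMaps, DynamicPhantom, make_coil_maps, sample_slices, default_slice_positions

__all__ = [
    "Protocol",
    "PhaseSchedule",
    "KSpaceShot",
    "AcquisitionResult",
    "caipirinha_phase_schedule",
    "saturation_recovery_weight",
    "encode_sms_shot",
    "tgrappa_sampling_mask",
    "acquire_series",
    "ft2c",
    "ift2c",
]

TWO_PI = 2.0 * np.pi


def ft2c(img: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2D DFT over the last two axes."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def ift2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol.  Defaults mirror the clinical 1.5 T protocol.

    ``n_read``/``n_pe`` default to FOV / resolution; desk-scale simulations
    override them (the reduced default run uses a 128 x 128 matrix).
    """

    fov_mm: tuple[float, float] = (360.0, 326.0)
    resolution_mm: float = 1.9
    slice_thickness_mm: float = 10.0
    n_slices: int = 6
    multiband: int = 2
    inplane_accel: float = 3.5
    n_dynamics: int = 80
    flip_deg: float = 50.0
    te_ms: float = 1.24
    tr_ms: float = 2.9
    ts_ms: float = 100.0
    sr_blocks_per_beat: int = 3
    n_read: int | None = None
    n_pe: int | None = None
    slice_pairing: tuple[tuple[int, int], ...] | None = None
    block_spacing_s: float = 0.18

    @property
    def matrix(self) -> tuple[int, int]:
        nr = self.n_read if self.n_read is not None else round(self.fov_mm[0] / self.resolution_mm)
        npe = self.n_pe if self.n_pe is not None else round(self.fov_mm[1] / self.resolution_mm)
        return nr, npe

    @property
    def n_pe_ext(self) -> int:
        """Extended-FOV phase-encode count (doubled phase FOV)."""
        return 2 * self.matrix[1]

    @property
    def r_ext(self) -> int:
        """Extended in-plane acceleration 2N (must be an integer)."""
        r = self.multiband * self.inplane_accel
        ri = int(round(r))
        if abs(r - ri) > 1e-9:
            raise ValueError(f"extended acceleration 2N = {r} is not an integer")
        return ri

    @property
    def total_acceleration(self) -> float:
        return self.multiband * self.inplane_accel

    @property
    def pairing(self) -> tuple[tuple[int, int], ...]:
        if self.slice_pairing is not None:
            return self.slice_pairing
        half = self.n_slices // self.multiband
        return tuple((i, i + half) for i in range(half))

    def validate(self) -> None:
        if self.sr_blocks_per_beat * self.multiband != self.n_slices:
            raise ValueError(
                f"{self.sr_blocks_per_beat} SR blocks x MB {self.multiband} "
                f"!= {self.n_slices} slices"
            )
        if self.matrix[1] % 2:
            raise ValueError("phase-encode count must be even")
        self.r_ext  # raises if 2N non-integer
        for a, b in self.pairing:
            if not (0 <= a < self.n_slices and 0 <= b < self.n_slices):
                raise ValueError(f"slice pairing ({a}, {b}) out of range")


@dataclass(frozen=True)
class PhaseSchedule:
    """Per-line RF phases (radians, in [0, 2pi)) for the two bands."""

    band1: np.ndarray
    band2: np.ndarray

    def relative(self) -> np.ndarray:
        return np.mod(self.band2 - self.band1, TWO_PI)


def caipirinha_phase_schedule(n_excitations: int, band: int) -> np.ndarray:
    """bSSFP-compatible CAIPIRINHA RF phase cycling for one band.

    Band 1 increments by +pi/2 per excitation, band 2 by -pi/2, so the
    inter-band phase difference alternates [0, pi, 0, pi, ...]: the second
    slice is shifted by half of the (extended) field of view while each band
    individually keeps the +/-pi/2-per-pulse cycling bSSFP requires.
    """
    if n_excitations < 1:
        raise ValueError("need at least one excitation")
    if band not in (1, 2):
        raise ValueError(f"band must be 1 or 2, got {band}")
    step = np.pi / 2.0 if band == 1 else -np.pi / 2.0
    return np.mod(step * np.arange(n_excitations), TWO_PI)


def full_phase_schedule(n_lines: int) -> PhaseSchedule:
    return PhaseSchedule(
        band1=caipirinha_phase_schedule(n_lines, 1),
        band2=caipirinha_phase_schedule(n_lines, 2),
    )


def saturation_recovery_weight(t1_ms: float, ts_ms: float) -> float:
    """Ideal-saturation signal scale 1 - exp(-TS/T1), in [0, 1]."""
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    if ts_ms < 0:
        raise ValueError("TS must be non-negative")
    return float(1.0 - np.exp(-ts_ms / t1_ms))


@dataclass
class KSpaceShot:
    """Multi-coil extended-FOV k-space of one SMS slice pair at one dynamic."""

    dynamic: int
    pair: tuple[int, int]
    kspace: np.ndarray          # (n_coils, n_read, n_pe_ext) complex
    mask: np.ndarray            # (n_pe_ext,) bool, acquired phase-encode lines
    time_s: float
    applied_offset_mm: float = 0.0
    phase_schedule: PhaseSchedule | None = None

    @property
    def r_ext(self) -> int:
        acquired = np.flatnonzero(self.mask)
        if acquired.size < 2:
            return 1
        strides = np.diff(acquired)
        return int(strides[0])


def encode_sms_shot(slice_images: Sequence[np.ndarray], coil_maps: np.ndarray,
                    schedule: PhaseSchedule,
                    line_order: np.ndarray | None = None) -> np.ndarray:
    """Encode a two-band SMS excitation into extended-FOV k-space.

    ``slice_images``: two (nx, ny) images; ``coil_maps``: (n_coils, 2, nx, ny).
    Per coil and extended phase-encode line r the signal is

        S[r] = FT(C1 * I1)[r] e^{i phi1(r)} + FT(C2 * I2)[r] e^{i phi2(r)}

    where each slice is embedded in its nominal half of the doubled phase
    FOV.  With the default schedule (relative phase alternating 0, pi) this
    equals, after band-1 demodulation, the transform of the two slices
    placed half an extended FOV apart.
    """
    img1, img2 = slice_images
    if img1.shape != img2.shape:
        raise ValueError(f"slice grids differ: {img1.shape} vs {img2.shape}")
    n_coils = coil_maps.shape[0]
    nx, ny = img1.shape
    n_ext = 2 * ny
    if len(schedule.band1) != n_ext:
        raise ValueError("schedule must cover all extended phase-encode lines")
    if ny % 2:
        raise ValueError("phase-encode count must be even")

    # Embed each band in the first half of the doubled FOV; the CAIPI
    # relative phase applied below shifts band 2 into the second half.
    pad = np.zeros((n_coils, nx, n_ext), dtype=np.complex128)
    e1 = pad.copy()
    e1[..., :ny] = coil_maps[:, 0] * img1
    e2 = pad.copy()
    e2[..., :ny] = coil_maps[:, 1] * img2
    k1 = ft2c(e1)
    k2 = ft2c(e2)
    p1 = np.exp(1j * schedule.band1)[None, None, :]
    p2 = np.exp(1j * schedule.band2)[None, None, :]
    return k1 * p1 + k2 * p2


def demodulate_band1(kspace: np.ndarray, schedule: PhaseSchedule) -> np.ndarray:
    """Remove the band-1 bSSFP phase cycling (receiver demodulation)."""
    return kspace * np.exp(-1j * schedule.band1)[None, None, :]


def tgrappa_sampling_mask(dynamic_index: int, r_ext: int, n_pe_ext: int) -> np.ndarray:
    """Time-interleaved undersampling: lines k = dynamic_index (mod R_ext).

    The union over R_ext consecutive dynamics tiles all lines exactly once,
    which is what makes merged-dynamics GRAPPA calibration possible.
    """
    if r_ext < 1:
        raise ValueError("R_ext must be >= 1")
    mask = np.zeros(n_pe_ext, dtype=bool)
    mask[dynamic_index % r_ext::r_ext] = True
    return mask


@dataclass
class AcquisitionResult:
    shots: list[KSpaceShot]
    tracking_log: "pd.DataFrame"
    gt_masks: np.ndarray        # (n_slices, n_dynamics, nx, ny) bool
    truth: np.ndarray           # (n_slices, n_dynamics, nx, ny) float, coil-combined truth
    protocol: Protocol
    slice_positions_mm: np.ndarray
    coils: CoilMaps
    tracking: bool


def acquire_series(phantom: DynamicPhantom, protocol: Protocol,
                   tracking: bool = False,
                   tracker: Callable | None = None,
                   slice_positions_mm: Sequence[float] | None = None,
                   noise_sigma: float = 0.0,
                   seed: int = 0,
                   undersample: bool = True) -> AcquisitionResult:
    """Run the full ECG-triggered acquisition over all dynamics.

    Per dynamic and SR block: evaluate the motion state, (optionally) run the
    navigator tracker and offset the slice pair by tracking_factor times the
    estimated diaphragm displacement, sample the pair with saturation-
    recovery tissue weights, CAIPIRINHA-encode, and apply the TGRAPPA mask.
    Complex Gaussian k-space noise is drawn from per-shot seeds derived only
    from (seed, dynamic, block), so paired tracked/untracked runs see
    identical noise realisations.

    A failing tracker never aborts the scan: the error is logged and the
    previous applied offset is reused for that shot.
    """
    import pandas as pd

    protocol.validate()
    phantom.check_timeline(protocol.n_dynamics)
    if slice_positions_mm is None:
        slice_positions_mm = default_slice_positions(
            phantom.spec, protocol.n_slices, protocol.slice_thickness_mm)
    slice_positions_mm = np.asarray(slice_positions_mm, dtype=float)

    coils = phantom.coils
    if coils is None:
        coils = make_coil_maps(phantom.spec, slice_positions_mm, seed=phantom.spec.seed)

    if tracking and tracker is None:
        from .fastnav import CrossCorrelationTracker, TrackingConfig
        tracker = CrossCorrelationTracker(phantom, TrackingConfig(), seed=seed)

    nx, ny = protocol.matrix
    if (nx, ny) != phantom.spec.grid_shape[:2]:
        raise ValueError(
            f"protocol matrix {(nx, ny)} inconsistent with phantom grid "
            f"{phantom.spec.grid_shape[:2]}"
        )
    n_ext = protocol.n_pe_ext
    schedule = full_phase_schedule(n_ext)
    r_ext = protocol.r_ext if undersample else 1
    pairing = protocol.pairing

    n_sl, n_dyn = protocol.n_slices, protocol.n_dynamics
    gt_masks = np.zeros((n_sl, n_dyn, nx, ny), dtype=bool)
    truth = np.zeros((n_sl, n_dyn, nx, ny))
    shots: list[KSpaceShot] = []
    log_rows = []
    last_offset = 0.0

    coil_sos = coils.sos()  # (n_slices, nx, ny)

    for dyn in range(n_dyn):
        for block, pair in enumerate(pairing):
            t = dyn * phantom.rr_s + block * protocol.block_spacing_s
            d_true = phantom.motion.diaphragm(t)
            est = np.nan
            corr = np.nan
            accepted = False
            failed = False
            offset = 0.0
            if tracking:
                try:
                    est, corr, accepted = tracker(t, shot_index=len(shots))
                    if accepted:
                        offset = tracker.tracking_factor * est
                        last_offset = offset
                    else:
                        offset = last_offset
                except Exception:
                    failed = True
                    offset = last_offset

            weights = phantom.tissue_weights(t, protocol.ts_ms)
            positions = slice_positions_mm[list(pair)]
            images, masks = sample_slices(phantom, t, positions, weights,
                                          applied_offset_mm=offset)
            pair_maps = coils.maps[:, list(pair)]
            ksp = encode_sms_shot(images, pair_maps, schedule)
            mask = tgrappa_sampling_mask(dyn, r_ext, n_ext) if undersample \
                else np.ones(n_ext, dtype=bool)
            ksp = ksp * mask[None, None, :]
            if noise_sigma > 0:
                rng = np.random.default_rng(np.random.SeedSequence([seed, 0xACE, dyn, block]))
                noise = rng.normal(0, noise_sigma, ksp.shape) \
                    + 1j * rng.normal(0, noise_sigma, ksp.shape)
                ksp = ksp + noise * mask[None, None, :]
            shots.append(KSpaceShot(dynamic=dyn, pair=tuple(pair),
                                    kspace=ksp.astype(np.complex64), mask=mask,
                                    time_s=t, applied_offset_mm=offset,
                                    phase_schedule=schedule))
            for j, s in enumerate(pair):
                gt_masks[s, dyn] = masks[j]
                truth[s, dyn] = images[j] * coil_sos[s]
            log_rows.append(dict(
                shot=len(shots) - 1, dynamic=dyn, block=block, time_s=t,
                diaphragm_mm=d_true,
                heart_fh_mm=phantom.motion.config.heart_scale * d_true,
                est_mm=est, offset_mm=offset, corr=corr,
                accepted=accepted, tracker_failed=failed,
            ))

    log = pd.DataFrame(log_rows)
    return AcquisitionResult(shots=shots, tracking_log=log, gt_masks=gt_masks,
                             truth=truth, protocol=protocol,
                             slice_positions_mm=slice_positions_mm, coils=coils,
                             tracking=tracking)
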