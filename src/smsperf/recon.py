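"""TGRAPPA reconstruction of the undersampled extended-FOV SMS series.

Calibration merges the complementary line sets of R_ext consecutive
dynamics into one fully sampled k-space (a sliding window centred on the
target dynamic, clamped at the series ends).  A GRAPPA kernel -- ridge-
regularised least-squares weights mapping an acquired source-line
neighbourhood to the missing lines -- is refit per window and applied per
dynamic; coil images are combined by sum of squares and the doubled phase
FOV is split into the two simultaneously excited slices.

Kernel geometry: for each acquired base line b, the source block is the
four acquired lines {b - R, b, b + R, b + 2R} x 5 readout taps across all
coils, and the targets are the R-1 missing lines b+1 .. b+R-1.  Sharing one
source block across all target offsets lets a single normal-equation
factorisation serve every offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence import KSpaceShot, PhaseSchedule, demodulate_band1, ift2c

__all__ = [
    "GrappaKernel",
    "ImageSeries",
    "tgrappa_calibration",
    "grappa_fit",
    "grappa_apply",
    "sos_combine",
    "fov_split",
    "reconstruct_series",
    "series_nrmse",
    "nrmse",
]

_SRC_OFFSETS = (-1, 0, 1, 2)  # source lines at b + R*m


@dataclass
class GrappaKernel:
    """Fitted GRAPPA weights for one acceleration/window."""

    r_ext: int
    n_coils: int
    kernel_pe: int
    kernel_ro: int
    weights: np.ndarray  # (n_features, (R-1) * n_coils)
    reg: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("GRAPPA weights must be finite")


@dataclass
class ImageSeries:
    """Per-slice dynamic magnitude images, shape (n_slices, n_dynamics, nx, ny)."""

    data: np.ndarray
    pixel_mm: tuple[float, float] = (1.9, 1.9)
    registered: bool = False
    filtered: bool = False

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[1]


def nrmse(x: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error normalised by the reference RMS."""
    ref = np.asarray(ref, dtype=float)
    x = np.asarray(x, dtype=float)
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference has zero norm")
    return float(np.linalg.norm(x - ref) / denom)


def tgrappa_calibration(shots: Sequence[KSpaceShot]) -> np.ndarray:
    """Merge complementary undersampled dynamics into full k-space.

    Each phase-encode line is taken from the (unique) dynamic that acquired
    it; the merge is order-independent because the masks are disjoint where
    they overlap the missing set.  Raises if the union is incomplete,
    naming the missing lines.
    """
    n_pe = shots[0].mask.shape[0]
    out = np.zeros_like(shots[0].kspace, dtype=np.complex128)
    covered = np.zeros(n_pe, dtype=bool)
    for shot in shots:
        new = shot.mask & ~covered
        out[..., new] = shot.kspace[..., new]
        covered |= shot.mask
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise ValueError(f"calibration incomplete: missing phase-encode lines {missing.tolist()}")
    return out


def _gather_sources(ksp: np.ndarray, bases: np.ndarray, cols: np.ndarray,
                    r_ext: int, kernel_ro: int) -> np.ndarray:
    """Feature matrix (len(bases)*len(cols), n_coils*n_src*kernel_ro).

    ``ksp`` must be pre-padded so all indexing is in range; ``bases`` and
    ``cols`` index the padded array.
    """
    n_coils = ksp.shape[0]
    half = kernel_ro // 2
    rows = []
    for m in _SRC_OFFSETS:
        line = bases + m * r_ext
        for dx in range(-half, half + 1):
            # (n_coils, len(cols), len(bases))
            rows.append(ksp[:, cols[:, None] + dx, line[None, :]])
    feat = np.stack(rows, axis=0)  # (n_src*kernel_ro, n_coils, n_cols, n_bases)
    return feat.reshape(feat.shape[0] * n_coils, -1).T  # (n_cols*n_bases, n_feat)


def _pad_pe_ro(ksp: np.ndarray, pad_pe: int, pad_ro: int) -> np.ndarray:
    return np.pad(ksp, ((0, 0), (pad_ro, pad_ro), (pad_pe, pad_pe)))


def grappa_fit(calib: np.ndarray, r_ext: int, kernel_pe: int = 4,
               kernel_ro: int = 5, reg: float = 1e-4,
               fit_stride: int = 2) -> GrappaKernel:
    """Fit GRAPPA weights on fully sampled calibration k-space.

    ``calib``: (n_coils, n_read, n_pe).  Ridge regularisation is scaled by
    the mean diagonal of the normal matrix; ``reg=0`` with a singular system
    raises with advice to use reg > 0.  ``fit_stride`` subsamples training
    *readout columns* for speed; every phase-encode base participates
    (subsampling the phase-encode lattice aliases the k-space oscillations
    of off-centre structures into the normal equations and visibly biases
    the weights).
    """
    if kernel_pe != len(_SRC_OFFSETS):
        raise ValueError("kernel geometry fixed at 4 phase-encode source lines")
    n_coils, n_ro, n_pe = calib.shape
    half = kernel_ro // 2
    span_lo, span_hi = -min(_SRC_OFFSETS) * r_ext, max(_SRC_OFFSETS) * r_ext
    bases = np.arange(span_lo, n_pe - span_hi - (r_ext - 1))
    cols = np.arange(half, n_ro - half, max(1, fit_stride))
    if bases.size < 2 or cols.size < 1:
        raise ValueError("calibration region too small for the kernel geometry")

    a = _gather_sources(calib, bases, cols, r_ext, kernel_ro)
    n_feat = a.shape[1]
    targets = np.empty((a.shape[0], (r_ext - 1) * n_coils), dtype=np.complex128)
    for di, delta in enumerate(range(1, r_ext)):
        tgt = calib[:, cols[:, None], (bases + delta)[None, :]]  # (n_coils, n_cols, n_bases)
        targets[:, di * n_coils:(di + 1) * n_coils] = tgt.reshape(n_coils, -1).T

    ata = a.conj().T @ a
    scale = np.real(np.trace(ata)) / n_feat
    if reg < 0:
        raise ValueError("reg must be non-negative")
    lam = reg * scale
    try:
        w = np.linalg.solve(ata + lam * np.eye(n_feat), a.conj().T @ targets)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular GRAPPA normal equations; use reg > 0 for a ridge solution"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "non-finite GRAPPA weights; use reg > 0 for a ridge solution")
    return GrappaKernel(r_ext=r_ext, n_coils=n_coils, kernel_pe=kernel_pe,
                        kernel_ro=kernel_ro, weights=w, reg=reg)


def grappa_apply(shot: KSpaceShot, kernel: GrappaKernel) -> np.ndarray:
    """Synthesize the missing lines of an undersampled shot.

    Acquired lines are preserved bit-exactly; each missing line b+delta is
    predicted from the source block around its acquired base line b.
    k-space is zero-padded at the edges so border targets remain defined.
    """
    ksp = shot.kspace.astype(np.complex128)
    mask = shot.mask
    acquired = np.flatnonzero(mask)
    if acquired.size == mask.size:
        return ksp
    stride = int(np.diff(acquired)[0]) if acquired.size > 1 else 1
    if stride != kernel.r_ext:
        raise ValueError(f"mask stride {stride} does not match kernel R_ext {kernel.r_ext}")
    n_coils, n_ro, n_pe = ksp.shape
    half = kernel.kernel_ro // 2
    pad_pe = 2 * kernel.r_ext
    pad_ro = half
    padded = _pad_pe_ro(ksp, pad_pe, pad_ro)
    cols = np.arange(n_ro) + pad_ro
    bases = acquired + pad_pe
    a = _gather_sources(padded, bases, cols, kernel.r_ext, kernel.kernel_ro)
    pred = a @ kernel.weights  # (n_ro*n_bases, (R-1)*n_coils)
    pred = pred.reshape(len(cols), len(bases), kernel.r_ext - 1, n_coils)
    out = padded
    for di, delta in enumerate(range(1, kernel.r_ext)):
        lines = bases + delta
        out[:, cols[:, None], lines[None, :]] = np.moveaxis(pred[:, :, di, :], 2, 0)
    out = out[:, pad_ro:pad_ro + n_ro, pad_pe:pad_pe + n_pe]
    out[..., mask] = ksp[..., mask]  # data consistency, bit-exact
    return out


def sos_combine(coil_images: np.ndarray) -> np.ndarray:
    """Sum-of-squares coil combination: sqrt(sum_c |I_c|^2)."""
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def fov_split(extended: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cut the doubled phase-FOV image into the two bands.

    Band 1 occupies the first half; the CAIPIRINHA half-FOV shift placed
    band 2 in the second half, so taking that half undoes the shift.
    """
    n_ext = extended.shape[-1]
    if n_ext % 2:
        raise ValueError("extended FOV extent must be even")
    ny = n_ext // 2
    return extended[..., :ny], extended[..., ny:]


def _window(dyn: int, n_dyn: int, r_ext: int) -> range:
    lo = int(np.clip(dyn - (r_ext - 1) // 2, 0, max(0, n_dyn - r_ext)))
    return range(lo, lo + min(r_ext, n_dyn))


def reconstruct_series(shots: Sequence[KSpaceShot], protocol,
                       kernel_pe: int = 4, kernel_ro: int = 5,
                       reg: float = 1e-4, fit_stride: int = 2) -> ImageSeries:
    """Full TGRAPPA pipeline: calibrate, fit, fill, transform, combine, split.

    Produces the unregistered, unfiltered magnitude series (slice, dynamic).
    The calibration window is the R_ext dynamics centred on each target
    dynamic (clamped at the ends) and the kernel is refit per window, so
    outlier breathing positions inside a window degrade that window's
    weights -- the mechanism behind deep-breath ghosting.
    """
    protocol.validate()
    by_pair: dict[tuple[int, int], dict[int, KSpaceShot]] = {}
    for s in shots:
        by_pair.setdefault(s.pair, {})[s.dynamic] = s
    n_dyn = protocol.n_dynamics
    nx, ny = protocol.matrix
    series = np.zeros((protocol.n_slices, n_dyn, nx, ny))
    for pair, dyn_shots in by_pair.items():
        if len(dyn_shots) != n_dyn:
            raise ValueError(f"pair {pair}: expected {n_dyn} dynamics, got {len(dyn_shots)}")
        any_shot = next(iter(dyn_shots.values()))
        r_ext = any_shot.r_ext
        schedule = any_shot.phase_schedule
        if n_dyn < r_ext:
            raise ValueError(
                f"cannot calibrate: {n_dyn} dynamics < acceleration R_ext = {r_ext}")
        for dyn in range(n_dyn):
            shot = dyn_shots[dyn]
            if r_ext == 1:
                filled = shot.kspace.astype(np.complex128)
            else:
                try:
                    calib = tgrappa_calibration([dyn_shots[i] for i in _window(dyn, n_dyn, r_ext)])
                    kernel = grappa_fit(calib, r_ext, kernel_pe, kernel_ro, reg,
                                        fit_stride=fit_stride)
                    filled = grappa_apply(shot, kernel)
                except Exception as exc:
                    raise RuntimeError(
                        f"reconstruction failed at pair {pair}, dynamic {dyn}: {exc}"
                    ) from exc
            if schedule is not None:
                filled = demodulate_band1(filled, schedule)
            extended = sos_combine(ift2c(filled))
            img1, img2 = fov_split(extended)
            series[pair[0], dyn] = img1
            series[pair[1], dyn] = img2
    return ImageSeries(data=series, registered=False, filtered=False)


def series_nrmse(series: ImageSeries, truth: np.ndarray):
    """Per-frame NRMSE of a reconstructed series against matched truth frames.

    Returns a DataFrame (slice, dynamic, nrmse); truth frames are the
    coil-combined fully-sampled ground-truth images of the same motion and
    enhancement state, so the residual isolates undersampling/calibration
    artefacts.
    """
    import pandas as pd

    rows = []
    for s in range(series.n_slices):
        for d in range(series.n_dynamics):
            rows.append(dict(slice=s, dynamic=d,
                             nrmse=nrmse(series.data[s, d], truth[s, d])))
    return pd.DataFrame(rows)
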