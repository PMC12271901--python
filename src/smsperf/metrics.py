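"""Residual-motion metrics: avDICE and avCOM over the LV mask series.

avDICE is the mean, over the analysis window, of the Dice overlap
2|A n B| / (|A| + |B|) between each dynamic's epicardial LV mask and the
reference mask; avCOM is the mean Euclidean displacement (mm) of the mask
centre of mass from the reference location.  The analysis window runs from
peak myocardial enhancement to the end of the series; the reference is the
first window dynamic by default (a temporal-mean-COM variant is available
for avCOM).  Slices are grouped base (1-2), mid (3-4), apex (5-6) for the
regional summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MaskSeries",
    "dice",
    "center_of_mass",
    "av_dice",
    "av_com",
    "regional_summary",
    "analysis_window_start",
]

REGIONS = {"base": (0, 1), "mid": (2, 3), "apex": (4, 5)}


@dataclass(frozen=True)
class MaskSeries:
    """Binary epicardial LV masks, shape (n_slices, n_dynamics, nx, ny)."""

    masks: np.ndarray
    pixel_mm: tuple[float, float] = (1.9, 1.9)
    window: tuple[int, int] | None = None  # [start, stop) dynamics

    def __post_init__(self):
        if self.masks.dtype != bool:
            object.__setattr__(self, "masks", self.masks.astype(bool))
        start, stop = self.effective_window
        if stop <= start:
            raise ValueError("analysis window is empty")

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def n_dynamics(self) -> int:
        return self.masks.shape[1]

    @property
    def effective_window(self) -> tuple[int, int]:
        return self.window if self.window is not None else (0, self.masks.shape[1])


def analysis_window_start(bolus, rr_s: float, n_dynamics: int) -> int:
    """First usable dynamic: peak myocardial enhancement.

    The myocardial curve peaks at t0 + tissue_delay + alpha*(beta +
    dispersion); the window runs from there to the end of the series.
    """
    t_peak = bolus.t0_s + bolus.tissue_delay_s + bolus.alpha * (
        bolus.beta_s + bolus.tissue_dispersion_s)
    return int(min(max(round(t_peak / rr_s), 0), n_dynamics - 1))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); undefined for two empty masks."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share the grid")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("Dice undefined: both masks empty")
    return float(2.0 * np.logical_and(a, b).sum() / total)


def center_of_mass(mask: np.ndarray, pixel_mm=(1.9, 1.9)) -> tuple[float, float]:
    """Area centroid of a binary mask in physical (mm) units."""
    m = mask.astype(bool)
    n = m.sum()
    if n == 0:
        raise ValueError("centre of mass undefined for an empty mask")
    ix, iy = np.nonzero(m)
    return float(ix.mean() * pixel_mm[0]), float(iy.mean() * pixel_mm[1])


def av_dice(series: MaskSeries, slice_index: int) -> float:
    """Mean Dice of each window dynamic against the first window dynamic."""
    start, stop = series.effective_window
    ref = series.masks[slice_index, start]
    vals = [dice(series.masks[slice_index, d], ref) for d in range(start, stop)]
    return float(np.mean(vals))


def av_com(series: MaskSeries, slice_index: int, reference: str = "first") -> float:
    """Mean COM displacement (mm) over the window.

    ``reference="first"`` measures against the first window dynamic (default);
    ``"mean"`` against the temporal mean COM.
    """
    start, stop = series.effective_window
    coms = np.array([center_of_mass(series.masks[slice_index, d], series.pixel_mm)
                     for d in range(start, stop)])
    if reference == "first":
        ref = coms[0]
    elif reference == "mean":
        ref = coms.mean(axis=0)
    else:
        raise ValueError(f"unknown COM reference {reference!r}")
    return float(np.mean(np.linalg.norm(coms - ref, axis=1)))


def regional_summary(series: MaskSeries, method: str = "",
                     com_reference: str = "first") -> pd.DataFrame:
    """Per-slice, per-region (base/mid/apex) and global avDICE/avCOM table."""
    rows = []
    per_slice = {}
    for s in range(series.n_slices):
        d = av_dice(series, s)
        c = av_com(series, s, reference=com_reference)
        per_slice[s] = (d, c)
        rows.append(dict(method=method, scope=f"slice{s + 1}", avdice=d, avcom_mm=c))
    for region, idx in REGIONS.items():
        members = [per_slice[s] for s in idx if s in per_slice]
        if members:
            rows.append(dict(method=method, scope=region,
                             avdice=float(np.mean([m[0] for m in members])),
                             avcom_mm=float(np.mean([m[1] for m in members]))))
    rows.append(dict(method=method, scope="global",
                     avdice=float(np.mean([v[0] for v in per_slice.values()])),
                     avcom_mm=float(np.mean([v[1] for v in per_slice.values()]))))
    return pd.DataFrame(rows)
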