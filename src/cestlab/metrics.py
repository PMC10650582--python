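"""Evaluation metrics: PSNR, spectral-minimum B0 self-correction, MTR_asym."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .bm_simulator import CestVolume, ZSpectrum

__all__ = ["EvalReport", "MtrAsymMap", "psnr", "psnr_map", "wassr_correct",
           "mtr_asym",
           "mtr_asym_map", "find_water_minimum", "CREATINE_RANGE_PPM",
           "GAG_RANGE_PPM", "default_mask"]

#: Creatine-sensitive MTR_asym integration range (ppm).
CREATINE_RANGE_PPM = (1.5, 2.5)
#: Glycosaminoglycan OH range (ppm).
GAG_RANGE_PPM = (0.9, 1.9)

#: Returned when MSE is exactly zero.
PSNR_INF = float("inf")

_WASSR_GRID_PPM = 0.01


@dataclass(frozen=True)
class EvalReport:
    """Per-(method, sigma) PSNR summary over a set of datasets."""

    method: str
    sigma: float
    psnr_mean: float
    psnr_sd: float
    n_datasets: int

    def __post_init__(self) -> None:
        if self.psnr_sd < 0 or self.n_datasets < 1:
            raise ValueError("invalid report row")

    def to_dict(self) -> dict:
        return {"method": self.method, "sigma": self.sigma,
                "psnr_mean": self.psnr_mean, "psnr_sd": self.psnr_sd,
                "n_datasets": self.n_datasets}


@dataclass
class MtrAsymMap:
    """Voxel-wise MTR_asym in percent plus per-ROI statistics."""

    values: np.ndarray
    range_ppm: tuple[float, float]
    roi_stats: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.range_ppm
        if not lo < hi:
            raise ValueError("range low must be < high")


def default_mask(vol: CestVolume) -> np.ndarray:
    """Foreground heuristic when no mask is supplied: m0 > 0.1 max(m0)."""
    return vol.m0 > 0.1 * vol.m0.max()


def psnr(clean: CestVolume, test: CestVolume,
         mask: np.ndarray | None = None) -> float:
    """Pooled PSNR in dB with MAX_I = 1 over masked voxels x offsets."""
    if clean.shape != test.shape:
        raise ValueError("shape mismatch")
    if not np.allclose(clean.offsets_ppm, test.offsets_ppm):
        raise ValueError("offset axes differ")
    if mask is None:
        mask = np.ones(clean.shape[:2], dtype=bool)
    err = clean.data[mask] - test.data[mask]
    mse = float(np.mean(err * err))
    if mse == 0.0:
        return PSNR_INF
    return float(10.0 * np.log10(1.0 / mse))


def find_water_minimum(zs: ZSpectrum) -> float:
    """Offset (ppm) of the spectral minimum on a 0.01-ppm spline grid."""
    order = np.argsort(zs.offsets_ppm)
    return _spline_minimum(zs.z[order], zs.offsets_ppm[order])


def psnr_map(clean: CestVolume, test: CestVolume) -> np.ndarray:
    """Per-voxel PSNR (dB) over the offset axis; +inf where MSE is zero."""
    if clean.shape != test.shape:
        raise ValueError("shape mismatch")
    mse = np.mean((clean.data - test.data) ** 2, axis=2)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(np.where(mse > 0, 1.0 / mse, np.inf))


def _spline_minimum(z: np.ndarray, offsets: np.ndarray) -> float:
    spline = CubicSpline(offsets, z)
    grid = np.arange(offsets[0], offsets[-1] + _WASSR_GRID_PPM / 2,
                     _WASSR_GRID_PPM)
    return float(grid[np.argmin(spline(grid))])


def wassr_correct(zs: ZSpectrum) -> ZSpectrum:
    """Shift the offset axis so the spectral minimum sits at 0 ppm.

    The minimum is located on a 0.01-ppm cubic-spline grid.  The spectrum is
    then re-interpolated onto the original axis; points that fall outside the
    shifted support are clamped to the edge values.
    """
    offsets = zs.offsets_ppm
    order = np.argsort(offsets)
    off_s, z_s = offsets[order], zs.z[order]
    shift = _spline_minimum(z_s, off_s)
    i_min = int(np.argmin(z_s))
    if i_min in (0, len(z_s) - 1):
        warnings.warn("Z minimum at axis boundary; no B0 shift applied")
        return ZSpectrum(z=zs.z.copy(), offsets_ppm=offsets.copy())
    spline = CubicSpline(off_s - shift, z_s)
    z_new = spline(np.clip(off_s, off_s[0] - shift, off_s[-1] - shift))
    out = np.empty_like(z_new)
    out[order] = z_new
    return ZSpectrum(z=out, offsets_ppm=offsets.copy())


def mtr_asym(zs: ZSpectrum, range_ppm: tuple[float, float]) -> float:
    """Mean of Z(-dw) - Z(+dw) over ``range_ppm``, in percent."""
    lo, hi = range_ppm
    if not lo < hi:
        raise ValueError("range low must be < high")
    offsets = zs.offsets_ppm
    order = np.argsort(offsets)
    off_s, z_s = offsets[order], zs.z[order]
    if hi > off_s[-1] + 1e-9 or -hi < off_s[0] - 1e-9:
        raise ValueError("asymmetry range not covered by offset axis")
    grid = np.arange(lo, hi + _WASSR_GRID_PPM / 2, _WASSR_GRID_PPM)
    spline = CubicSpline(off_s, z_s)
    return float(np.mean(spline(-grid) - spline(grid)) * 100.0)


def mtr_asym_map(vol: CestVolume, range_ppm: tuple[float, float],
                 rois: list[np.ndarray] | None = None,
                 b0_correct: bool = True) -> MtrAsymMap:
    """Voxel-wise (optionally B0 self-corrected) MTR_asym with ROI stats."""
    mask = vol.mask if vol.mask.any() else default_mask(vol)
    values = np.zeros(vol.shape[:2])
    for iy, ix in zip(*np.nonzero(mask)):
        zs = ZSpectrum(z=vol.data[iy, ix], offsets_ppm=vol.offsets_ppm)
        if b0_correct:
            zs = wassr_correct(zs)
        values[iy, ix] = mtr_asym(zs, range_ppm)
    stats = []
    for i, roi in enumerate(rois or []):
        sel = roi & mask
        vals = values[sel]
        stats.append({"roi": i, "mean": float(vals.mean()),
                      "sd": float(vals.std()), "n": int(sel.sum())})
    return MtrAsymMap(values=values, range_ppm=tuple(range_ppm),
                      roi_stats=stats)
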