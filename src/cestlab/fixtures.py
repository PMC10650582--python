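"""Deterministic synthetic fixtures used across the test suite.

Every fixture is fully specified (no hidden randomness) and small enough
that the whole canonical set simulates in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bm_simulator import (CestVolume, SequenceParams, simulate_dataset,
                           symmetric_offsets)
from .noise import NoiseSpec, add_kspace_noise
from .phantom_geometry import (WATER_PROTON_MM, LabelMap, PhantomMaps,
                               PoolParams)

__all__ = ["FixtureSpec", "make_fixture", "ladder_rois", "CANONICAL"]

CANONICAL = ("water-only", "creatine-ladder", "rank1-spectral", "pure-noise")

#: Creatine-like ladder concentrations (mM) mirroring a 1:2:3:4 design.
LADDER_CONC_MM = (50.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class FixtureSpec:
    name: str = "water-only"
    grid: tuple[int, int] = (32, 32)
    dyn: int = 25
    sigma: float = 0.0
    seed: int = 0
    b1_uT: float = 1.0
    half_range_ppm: float = 4.0

    def sequence(self) -> SequenceParams:
        return SequenceParams(
            b1_uT=self.b1_uT, tp_ms=100.0, td_ms=100.0, n_pulses=10,
            offsets_ppm=symmetric_offsets(self.half_range_ppm, self.dyn))


def _water(t1_s: float = 1.5, t2_ms: float = 100.0) -> PoolParams:
    return PoolParams(t1_s=t1_s, t2_ms=t2_ms, delta_ppm=0.0, k_hz=0.0,
                      conc_mM=WATER_PROTON_MM)


def _creatine(conc_mM: float) -> PoolParams:
    return PoolParams(t1_s=1.2, t2_ms=10.0, delta_ppm=1.9, k_hz=200.0,
                      conc_mM=conc_mM)


def _ellipse_fg(grid: tuple[int, int]) -> np.ndarray:
    h, w = grid
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - h / 2) / (0.45 * h)) ** 2
            + ((xx - w / 2) / (0.45 * w)) ** 2) <= 1.0


def ladder_rois(grid: tuple[int, int]) -> list[np.ndarray]:
    """Four vertical-strip ROIs matching the ladder fixture regions."""
    fg = _ellipse_fg(grid)
    w = grid[1]
    rois = []
    for i in range(4):
        m = np.zeros(grid, dtype=bool)
        m[:, i * w // 4:(i + 1) * w // 4] = True
        rois.append(m & fg)
    return rois


def _ladder_phantom(grid: tuple[int, int]) -> PhantomMaps:
    fg = _ellipse_fg(grid)
    labels = np.zeros(grid, dtype=np.int32)
    w = grid[1]
    for i in range(4):
        labels[:, i * w // 4:(i + 1) * w // 4] = i + 1
    labels[~fg] = 0
    lm = LabelMap(labels=labels, foreground=fg)
    pools = {i + 1: [_water(), _creatine(conc)]
             for i, conc in enumerate(LADDER_CONC_MM)}
    pools[0] = [_water()]  # fg voxels carved away from strips by the ellipse
    return PhantomMaps(label_map=lm, region_pools=pools)


def make_fixture(spec: FixtureSpec,
                 ) -> tuple[CestVolume, CestVolume, PhantomMaps | None]:
    """Return (clean, noisy, truth) for one canonical fixture."""
    seq = spec.sequence()
    if spec.name == "water-only":
        fg = _ellipse_fg(spec.grid)
        lm = LabelMap(labels=np.zeros(spec.grid, dtype=np.int32),
                      foreground=fg)
        truth = PhantomMaps(label_map=lm, region_pools={0: [_water()]})
        clean = simulate_dataset(truth, seq, rng_seed=spec.seed)
    elif spec.name == "creatine-ladder":
        truth = _ladder_phantom(spec.grid)
        clean = simulate_dataset(truth, seq, rng_seed=spec.seed)
    elif spec.name == "rank1-spectral":
        # analytic rank-1 stack: one spectral profile scaled per voxel
        truth = None
        fg = _ellipse_fg(spec.grid)
        offsets = symmetric_offsets(spec.half_range_ppm, spec.dyn)
        profile = 1.0 - 0.6 * np.exp(-0.5 * (offsets / 1.2) ** 2)
        rng = np.random.default_rng(spec.seed)
        amp = np.where(fg, rng.uniform(0.7, 1.0, size=spec.grid), 0.0)
        clean = CestVolume(data=amp[:, :, None] * profile[None, None, :],
                           offsets_ppm=offsets, m0=amp, mask=fg,
                           meta={"fixture": spec.name})
    elif spec.name == "pure-noise":
        truth = None
        offsets = symmetric_offsets(spec.half_range_ppm, spec.dyn)
        fg = np.ones(spec.grid, dtype=bool)
        clean = CestVolume(data=np.zeros(spec.grid + (spec.dyn,)),
                           offsets_ppm=offsets,
                           m0=np.ones(spec.grid), mask=fg,
                           meta={"fixture": spec.name})
    else:
        raise ValueError(f"unknown fixture {spec.name!r}; "
                         f"choose from {CANONICAL}")
    sigma = spec.sigma if spec.name != "pure-noise" else max(spec.sigma, 0.1)
    noisy = add_kspace_noise(clean, NoiseSpec(sigma=sigma, seed=spec.seed))
    return clean, noisy, truth
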