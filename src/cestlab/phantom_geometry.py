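"""Randomized 2D phantom geometry: label maps and per-pool parameter maps.

A phantom is an ellipsoidal foreground populated by iteratively stamped
geometric primitives (ellipses, rectangles, convex polygons).  Each resulting
label region is assigned a number of exchange pools (2-5, water always
present) and one uniform draw of pool parameters per region, so regions are
internally homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as _sk_polygon
from skimage.morphology import disk

__all__ = [
    "LabelMap",
    "PoolParams",
    "Table1Ranges",
    "PhantomMaps",
    "WATER_PROTON_MM",
    "sample_label_map",
    "sample_pool_maps",
]

#: Proton concentration of pure water in mM (2 protons x 55.5 M).
WATER_PROTON_MM = 111_000.0

MAX_POOLS = 5
MIN_PRIMITIVE_PX = 4


@dataclass(frozen=True)
class PoolParams:
    """Relaxation / exchange description of a single proton pool."""

    t1_s: float
    t2_ms: float
    delta_ppm: float
    k_hz: float
    conc_mM: float

    def validate(self, water: bool = False) -> None:
        if self.t1_s <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if water:
            if self.delta_ppm != 0.0 or self.k_hz != 0.0:
                raise ValueError("water pool must have delta=0 and k=0")


@dataclass(frozen=True)
class Table1Ranges:
    """Uniform sampling intervals for phantom pool/sequence parameters.

    Defaults are the full simulation intervals; tests may narrow them.
    """

    water_t1_s: tuple[float, float] = (0.5, 2.5)
    water_t2_ms: tuple[float, float] = (40.0, 500.0)
    met_t1_s: tuple[float, float] = (0.5, 2.5)
    met_t2_ms: tuple[float, float] = (1.0, 20.0)
    met_k_hz: tuple[float, float] = (50.0, 4000.0)
    met_conc_mM: tuple[float, float] = (0.0, 800.0)
    met_delta_ppm: tuple[float, float] = (0.5, 5.0)
    n_pools: tuple[int, int] = (2, 5)

    def validate(self) -> None:
        bounds = {
            "water_t1_s": (0.5, 2.5),
            "water_t2_ms": (40.0, 500.0),
            "met_t1_s": (0.5, 2.5),
            "met_t2_ms": (1.0, 20.0),
            "met_k_hz": (50.0, 4000.0),
            "met_conc_mM": (0.0, 800.0),
            "met_delta_ppm": (0.5, 5.0),
        }
        for name, (lo, hi) in bounds.items():
            a, b = getattr(self, name)
            if not (lo <= a <= b <= hi):
                raise ValueError(f"{name}={a, b} outside allowed [{lo}, {hi}]")
        lo, hi = self.n_pools
        if not (2 <= lo <= hi <= MAX_POOLS):
            raise ValueError("n_pools must lie within [2, 5]")


@dataclass
class LabelMap:
    """Integer region map (0 = background) plus the ellipsoidal foreground."""

    labels: np.ndarray
    foreground: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.labels.shape != self.foreground.shape:
            raise ValueError("labels and foreground shapes differ")
        if (self.labels < 0).any():
            raise ValueError("labels must be nonnegative")
        if (self.labels[~self.foreground] != 0).any():
            raise ValueError("nonzero labels outside foreground")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_labels(self) -> np.ndarray:
        """Distinct labels on the foreground, including 0 for plain water."""
        return np.unique(self.labels[self.foreground])


@dataclass
class PhantomMaps:
    """Label map plus per-region pool assignments.

    ``region_pools`` maps each label present on the foreground (including 0,
    the unstamped water-only area) to its pool list; pool 0 is always water.
    Dense per-voxel grids are derived views used by downstream consumers.
    """

    label_map: LabelMap
    region_pools: dict[int, list[PoolParams]]
    seed: int | None = None

    def __post_init__(self) -> None:
        for lab, pools in self.region_pools.items():
            if not 1 <= len(pools) <= MAX_POOLS:
                raise ValueError(f"region {lab}: need 1-{MAX_POOLS} pools")
            pools[0].validate(water=True)

    @property
    def n_pools(self) -> np.ndarray:
        """Integer grid of pool counts (0 on background)."""
        out = np.zeros(self.label_map.shape, dtype=np.int32)
        for lab, pools in self.region_pools.items():
            out[(self.label_map.labels == lab) & self.label_map.foreground] = len(pools)
        return out

    def param_grid(self, pool: int, fld: str) -> np.ndarray:
        """Dense map of one PoolParams field for pool index ``pool`` (NaN where absent)."""
        out = np.full(self.label_map.shape, np.nan)
        for lab, pools in self.region_pools.items():
            if pool < len(pools):
                sel = (self.label_map.labels == lab) & self.label_map.foreground
                out[sel] = getattr(pools[pool], fld)
        return out


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / max(rx, 1e-9)
    v = (-x * st + y * ct) / max(ry, 1e-9)
    return u * u + v * v <= 1.0


def _stamp_primitive(rng: np.random.Generator, labels: np.ndarray,
                     fg: np.ndarray, value: int, max_size: float) -> None:
    h, w = labels.shape
    kind = rng.integers(0, 3)
    cy = rng.uniform(0.2 * h, 0.8 * h)
    cx = rng.uniform(0.2 * w, 0.8 * w)
    size = rng.uniform(MIN_PRIMITIVE_PX, max_size)
    if kind == 0:  # ellipse
        ry = size / 2 * rng.uniform(0.5, 1.0)
        rx = size / 2 * rng.uniform(0.5, 1.0)
        mask = _ellipse_mask(h, w, cy, cx, max(ry, 2), max(rx, 2),
                             rng.uniform(0, np.pi))
    elif kind == 1:  # axis-aligned rectangle
        hh = max(size * rng.uniform(0.5, 1.0) / 2, 2)
        hw = max(size * rng.uniform(0.5, 1.0) / 2, 2)
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (np.abs(yy - cy) <= hh) & (np.abs(xx - cx) <= hw)
    else:  # random convex polygon: hull of points on a jittered circle
        n_v = int(rng.integers(3, 8))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_v))
        rad = size / 2 * rng.uniform(0.5, 1.0, n_v)
        py = cy + rad * np.sin(ang)
        px = cx + rad * np.cos(ang)
        rr, cc = _sk_polygon(py, px, shape=labels.shape)
        mask = np.zeros_like(fg)
        mask[rr, cc] = True
    mask &= fg
    labels[mask] = value


def sample_label_map(rng_seed: int, grid: tuple[int, int],
                     n_layers: int) -> LabelMap:
    """Stamp ``n_layers`` random primitives inside an ellipsoidal foreground.

    Later primitives overwrite earlier ones (painter's algorithm).  The result
    is smoothed by binary closing per label and pruning of tiny fragments.
    Deterministic for a given ``rng_seed``.
    """
    h, w = grid
    if h < 16 or w < 16:
        raise ValueError("grid must be at least 16x16 to hold a primitive")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = np.random.default_rng(rng_seed)

    ry = rng.uniform(0.32, 0.45) * h
    rx = rng.uniform(0.32, 0.45) * w
    fg = _ellipse_mask(h, w, h / 2, w / 2, ry, rx, 0.0)

    labels = np.zeros((h, w), dtype=np.int32)
    max_size = max(h, w) / 3
    for i in range(n_layers):
        _stamp_primitive(rng, labels, fg, i + 1, max_size)

    # morphological optimisation: close each label, drop fragments < 16 px
    selem = disk(2)
    out = np.zeros_like(labels)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = ndi.binary_closing(labels == lab, structure=selem) & fg
        comp, n_comp = ndi.label(m)
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= 16)
        m = np.isin(comp, keep[keep > 0])
        out[m] = lab
    # renumber surviving labels densely
    survivors = np.unique(out[out > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[survivors] = np.arange(1, len(survivors) + 1, dtype=np.int32)
    return LabelMap(labels=remap[out], foreground=fg)


def _draw_pools(rng: np.random.Generator, ranges: Table1Ranges) -> list[PoolParams]:
    n = int(rng.integers(ranges.n_pools[0], ranges.n_pools[1] + 1))
    water = PoolParams(
        t1_s=rng.uniform(*ranges.water_t1_s),
        t2_ms=rng.uniform(*ranges.water_t2_ms),
        delta_ppm=0.0, k_hz=0.0, conc_mM=WATER_PROTON_MM,
    )
    pools = [water]
    for _ in range(n - 1):
        pools.append(PoolParams(
            t1_s=rng.uniform(*ranges.met_t1_s),
            t2_ms=rng.uniform(*ranges.met_t2_ms),
            delta_ppm=rng.uniform(*ranges.met_delta_ppm),
            k_hz=rng.uniform(*ranges.met_k_hz),
            conc_mM=rng.uniform(*ranges.met_conc_mM),
        ))
    return pools


def sample_pool_maps(label_map: LabelMap, ranges: Table1Ranges,
                     rng_seed: int) -> PhantomMaps:
    """Assign one (n_pools, parameters) draw per label region.

    Every foreground region — including the unstamped water-only remainder,
    label 0 — receives a water pool plus 1-4 metabolite pools drawn uniformly
    from ``ranges``.
    """
    ranges.validate()
    if not label_map.foreground.any():
        raise ValueError("empty foreground")
    rng = np.random.default_rng(rng_seed)
    region_pools = {int(lab): _draw_pools(rng, ranges)
                    for lab in label_map.region_labels()}
    return PhantomMaps(label_map=label_map, region_pools=region_pools,
                       seed=rng_seed)


def water_only_phantom(grid: tuple[int, int], t1_s: float = 1.5,
                       t2_ms: float = 100.0) -> PhantomMaps:
    """Uniform single-pool phantom on a centred ellipse (test helper)."""
    h, w = grid
    fg = _ellipse_mask(h, w, h / 2, w / 2, 0.4 * h, 0.4 * w, 0.0)
    lm = LabelMap(labels=np.zeros(grid, dtype=np.int32), foreground=fg)
    water = PoolParams(t1_s=t1_s, t2_ms=t2_ms, delta_ppm=0.0, k_hz=0.0,
                       conc_mM=WATER_PROTON_MM)
    return PhantomMaps(label_map=lm, region_pools={0: [water]})
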