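"""Synthetic porous geometries and time-lapse stacks with known ground truth.

The generator emulates the study system — a quasi-2D disordered porous
micromodel colonized by *E. coli* under constant flow — at the level the
downstream analysis needs: a percolating network of transmitting channels
(TPs) between solid grains, with cavity-like dead-end pores (DEPs) carved
into single grains (deeper than wide, so the inscribed-disk classification
labels them DEP), plus bright-field / reporter / tracer stacks rendered from
prescribed biomass dynamics.

Construction is explicit rather than emergent: grains are laid out on a
jittered lattice separated by channels of width equal to the target mean
pore size, and cavities are carved one by one until the requested DEP volume
fraction is met.  Every carved pixel, cluster centre, activation front and
imposed concentration ratio is recorded as ground truth, so each
quantification stage can be validated closed-loop.

Default physical scales follow the study conditions: 0.65 µm/pixel, mean
pore size 0.04 mm, mean DEP depth 0.2 mm, DEP volume fraction 8% of the
pore space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import DEP, TP, DepRegion, PoreLabelMap, PoreMask
from .stacks import ImageStack

__all__ = [
    "GeometryParams",
    "Cavity",
    "SceneTruth",
    "generate_geometry",
    "generate_biomass_stack",
    "generate_reporter_stack",
    "generate_tracer_stack",
    "three_phase_curve",
]

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class GeometryParams:
    """Parameters of the grain-lattice geometry generator.

    Lengths are physical: ``mean_pore_size`` and ``mean_dep_depth`` in mm,
    ``pixel_size`` in µm per pixel.  ``cavity_aspect`` is the depth/width
    ratio of the carved cavities and must exceed 1 so that they are deeper
    than wide and classify as dead-end pores.
    """

    domain_size_px: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65
    target_porosity: float = 0.30
    target_dep_fraction: float = 0.08
    mean_pore_size: float = 0.04
    mean_dep_depth: float = 0.2
    cavity_aspect: float = 5.0
    wall_px: int = 6
    jitter_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.domain_size_px) < 64:
            raise ValueError("domain must be at least 64 pixels on a side")
        if not 0 < self.target_porosity < 1:
            raise ValueError("target_porosity must lie in (0, 1)")
        if not 0 <= self.target_dep_fraction < 1:
            raise ValueError("target_dep_fraction must lie in [0, 1)")
        if self.cavity_aspect <= 1:
            raise ValueError("cavity_aspect must exceed 1 (deeper than wide)")
        if self.pixel_size <= 0 or self.mean_pore_size <= 0 or self.mean_dep_depth <= 0:
            raise ValueError("physical lengths must be positive")

    @property
    def channel_px(self) -> int:
        return max(4, round(self.mean_pore_size * 1000.0 / self.pixel_size))

    @property
    def dep_depth_px(self) -> int:
        return max(6, round(self.mean_dep_depth * 1000.0 / self.pixel_size))

    @property
    def cavity_width_px(self) -> int:
        return max(3, round(self.dep_depth_px / self.cavity_aspect))


@dataclass
class Cavity:
    """One carved dead-end cavity: mouth anchor, inward axis and extent."""

    dep_id: int
    side: str  # which grain side the mouth opens through: N/S/E/W
    mouth_rc: tuple[float, float]  # (row, col) of the mouth centre
    direction: tuple[int, int]  # unit step pointing into the cavity
    depth_px: float
    width_px: int
    pixels: tuple[np.ndarray, np.ndarray]

    def axial_depth_px(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Distance of pixels from the mouth line, measured along the axis."""
        dr, dc = self.direction
        return (rows - self.mouth_rc[0]) * dr + (cols - self.mouth_rc[1]) * dc


@dataclass
class SceneTruth:
    """Ground truth attached to a generated scene."""

    true_label_map: PoreLabelMap
    cavities: list[Cavity] = field(default_factory=list)
    porosity: float = 0.0
    dep_fraction: float = 0.0
    seed: int = 0
    noise_sigma: float = 0.0
    true_retention_curve: np.ndarray | None = None
    true_cluster_centers: list[tuple[float, float, float, float]] | None = None
    true_front_depth_mm: dict[int, float] | None = None
    deposits: np.ndarray | None = None  # clean (pre-noise) biomass signal
    saturated: bool = False


def _carve_cavity_pixels(
    side: str,
    grain: tuple[int, int, int, int],
    center: int,
    width: int,
    depth: float,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[float, float], tuple[int, int]]:
    """Pixel set of a rounded-end slot carved into a rectangular grain.

    ``grain`` is (r0, c0, height, width); ``center`` is the mouth-centre
    coordinate along the opened side; ``depth`` is measured from the grain
    edge inward.  Returns (pixels, mouth centre, inward direction).
    """
    r0, c0, gh, gw = grain
    half = width / 2.0
    if side in ("N", "S"):
        cols = np.arange(int(np.floor(center - half)) + 1, int(np.ceil(center + half)))
        if side == "N":
            rows = np.arange(r0, r0 + int(np.ceil(depth)))
            mouth = (r0 - 0.5, float(center))
            direction = (1, 0)
            axial = rows - r0 + 0.5
        else:
            rows = np.arange(r0 + gh - int(np.ceil(depth)), r0 + gh)
            mouth = (r0 + gh - 0.5, float(center))
            direction = (-1, 0)
            axial = (r0 + gh - 1) - rows + 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        ax = np.broadcast_to(axial[:, None], rr.shape)
        lat = np.abs(cc - center)
    else:
        rows = np.arange(int(np.floor(center - half)) + 1, int(np.ceil(center + half)))
        if side == "W":
            cols = np.arange(c0, c0 + int(np.ceil(depth)))
            mouth = (float(center), c0 - 0.5)
            direction = (0, 1)
            axial = cols - c0 + 0.5
        else:
            cols = np.arange(c0 + gw - int(np.ceil(depth)), c0 + gw)
            mouth = (float(center), c0 + gw - 0.5)
            direction = (0, -1)
            axial = (c0 + gw - 1) - cols + 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        ax = np.broadcast_to(axial[None, :], rr.shape)
        lat = np.abs(rr - center)
    # rectangular shaft with a semicircular far end
    shaft = ax <= depth - half
    cap = (~shaft) & (np.hypot(ax - (depth - half), lat) <= half)
    keep = (lat <= half) & (shaft | cap)
    return (rr[keep].ravel(), cc[keep].ravel()), mouth, direction


def _grain_lattice(params: GeometryParams, rng: np.random.Generator):
    """Jittered lattice of rectangular grains with channels and wall strips."""
    H, W = params.domain_size_px
    w_ch = params.channel_px
    depth = params.dep_depth_px
    phi = params.target_porosity
    s = np.sqrt(1.0 - phi)
    g_por = int(round(w_ch * s / (1.0 - s)))
    g = max(g_por, depth + 6)
    wall = params.wall_px

    usable_h = H - 2 * (wall + w_ch)
    usable_w = W - 2 * w_ch
    n_rows = (usable_h + w_ch) // (g + w_ch)
    n_cols = (usable_w + w_ch) // (g + w_ch)
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            "domain too small for one grain of size "
            f"{g}px plus channels; enlarge the domain or coarsen pixel_size"
        )
    # leftover space goes to the bottom wall and the inlet/outlet manifolds,
    # never to the channels: parallel channels of unequal width would carry
    # unequal speeds and artificially disperse any displacement front
    extra_rows = usable_h - (n_rows * (g + w_ch) - w_ch)
    extra_cols = usable_w - (n_cols * (g + w_ch) - w_ch)
    grains = []
    j = params.jitter_px
    for ir in range(n_rows):
        for ic in range(n_cols):
            r0 = wall + w_ch + ir * (g + w_ch)
            c0 = w_ch + extra_cols // 2 + ic * (g + w_ch)
            dr = int(rng.integers(-j, j + 1)) if j else 0
            dc = int(rng.integers(-j, j + 1)) if j else 0
            grains.append((r0 + dr, c0 + dc, g, g))
    return grains, g, wall, wall + extra_rows


def generate_geometry(params: GeometryParams) -> tuple[PoreMask, SceneTruth]:
    """Generate a percolating binary pore mask with carved dead-end cavities.

    Grains sit on a jittered lattice separated by channels of the target mean
    pore size; the top and bottom domain edges are sealed by solid wall
    strips, so the medium percolates left (inlet) to right (outlet).
    Cavities (rounded-end slots, depth/width = ``cavity_aspect``) are carved
    into randomly chosen grain sides until the DEP volume fraction reaches
    the target; the last cavity is shortened to land the fraction, never
    below a depth of 1.2 widths.  Identical parameters and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.domain_size_px
    grains, g, wall, wall_bottom = _grain_lattice(params, rng)

    solid = np.zeros((H, W), dtype=bool)
    solid[:wall, :] = True
    solid[H - wall_bottom :, :] = True
    for r0, c0, gh, gw in grains:
        solid[r0 : r0 + gh, c0 : c0 + gw] = True
    pore = ~solid

    p0 = int(pore.sum())
    f = params.target_dep_fraction
    need = int(round(f * p0 / (1.0 - f))) if f > 0 else 0

    w_c = params.cavity_width_px
    depth = float(params.dep_depth_px)
    # candidate sites: one per grain, random side and mouth position
    sides = ["N", "S", "E", "W"]
    order = rng.permutation(len(grains))
    cavities: list[Cavity] = []
    label = np.zeros((H, W), dtype=np.uint8)
    label[pore] = TP
    carved = 0
    margin = max(4, w_c // 2 + 2)
    for gi in order:
        if carved >= need:
            break
        grain = grains[gi]
        side = sides[int(rng.integers(0, 4))]
        span = grain[3] if side in ("N", "S") else grain[2]
        lo = (grain[1] if side in ("N", "S") else grain[0]) + margin
        hi = (grain[1] if side in ("N", "S") else grain[0]) + span - margin
        if hi <= lo:
            continue
        center = int(rng.integers(lo, hi + 1))
        d = depth
        remaining = need - carved
        approx_area = w_c * d - 0.11 * w_c**2
        if remaining < approx_area:
            d = max(1.2 * w_c, (remaining + 0.11 * w_c**2) / w_c)
            if d > depth:
                d = depth
        d = min(d, (grain[2] if side in ("N", "S") else grain[3]) - 4.0)
        if d < 1.2 * w_c:
            continue
        pix, mouth, direction = _carve_cavity_pixels(side, grain, center, w_c, d)
        if len(pix[0]) == 0:
            continue
        solid[pix] = False
        label[pix] = DEP
        carved += len(pix[0])
        cavities.append(
            Cavity(
                dep_id=len(cavities) + 1,
                side=side,
                mouth_rc=mouth,
                direction=direction,
                depth_px=d,
                width_px=w_c,
                pixels=pix,
            )
        )

    pore = ~solid
    achieved = carved / pore.sum() if pore.sum() else 0.0
    if f > 0 and abs(achieved - f) > 0.02:
        raise ValueError(
            f"infeasible target_dep_fraction {f}: achieved {achieved:.3f} "
            "with the available grain sites; enlarge the domain or lower the target"
        )

    # percolation check, inlet (left edge) to outlet (right edge)
    comp, _ = ndimage.label(pore, structure=_STRUCT4)
    left = set(np.unique(comp[:, 0])) - {0}
    right = set(np.unique(comp[:, -1])) - {0}
    if not (left & right):
        raise RuntimeError("generated geometry does not percolate inlet to outlet")

    mask = PoreMask(grid=pore, pixel_size=params.pixel_size)
    lmap = PoreLabelMap(grid=label, pixel_size=params.pixel_size)
    lmap.dep_regions = _truth_dep_regions(lmap, cavities)
    truth = SceneTruth(
        true_label_map=lmap,
        cavities=cavities,
        porosity=float(pore.mean()),
        dep_fraction=float(achieved),
        seed=params.seed,
    )
    return mask, truth


def _truth_dep_regions(lmap: PoreLabelMap, cavities: list[Cavity]) -> list[DepRegion]:
    tp_neighbors = ndimage.binary_dilation(lmap.grid == TP, structure=_STRUCT4)
    regions = []
    for cav in cavities:
        on_mouth = tp_neighbors[cav.pixels]
        regions.append(
            DepRegion(
                dep_id=cav.dep_id,
                pixel_index=cav.pixels,
                entrance_pixels=(cav.pixels[0][on_mouth], cav.pixels[1][on_mouth]),
                depth_mm=cav.depth_px * lmap.pixel_size / 1000.0,
                skeleton_points=np.array([], dtype=np.int64),
                entrance_point=-1,
                arc_length_px=np.array([]),
                area_px=int(len(cav.pixels[0])),
            )
        )
    return regions


def three_phase_curve(
    times: np.ndarray,
    t_attach: float,
    t_growth: float,
    level_attach: float = 1.0,
    level_plateau: float = 2.5,
    level_final: float = 2.5,
) -> np.ndarray:
    """Piecewise-linear three-phase dynamic: attachment, differentiation, growth.

    Mirrors the phenomenology of colonization time series: an early rise
    during single-cell accumulation (up to ``t_attach``), a plateau during
    differentiation into sessile colonies (to ``t_growth``), then a late
    change during colony growth.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= t_attach:
            out[i] = level_attach * (t / t_attach) if t_attach > 0 else level_attach
        elif t <= t_growth:
            w = (t - t_attach) / (t_growth - t_attach)
            out[i] = level_attach + w * (level_plateau - level_attach)
        else:
            out[i] = level_plateau + (t - t_growth) / max(t_growth, 1.0) * (
                level_final - level_plateau
            )
    return out


def _place_discs(
    region: np.ndarray,
    n: int,
    radius: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Centres of ``n`` non-overlapping discs fully inside ``region``."""
    dist = ndimage.distance_transform_edt(region)
    candidates = np.argwhere(dist >= radius + 1)
    if len(candidates) == 0:
        return []
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n and tries < 200 * n:
        tries += 1
        r, c = candidates[rng.integers(0, len(candidates))]
        if all(np.hypot(r - r0, c - c0) > 2 * radius + 2 for r0, c0 in centers):
            centers.append((int(r), int(c)))
    return centers


def generate_biomass_stack(
    label_map: PoreLabelMap,
    times: Sequence[float],
    ratio_curve: Sequence[float],
    tp_mean: float | Sequence[float] = 3000.0,
    mode: str = "uniform",
    n_spots_per_dep: int = 0,
    n_spots_tp: int = 0,
    spot_radius_px: int = 4,
    noise_sigma: float = 0.0,
    background: float = 30000.0,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Render a bright-field stack whose DEP:TP concentration ratio is known.

    Biomass appears as additive attenuation of a constant bright background.
    Per frame t ≥ 1 the deposited signal has area-normalized mean ``tp_mean``
    in the TP class and ``ratio_curve[t] × tp_mean`` in the DEP class, either
    spread uniformly or concentrated in equal-intensity discs ("colonies")
    whose centres and integrated masses are recorded as truth.  Frame 0 is
    the pre-injection background.  Noise is Gaussian read noise seeded
    independently of the geometry.
    """
    times = np.asarray(times, dtype=float)
    ratio = np.asarray(ratio_curve, dtype=float)
    if len(ratio) != len(times):
        raise ValueError("ratio_curve must be defined on the frame times")
    if np.any(ratio < 0):
        raise ValueError("concentration ratios must be non-negative")
    tp_levels = np.broadcast_to(np.asarray(tp_mean, dtype=float), times.shape)
    rng = np.random.default_rng(seed)

    grid = label_map.grid
    tp_mask = grid == TP
    dep_mask = grid == DEP
    n_tp = int(tp_mask.sum())
    T = len(times)
    H, W = grid.shape
    deposits = np.zeros((T, H, W), dtype=np.float64)
    centers_truth: list[tuple[float, float, float, float]] = []
    saturated = False

    spot_supports: list[tuple[np.ndarray, np.ndarray, str, int]] = []
    if mode == "colonies":
        for reg in label_map.dep_regions:
            reg_mask = np.zeros_like(grid, dtype=bool)
            reg_mask[reg.pixel_index] = True
            for r, c in _place_discs(reg_mask, n_spots_per_dep, spot_radius_px, rng):
                yy, xx = np.mgrid[
                    max(0, r - spot_radius_px) : min(H, r + spot_radius_px + 1),
                    max(0, c - spot_radius_px) : min(W, c + spot_radius_px + 1),
                ]
                keep = (np.hypot(yy - r, xx - c) <= spot_radius_px) & reg_mask[yy, xx]
                spot_supports.append((yy[keep], xx[keep], "dep", reg.dep_id))
        if n_spots_tp:
            for r, c in _place_discs(tp_mask, n_spots_tp, spot_radius_px, rng):
                yy, xx = np.mgrid[
                    max(0, r - spot_radius_px) : min(H, r + spot_radius_px + 1),
                    max(0, c - spot_radius_px) : min(W, c + spot_radius_px + 1),
                ]
                keep = (np.hypot(yy - r, xx - c) <= spot_radius_px) & tp_mask[yy, xx]
                spot_supports.append((yy[keep], xx[keep], "tp", 0))
    elif mode != "uniform":
        raise ValueError("mode must be 'uniform' or 'colonies'")

    n_dep = int(dep_mask.sum())
    for t in range(1, T):
        m_tp = tp_levels[t]
        m_dep = ratio[t] * m_tp
        if mode == "uniform":
            deposits[t][tp_mask] = m_tp
            deposits[t][dep_mask] = m_dep
        else:
            dep_area = sum(len(s[0]) for s in spot_supports if s[2] == "dep")
            tp_area = sum(len(s[0]) for s in spot_supports if s[2] == "tp")
            amp_dep = m_dep * n_dep / dep_area if dep_area else 0.0
            amp_tp = m_tp * n_tp / tp_area if tp_area else 0.0
            for yy, xx, cls, _dep_id in spot_supports:
                amp = amp_dep if cls == "dep" else amp_tp
                deposits[t][yy, xx] = amp
                cy, cx = float(yy.mean()), float(xx.mean())
                centers_truth.append((cx, cy, times[t], amp * len(yy)))
        if np.any(deposits[t] > background):
            saturated = True

    frames = np.empty((T, H, W), dtype=np.uint16)
    for t in range(T):
        img = background - deposits[t]
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0, 65535).astype(np.uint16)
    if saturated:
        warnings.warn("requested biomass exceeds the background level; clipped")

    stack = ImageStack(
        frames=frames, times=times, channel="brightfield", pixel_size=label_map.pixel_size
    )
    truth = SceneTruth(
        true_label_map=label_map,
        true_retention_curve=ratio.copy(),
        true_cluster_centers=centers_truth or None,
        noise_sigma=noise_sigma,
        seed=seed,
        deposits=deposits,
        saturated=saturated,
    )
    return stack, truth


def generate_reporter_stack(
    label_map: PoreLabelMap,
    biomass_stack: ImageStack,
    biomass_truth: SceneTruth,
    cavities: list[Cavity],
    front_depth_mm: float | dict[int, float],
    steepness_um: float = 5.0,
    noise_sigma: float = 0.0,
    background: float = 100.0,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Render a GFP reporter stack as biomass × sigmoidal depth activation.

    Activation along each cavity axis is ``1/(1 + exp(-(s - s_front)/k))``
    with ``s`` the depth from the DEP entrance: low near the entrance, high
    deeper than the prescribed front.  Transmitting-pore biomass carries the
    entrance-level (s = 0) activation.  Frame 0 is background only.
    """
    if biomass_truth.deposits is None:
        raise ValueError("biomass truth must carry the clean deposit stack")
    deposits = biomass_truth.deposits
    T, H, W = deposits.shape
    px = label_map.pixel_size
    rng = np.random.default_rng(seed)
    if not isinstance(front_depth_mm, dict):
        # a scalar front applies to every DEP, capped at each cavity's depth
        front_depth_mm = {
            cav.dep_id: min(
                float(front_depth_mm), cav.depth_px * label_map.pixel_size / 1000.0
            )
            for cav in cavities
        }

    activation = np.zeros((H, W), dtype=np.float64)
    fronts: dict[int, float] = {}
    k = steepness_um / px  # sigmoid width in px
    for cav in cavities:
        front = front_depth_mm.get(cav.dep_id)
        if front is None:
            continue
        if front > cav.depth_px * px / 1000.0 + 1e-9:
            raise ValueError(
                f"front depth {front} mm exceeds DEP {cav.dep_id} depth"
            )
        fronts[cav.dep_id] = front
        s = cav.axial_depth_px(cav.pixels[0].astype(float), cav.pixels[1].astype(float))
        s_front = front * 1000.0 / px
        activation[cav.pixels] = 1.0 / (1.0 + np.exp(-(s - s_front) / k))
    # TP biomass sits at the entrance level of activation
    mean_front_px = (
        np.mean([f * 1000.0 / px for f in fronts.values()]) if fronts else 0.0
    )
    tp_act = 1.0 / (1.0 + np.exp(mean_front_px / k))
    activation[label_map.grid == TP] = tp_act

    frames = np.empty((T, H, W), dtype=np.uint16)
    for t in range(T):
        img = background + deposits[t] * activation
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0, 65535).astype(np.uint16)

    stack = ImageStack(
        frames=frames,
        times=biomass_stack.times,
        channel="gfp",
        pixel_size=px,
    )
    truth = SceneTruth(
        true_label_map=label_map,
        cavities=cavities,
        true_front_depth_mm=fronts,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return stack, truth


def generate_tracer_stack(
    mask: PoreMask,
    velocity,
    D: float,
    save_times: Sequence[float],
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[ImageStack, "object"]:
    """Render a dye-displacement experiment as a 16-bit fluorescence stack.

    The pore space starts saturated with dye (c = 1) and is displaced by
    clean fluid entering at the inlet (c = 0); concentrations come from the
    advection–diffusion solver and are rendered at full scale 65535 = c 1.
    """
    from .transport import simulate_tracer

    series = simulate_tracer(
        mask, velocity, D=D, save_times=np.asarray(save_times, dtype=float),
        init=1.0, inlet_value=0.0,
    )
    rng = np.random.default_rng(seed)
    frames = []
    for c in series.concentrations:
        img = c * 65535.0
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames.append(np.clip(img, 0, 65535).astype(np.uint16))
    stack = ImageStack(
        frames=np.stack(frames),
        times=series.times,
        channel="tracer",
        pixel_size=mask.pixel_size,
    )
    return stack, series
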