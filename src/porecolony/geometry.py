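"""Geometric discretization of a binary pore mask.

A 2D porous medium is represented as a binary mask (pore = 1, solid = 0).
The pore space is split into two functional classes:

* transmitting pores (TP) — percolating channels that carry advective flow,
* dead-end pores (DEP) — cavity-like regions connected to the flow network
  through a single entrance, where transport is essentially diffusive.

The classification follows the maximum-inscribed-disk construction: at every
point of the pore-space skeleton the largest disk fitting in the pore space
is found, and a segregation index ``zeta_seg`` counts how many distinct solid
grains that disk touches.  A disk lodged in a cavity carved into a single
grain touches only that grain (``zeta_seg == 1``, DEP); a disk in a channel
between grains touches at least two (``zeta_seg > 1``, TP).  Every pore pixel
then inherits the label of its nearest skeleton point.

Conventions: 0-based row-major coordinates with the origin at the top-left;
solid phase 8-connected, pore phase 4-connected; lengths are converted to
micrometres / millimetres through ``pixel_size`` (µm per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.morphology import medial_axis

__all__ = [
    "SOLID",
    "DEP",
    "TP",
    "PoreMask",
    "GrainLabelMap",
    "DiskMap",
    "Skeleton",
    "DepRegion",
    "PoreLabelMap",
    "PoreStats",
    "label_grains",
    "max_inscribed_disk_map",
    "skeletonize_pores",
    "segregation_index",
    "classify_pores",
    "pore_stats",
    "discretize",
]

# label palette of the mapped mask
SOLID, DEP, TP = 0, 1, 2

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class PoreMask:
    """Binary pore geometry (pore = 1 / solid = 0) with physical pixel size."""

    grid: np.ndarray
    pixel_size: float  # µm per pixel

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("pore mask must be a 2D array")
        self.grid = grid.astype(bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def porosity(self) -> float:
        return float(self.grid.mean())


@dataclass
class GrainLabelMap:
    """Connected components of the solid phase; 0 = pore, 1..n_grains = grain id."""

    grid: np.ndarray
    n_grains: int


@dataclass
class DiskMap:
    """Radius of the maximum inscribed disk centred at each pore pixel.

    ``radius_px`` is the Euclidean distance (in pixels) from the pixel centre
    to the nearest solid pixel centre; zero on solid pixels.
    """

    radius_px: np.ndarray
    pixel_size: float

    @property
    def radius_um(self) -> np.ndarray:
        return self.radius_px * self.pixel_size


@dataclass
class Skeleton:
    """1-pixel-wide medial representation of the pore space.

    Points are stored as an ``(n, 2)`` array of (row, col) indices; per-point
    annotations (inscribed radius, segregation index) are parallel arrays.
    ``index_map`` maps a pixel back to its point index (-1 off-skeleton).
    """

    coords: np.ndarray
    radius_px: np.ndarray
    pixel_size: float
    zeta_seg: np.ndarray | None = None
    contact_spread_deg: np.ndarray | None = None
    boundary_flag: np.ndarray | None = None
    index_map: np.ndarray = field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def radius_um(self) -> np.ndarray:
        return self.radius_px * self.pixel_size

    def graph(self):
        """Sparse 8-adjacency graph of skeleton pixels, edge weights in pixels."""
        return _skeleton_graph(self.coords, self.index_map)


def _skeleton_graph(coords: np.ndarray, index_map: np.ndarray):
    rows, cols = [], []
    data = []
    n = len(coords)
    h, w = index_map.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    r, c = coords[:, 0], coords[:, 1]
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        nb = np.full(n, -1, dtype=np.int64)
        nb[ok] = index_map[rr[ok], cc[ok]]
        src = np.nonzero(nb >= 0)[0]
        rows.append(src)
        cols.append(nb[src])
        data.append(np.full(len(src), np.hypot(dr, dc)))
    if not rows:
        return coo_matrix((n, n)).tocsr()
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


@dataclass
class DepRegion:
    """A single dead-end pore: pixels, entrance, depth and skeleton support."""

    dep_id: int
    pixel_index: tuple[np.ndarray, np.ndarray]
    entrance_pixels: tuple[np.ndarray, np.ndarray]
    depth_mm: float
    skeleton_points: np.ndarray  # indices into the Skeleton arrays
    entrance_point: int  # skeleton point index at the DEP–TP juncture (-1 if none)
    arc_length_px: np.ndarray  # per skeleton point, from the entrance
    area_px: int
    unreachable: bool = False


@dataclass
class PoreLabelMap:
    """The mapped mask: 0 = solid/grain, 1 = DEP, 2 = TP, plus per-DEP records."""

    grid: np.ndarray
    pixel_size: float
    dep_regions: list[DepRegion] = field(default_factory=list)

    @property
    def dep_mask(self) -> np.ndarray:
        return self.grid == DEP

    @property
    def tp_mask(self) -> np.ndarray:
        return self.grid == TP

    @property
    def pore_mask(self) -> np.ndarray:
        return self.grid != SOLID

    @property
    def dep_volume_fraction(self) -> float:
        pore = int(np.count_nonzero(self.grid != SOLID))
        if pore == 0:
            return 0.0
        return float(np.count_nonzero(self.grid == DEP)) / pore


@dataclass
class PoreStats:
    lambda_values: np.ndarray  # local pore size λ = 2·r along the skeleton, µm
    lambda_m: float  # mean pore size, µm
    dep_volume_fraction: float
    dep_depths_mm: np.ndarray
    porosity: float


def _validate_mask(mask: PoreMask) -> np.ndarray:
    grid = mask.grid
    if not grid.any():
        raise ValueError("degenerate mask: no pore pixels")
    if grid.all():
        raise ValueError("degenerate mask: no solid pixels")
    return grid


def label_grains(mask: PoreMask) -> GrainLabelMap:
    """Label maximal 8-connected components of the solid phase."""
    grid = _validate_mask(mask)
    labels, n = ndimage.label(~grid, structure=_STRUCT8)
    return GrainLabelMap(grid=labels, n_grains=int(n))


def max_inscribed_disk_map(mask: PoreMask) -> DiskMap:
    """Per-pixel maximum inscribed disk radius (exact Euclidean distance)."""
    grid = _validate_mask(mask)
    dist = ndimage.distance_transform_edt(grid)
    return DiskMap(radius_px=dist, pixel_size=mask.pixel_size)


def skeletonize_pores(mask: PoreMask, disks: DiskMap | None = None) -> Skeleton:
    """Topology-preserving 1-pixel skeleton annotated with inscribed radii.

    Uses the medial axis (ridge of the distance transform), whose points are
    genuine centres of maximal inscribed disks — the property the
    segregation index relies on; plain iterative thinning can leave branch
    pixels that hug one wall in wide junctions.
    """
    grid = _validate_mask(mask)
    if disks is None:
        disks = max_inscribed_disk_map(mask)
    # fixed rng: medial_axis breaks thinning-order ties pseudo-randomly, and
    # the skeleton must be reproducible run to run
    skel = medial_axis(grid, rng=0)
    coords = np.argwhere(skel)
    index_map = np.full(grid.shape, -1, dtype=np.int64)
    index_map[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    radius = disks.radius_px[coords[:, 0], coords[:, 1]]
    return Skeleton(
        coords=coords,
        radius_px=radius,
        pixel_size=mask.pixel_size,
        index_map=index_map,
    )


def segregation_index(
    skeleton: Skeleton,
    disks: DiskMap,
    grains: GrainLabelMap,
    band_px: float = 2.5,
) -> Skeleton:
    """Annotate each skeleton point with the number of grains its disk touches.

    The maximal inscribed disk at a skeleton point has radius r; solid pixels
    whose centre lies within ``band_px`` of the disk boundary (|d − r| ≤ band)
    form the tangency band, and ``zeta_seg`` is the number of distinct grain
    ids found there.  ``zeta_seg == 1`` marks dead-end cavities carved into a
    single grain; ``zeta_seg > 1`` marks channels between grains.

    Counting grains alone is not enough on a raster grid: a disk sitting in
    an open junction just outside a cavity mouth touches only the two mouth
    corners — one grain, but only two contact points.  The defining property
    of a dead-end cavity is tangency in at least three points of one grain,
    which is captured by the angular spread of the contact set around the
    disk: inside a slot the contacts sit on opposing walls (spread ≥ 180°),
    outside the mouth they cluster in front of the disk.  The spread is
    stored per point (``contact_spread_deg``) and used by
    :func:`classify_pores` to accept ζ = 1 points as DEP seeds.

    Open domain edges (the crop boundary at inlet/outlet) count as one extra
    pseudo-grain: the pore continues past the crop, so a disk clipped by the
    edge is never lodged in a single-grain cavity.  Such points are flagged.
    """
    glab = grains.grid
    h, w = glab.shape
    n = skeleton.n_points
    zeta = np.ones(n, dtype=np.int32)
    spread = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        r0, c0 = skeleton.coords[i]
        r = skeleton.radius_px[i]
        reach = int(np.ceil(r + band_px)) + 1
        r1, r2 = max(0, r0 - reach), min(h, r0 + reach + 1)
        c1, c2 = max(0, c0 - reach), min(w, c0 + reach + 1)
        sub = glab[r1:r2, c1:c2]
        yy, xx = np.mgrid[r1:r2, c1:c2]
        d = np.hypot(yy - r0, xx - c0)
        in_band = (np.abs(d - r) <= band_px) & (sub > 0)
        ids = np.unique(sub[in_band])
        count = int(ids.size)
        if in_band.any():
            ang = np.sort(np.arctan2(yy[in_band] - r0, xx[in_band] - c0))
            gaps = np.diff(np.concatenate([ang, ang[:1] + 2 * np.pi]))
            spread[i] = np.degrees(2 * np.pi - gaps.max())
        # an open domain edge inside the tangency band acts as one extra
        # "grain": the pore continues past the crop
        edge_dist = min(r0, c0, h - 1 - r0, w - 1 - c0)
        if edge_dist <= r + band_px:
            count += 1
            flagged[i] = True
        if count == 0:
            flagged[i] = True
            count = 1
        zeta[i] = count
    skeleton.zeta_seg = zeta
    skeleton.contact_spread_deg = spread
    skeleton.boundary_flag = flagged
    return skeleton


def classify_pores(
    skeleton: Skeleton,
    grains: GrainLabelMap,
    mask: PoreMask,
    min_spread_deg: float = 160.0,
) -> PoreLabelMap:
    """Build the mapped mask {0 solid, 1 DEP, 2 TP} from an annotated skeleton.

    Skeleton points lodged in a single grain (``zeta_seg == 1`` with contact
    spread ≥ ``min_spread_deg``, the three-point tangency condition) seed DEP
    regions; all other points seed TP regions.  Pixels are assigned by the
    maximal-disk covering rule: a pore pixel covered by the inscribed disk of
    any TP point is TP; otherwise, if covered by a DEP-point disk, it is DEP
    (TP wins overlaps, keeping DEP entrances conservative).  The few raster
    pixels covered by no maximal disk fall back to the nearest seed, ties to
    TP.  Pore components containing no TP-seeding point (isolated cavities)
    are labelled DEP and flagged unreachable.
    """
    if skeleton.zeta_seg is None:
        raise ValueError("skeleton must be annotated with segregation_index first")
    grid = mask.grid
    labels = np.zeros(grid.shape, dtype=np.uint8)

    is_dep_seed = (skeleton.zeta_seg == 1) & (
        skeleton.contact_spread_deg >= min_spread_deg
    )
    dep_pts = skeleton.coords[is_dep_seed]
    tp_pts = skeleton.coords[~is_dep_seed]
    pore_idx = np.argwhere(grid)
    if len(tp_pts) == 0:
        labels[grid] = DEP
    elif len(dep_pts) == 0:
        labels[grid] = TP
    else:
        h, w = grid.shape
        cover_tol = 0.5

        def paint(points, radii):
            covered = np.zeros(grid.shape, dtype=bool)
            for (r0, c0), r in zip(points, radii):
                reach = int(np.ceil(r + cover_tol))
                r1, r2 = max(0, r0 - reach), min(h, r0 + reach + 1)
                c1, c2 = max(0, c0 - reach), min(w, c0 + reach + 1)
                yy, xx = np.ogrid[r1:r2, c1:c2]
                covered[r1:r2, c1:c2] |= (
                    np.hypot(yy - r0, xx - c0) <= r + cover_tol
                )
            return covered

        cov_tp = paint(tp_pts, skeleton.radius_px[~is_dep_seed])
        cov_dep = paint(dep_pts, skeleton.radius_px[is_dep_seed])
        labels[grid & cov_tp] = TP
        labels[grid & cov_dep & ~cov_tp] = DEP
        orphan = grid & ~cov_tp & ~cov_dep
        if orphan.any():
            oidx = np.argwhere(orphan)
            d_tp, _ = cKDTree(tp_pts).query(oidx, workers=-1)
            d_dep, _ = cKDTree(dep_pts).query(oidx, workers=-1)
            lab = np.where(d_tp <= d_dep, TP, DEP).astype(np.uint8)
            labels[oidx[:, 0], oidx[:, 1]] = lab

    # pore components never visited by a transmitting skeleton point are
    # isolated cavities: label them DEP wholesale
    unreachable_comps: set[int] = set()
    comp, n_comp = ndimage.label(grid, structure=_STRUCT4)
    if len(tp_pts):
        tp_comps = set(comp[tp_pts[:, 0], tp_pts[:, 1]].tolist())
    else:
        tp_comps = set()
    for k in range(1, n_comp + 1):
        if k not in tp_comps:
            labels[comp == k] = DEP
            unreachable_comps.add(k)

    lmap = PoreLabelMap(grid=labels, pixel_size=mask.pixel_size)
    lmap.dep_regions = _extract_dep_regions(lmap, skeleton, comp, unreachable_comps)
    return lmap


def _extract_dep_regions(
    lmap: PoreLabelMap,
    skeleton: Skeleton,
    pore_comp: np.ndarray,
    unreachable_comps: set[int],
) -> list[DepRegion]:
    dep = lmap.grid == DEP
    if not dep.any():
        return []
    tp = lmap.grid == TP
    dep_lab, n_dep = ndimage.label(dep, structure=_STRUCT4)
    # entrance pixels: DEP pixels 4-adjacent to a TP pixel
    tp_neighbors = ndimage.binary_dilation(tp, structure=_STRUCT4)
    entrance_all = dep & tp_neighbors

    pt_region = dep_lab[skeleton.coords[:, 0], skeleton.coords[:, 1]]
    pt_label = lmap.grid[skeleton.coords[:, 0], skeleton.coords[:, 1]]
    graph = skeleton.graph()
    px = skeleton.pixel_size

    regions: list[DepRegion] = []
    for k in range(1, n_dep + 1):
        pix = np.nonzero(dep_lab == k)
        ent = np.nonzero((dep_lab == k) & entrance_all)
        pts = np.nonzero(pt_region == k)[0]
        unreachable = bool(
            len(pix[0]) and pore_comp[pix[0][0], pix[1][0]] in unreachable_comps
        )
        entrance_point = -1
        arc = np.zeros(len(pts))
        depth_mm = 0.0
        if len(pts):
            # entrance skeleton point: a point of this region whose skeleton
            # neighbour is labelled TP (the DEP–TP juncture)
            sub = graph[pts]
            cand = []
            for row_i, p in enumerate(pts):
                nbrs = sub.indices[sub.indptr[row_i] : sub.indptr[row_i + 1]]
                if np.any(pt_label[nbrs] == TP):
                    cand.append(p)
            if cand:
                sources = np.array(cand)
            elif len(ent[0]):
                # no skeleton juncture (short spur): anchor at the point
                # closest to the entrance pixel centroid
                cy, cx = ent[0].mean(), ent[1].mean()
                d = np.hypot(
                    skeleton.coords[pts, 0] - cy, skeleton.coords[pts, 1] - cx
                )
                sources = np.array([pts[int(np.argmin(d))]])
            else:
                sources = pts[:1]
            entrance_point = int(sources[0])
            dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
            arc = dist[pts]
            finite = arc[np.isfinite(arc)]
            depth_mm = float(finite.max()) * px / 1000.0 if len(finite) else 0.0
        elif len(pix[0]):
            # DEP thinner than the skeleton support: use pixel extent
            ext = max(len(np.unique(pix[0])), len(np.unique(pix[1])))
            depth_mm = ext * px / 1000.0
        regions.append(
            DepRegion(
                dep_id=k,
                pixel_index=pix,
                entrance_pixels=ent,
                depth_mm=depth_mm,
                skeleton_points=pts,
                entrance_point=entrance_point,
                arc_length_px=arc,
                area_px=int(len(pix[0])),
                unreachable=unreachable,
            )
        )
    return regions


def pore_stats(
    label_map: PoreLabelMap,
    skeleton: Skeleton,
    disks: DiskMap,
) -> PoreStats:
    """Pore-size distribution, DEP volume fraction and per-DEP depths.

    The local pore size λ is twice the inscribed-disk radius, sampled at every
    skeleton point; the DEP volume fraction is the pixel-count share of the
    DEP class within the pore space.
    """
    lam = 2.0 * skeleton.radius_um
    depths = np.array([r.depth_mm for r in label_map.dep_regions])
    return PoreStats(
        lambda_values=lam,
        lambda_m=float(lam.mean()) if len(lam) else 0.0,
        dep_volume_fraction=label_map.dep_volume_fraction,
        dep_depths_mm=depths,
        porosity=float(label_map.pore_mask.mean()),
    )


def discretize(mask: PoreMask, band_px: float = 2.5) -> tuple[PoreLabelMap, Skeleton, DiskMap, GrainLabelMap]:
    """Full discretization chain: grains → disks → skeleton → ζ → mapped mask."""
    grains = label_grains(mask)
    disks = max_inscribed_disk_map(mask)
    skel = skeletonize_pores(mask, disks)
    skel = segregation_index(skel, disks, grains, band_px=band_px)
    lmap = classify_pores(skel, grains, mask)
    return lmap, skel, disks, grains
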