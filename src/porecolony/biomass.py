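"""Biomass quantification from time-lapse stacks.

The bright-field signal of accumulating biomass is an attenuation of the
bright background: quantification therefore starts by subtracting the
pre-injection frame (frame 0), flipping sign for bright-field so that
intensity increases with biomass, clipping negatives and masking the solid
phase.  From corrected stacks the module measures

* per-colony statistics — clusters of biomass found by thresholding at the
  mean of the regional maximum intensities, each dead-end pore processed
  independently, the transmitting network as one region;
* the retention curve C_dep/C_tp — the ratio of area-normalized mean
  intensities between the two pore classes, the study's macroscopic
  colonization observable;
* class-resolved biomass time series B_tp, B_dep, B_tot and the DEP
  partition B_dep/B_tot.

Intensities are instrument-relative (arbitrary units); every ratio and
partition is invariant to the overall intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.morphology import local_maxima

from .geometry import DEP, TP, PoreLabelMap
from .stacks import ImageStack

__all__ = [
    "ClusterSet",
    "preprocess_stack",
    "detect_clusters",
    "detect_clusters_stack",
    "colony_mass_pdf",
    "retention_curve",
    "biomass_timeseries",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ClusterSet:
    """Detected biomass clusters of one frame/region.

    ``table`` has one row per cluster: area (px and µm²), integrated
    intensity, mass_per_area, centroid, host region; ``pixel_sets`` holds
    the pixel index arrays in matching order.
    """

    table: pd.DataFrame
    pixel_sets: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    threshold: float = np.nan

    def __len__(self) -> int:
        return len(self.table)


def preprocess_stack(stack: ImageStack, label_map: PoreLabelMap) -> ImageStack:
    """Background-subtract, sign-convert and pore-mask a raw stack.

    Frame 0 is the pre-injection background.  For bright field the corrected
    intensity is background − frame (cells darken the image); fluorescence
    channels use frame − background.  Negatives are clipped to zero (the
    signal is a mass) and solid pixels zeroed exactly.
    """
    if stack.frames.shape[1:] != label_map.grid.shape:
        raise ValueError(
            f"stack frames {stack.frames.shape[1:]} do not match the "
            f"label map {label_map.grid.shape}; register the stack first"
        )
    bg = stack.frames[0].astype(np.float64)
    pore = label_map.pore_mask
    corrected = np.empty(stack.frames.shape, dtype=np.float64)
    for i, frame in enumerate(stack.frames):
        f = frame.astype(np.float64)
        diff = bg - f if stack.channel == "brightfield" else f - bg
        np.clip(diff, 0.0, None, out=diff)
        diff[~pore] = 0.0
        corrected[i] = diff
    return ImageStack(
        frames=corrected,
        times=stack.times,
        channel=stack.channel,
        pixel_size=stack.pixel_size,
    )


def detect_clusters(
    frame: np.ndarray,
    region: np.ndarray,
    pixel_size: float = 1.0,
    host: str = "tp",
    smooth_px: int = 3,
    threshold_multiplier: float = 1.0,
) -> ClusterSet:
    """Detect biomass clusters in one region of a corrected frame.

    The threshold is ``threshold_multiplier`` × the mean intensity of the
    regional maxima (8-connected local maxima of the median-smoothed frame
    restricted to the region); clusters are the 8-connected components of
    raw pixels at or above the threshold inside the region.  A region with
    no positive maxima yields an empty set.
    """
    if not region.any():
        raise ValueError("region must contain at least one pixel")
    work = np.where(region, frame, 0.0)
    if smooth_px > 1:
        footprint = np.ones((smooth_px, smooth_px), dtype=bool)
        smoothed = median_filter(work, footprint=footprint)
    else:
        smoothed = work
    maxima = local_maxima(smoothed, connectivity=2) & region & (smoothed > 0)
    empty = ClusterSet(
        table=pd.DataFrame(
            columns=[
                "area_px",
                "area_um2",
                "integrated_intensity",
                "mass_per_area",
                "centroid_row",
                "centroid_col",
                "host",
            ]
        )
    )
    if not maxima.any():
        return empty
    threshold = threshold_multiplier * float(smoothed[maxima].mean())
    above = region & (frame >= threshold) & (frame > 0)
    lab, n = ndimage.label(above, structure=_STRUCT8)
    rows = []
    pixel_sets = []
    for k in range(1, n + 1):
        pix = np.nonzero(lab == k)
        intens = frame[pix]
        area = len(pix[0])
        rows.append(
            {
                "area_px": area,
                "area_um2": area * pixel_size**2,
                "integrated_intensity": float(intens.sum()),
                "mass_per_area": float(intens.sum()) / area,
                "centroid_row": float(pix[0].mean()),
                "centroid_col": float(pix[1].mean()),
                "host": host,
            }
        )
        pixel_sets.append(pix)
    return ClusterSet(
        table=pd.DataFrame(rows), pixel_sets=pixel_sets, threshold=threshold
    )


def detect_clusters_stack(
    corrected: ImageStack,
    label_map: PoreLabelMap,
    smooth_px: int = 3,
    threshold_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Cluster detection over all frames: each DEP independently, TPs as one.

    Returns one table with ``frame_index`` and ``time_s`` columns; the host
    column is ``"dep_<id>"`` or ``"tp"``.
    """
    grid = label_map.grid
    tp_region = grid == TP
    tables = []
    for fi in range(1, corrected.n_frames):
        frame = corrected.frames[fi]
        sets = []
        for reg in label_map.dep_regions:
            rmask = np.zeros(grid.shape, dtype=bool)
            rmask[reg.pixel_index] = True
            cs = detect_clusters(
                frame,
                rmask,
                pixel_size=corrected.pixel_size,
                host=f"dep_{reg.dep_id}",
                smooth_px=smooth_px,
                threshold_multiplier=threshold_multiplier,
            )
            sets.append(cs.table)
        if tp_region.any():
            cs = detect_clusters(
                frame,
                tp_region,
                pixel_size=corrected.pixel_size,
                host="tp",
                smooth_px=smooth_px,
                threshold_multiplier=threshold_multiplier,
            )
            sets.append(cs.table)
        sets = [t for t in sets if not t.empty]
        if not sets:
            continue
        tab = pd.concat(sets, ignore_index=True)
        tab["frame_index"] = fi
        tab["time_s"] = corrected.times[fi]
        tables.append(tab)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def colony_mass_pdf(
    clusters: pd.DataFrame,
    n_bins: int = 64,
) -> pd.DataFrame:
    """Probability density of colony biomass per surface, per time point.

    Densities are normalized to unit integral over mass_per_area on a shared
    logarithmic binning spanning the observed range, so curves from
    different frames are directly comparable.
    """
    if clusters.empty:
        raise ValueError("no clusters to build a density from")
    values = clusters["mass_per_area"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("mass_per_area must be positive")
    lo, hi = values.min(), values.max()
    if lo == hi:
        lo, hi = lo * 0.5, hi * 2.0
    edges = np.geomspace(lo, hi, n_bins + 1)
    out = []
    for t, sub in clusters.groupby("time_s"):
        vals = sub["mass_per_area"].to_numpy(dtype=float)
        degenerate = len(vals) < 2
        dens, _ = np.histogram(vals, bins=edges, density=True)
        centers = np.sqrt(edges[:-1] * edges[1:])
        out.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "mass_per_area": centers,
                    "density": dens,
                    "n_clusters": len(vals),
                    "degenerate": degenerate,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _class_means(frame: np.ndarray, label_map: PoreLabelMap):
    dep = label_map.grid == DEP
    tp = label_map.grid == TP
    c_dep = float(frame[dep].mean()) if dep.any() else np.nan
    c_tp = float(frame[tp].mean()) if tp.any() else np.nan
    return c_dep, c_tp


def retention_curve(
    stacks: ImageStack | list[ImageStack],
    label_map: PoreLabelMap,
    floor: float = 1e-9,
    pv_time_s: float | None = None,
) -> pd.DataFrame:
    """C_dep/C_tp per frame, averaged over replicates when several are given.

    C_class is the area-normalized mean corrected intensity over the class
    pixels.  Frames whose C_tp falls below ``floor`` yield NaN (undefined
    ratio).  With ``pv_time_s`` the time axis is also given in eluted pore
    volumes.
    """
    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    times = stacks[0].times
    ratios = np.full((len(stacks), len(times)), np.nan)
    for si, st in enumerate(stacks):
        if not np.array_equal(st.times, times):
            raise ValueError("replicate stacks must share frame times")
        for fi in range(st.n_frames):
            c_dep, c_tp = _class_means(st.frames[fi], label_map)
            if np.isfinite(c_tp) and c_tp > floor:
                ratios[si, fi] = c_dep / c_tp
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        mean = np.nanmean(ratios, axis=0)
        sd = np.nanstd(ratios, axis=0, ddof=1) if len(stacks) > 1 else np.zeros_like(mean)
    df = pd.DataFrame({"time_s": times, "ratio": mean, "mean": mean, "sd": sd})
    if pv_time_s:
        df["pv"] = df["time_s"] / pv_time_s
    return df


def biomass_timeseries(
    corrected: ImageStack,
    label_map: PoreLabelMap,
) -> pd.DataFrame:
    """Class-summed biomass trajectories B_tp, B_dep, B_tot and DEP partition."""
    dep = label_map.grid == DEP
    tp = label_map.grid == TP
    rows = []
    for fi in range(corrected.n_frames):
        frame = corrected.frames[fi]
        b_dep = float(frame[dep].sum())
        b_tp = float(frame[tp].sum())
        b_tot = b_dep + b_tp
        rows.append(
            {
                "time_s": corrected.times[fi],
                "B_tp": b_tp,
                "B_dep": b_dep,
                "B_tot": b_tot,
                "dep_partition": b_dep / b_tot if b_tot > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
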