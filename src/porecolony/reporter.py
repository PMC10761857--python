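"""Reporter activity maps and depth profiles along dead-end pores.

Fluorescent transcriptional reporter intensity is a proxy for quorum-sensing
induction, but it scales with how many cells are present; the meaningful
quantity is activity = reporter intensity / biomass intensity, valid only
where biomass exceeds a floor.  Activity is then profiled along each DEP:
at every 10th skeleton pixel of the DEP (arc length from the entrance), the
activity and biomass are averaged over the maximal inscribed disk clipped
to the DEP, giving activity(s) and biomass(s) with s ∈ [0, L].  The
activation front is the shallowest depth at which activity reaches 80% of
the profile's own maximum — the measured counterpart of the glucose
limitation length ζ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DEP, DiskMap, PoreLabelMap, Skeleton

__all__ = [
    "ActivityMap",
    "DepthProfile",
    "FrontPosition",
    "normalize_activity",
    "dep_depth_profile",
    "extract_front",
    "mean_profile",
]


@dataclass
class ActivityMap:
    """Per-pixel reporter activity with a validity mask (biomass ≥ floor)."""

    values: np.ndarray
    valid: np.ndarray
    floor: float


@dataclass
class DepthProfile:
    """Disk-averaged activity and biomass vs arc length from the DEP entrance."""

    dep_id: int
    s_um: np.ndarray
    activity: np.ndarray
    biomass: np.ndarray
    L_um: float
    time_s: float = np.nan
    single_point: bool = False


def normalize_activity(
    reporter_frame: np.ndarray,
    biomass_frame: np.ndarray,
    floor: float,
) -> ActivityMap:
    """Reporter / biomass ratio where biomass is above the floor."""
    if floor <= 0:
        raise ValueError("biomass floor must be positive")
    valid = biomass_frame >= floor
    values = np.zeros_like(biomass_frame, dtype=np.float64)
    np.divide(reporter_frame, biomass_frame, out=values, where=valid)
    return ActivityMap(values=values, valid=valid, floor=floor)


def dep_depth_profile(
    activity: ActivityMap,
    label_map: PoreLabelMap,
    skeleton: Skeleton,
    disks: DiskMap,
    biomass_frame: np.ndarray | None = None,
    step_px: int = 10,
    time_s: float = np.nan,
) -> list[DepthProfile]:
    """Profile activity and biomass along each DEP skeleton, every 10 pixels.

    Samples are taken at the skeleton points closest to arc lengths
    0, step, 2·step, … from the entrance; at each sample the maximal
    inscribed disk, clipped to the DEP pixels and the validity mask, is
    averaged.  DEPs shorter than one step yield a flagged single-point
    profile.
    """
    px = label_map.pixel_size
    grid = label_map.grid
    dep_grid = grid == DEP
    h, w = grid.shape
    profiles = []
    for reg in label_map.dep_regions:
        pts = reg.skeleton_points
        if len(pts) == 0:
            continue
        arc = reg.arc_length_px
        finite = np.isfinite(arc)
        pts, arc = pts[finite], arc[finite]
        if len(pts) == 0:
            continue
        order = np.argsort(arc)
        pts, arc = pts[order], arc[order]
        L_px = arc[-1]
        targets = np.arange(0.0, L_px + step_px / 2.0, step_px)
        if len(targets) < 2:
            targets = np.array([0.0, L_px]) if L_px > 0 else np.array([0.0])
        s_list, a_list, b_list = [], [], []
        for st in targets:
            k = int(np.argmin(np.abs(arc - st)))
            r0, c0 = skeleton.coords[pts[k]]
            r = disks.radius_px[r0, c0]
            reach = int(np.ceil(r))
            r1, r2 = max(0, r0 - reach), min(h, r0 + reach + 1)
            c1, c2 = max(0, c0 - reach), min(w, c0 + reach + 1)
            yy, xx = np.ogrid[r1:r2, c1:c2]
            disk = (np.hypot(yy - r0, xx - c0) <= r) & dep_grid[r1:r2, c1:c2]
            val = activity.valid[r1:r2, c1:c2] & disk
            if not val.any():
                continue
            s_list.append(arc[k] * px)
            a_list.append(float(activity.values[r1:r2, c1:c2][val].mean()))
            if biomass_frame is not None:
                b_list.append(float(biomass_frame[r1:r2, c1:c2][disk].mean()))
            else:
                b_list.append(float(np.count_nonzero(val)))
        if not s_list:
            continue
        s = np.asarray(s_list)
        uniq, idx = np.unique(s, return_index=True)
        profiles.append(
            DepthProfile(
                dep_id=reg.dep_id,
                s_um=uniq,
                activity=np.asarray(a_list)[idx],
                biomass=np.asarray(b_list)[idx],
                L_um=float(L_px * px),
                time_s=time_s,
                single_point=len(uniq) < 2,
            )
        )
    return profiles


@dataclass
class FrontPosition:
    """Depth of the 80%-of-maximum activation front, from the DEP entrance."""

    dep_id: int
    zeta_mm: float
    time_s: float = np.nan
    defined: bool = True


def extract_front(profile: DepthProfile, fraction: float = 0.8) -> FrontPosition:
    """Shallowest depth where activity reaches ``fraction`` of its maximum.

    Linear interpolation between profile samples; a constant-positive
    profile fronts at the entrance (s = 0); an all-zero profile has no
    defined front and is flagged.
    """
    a = profile.activity
    s = profile.s_um
    amax = a.max() if len(a) else 0.0
    if amax <= 0 or len(a) < 2:
        return FrontPosition(
            dep_id=profile.dep_id, zeta_mm=np.nan, time_s=profile.time_s, defined=False
        )
    thr = fraction * amax
    above = a >= thr
    i = int(np.argmax(above))
    if i == 0:
        zeta_um = s[0]
    else:
        s0, s1 = s[i - 1], s[i]
        a0, a1 = a[i - 1], a[i]
        zeta_um = s0 + (thr - a0) / (a1 - a0) * (s1 - s0) if a1 != a0 else s1
    return FrontPosition(
        dep_id=profile.dep_id,
        zeta_mm=float(zeta_um) / 1000.0,
        time_s=profile.time_s,
    )


def mean_profile(profiles: list[DepthProfile], n_points: int = 50) -> pd.DataFrame:
    """Average profiles across DEPs at matched normalized depth s/L.

    Each profile is resampled onto a common s/L ∈ [0, 1] grid before
    averaging, then the depth axis is rescaled to the mean DEP length.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    grid_norm = np.linspace(0.0, 1.0, n_points)
    acts = []
    for p in profiles:
        if p.L_um <= 0 or len(p.s_um) < 2:
            continue
        acts.append(np.interp(grid_norm, p.s_um / p.L_um, p.activity))
    if not acts:
        raise ValueError("no multi-point profiles to average")
    acts = np.vstack(acts)
    mean_L = float(np.mean([p.L_um for p in profiles]))
    return pd.DataFrame(
        {
            "s_norm": grid_norm,
            "s_um": grid_norm * mean_L,
            "activity_mean": acts.mean(axis=0),
            "activity_sd": acts.std(axis=0),
            "n_deps": len(acts),
        }
    )
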