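"""Dynamic glucoCEST-enhancement (GCE) analysis of an infusion series.

A :class:`CestSeries` holds per-offset image stacks at the seven acquisition
timepoints of the infusion protocol (baseline; 10/20/30/40 min during
infusion; 10/20 min post), a B0 map and named ROI masks.  The enhancement
map is the subtraction rule

    GCE = mean( MTRasym map at 40 min infusion, at 10 min post ) - baseline map,

with the post - pre sign convention so that glucose uptake yields positive
GCE.  ROI time courses report the baseline-subtracted ROI-mean MTRasym at
every timepoint.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import larmor_hz_per_ppm
from .zspec import B0Map, mtr_asym_map

__all__ = [
    "TIMEPOINTS",
    "CestSeries",
    "GceMap",
    "GceTimecourse",
    "glucocest_map",
    "gce_map",
    "roi_timecourse",
    "cohort_table",
]

#: Canonical infusion timepoints: label -> minutes from baseline.
TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("baseline", 0.0),
    ("inf10", 10.0),
    ("inf20", 20.0),
    ("inf30", 30.0),
    ("inf40", 40.0),
    ("post10", 50.0),
    ("post20", 60.0),
)

#: Bilateral ROI unions derivable from per-side masks.
_BILATERAL = {
    "hippocampus": ("hippocampus_L", "hippocampus_R"),
    "parietal_cortex": ("parietal_cortex_L", "parietal_cortex_R"),
}


@dataclass
class CestSeries:
    """Dynamic stack of per-offset images over the infusion timepoints."""

    stacks: dict[str, np.ndarray]       # label -> (ny, nx, n_offsets)
    s0_images: dict[str, np.ndarray]    # label -> (ny, nx)
    offsets_hz: np.ndarray
    rois: dict[str, np.ndarray]
    b0: B0Map | None = None
    timepoints: tuple[tuple[str, float], ...] = TIMEPOINTS
    larmor_hz_per_ppm: float = field(default_factory=larmor_hz_per_ppm)

    def __post_init__(self) -> None:
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        labels = [t for t, _ in self.timepoints]
        minutes = [m for _, m in self.timepoints]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError("timepoints must be strictly ordered in time")
        missing = [t for t in labels if t not in self.stacks]
        if missing:
            raise ValueError(f"missing stacks for timepoints: {missing}")
        shapes = {self.stacks[t].shape for t in labels}
        if len(shapes) != 1:
            raise ValueError(f"timepoint stacks have incongruent shapes: {shapes}")
        (shape,) = shapes
        if shape[-1] != self.offsets_hz.size:
            raise ValueError("stack depth does not match offsets_hz")
        self.grid = shape[:-1]
        for t in labels:
            if self.s0_images[t].shape != self.grid:
                raise ValueError(f"s0 image for {t!r} does not match grid {self.grid}")
        for name, mask in self.rois.items():
            if mask.shape != self.grid:
                raise ValueError(f"ROI {name!r} does not match grid {self.grid}")
        if self.b0 is not None and self.b0.shift_hz.shape != self.grid:
            raise ValueError("B0 map does not match grid")
        brain = self.rois.get("total_brain")
        if brain is not None:
            for name, mask in self.rois.items():
                if name != "total_brain" and np.any(mask & ~brain):
                    raise ValueError(f"ROI {name!r} extends outside total_brain")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.timepoints)

    @property
    def minutes(self) -> np.ndarray:
        return np.asarray([m for _, m in self.timepoints], dtype=float)

    def roi_mask(self, roi: str) -> np.ndarray:
        """Resolve an ROI name; bilateral names resolve to L/R unions."""
        if roi in self.rois:
            return self.rois[roi]
        if roi in _BILATERAL:
            l, r = _BILATERAL[roi]
            if l in self.rois and r in self.rois:
                return self.rois[l] | self.rois[r]
        raise KeyError(f"no ROI named {roi!r}")


@dataclass
class GceMap:
    """Per-voxel glucoCEST enhancement with validity mask."""

    values: np.ndarray
    mask: np.ndarray


@dataclass
class GceTimecourse:
    """Baseline-subtracted ROI-mean MTRasym over the infusion timepoints."""

    roi: str
    minutes: np.ndarray
    delta_mtr: np.ndarray
    baseline_mtr: float
    mean_mtr: np.ndarray    # raw (non-subtracted) ROI means, same order


def glucocest_map(
    series: CestSeries, t: str, delta_ppm: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise MTRasym(delta_ppm) image at timepoint ``t``."""
    if t not in series.stacks:
        raise KeyError(f"timepoint {t!r} not in series (have {series.labels})")
    return mtr_asym_map(
        series.stacks[t],
        series.s0_images[t],
        series.offsets_hz,
        b0=series.b0,
        delta_ppm=delta_ppm,
        larmor=series.larmor_hz_per_ppm,
    )


def _maps(series: CestSeries, labels, delta_ppm: float, cache=None):
    out = {}
    for t in labels:
        if cache is not None and t in cache:
            out[t] = cache[t]
        else:
            out[t] = glucocest_map(series, t, delta_ppm)
            if cache is not None:
                cache[t] = out[t]
    return out


def gce_map(series: CestSeries, delta_ppm: float = 0.9, sign: str = "post-pre") -> GceMap:
    """GCE image: mean of the 40-min and post-10-min maps minus baseline.

    ``sign='pre-post'`` flips the convention (baseline minus infusion mean).
    """
    if sign not in ("post-pre", "pre-post"):
        raise ValueError("sign must be 'post-pre' or 'pre-post'")
    needed = ("baseline", "inf40", "post10")
    missing = [t for t in needed if t not in series.stacks]
    if missing:
        raise ValueError(f"GCE needs timepoints {needed}, missing {missing}")
    m = _maps(series, needed, delta_ppm)
    values = 0.5 * (m["inf40"][0] + m["post10"][0]) - m["baseline"][0]
    if sign == "pre-post":
        values = -values
    mask = m["baseline"][1] & m["inf40"][1] & m["post10"][1]
    values = np.where(mask, values, np.nan)
    return GceMap(values, mask)


def roi_timecourse(
    series: CestSeries, roi: str, delta_ppm: float = 0.9, _map_cache=None
) -> GceTimecourse:
    """ROI-mean MTRasym at each timepoint, baseline-subtracted."""
    mask = series.roi_mask(roi)
    if not np.any(mask):
        raise ValueError(f"ROI {roi!r} is empty")
    maps = _maps(series, series.labels, delta_ppm, cache=_map_cache)
    means = []
    for t in series.labels:
        values, valid = maps[t]
        sel = mask & valid
        if not np.any(sel):
            raise ValueError(f"ROI {roi!r} has no valid voxels at timepoint {t!r}")
        means.append(float(np.mean(values[sel])))
    means = np.asarray(means)
    return GceTimecourse(roi, series.minutes, means - means[0], float(means[0]), means)


def cohort_table(
    animals,
    rois: tuple[str, ...] = (
        "total_brain",
        "hippocampus",
        "hippocampus_L",
        "hippocampus_R",
        "parietal_cortex",
        "parietal_cortex_L",
        "parietal_cortex_R",
    ),
    delta_ppm: float = 0.9,
) -> pd.DataFrame:
    """Tidy per-animal, per-ROI summary feeding the statistics stage.

    ``animals`` is an iterable of ``(animal_id, group, CestSeries)``.  Each
    row carries the baseline ROI-mean MTRasym, the ROI-mean GCE and the
    baseline-subtracted time course (one ``delta_<minutes>min`` column per
    timepoint).  Rows are ordered by input order then ROI order.
    """
    rows = []
    seen = set()
    for animal_id, group, series in animals:
        if animal_id in seen:
            raise ValueError(f"duplicated animal id {animal_id!r}")
        seen.add(animal_id)
        cache: dict = {}
        g = gce_map(series, delta_ppm)
        for roi in rois:
            try:
                mask = series.roi_mask(roi)
            except KeyError:
                continue
            tc = roi_timecourse(series, roi, delta_ppm, _map_cache=cache)
            sel = mask & g.mask
            row = {
                "animal": animal_id,
                "group": group,
                "roi": roi,
                "n_voxels": int(np.sum(sel)),
                "baseline_mtr": tc.baseline_mtr,
                "gce": float(np.mean(g.values[sel])),
            }
            for minutes, d in zip(tc.minutes, tc.delta_mtr):
                row[f"delta_{int(minutes)}min"] = float(d)
            rows.append(row)
    if not rows:
        raise ValueError("no animals provided")
    return pd.DataFrame(rows)
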