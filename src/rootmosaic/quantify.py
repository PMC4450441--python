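"""Per-cell mean fluorescence over reconstructed volumes; depth exclusion.

The mean intensity of a reconstructed cell is the reporter intensity summed
over the exact labelled pixels of its member 2D regions across all its
planes, divided by the total reconstructed area (the volume proxy).  No
background subtraction or flat-field correction is applied: raw means are
reported.

Because stacks are acquired top to bottom, per-cell means decay with depth
(bleaching/depth confound).  The depth filter restricts analysis to the
depth range over which the profile of per-depth mean intensity is
approximately constant: the cut depth is the deepest depth at which the
running (cumulative) mean of the profile stays within a tolerance band of
the shallowest depth's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .reconstruct import Cell3D
from .segmentation import PlaneSegmentation
from .stack import ImageStack


@dataclass
class CellMeasurement:
    """Measured quantities of one reconstructed cell."""

    cell_id: int
    means: dict[str, float]  # per reporter channel, a.u.
    total_area_px: float
    n_planes: int
    depth_um: float
    border_flag: bool
    included: bool = True
    root_id: str = ""


@dataclass
class DepthProfile:
    """Mean of per-cell means binned by depth, and the accepted depth range."""

    depths_um: np.ndarray
    mean_intensity: np.ndarray
    n_cells: np.ndarray
    d_cut_um: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths_um,
                "mean_intensity": self.mean_intensity,
                "n_cells": self.n_cells,
            }
        )


def measure_cells(
    cells: list[Cell3D],
    segs: list[PlaneSegmentation],
    stack: ImageStack,
    channels: list[str] | None = None,
    root_id: str = "",
) -> list[CellMeasurement]:
    """Sum reporter intensity over each cell's labelled pixels / total area.

    ``channels`` defaults to every non-wall channel of the stack.
    """
    if channels is None:
        channels = stack.reporter_channels
    for ch in channels:
        if ch not in stack.channels:
            raise KeyError(f"channel {ch!r} not in stack {stack.channels}")
    by_plane = {s.plane_index: s for s in segs}
    for cell in cells:
        for p, _ in cell.regions:
            if p not in by_plane or not (0 <= p < stack.n_planes):
                raise ValueError(f"cell {cell.cell_id} references missing plane {p}")

    # per-plane, per-label intensity sums for each channel
    sums: dict[str, dict[tuple[int, int], float]] = {ch: {} for ch in channels}
    for p, seg in by_plane.items():
        if seg.labels is None:
            raise ValueError("measurement requires label images in segmentations")
        labels = seg.labels
        idx = seg.regions["label"].to_numpy()
        if idx.size == 0:
            continue
        for ch in channels:
            plane_img = stack.channel(ch)[p]
            s = ndi.sum_labels(plane_img, labels=labels, index=idx)
            for lab, v in zip(idx, s):
                sums[ch][(p, int(lab))] = float(v)

    out = []
    for cell in cells:
        means = {}
        for ch in channels:
            total = sum(sums[ch][node] for node in cell.regions)
            means[ch] = total / cell.total_area_px
        out.append(
            CellMeasurement(
                cell_id=cell.cell_id,
                means=means,
                total_area_px=cell.total_area_px,
                n_planes=cell.n_planes,
                depth_um=cell.depth_um,
                border_flag=cell.border_flag,
                included=True,
                root_id=root_id,
            )
        )
    return out


def depth_filter(
    measurements: list[CellMeasurement],
    channel: str | None = None,
    method: str = "plateau",
    tol: float = 0.15,
    d_cut_um: float | None = None,
    z_step_um: float = 3.0,
) -> tuple[DepthProfile, list[CellMeasurement]]:
    """Mark cells outside the constant-intensity depth range as excluded.

    ``plateau`` method: bin cells by depth (nearest plane), take the mean of
    per-cell means per bin, and set the cut at the deepest bin whose running
    mean is still >= (1 - tol) times the shallowest bin's mean.  ``manual``
    method: the caller supplies ``d_cut_um`` directly.  Cells deeper than
    the cut get ``included = False``; everything else is untouched, so the
    filter is idempotent.
    """
    if not measurements:
        return DepthProfile(np.array([]), np.array([]), np.array([]), np.nan), []
    if channel is None:
        channel = next(iter(measurements[0].means))
    active = [m for m in measurements if m.included]
    depths = np.array([m.depth_um for m in active])
    values = np.array([m.means[channel] for m in active])
    bins = np.round(depths / z_step_um).astype(int)
    uniq = np.unique(bins)
    bin_depth = uniq * z_step_um
    bin_mean = np.array([values[bins == b].mean() for b in uniq])
    bin_n = np.array([int((bins == b).sum()) for b in uniq])

    if method == "manual":
        if d_cut_um is None:
            raise ValueError("manual depth filtering requires d_cut_um")
        cut = float(d_cut_um)
    elif method == "plateau":
        if len(uniq) < 3:
            warnings.warn("fewer than 3 distinct depths: depth filter skipped")
            cut = float(bin_depth.max()) if len(uniq) else np.nan
        else:
            ref = bin_mean[0]
            running = np.cumsum(bin_mean) / np.arange(1, len(bin_mean) + 1)
            ok = running >= (1.0 - tol) * ref
            cut = float(bin_depth[np.flatnonzero(ok)[-1]]) if ok.any() else float(
                bin_depth[0]
            )
    else:
        raise ValueError(f"unknown depth filter method {method!r}")

    # half a bin of slack so cells exactly at the cut depth bin survive
    limit = cut + 0.5 * z_step_um
    filtered = [
        replace(m, included=bool(m.included and m.depth_um <= limit))
        for m in measurements
    ]
    profile = DepthProfile(
        depths_um=bin_depth, mean_intensity=bin_mean, n_cells=bin_n, d_cut_um=cut
    )
    return profile, filtered


def render_heatmap(
    cells: list[Cell3D],
    measurements: list[CellMeasurement],
    segs: list[PlaneSegmentation],
    plane_index: int,
    channel: str | None = None,
) -> np.ndarray:
    """Label image of one plane recoloured by per-cell mean intensity.

    Pixels of successfully reconstructed cells carry the cell's mean
    intensity; everything else (background, walls, unreconstructed regions)
    is zero, matching the convention that unreconstructed cells render
    black.
    """
    by_plane = {s.plane_index: s for s in segs}
    if plane_index not in by_plane:
        raise ValueError(f"no segmentation for plane {plane_index}")
    seg = by_plane[plane_index]
    if seg.labels is None:
        raise ValueError("heat map rendering requires label images")
    mean_of = {}
    for m in measurements:
        if channel is None:
            channel = next(iter(m.means))
        mean_of[m.cell_id] = m.means[channel]
    out = np.zeros(seg.labels.shape, dtype=np.float64)
    for cell in cells:
        if cell.cell_id not in mean_of:
            continue
        for p, lab in cell.regions:
            if p == plane_index:
                out[seg.labels == lab] = mean_of[cell.cell_id]
    return out


def measurements_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Flatten measurements into a per-cell table."""
    rows = []
    for m in measurements:
        rec = {
            "root_id": m.root_id,
            "cell_id": m.cell_id,
            "total_area_px": m.total_area_px,
            "n_planes": m.n_planes,
            "depth_um": m.depth_um,
            "border": m.border_flag,
            "included": m.included,
        }
        for ch, v in m.means.items():
            rec[f"mean_{ch}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)
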