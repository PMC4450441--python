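"""Synthetic root-meristem z-stacks with per-cell ground truth.

The generator emulates the statistical structure of confocal z-stacks of
*Arabidopsis* primary root meristems carrying nuclear fluorescent reporters:

* parallel longitudinal **files** of cells produced by repeated anticlinal
  divisions, laid out here as a rectangular grid of rectangular cells
  (an idealised meristem — the downstream operators only need walls, files
  and nuclei, not realistic root morphology);
* a bright **cell-wall channel** (emulating a propidium-iodide stain) with
  ridges at every cell boundary, including transverse walls between cell
  layers along z;
* **reporter channels** with one nuclear blob per cell whose diameter
  (7 µm at the default 3.5 µm radius) makes each nucleus intersect 2–3
  consecutive optical sections at the default 3 µm z-step;
* **clonal expression states**: every cell in a file shares its ON/OFF state
  per reporter.  The ON probability of a file is a monotone-decreasing
  function of a cold-exposure duration parameter.  In ``trans`` memory mode
  both reporters of a file share a single state; in ``cis`` mode the two
  reporter states are drawn independently per file, so mixed ON/OFF files
  occur;
* **depth-dependent decay**: plane-wise intensity is attenuated by a fixed
  fraction per plane of acquisition depth, emulating the bleaching/depth
  confound of top-to-bottom acquisition;
* additive Gaussian detector noise, clipped at zero.

Randomness is controlled by a single master seed split into independent
sub-streams for geometry jitter, expression states and detector noise, so
states are reproducible independently of the noise realisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import gaussian

from .stack import DEFAULT_PX_PER_UM, ImageStack

ON = "ON"
OFF = "OFF"


class GeometryError(ValueError):
    """Raised when a requested phantom geometry is physically inconsistent."""


def p_on_from_cold_weeks(
    weeks: float, midpoint_weeks: float = 6.5, scale_weeks: float = 1.4
) -> float:
    """ON probability of a cell file as a function of cold-exposure duration.

    A logistic decay calibrated so that non-vernalized files are almost all
    ON, the population is strongly bimodal after 6-8 weeks of cold, and
    nearly all files are silenced after 10 weeks.
    """
    return float(1.0 / (1.0 + math.exp((weeks - midpoint_weeks) / scale_weeks)))


# ----------------------------------------------------------------------
@dataclass
class RootGeometry:
    """Geometry of the idealised meristem phantom.

    In-plane, the root is ``n_files`` longitudinal files of
    ``cells_per_file`` cells; along z it is ``n_layers`` layers of cells
    separated by transverse walls.  All lengths default to values typical of
    meristematic cells (~8 x 12 x 9 um) at the instrument calibration of
    ~4.016 px/um (2048 px across a 510 um field).
    """

    n_files: int = 6
    cells_per_file: int = 12
    cell_length_px: int = 48  # extent along the root axis (image rows)
    cell_width_px: int = 32  # extent across files (image columns)
    nucleus_radius_um: float = 3.5
    n_layers: int = 4
    cell_depth_um: float = 9.0  # z extent of one cell layer
    z_wall_um: float = 3.0  # transverse wall gap between layers
    z_planes: int | None = None  # default: cover all layers
    z_step_um: float = 3.0
    px_per_um: float = DEFAULT_PX_PER_UM
    margin_px: int = 64
    wall_intensity: float = 200.0
    wall_background: float = 5.0
    outside_level: float = 1.0
    wall_noise_sd: float = 3.0
    render_blur_px: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_files", "cells_per_file", "n_layers", "cell_length_px", "cell_width_px"):
            if getattr(self, name) < 1:
                raise GeometryError(f"{name} must be >= 1")
        if self.z_step_um <= 0 or self.px_per_um <= 0:
            raise GeometryError("calibration values must be positive")
        d_px = 2.0 * self.nucleus_radius_um * self.px_per_um
        if d_px > self.interior_width_px or d_px > self.interior_length_px:
            raise GeometryError(
                "nucleus diameter exceeds the cell cross-section: "
                f"{d_px:.1f} px vs {self.interior_width_px} x {self.interior_length_px} px"
            )
        if 2.0 * self.nucleus_radius_um > self.cell_depth_um:
            raise GeometryError("nucleus diameter exceeds the cell depth")

    # -- derived quantities -------------------------------------------
    @property
    def interior_width_px(self) -> int:
        return self.cell_width_px - 2

    @property
    def interior_length_px(self) -> int:
        return self.cell_length_px - 2

    @property
    def z_period_um(self) -> float:
        return self.cell_depth_um + self.z_wall_um

    @property
    def planes_per_period(self) -> int:
        return int(round(self.z_period_um / self.z_step_um))

    @property
    def n_planes(self) -> int:
        if self.z_planes is not None:
            return self.z_planes
        return self.n_layers * self.planes_per_period + 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = 2 * self.margin_px + self.cells_per_file * self.cell_length_px
        w = 2 * self.margin_px + self.n_files * self.cell_width_px
        return h, w

    @property
    def n_cells(self) -> int:
        return self.n_files * self.cells_per_file * self.n_layers


@dataclass
class ExpressionModel:
    """Generative model for per-file reporter expression states.

    ``p_on`` is the probability that a cell file is ON.  With two reporters,
    ``memory_mode="trans"`` forces both reporters of a file into one shared
    state (memory carried by diffusible factors), while ``"cis"`` draws the
    two reporter states independently per file (memory carried locally at
    each gene copy), so ON/OFF and OFF/ON mixed files arise with probability
    ``2 p_on (1 - p_on)``.

    Intensities are arbitrary fluorescence units; ``bleach_rate`` is the
    fractional intensity loss per plane of acquisition depth.
    ``switch_noise`` flips individual cells away from their file state with
    the given probability (default 0: files are perfectly coherent).
    """

    p_on: float = 0.5
    memory_mode: str = "cis"
    n_reporters: int = 1
    on_intensity: float = 200.0
    off_intensity: float = 20.0
    background: float = 10.0
    noise_sd: float = 5.0
    bleach_rate: float = 0.03
    switch_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must lie in [0, 1]")
        if self.memory_mode not in ("cis", "trans"):
            raise ValueError("memory_mode must be 'cis' or 'trans'")
        if self.n_reporters not in (1, 2):
            raise ValueError("n_reporters must be 1 or 2")
        if self.off_intensity < 0 or self.on_intensity <= self.off_intensity:
            raise ValueError("need on_intensity > off_intensity >= 0")
        if not 0.0 <= self.bleach_rate < 1.0:
            raise ValueError("bleach_rate must lie in [0, 1)")

    @classmethod
    def from_cold_weeks(cls, weeks: float, **kwargs) -> "ExpressionModel":
        """Expression model whose ON probability follows the cold-duration curve."""
        return cls(p_on=p_on_from_cold_weeks(weeks), **kwargs)

    @property
    def reporter_names(self) -> list[str]:
        return [f"reporter_{i + 1}" for i in range(self.n_reporters)]


@dataclass
class GroundTruth:
    """Generator output pairing every true cell with its geometry and state.

    ``table`` has one row per true cell (cell_id, file_id, position, plane
    span, per-reporter state and noise-free mean intensity);
    ``label_volume`` is a ``(planes, H, W)`` int32 image of true cell ids
    (0 = wall/background); ``footprint`` is the in-plane tissue mask.
    """

    table: pd.DataFrame
    label_volume: np.ndarray
    footprint: np.ndarray
    geometry: RootGeometry
    expression: ExpressionModel

    def save(self, csv_path, labels_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if labels_path is not None:
            import tifffile

            tifffile.imwrite(labels_path, self.label_volume.astype(np.int32))


# ----------------------------------------------------------------------
def _draw_states(
    rng: np.random.Generator, n_files: int, expression: ExpressionModel
) -> np.ndarray:
    """Per-file ON indicators, shape (n_files, n_reporters)."""
    if expression.memory_mode == "trans":
        s = rng.random(n_files) < expression.p_on
        return np.repeat(s[:, None], expression.n_reporters, axis=1)
    return rng.random((n_files, expression.n_reporters)) < expression.p_on


def _cell_states(
    rng: np.random.Generator,
    file_states: np.ndarray,
    cells_per_file: int,
    switch_noise: float,
) -> np.ndarray:
    """Expand file states to cells, optionally flipping with switch_noise.

    Returns shape (n_files, cells_per_file, n_reporters).
    """
    n_files, n_rep = file_states.shape
    cells = np.repeat(file_states[:, None, :], cells_per_file, axis=1)
    if switch_noise > 0:
        flips = rng.random(cells.shape) < switch_noise
        cells = cells ^ flips
    return cells


def generate_root(
    geometry: RootGeometry, expression: ExpressionModel, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic two- or three-channel root z-stack with truth.

    The wall channel shows bright ridges at every cell boundary (and fully
    bright transverse-wall planes between cell layers); reporter channels
    show nuclear blobs at the ON or OFF intensity, attenuated per plane by
    the bleach rate.  The same seed always yields bit-identical output.
    """
    g, e = geometry, expression
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_state, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    h, w = g.frame_shape
    n_planes = g.n_planes
    z = np.arange(n_planes) * g.z_step_um
    # Random phase of the plane grid relative to the tissue, so nuclei fall
    # at varying offsets from the sampling planes (2 vs 3 intersected planes).
    phase = float(rng_geom.uniform(0.0, g.z_step_um))

    # ---- in-plane layout -------------------------------------------------
    row_bounds = g.margin_px + np.arange(g.cells_per_file + 1) * g.cell_length_px
    col_bounds = g.margin_px + np.arange(g.n_files + 1) * g.cell_width_px
    wall2d = np.zeros((h, w), dtype=bool)
    r0, r1 = row_bounds[0] - 1, row_bounds[-1] + 1
    c0, c1 = col_bounds[0] - 1, col_bounds[-1] + 1
    for b in row_bounds:
        wall2d[b - 1 : b + 1, c0:c1] = True
    for b in col_bounds:
        wall2d[r0:r1, b - 1 : b + 1] = True
    footprint = np.zeros((h, w), dtype=bool)
    footprint[r0:r1, c0:c1] = True

    # ---- z layout --------------------------------------------------------
    layer_start = phase + np.arange(g.n_layers) * g.z_period_um
    plane_layer = np.full(n_planes, -1, dtype=int)  # -1: outside / transverse wall
    wall_plane = np.zeros(n_planes, dtype=bool)
    for j in range(n_planes):
        k = int(math.floor((z[j] - phase) / g.z_period_um)) if z[j] >= phase else -1
        if 0 <= k < g.n_layers:
            rel = z[j] - layer_start[k]
            if rel < g.cell_depth_um:
                plane_layer[j] = k
            else:
                wall_plane[j] = True

    # ---- states (independent sub-stream) ---------------------------------
    n_files_total = g.n_layers * g.n_files
    file_states = _draw_states(rng_state, n_files_total, e)
    cell_states = _cell_states(
        rng_state, file_states, g.cells_per_file, e.switch_noise
    )  # (files_total, cells_per_file, n_rep)

    # ---- nucleus centres (geometry sub-stream) ----------------------------
    r_um = g.nucleus_radius_um
    r_px = r_um * g.px_per_um
    slack_r = max(0.0, (g.interior_length_px - 2 * r_px) / 2.0 - 0.5)
    slack_c = max(0.0, (g.interior_width_px - 2 * r_px) / 2.0 - 0.5)
    slack_z = max(0.0, (g.cell_depth_um - 2 * r_um) / 2.0)
    jit_r = min(2.0, slack_r)
    jit_c = min(2.0, slack_c)
    jit_z = min(1.0, slack_z)

    label_volume = np.zeros((n_planes, h, w), dtype=np.int32)

    reporters = e.reporter_names
    # noise-free reporter volumes
    rep0 = {
        name: np.full((n_planes, h, w), g.outside_level, dtype=np.float64)
        for name in reporters
    }
    for vol in rep0.values():
        vol[:, footprint] = e.background

    records = []
    cell_id = 0
    for k in range(g.n_layers):
        planes_k = np.flatnonzero(plane_layer == k)
        for f in range(g.n_files):
            file_id = k * g.n_files + f
            for p in range(g.cells_per_file):
                cell_id += 1
                ri0, ri1 = row_bounds[p] + 1, row_bounds[p + 1] - 1  # interior rows
                ci0, ci1 = col_bounds[f] + 1, col_bounds[f + 1] - 1
                for j in planes_k:
                    label_volume[j, ri0:ri1, ci0:ci1] = cell_id
                # nucleus centre, jittered within the cell
                cr = (ri0 + ri1 - 1) / 2.0 + rng_geom.uniform(-jit_r, jit_r)
                cc = (ci0 + ci1 - 1) / 2.0 + rng_geom.uniform(-jit_c, jit_c)
                cz = (
                    layer_start[k]
                    + g.cell_depth_um / 2.0
                    + rng_geom.uniform(-jit_z, jit_z)
                )
                n_nuc_planes = 0
                for j in planes_k:
                    dz = z[j] - cz
                    if abs(dz) >= r_um:
                        continue
                    disk_r = math.sqrt(r_um**2 - dz**2) * g.px_per_um
                    if disk_r < 0.5:
                        continue
                    n_nuc_planes += 1
                    lo_r = max(0, int(cr - disk_r) - 1)
                    hi_r = min(h, int(cr + disk_r) + 2)
                    lo_c = max(0, int(cc - disk_r) - 1)
                    hi_c = min(w, int(cc + disk_r) + 2)
                    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
                    sel = (yy - cr) ** 2 + (xx - cc) ** 2 <= disk_r**2
                    states = cell_states[file_id, p]
                    for ir, name in enumerate(reporters):
                        val = e.on_intensity if states[ir] else e.off_intensity
                        rep0[name][j, lo_r:hi_r, lo_c:hi_c][sel] = val
                rec = {
                    "cell_id": cell_id,
                    "file_id": file_id,
                    "layer": k,
                    "lateral_file": f,
                    "pos_in_file": p,
                    "centroid_row": (ri0 + ri1 - 1) / 2.0,
                    "centroid_col": (ci0 + ci1 - 1) / 2.0,
                    "plane_lo": int(planes_k[0]) if planes_k.size else -1,
                    "plane_hi": int(planes_k[-1]) if planes_k.size else -1,
                    "n_planes": int(planes_k.size),
                    "n_nucleus_planes": n_nuc_planes,
                    "area_px": (ri1 - ri0) * (ci1 - ci0),
                }
                for ir, name in enumerate(reporters):
                    rec[f"state_{name}"] = ON if cell_states[file_id, p, ir] else OFF
                records.append(rec)

    # ---- render ----------------------------------------------------------
    bleach = (1.0 - e.bleach_rate) ** np.arange(n_planes)
    for name in reporters:
        vol = rep0[name]
        for j in range(n_planes):
            vol[j] = gaussian(vol[j], sigma=g.render_blur_px, preserve_range=True)
        vol *= bleach[:, None, None]

    table = pd.DataFrame.from_records(records)
    ids = table["cell_id"].to_numpy()
    voxel_counts = np.bincount(label_volume.ravel(), minlength=ids.max() + 1)
    table["n_voxels"] = voxel_counts[ids]
    for name in reporters:
        sums = ndi.sum_labels(rep0[name], labels=label_volume, index=ids)
        with np.errstate(invalid="ignore"):
            table[f"true_mean_{name}"] = np.where(
                voxel_counts[ids] > 0, sums / np.maximum(voxel_counts[ids], 1), np.nan
            )

    wall_vol = np.full((n_planes, h, w), g.outside_level, dtype=np.float64)
    for j in range(n_planes):
        if plane_layer[j] >= 0:
            frame = np.full((h, w), g.outside_level)
            frame[footprint] = g.wall_background
            frame[wall2d] = g.wall_intensity
        elif wall_plane[j]:
            frame = np.full((h, w), g.outside_level)
            frame[footprint] = g.wall_intensity
        else:
            frame = np.full((h, w), g.outside_level)
        wall_vol[j] = gaussian(frame, sigma=g.render_blur_px, preserve_range=True)

    channels = ["wall"] + reporters
    data = np.zeros((n_planes, len(channels), h, w), dtype=np.float32)
    data[:, 0] = np.clip(
        wall_vol + rng_noise.normal(0.0, g.wall_noise_sd, wall_vol.shape), 0, None
    )
    for i, name in enumerate(reporters, start=1):
        noisy = rep0[name] + rng_noise.normal(0.0, e.noise_sd, rep0[name].shape)
        data[:, i] = np.clip(noisy, 0, None)

    stack = ImageStack(
        data=data, channels=channels, px_per_um=g.px_per_um, z_step_um=g.z_step_um
    )
    truth = GroundTruth(
        table=table,
        label_volume=label_volume,
        footprint=footprint,
        geometry=g,
        expression=e,
    )
    return stack, truth


# ----------------------------------------------------------------------
def truth_state_table(truth: GroundTruth) -> pd.DataFrame:
    """Flat per-cell table of file membership and per-reporter true states."""
    cols = ["cell_id", "file_id", "pos_in_file"]
    cols += [c for c in truth.table.columns if c.startswith("state_")]
    cols += [c for c in truth.table.columns if c.startswith("true_mean_")]
    return truth.table[cols].copy()


def simulate_state_table(
    expression: ExpressionModel, n_files: int, cells_per_file: int, seed: int
) -> pd.DataFrame:
    """Draw per-cell states from the generative model without rendering images.

    Uses the same state-drawing code as :func:`generate_root`; intended for
    statistical studies (coherence, cis/trans power) that do not need pixels.
    """
    ss = np.random.SeedSequence(seed)
    _, rng_state, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    file_states = _draw_states(rng_state, n_files, expression)
    cells = _cell_states(rng_state, file_states, cells_per_file, expression.switch_noise)
    rows = []
    cid = 0
    for f in range(n_files):
        for p in range(cells_per_file):
            cid += 1
            rec = {"cell_id": cid, "file_id": f, "pos_in_file": p}
            for ir, name in enumerate(expression.reporter_names):
                rec[f"state_{name}"] = ON if cells[f, p, ir] else OFF
            rows.append(rec)
    return pd.DataFrame.from_records(rows)


#: nuclear volume fraction of a reconstructed cell under the default
#: geometry (nucleus px / cell px over the intersected planes); the range
#: reflects the 2-vs-3-plane sampling of the nucleus.
NUCLEUS_FRACTION_RANGE = (0.18, 0.30)


def simulate_cell_means(
    expression: ExpressionModel,
    n_files: int,
    cells_per_file: int,
    seed: int,
    nucleus_fraction_range: tuple[float, float] = NUCLEUS_FRACTION_RANGE,
) -> pd.DataFrame:
    """Per-cell mean intensities drawn from the generative model directly.

    Emulates what the measurement stage produces on a rendered stack: each
    cell mean is background plus the nuclear volume fraction times the
    nuclear excess intensity, with a small measurement error (per-pixel
    detector noise averaged over the ~3000 voxels of a reconstructed cell).
    Depth attenuation is not applied (equivalent to bleach_rate = 0).
    """
    table = simulate_state_table(expression, n_files, cells_per_file, seed)
    ss = np.random.SeedSequence(seed)
    *_, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    lo, hi = nucleus_fraction_range
    n = len(table)
    for name in expression.reporter_names:
        frac = rng_noise.uniform(lo, hi, n)
        on = table[f"state_{name}"].to_numpy() == ON
        level = np.where(on, expression.on_intensity, expression.off_intensity)
        mean = expression.background + frac * (level - expression.background)
        mean = mean + rng_noise.normal(0.0, expression.noise_sd / 30.0, n)
        table[f"mean_{name}"] = np.clip(mean, 1e-6, None)
    return table
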