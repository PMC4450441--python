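"""Linking of 2D cell regions across consecutive z-planes into 3D cells.

Two regions in neighbouring optical sections are considered parts of the
same cell when (i) their centroids lie within 20 px of each other and
(ii) their relative areas differ by at most 50 % (``|a1-a2|/max(a1,a2)``).
Chains are additionally capped at 18 um of z extent (6 planes at the 3 um
step).  Within each plane pair, regions are matched one-to-one by a
minimum-total-centroid-distance optimal assignment restricted to pairs
meeting both criteria; this is deterministic and order-independent, unlike
first-come greedy matching.

Tie-breaking is folded into the scalar assignment cost::

    cost(i, j) = dist + 1e-6 * rel_area_diff + 1e-9 * label_i + 1e-12 * label_j

so exact distance ties resolve by smaller area difference, then lower labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import PlaneSegmentation

#: cost assigned to pairs violating a linking criterion; far above any
#: feasible total, so the assignment maximises the number of links first
INFEASIBLE = 1.0e6


@dataclass
class LinkCriteria:
    """The three linking criteria, with their published defaults."""

    max_centroid_dist: float = 20.0  # px
    max_area_change: float = 0.5  # fraction of the larger area
    max_z_extent_planes: int = 6
    max_z_extent_um: float = 18.0

    def __post_init__(self) -> None:
        if (
            self.max_centroid_dist <= 0
            or self.max_area_change <= 0
            or self.max_z_extent_planes <= 0
            or self.max_z_extent_um <= 0
        ):
            raise ValueError("all linking criteria must be positive")

    def validate_z_step(self, z_step_um: float) -> None:
        expected = int(round(self.max_z_extent_um / z_step_um))
        if expected != self.max_z_extent_planes:
            raise ValueError(
                f"max_z_extent_planes={self.max_z_extent_planes} inconsistent with "
                f"{self.max_z_extent_um} um at a {z_step_um} um step"
            )


@dataclass
class Cell3D:
    """A reconstructed cell: linked 2D regions on strictly consecutive planes.

    ``total_area_px`` (the summed member areas) is the volume proxy used as
    the denominator of the mean-intensity formula; ``depth_um`` is the mean
    distance of the cell from the top focal plane.
    """

    cell_id: int
    regions: list[tuple[int, int]]  # (plane_index, label)
    areas: list[float]
    total_area_px: float
    depth_um: float
    border_flag: bool

    @property
    def n_planes(self) -> int:
        return len(self.regions)


def relative_area_diff(a1: float, a2: float) -> float:
    """Symmetric relative area difference ``|a1 - a2| / max(a1, a2)``."""
    if a1 <= 0 or a2 <= 0:
        raise ValueError("areas must be positive")
    return abs(a1 - a2) / max(a1, a2)


def pair_cost(dist: float, rel: float, label_a: int, label_b: int) -> float:
    """Scalar assignment cost with deterministic tie-breaking (see module doc)."""
    return dist + 1e-6 * rel + 1e-9 * label_a + 1e-12 * label_b


def match_adjacent(
    regions_a, regions_b, criteria: LinkCriteria
) -> list[tuple[int, int]]:
    """One-to-one matching between region tables of two adjacent planes.

    Returns (label_a, label_b) pairs; every pair satisfies both linking
    criteria, the matching has maximum cardinality among criterion-respecting
    matchings, and among those it minimises the total centroid distance.
    """
    if len(regions_a) == 0 or len(regions_b) == 0:
        return []
    la = regions_a["label"].to_numpy()
    lb = regions_b["label"].to_numpy()
    pa = regions_a[["row", "col"]].to_numpy(dtype=float)
    pb = regions_b[["row", "col"]].to_numpy(dtype=float)
    aa = regions_a["area_px"].to_numpy(dtype=float)
    ab = regions_b["area_px"].to_numpy(dtype=float)

    dist = np.hypot(
        pa[:, 0:1] - pb[None, :, 0], pa[:, 1:2] - pb[None, :, 1]
    )
    rel = np.abs(aa[:, None] - ab[None, :]) / np.maximum(aa[:, None], ab[None, :])
    feasible = (dist <= criteria.max_centroid_dist) & (rel <= criteria.max_area_change)
    cost = dist + 1e-6 * rel + 1e-9 * la[:, None] + 1e-12 * lb[None, :]
    cost = np.where(feasible, cost, INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(la[i]), int(lb[j]))
        for i, j in zip(rows, cols)
        if cost[i, j] < INFEASIBLE
    ]


def link_planes(
    segs: list[PlaneSegmentation],
    criteria: LinkCriteria | None = None,
    z_step_um: float = 3.0,
    min_planes: int = 2,
) -> list[Cell3D]:
    """Assemble per-plane regions into 3D cells.

    Matches regions between every pair of planes with consecutive indices
    (no plane skipping), walks the resulting forward links into chains,
    cuts chains after ``max_z_extent_planes`` planes, and keeps chains
    spanning at least ``min_planes`` planes (default 2: nuclei span 2-3
    planes, and single-plane fragments are mostly segmentation noise).
    """
    if criteria is None:
        criteria = LinkCriteria()
    criteria.validate_z_step(z_step_um)
    segs = sorted(segs, key=lambda s: s.plane_index)
    by_plane = {s.plane_index: s for s in segs}
    if len(by_plane) != len(segs):
        raise ValueError("duplicate plane_index in segmentations")

    forward: dict[tuple[int, int], tuple[int, int]] = {}
    has_incoming: set[tuple[int, int]] = set()
    for s in segs:
        nxt = by_plane.get(s.plane_index + 1)
        if nxt is None:
            continue
        for la, lb in match_adjacent(s.regions, nxt.regions, criteria):
            forward[(s.plane_index, la)] = (nxt.plane_index, lb)
            has_incoming.add((nxt.plane_index, lb))

    area_of: dict[tuple[int, int], float] = {}
    border_of: dict[tuple[int, int], bool] = {}
    for s in segs:
        for rec in s.regions.itertuples():
            area_of[(s.plane_index, rec.label)] = float(rec.area_px)
            border_of[(s.plane_index, rec.label)] = bool(rec.border)

    cells: list[Cell3D] = []
    cid = 0
    for s in segs:
        for lab in sorted(s.regions["label"].tolist()):
            node = (s.plane_index, int(lab))
            if node in has_incoming:
                continue
            chain = [node]
            while chain[-1] in forward:
                chain.append(forward[chain[-1]])
            # cut after every max_z_extent_planes planes
            for start in range(0, len(chain), criteria.max_z_extent_planes):
                seg_chain = chain[start : start + criteria.max_z_extent_planes]
                if len(seg_chain) < min_planes:
                    continue
                cid += 1
                areas = [area_of[n] for n in seg_chain]
                planes = [n[0] for n in seg_chain]
                cells.append(
                    Cell3D(
                        cell_id=cid,
                        regions=seg_chain,
                        areas=areas,
                        total_area_px=float(sum(areas)),
                        depth_um=float(np.mean(planes) * z_step_um),
                        border_flag=any(border_of[n] for n in seg_chain),
                    )
                )
    return cells


def audit_cells(
    cells: list[Cell3D],
    segs: list[PlaneSegmentation],
    criteria: LinkCriteria | None = None,
    z_step_um: float = 3.0,
) -> list[str]:
    """Post-hoc audit of every reconstructed cell against the criteria.

    Re-checks, from the recorded region tables and independently of the
    matching code path, that every adjacent region pair inside every cell
    satisfies both linking criteria, that plane indices are strictly
    consecutive, that no cell exceeds the z-extent cap, and that no 2D
    region is used by more than one cell.  Returns a list of violation
    descriptions (empty when the reconstruction is sound).
    """
    if criteria is None:
        criteria = LinkCriteria()
    info: dict[tuple[int, int], tuple[float, float, float]] = {}
    for s in segs:
        for rec in s.regions.itertuples():
            info[(s.plane_index, rec.label)] = (rec.row, rec.col, rec.area_px)

    problems: list[str] = []
    seen: set[tuple[int, int]] = set()
    for cell in cells:
        if cell.n_planes > criteria.max_z_extent_planes:
            problems.append(f"cell {cell.cell_id}: spans {cell.n_planes} planes")
        if (cell.n_planes - 1) * z_step_um > criteria.max_z_extent_um:
            problems.append(f"cell {cell.cell_id}: physical extent exceeds cap")
        for node in cell.regions:
            if node in seen:
                problems.append(f"region {node} used by more than one cell")
            seen.add(node)
        for (p1, l1), (p2, l2) in zip(cell.regions, cell.regions[1:]):
            if p2 != p1 + 1:
                problems.append(f"cell {cell.cell_id}: non-consecutive planes")
                continue
            r1, c1, a1 = info[(p1, l1)]
            r2, c2, a2 = info[(p2, l2)]
            d = float(np.hypot(r1 - r2, c1 - c2))
            if d > criteria.max_centroid_dist:
                problems.append(f"cell {cell.cell_id}: centroid distance {d:.2f} px")
            if relative_area_diff(a1, a2) > criteria.max_area_change:
                problems.append(f"cell {cell.cell_id}: area change too large")
    return problems
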