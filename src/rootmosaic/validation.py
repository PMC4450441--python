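"""Scoring of the automated pipeline against reference measurements.

Mirrors the manual validation of the original analysis: a random sample of
reconstructed cells is compared against reference per-cell means (synthetic
ground truth here, or a user-supplied table of manual measurements), and a
cell counts as accurate when its automated mean is within a relative-error
tolerance of the reference.  Automated cells that cannot be paired to any
reference cell are incorrectly segmented and count as inaccurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import CellMeasurement
from .reconstruct import Cell3D
from .segmentation import PlaneSegmentation
from .synthetic import GroundTruth


@dataclass
class ValidationReport:
    n_cells_checked: int
    n_accurate: int
    accuracy: float
    tolerance: float
    per_cell: pd.DataFrame  # cell_id, truth_id, auto, reference, rel_error, accurate


def match_cells(
    auto_cells: list[Cell3D],
    segs: list[PlaneSegmentation],
    truth: GroundTruth,
) -> dict[int, int]:
    """Pair each automated cell with the true cell owning most of its pixels.

    A cell pairs with the truth label holding the strict majority (> 50 %)
    of its voxels; at most one automated cell may claim a given true cell
    (largest overlap wins).  Returns ``{auto_cell_id: truth_cell_id}``.
    """
    by_plane = {s.plane_index: s for s in segs}
    overlap_best: dict[int, tuple[int, int, int]] = {}
    for cell in auto_cells:
        counts: dict[int, int] = {}
        total = 0
        for p, lab in cell.regions:
            seg = by_plane[p]
            if seg.labels is None:
                raise ValueError("matching requires label images")
            sel = seg.labels == lab
            truth_px = truth.label_volume[p][sel]
            total += truth_px.size
            ids, cnt = np.unique(truth_px, return_counts=True)
            for i, c in zip(ids, cnt):
                if i > 0:
                    counts[int(i)] = counts.get(int(i), 0) + int(c)
        if not counts or total == 0:
            continue
        best_id, best_n = max(counts.items(), key=lambda kv: kv[1])
        if best_n * 2 > total:
            overlap_best[cell.cell_id] = (best_id, best_n, total)

    # enforce at most one automated cell per true cell: largest overlap wins
    by_truth: dict[int, tuple[int, int]] = {}
    for auto_id, (tid, n, _) in overlap_best.items():
        if tid not in by_truth or n > by_truth[tid][1]:
            by_truth[tid] = (auto_id, n)
    return {auto_id: tid for tid, (auto_id, _) in by_truth.items()}


def accuracy_audit(
    pairing: dict[int, int],
    measurements: list[CellMeasurement],
    truth: GroundTruth,
    channel: str = "reporter_1",
    tolerance: float = 0.2,
    sample_n: int = 50,
    seed: int = 0,
    included_only: bool = True,
) -> ValidationReport:
    """Audit a random sample of automated cells against reference means.

    Draws ``sample_n`` automated cells at random (seeded).  Paired cells are
    accurate when ``|auto - reference| / reference <= tolerance``; unpaired
    cells (incorrect segmentations) are sampled in proportion and always
    count as inaccurate.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    pool = [m for m in measurements if m.included or not included_only]
    if not pool:
        return ValidationReport(0, 0, np.nan, tolerance, pd.DataFrame())
    if sample_n > len(pool):
        warnings.warn(
            f"requested {sample_n} cells but only {len(pool)} available: using all"
        )
        sample = pool
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=sample_n, replace=False)
        sample = [pool[i] for i in sorted(idx)]

    ref_means = truth.table.set_index("cell_id")[f"true_mean_{channel}"]
    rows = []
    for m in sample:
        tid = pairing.get(m.cell_id)
        if tid is None or tid not in ref_means.index:
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "truth_id": -1,
                    "auto": m.means[channel],
                    "reference": np.nan,
                    "rel_error": np.nan,
                    "accurate": False,
                }
            )
            continue
        ref = float(ref_means.loc[tid])
        rel = abs(m.means[channel] - ref) / ref
        rows.append(
            {
                "cell_id": m.cell_id,
                "truth_id": tid,
                "auto": m.means[channel],
                "reference": ref,
                "rel_error": rel,
                "accurate": bool(rel <= tolerance),
            }
        )
    per_cell = pd.DataFrame(rows)
    n_acc = int(per_cell["accurate"].sum())
    return ValidationReport(
        n_cells_checked=len(per_cell),
        n_accurate=n_acc,
        accuracy=n_acc / len(per_cell),
        tolerance=tolerance,
        per_cell=per_cell,
    )


def pooled_accuracy_audit(
    items: list[tuple[dict[int, int], list[CellMeasurement], GroundTruth]],
    channel: str = "reporter_1",
    tolerance: float = 0.2,
    sample_n: int = 50,
    seed: int = 0,
) -> ValidationReport:
    """Accuracy audit over a pooled random sample from several roots.

    ``items`` holds one ``(pairing, measurements, truth)`` triple per root.
    A single seeded sample of ``sample_n`` cells is drawn from the pooled
    included cells of all roots, mimicking a manual validation drawn across
    roots.
    """
    pool = [
        (idx, m)
        for idx, (_, measurements, _) in enumerate(items)
        for m in measurements
        if m.included
    ]
    rng = np.random.default_rng(seed)
    if sample_n > len(pool):
        warnings.warn("sample larger than pooled cells: using all")
        chosen = pool
    else:
        sel = rng.choice(len(pool), size=sample_n, replace=False)
        chosen = [pool[i] for i in sorted(sel)]

    frames = []
    n_acc = 0
    for idx, m in chosen:
        pairing, _, truth = items[idx]
        rep = accuracy_audit(
            pairing, [m], truth, channel=channel, tolerance=tolerance,
            sample_n=1, seed=0,
        )
        frames.append(rep.per_cell.assign(root=idx))
        n_acc += rep.n_accurate
    per_cell = pd.concat(frames, ignore_index=True)
    return ValidationReport(
        n_cells_checked=len(per_cell),
        n_accurate=n_acc,
        accuracy=n_acc / len(per_cell),
        tolerance=tolerance,
        per_cell=per_cell,
    )
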