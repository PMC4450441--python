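"""End-to-end orchestration: mask -> segment -> link -> measure -> classify.

The pipeline stages and their parameters are collected in a single
serialisable :class:`PipelineConfig`; :func:`run_pipeline` executes the
stages on one stack and returns the per-cell table together with per-stage
counts (planes, 2D regions, linked cells, cells surviving the depth filter),
mirroring the per-run statistics reported for the original analysis.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, quantify, segmentation, validation
from .reconstruct import LinkCriteria, link_planes
from .stack import ImageStack
from .synthetic import ExpressionModel, GroundTruth, RootGeometry, generate_root


@dataclass
class SegmentationParams:
    gauss_sd: float = 2.0
    threshold_radius: int = 40
    threshold_offset_frac: float = 0.02
    min_region_area: int = 50
    closing_radius: int = 5


@dataclass
class DepthFilterParams:
    method: str = "plateau"  # or "manual"
    tol: float = 0.15
    d_cut_um: float | None = None
    channel: str | None = None  # default: first reporter channel


@dataclass
class ClassifyParams:
    fallback_threshold: float = analysis.DEFAULT_FALLBACK_THRESHOLD
    random_state: int = 0


@dataclass
class ValidationParams:
    tolerance: float = 0.2
    sample_n: int = 50


@dataclass
class PipelineConfig:
    """All stage parameters, serialisable to/from a single YAML file."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    linking: LinkCriteria = field(default_factory=LinkCriteria)
    min_planes: int = 2
    depth_filter: DepthFilterParams = field(default_factory=DepthFilterParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    align: bool = False
    seed: int = 0

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown config keys for {klass.__name__}: {sorted(unknown)}")
            return klass(**sub)

        top_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - top_names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        sub_types = {
            "segmentation": SegmentationParams,
            "linking": LinkCriteria,
            "depth_filter": DepthFilterParams,
            "classify": ClassifyParams,
            "validation": ValidationParams,
        }
        for key, klass in sub_types.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = build(klass, kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PipelineResult:
    cell_table: pd.DataFrame
    stage_counts: dict[str, int]
    depth_profile: quantify.DepthProfile | None
    classify_info: dict
    segs: list
    cells: list
    measurements: list
    validation_report: validation.ValidationReport | None = None
    pairing: dict[int, int] | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
    root_id: str = "root0",
    classify: bool = True,
) -> PipelineResult:
    """Run mask/segment -> link -> measure -> depth-filter -> classify.

    When ``truth`` is given, automated cells are additionally matched to
    ground truth and an accuracy audit is attached to the result.
    Classification needs >= 20 included cells; with fewer, states are left
    uncalled and a warning is issued.
    """
    if config is None:
        config = PipelineConfig()
    counts: dict[str, int] = {"planes": stack.n_planes}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    if config.align:
        from .stack import align_stack

        stack, _ = stage("align", align_stack, stack)

    sp = config.segmentation
    segs = stage(
        "segment",
        segmentation.segment_stack,
        stack,
        gauss_sd=sp.gauss_sd,
        threshold_radius=sp.threshold_radius,
        threshold_offset_frac=sp.threshold_offset_frac,
        min_region_area=sp.min_region_area,
        closing_radius=sp.closing_radius,
    )
    counts["regions_2d"] = int(sum(s.n_regions for s in segs))

    cells = stage(
        "link",
        link_planes,
        segs,
        config.linking,
        z_step_um=stack.z_step_um,
        min_planes=config.min_planes,
    )
    counts["cells_3d"] = len(cells)

    measurements = stage(
        "measure", quantify.measure_cells, cells, segs, stack, root_id=root_id
    )

    dp = config.depth_filter
    profile = None
    if measurements:
        profile, measurements = stage(
            "depth_filter",
            quantify.depth_filter,
            measurements,
            channel=dp.channel,
            method=dp.method,
            tol=dp.tol,
            d_cut_um=dp.d_cut_um,
            z_step_um=stack.z_step_um,
        )
    counts["cells_included"] = int(sum(m.included for m in measurements))

    table = quantify.measurements_frame(measurements)
    infos: dict = {}
    if classify and counts["cells_included"] >= 20:
        reporters = stack.reporter_channels
        incl = table[table["included"] & ~table["border"]].copy()
        called, infos = stage(
            "classify",
            analysis.call_states,
            incl,
            reporters,
            fallback_threshold=config.classify.fallback_threshold,
            random_state=config.classify.random_state,
        )
        state_cols = [c for c in called.columns if c.startswith(("state_", "margin_"))]
        table = table.merge(
            called[["cell_id"] + state_cols], on="cell_id", how="left"
        )
    elif classify:
        warnings.warn("fewer than 20 included cells: state calls skipped")
    counts["cells_classified"] = int(
        table.filter(like="state_").notna().any(axis=1).sum()
    ) if len(table) else 0

    report = None
    pairing = None
    if truth is not None and cells:
        pairing = stage("validate", validation.match_cells, cells, segs, truth)
        vp = config.validation
        report = stage(
            "validate",
            validation.accuracy_audit,
            pairing,
            measurements,
            truth,
            tolerance=vp.tolerance,
            sample_n=vp.sample_n,
            seed=config.seed,
        )
    return PipelineResult(
        cell_table=table,
        stage_counts=counts,
        depth_profile=profile,
        classify_info=infos,
        segs=segs,
        cells=cells,
        measurements=measurements,
        validation_report=report,
        pairing=pairing,
    )


def run_synthetic_batch(
    n_roots: int,
    geometry: RootGeometry | None = None,
    expression: ExpressionModel | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    classify: bool = False,
) -> tuple[pd.DataFrame, list[PipelineResult], list[GroundTruth]]:
    """Simulate and process a batch of roots; returns the pooled cell table.

    Root seeds are spawned deterministically from the master seed.  Per-root
    truth is attached, so every result carries a pairing and an accuracy
    audit.  Classification is usually done on the pooled table afterwards
    (as in the original analysis, which pools cells over roots per
    treatment).
    """
    geometry = geometry or RootGeometry()
    expression = expression or ExpressionModel()
    config = config or PipelineConfig()
    root_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n_roots)]
    tables = []
    results = []
    truths = []
    for i, rs in enumerate(root_seeds):
        stack, truth = generate_root(geometry, expression, seed=rs)
        res = run_pipeline(
            stack, config, truth=truth, root_id=f"root{i}", classify=classify
        )
        tables.append(res.cell_table)
        results.append(res)
        truths.append(truth)
    pooled = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return pooled, results, truths
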