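"""Mean-intensity formula, conservation, depth filtering, heat maps."""

import warnings

import numpy as np
import pytest

import rootmosaic as rm
from rootmosaic.quantify import CellMeasurement
from rootmosaic.reconstruct import Cell3D
from rootmosaic.segmentation import PlaneSegmentation


def _toy_setup(values_by_plane):
    """Two 6x6 planes with one 10-px region each; wall channel is zeros."""
    segs, planes = [], []
    for p, v in enumerate(values_by_plane):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2:4, 0:5] = 1  # 10 px
        img = np.zeros((6, 6))
        img[2:4, 0:5] = v
        segs.append(
            PlaneSegmentation(
                plane_index=p,
                labels=labels,
                regions=__import__("pandas").DataFrame(
                    [{"label": 1, "row": 2.5, "col": 2.0, "area_px": 10.0, "border": False}]
                ),
            )
        )
        planes.append(img)
    data = np.stack(
        [np.stack([np.zeros((6, 6)), img]) for img in planes]
    )  # (planes, 2ch, 6, 6)
    stack = rm.ImageStack(data=data, channels=["wall", "reporter_1"])
    cell = Cell3D(
        cell_id=1,
        regions=[(p, 1) for p in range(len(values_by_plane))],
        areas=[10.0] * len(values_by_plane),
        total_area_px=10.0 * len(values_by_plane),
        depth_um=3.0 * (len(values_by_plane) - 1) / 2,
        border_flag=False,
    )
    return [cell], segs, stack


def test_mean_is_total_intensity_over_total_area():
    # plane sums 100 and 300 over areas 10 + 10 -> mean = 400 / 20 = 20
    cells, segs, stack = _toy_setup([10.0, 30.0])
    meas = rm.measure_cells(cells, segs, stack)
    assert meas[0].means["reporter_1"] == pytest.approx(20.0)


def test_uniform_channel_gives_exactly_constant_means(demo_root, demo_segs, demo_cells):
    stack, _ = demo_root
    const = stack.data.copy()
    const[:, 1] = 7.25
    uniform = rm.ImageStack(const, channels=stack.channels, z_step_um=stack.z_step_um)
    meas = rm.measure_cells(demo_cells, demo_segs, uniform)
    for m in meas:
        assert m.means["reporter_1"] == pytest.approx(7.25, rel=1e-6)


def test_missing_channel_rejected(demo_root, demo_segs, demo_cells):
    stack, _ = demo_root
    with pytest.raises(KeyError):
        rm.measure_cells(demo_cells, demo_segs, stack, channels=["reporter_9"])


def test_out_of_range_plane_rejected(demo_root, demo_segs):
    stack, _ = demo_root
    bad = Cell3D(1, [(99, 1)], [10.0], 10.0, 0.0, False)
    with pytest.raises(ValueError):
        rm.measure_cells([bad], demo_segs, stack)


def test_noise_free_measurements_match_truth(small_geometry):
    e = rm.ExpressionModel(p_on=0.5, noise_sd=0.0, bleach_rate=0.0)
    stack, truth = rm.generate_root(small_geometry, e, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segs = rm.segment_stack(stack)
    cells = rm.link_planes(segs, rm.LinkCriteria())
    meas = rm.measure_cells(cells, segs, stack)
    pairing = rm.match_cells(cells, segs, truth)
    ref = truth.table.set_index("cell_id")["true_mean_reporter_1"]
    rel = [
        abs(m.means["reporter_1"] - ref.loc[pairing[m.cell_id]])
        / ref.loc[pairing[m.cell_id]]
        for m in meas
        if m.cell_id in pairing
    ]
    assert np.mean(np.array(rel) <= 0.10) >= 0.8


def test_intensity_is_conserved_over_cells(demo_root, demo_segs, demo_cells):
    """Sum(mean x area) equals the total intensity over all cell pixels."""
    stack, _ = demo_root
    meas = rm.measure_cells(demo_cells, demo_segs, stack)
    lhs = sum(m.means["reporter_1"] * m.total_area_px for m in meas)
    rep = stack.channel("reporter_1")
    by_plane = {s.plane_index: s for s in demo_segs}
    rhs = 0.0
    for cell in demo_cells:
        for p, lab in cell.regions:
            rhs += float(rep[p][by_plane[p].labels == lab].sum())
    assert lhs == pytest.approx(rhs, rel=1e-6)


# ---------------------------------------------------------------------
def _measured_root(bleach, p_on=1.0, seed=8):
    g = rm.RootGeometry(n_files=4, cells_per_file=6, n_layers=4)
    e = rm.ExpressionModel(p_on=p_on, bleach_rate=bleach)
    stack, truth = rm.generate_root(g, e, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segs = rm.segment_stack(stack)
    cells = rm.link_planes(segs, rm.LinkCriteria())
    return rm.measure_cells(cells, segs, stack)


def test_no_bleaching_excludes_nothing():
    meas = _measured_root(bleach=0.0)
    profile, filtered = rm.depth_filter(meas)
    assert profile.d_cut_um == profile.depths_um.max()
    assert all(m.included for m in filtered)


def test_strong_bleaching_cuts_the_profile():
    meas = _measured_root(bleach=0.10)
    profile, filtered = rm.depth_filter(meas)
    assert profile.d_cut_um < profile.depths_um.max()
    excluded = {m.cell_id for m in filtered if not m.included}
    expected = {m.cell_id for m in meas if m.depth_um > profile.d_cut_um + 1.5}
    assert excluded == expected
    assert len(excluded) > 0


def test_manual_cut_at_zero_keeps_only_top_bin():
    meas = _measured_root(bleach=0.0)
    _, filtered = rm.depth_filter(meas, method="manual", d_cut_um=0.0)
    for m in filtered:
        assert m.included == (m.depth_um <= 1.5)
    assert any(not m.included for m in filtered)


def test_depth_filter_is_idempotent():
    meas = _measured_root(bleach=0.10)
    p1, f1 = rm.depth_filter(meas)
    p2, f2 = rm.depth_filter(f1)
    assert p2.d_cut_um >= p1.d_cut_um - 1e-9
    assert [m.included for m in f1] == [m.included for m in f2]


def test_too_few_depths_warns_and_keeps_everything():
    meas = [
        CellMeasurement(cell_id=i, means={"reporter_1": 10.0}, total_area_px=10,
                        n_planes=2, depth_um=d, border_flag=False)
        for i, d in enumerate([3.0, 3.0, 6.0])
    ]
    with pytest.warns(UserWarning):
        _, filtered = rm.depth_filter(meas)
    assert all(m.included for m in filtered)


# ---------------------------------------------------------------------
def test_heatmap_is_nonzero_exactly_on_reconstructed_cells(
    demo_root, demo_segs, demo_cells, demo_measurements
):
    _, truth = demo_root
    p = int(truth.table["plane_lo"].iloc[0])
    img = rm.render_heatmap(demo_cells, demo_measurements, demo_segs, p)
    covered = np.zeros_like(img, dtype=bool)
    for cell in demo_cells:
        for q, lab in cell.regions:
            if q == p:
                covered |= demo_segs[p].labels == lab
    assert (img[covered] > 0).all()
    assert (img[~covered] == 0).all()


def test_heatmap_empty_plane_is_black(demo_cells, demo_measurements, demo_segs):
    empty = [s for s in demo_segs if s.n_regions == 0]
    if not empty:
        pytest.skip("phantom produced no empty plane")
    img = rm.render_heatmap(demo_cells, demo_measurements, demo_segs, empty[0].plane_index)
    assert (img == 0).all()


def test_heatmap_single_cell_colour():
    cells, segs, stack = _toy_setup([10.0, 30.0])
    meas = rm.measure_cells(cells, segs, stack)
    img = rm.render_heatmap(cells, meas, segs, 0)
    assert img[segs[0].labels == 1].min() == pytest.approx(20.0)
    assert img[segs[0].labels == 0].max() == 0.0
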