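"""Layout construction, compartment queries, motion, serialization."""

import json

import numpy as np
import pytest

from rirrsim.exceptions import CapacityError, DomainError, ParameterError
from rirrsim.geometry import (
    CYTOSOL,
    CellGeometry,
    MotionSpec,
    compartment_of,
    make_gradient_layout,
    make_irregular_layout,
    make_layout,
    make_low_density_layout,
    make_moving_layout,
    make_regular_layout,
)


def brute_force_compartment(point, geometry, t=0):
    """Independent oracle: linear scan over all rectangles."""
    x, y = point
    for m, (rx, ry, rw, rh) in zip(geometry.mitochondria, geometry.rects_at(t)):
        if rx <= x < rx + rw and ry <= y < ry + rh:
            return m.id
    return CYTOSOL


def assert_no_overlaps_inside(geometry, t=0):
    rects = geometry.rects_at(t)
    for i in range(len(rects)):
        x, y, w, h = rects[i]
        assert 0 <= x and x + w <= geometry.grid_width
        assert 0 <= y and y + h <= geometry.grid_height
        for j in range(i + 1, len(rects)):
            x2, y2, w2, h2 = rects[j]
            assert not (x < x2 + w2 and x2 < x + w and y < y2 + h2 and y2 < y + h), (
                f"rects {i} and {j} overlap"
            )


class TestRegularLayout:
    def test_cardiomyocyte_lattice(self):
        geo = make_regular_layout(rows=9, cols=9)
        assert geo.n_mitochondria == 81
        assert (geo.grid_width, geo.grid_height) == (972, 684)
        assert_no_overlaps_inside(geo)

    def test_degenerate_single_cell(self):
        geo = make_regular_layout(rows=1, cols=1, margin=0)
        assert (geo.grid_width, geo.grid_height) == (54, 54)
        assert geo.mitochondria[0].rect_at(0) == (0, 0, 54, 54)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            make_regular_layout(mito_side=0)
        with pytest.raises(ParameterError):
            make_regular_layout(rows=0)
        with pytest.raises(ParameterError):
            make_regular_layout(margin=-1)


class TestLowDensityLayout:
    def test_counts_and_shared_cell_size(self):
        low = make_low_density_layout()
        ref = make_regular_layout()
        assert low.n_mitochondria == 25
        assert (low.grid_width, low.grid_height) == (ref.grid_width, ref.grid_height)
        # pixel coverage ratio 81/25
        assert ref.sizes.sum() / low.sizes.sum() == pytest.approx(3.24)

    def test_uniform_spacing(self):
        low = make_low_density_layout()
        xs = sorted({m.x for m in low.mitochondria})
        ys = sorted({m.y for m in low.mitochondria})
        assert np.ptp(np.diff(xs)) <= 1  # integer rounding only
        assert np.ptp(np.diff(ys)) <= 1
        assert_no_overlaps_inside(low)


class TestRandomLayouts:
    def test_irregular_seeded_determinism(self):
        a = make_irregular_layout(n=81, seed=1)
        b = make_irregular_layout(n=81, seed=1)
        assert np.array_equal(a.rects_at(0), b.rects_at(0))

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_irregular_no_overlaps(self, seed):
        assert_no_overlaps_inside(make_irregular_layout(n=81, seed=seed))

    def test_irregular_empty(self):
        geo = make_irregular_layout(n=0, seed=0)
        assert geo.n_mitochondria == 0
        assert geo.grid_width > 0

    def test_capacity_error_when_overfull(self):
        with pytest.raises(CapacityError):
            make_irregular_layout(n=50, seed=0, grid=(200, 200))

    def test_gradient_is_center_biased(self):
        ref = make_regular_layout()
        c = np.array([ref.grid_width / 2, ref.grid_height / 2])

        def mean_dist(geo):
            centers = geo.rects_at(0)[:, :2] + 27.0
            return np.linalg.norm(centers - c, axis=1).mean()

        grad = np.mean([mean_dist(make_gradient_layout(n=81, seed=s)) for s in range(20)])
        irr = np.mean([mean_dist(make_irregular_layout(n=81, seed=s)) for s in range(20)])
        assert grad < irr

    def test_gradient_single_mitochondrion_near_center(self):
        ref = make_regular_layout()
        c = np.array([ref.grid_width / 2, ref.grid_height / 2])
        dists = []
        for s in range(100):
            geo = make_gradient_layout(n=1, seed=s)
            center = geo.rects_at(0)[0, :2] + 27.0
            dists.append(np.linalg.norm(center - c))
        # mean offset ~ sigma * sqrt(pi/2) ~ 203 px; an unbiased uniform draw
        # would average ~ 300 px from the center of a 972 x 684 grid
        assert np.mean(dists) < 260

    def test_gradient_large_sigma_approaches_irregular(self):
        def mean_dist(geo):
            ref = make_regular_layout()
            c = np.array([ref.grid_width / 2, ref.grid_height / 2])
            centers = geo.rects_at(0)[:, :2] + 27.0
            return np.linalg.norm(centers - c, axis=1).mean()

        irr = np.mean([mean_dist(make_irregular_layout(n=40, seed=s)) for s in range(10)])
        tight = np.mean([mean_dist(make_gradient_layout(n=40, sigma=80, seed=s)) for s in range(10)])
        wide = np.mean([mean_dist(make_gradient_layout(n=40, sigma=5000, seed=s)) for s in range(10)])
        assert abs(wide - irr) < abs(tight - irr)


class TestMovingLayout:
    def test_peripheral_ring_size(self):
        geo = make_moving_layout()
        moving = [m for m in geo.mitochondria if m.motion is not None]
        assert len(moving) == 32
        assert geo.n_mitochondria == 81

    def test_triangle_wave_period(self):
        spec = MotionSpec(amplitude=18, speed=1)
        offsets = [spec.offset(t) for t in range(37)]
        assert offsets[0] == 0.0
        assert offsets[36] == 0.0  # one full period
        assert min(offsets) == -18.0
        assert max(np.abs(np.diff(offsets))) == 1.0

    def test_interior_static(self):
        geo = make_moving_layout()
        interior = geo.mitochondria[40]  # row 4, col 4
        assert interior.motion is None
        assert interior.rect_at(1000) == interior.rect_at(0)

    def test_no_overlap_over_full_period(self):
        geo = make_moving_layout()
        for t in range(37):
            assert_no_overlaps_inside(geo, t)


class TestCompartmentQuery:
    def test_half_open_corners(self):
        geo = make_regular_layout()
        m = geo.mitochondria[0]
        assert compartment_of((m.x, m.y), geo) == m.id  # top-left corner inside
        assert compartment_of((m.x + m.w, m.y), geo) == CYTOSOL  # right edge outside

    def test_outside_grid_rejected(self):
        geo = make_regular_layout()
        with pytest.raises(DomainError):
            compartment_of((-0.1, 5.0), geo)
        with pytest.raises(DomainError):
            compartment_of((5.0, geo.grid_height), geo)

    @pytest.mark.parametrize("builder,seed", [(make_irregular_layout, 3), (None, None)])
    def test_agrees_with_brute_force(self, builder, seed, rng):
        geo = make_irregular_layout(n=40, seed=seed) if builder else make_regular_layout()
        pts = rng.uniform(size=(10_000, 2)) * [geo.grid_width, geo.grid_height]
        lab = geo.label_map(0)
        for p in pts[:200]:  # exact oracle on a subsample
            assert compartment_of(p, geo) == brute_force_compartment(p, geo)
        # full sample against the pixel map
        ids = lab[pts[:, 1].astype(int), pts[:, 0].astype(int)]
        sub = [compartment_of(p, geo) for p in pts[:200]]
        assert np.array_equal(ids[:200], sub)


def test_json_round_trip(tmp_path):
    geo = make_moving_layout()
    path = tmp_path / "layout.json"
    geo.to_json(path)
    back = CellGeometry.from_json(path)
    assert back.to_dict() == geo.to_dict()
    d = json.loads(path.read_text())
    assert [m["id"] for m in d["mitochondria"]] == sorted(m["id"] for m in d["mitochondria"])


def test_make_layout_dispatch():
    assert make_layout("low_density").n_mitochondria == 25
    with pytest.raises(ParameterError):
        make_layout("hexagonal")
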