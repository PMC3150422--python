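"""Cell geometry and mitochondrial network layouts.

The cell is a 2D pixel grid with origin at the top-left corner. Coordinates
are continuous; the pixel containing a point is found by flooring each
coordinate. Mitochondria are axis-aligned squares (54x54 px by default, the
measured longitudinal length of a cardiomyocyte mitochondrion at the model's
resolution of 45 px/um) with integer-valued, half-open rectangles
[x, x+w) x [y, y+h). Everything outside a mitochondrion is cytosol.

Five network layouts are provided:

* ``regular``      -- the cardiomyocyte lattice, 9x9 mitochondria with 18 px
                      vertical and 54 px horizontal gaps;
* ``low_density``  -- 5x5 mitochondria on the *same* cell dimensions, so the
                      cytosolic density drops (81 -> 25) without shrinking
                      the cell;
* ``irregular``    -- uniform random non-overlapping placement (e.g. neurons);
* ``gradient``     -- perinuclear clustering, positions drawn from a truncated
                      isotropic Gaussian around the cell center;
* ``moving``       -- the regular lattice whose peripheral ring oscillates
                      vertically (rapidly moving mitochondria).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import CapacityError, DomainError, ParameterError

#: Default lattice constants, in pixels.
MITO_SIDE = 54
VGAP = 18
HGAP = 54
MARGIN = 27

CYTOSOL = -1


@dataclass(frozen=True)
class MotionSpec:
    """Vertical triangle-wave oscillation of a mitochondrion.

    The offset at step ``t`` rises from 0 to ``-amplitude`` (upward, since y
    grows downward) and back, with period ``2*amplitude/speed`` steps. An
    amplitude of one vertical gap keeps moving rectangles from ever
    overlapping their static neighbours.
    """

    amplitude: float = 0.0  # px
    speed: float = 0.0  # px per step

    def offset(self, t: int | np.ndarray) -> float | np.ndarray:
        if self.amplitude <= 0 or self.speed <= 0:
            return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
        phase = (self.speed * np.asarray(t, dtype=float)) % (2.0 * self.amplitude)
        tri = np.where(phase <= self.amplitude, phase, 2.0 * self.amplitude - phase)
        return -tri if np.ndim(t) else -float(tri)


@dataclass(frozen=True)
class Mitochondrion:
    """An axis-aligned square mitochondrion with optional vertical motion."""

    id: int
    x: int
    y: int
    w: int = MITO_SIDE
    h: int = MITO_SIDE
    motion: MotionSpec | None = None

    @property
    def size(self) -> int:
        """Pixel area of the mitochondrion."""
        return self.w * self.h

    def rect_at(self, t: int) -> tuple[int, int, int, int]:
        """(x, y, w, h) at simulation step ``t`` (motion applied)."""
        dy = 0 if self.motion is None else int(round(self.motion.offset(t)))
        return (self.x, self.y + dy, self.w, self.h)


@dataclass
class CellGeometry:
    """The cell grid plus its ordered collection of mitochondria."""

    grid_width: int
    grid_height: int
    mitochondria: list[Mitochondrion] = field(default_factory=list)
    margin: int = MARGIN
    layout_name: str = "regular"

    @property
    def n_mitochondria(self) -> int:
        return len(self.mitochondria)

    @property
    def total_pixels(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def has_motion(self) -> bool:
        return any(m.motion is not None for m in self.mitochondria)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([m.size for m in self.mitochondria], dtype=np.int64)

    def rects_at(self, t: int = 0) -> np.ndarray:
        """Integer (n, 4) array of (x, y, w, h) at step ``t``."""
        return np.array([m.rect_at(t) for m in self.mitochondria], dtype=np.int64).reshape(-1, 4)

    def label_map(self, t: int = 0) -> np.ndarray:
        """Per-pixel compartment labels at step ``t``.

        Shape (grid_height, grid_width), int32; ``CYTOSOL`` (-1) for cytosol,
        otherwise the id of the (unique, rects never overlap) mitochondrion
        covering the pixel.
        """
        lab = np.full((self.grid_height, self.grid_width), CYTOSOL, dtype=np.int32)
        for m, (x, y, w, h) in zip(self.mitochondria, self.rects_at(t)):
            lab[y : y + h, x : x + w] = m.id
        return lab

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        mitos = []
        for m in sorted(self.mitochondria, key=lambda m: m.id):
            rec = {"id": m.id, "x": m.x, "y": m.y, "w": m.w, "h": m.h}
            if m.motion is not None:
                rec["motion"] = {"amplitude": m.motion.amplitude, "speed": m.motion.speed}
            mitos.append(rec)
        return {
            "layout_name": self.layout_name,
            "grid_width": self.grid_width,
            "grid_height": self.grid_height,
            "margin": self.margin,
            "mitochondria": mitos,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellGeometry":
        mitos = []
        for rec in d["mitochondria"]:
            motion = None
            if rec.get("motion"):
                motion = MotionSpec(**rec["motion"])
            mitos.append(
                Mitochondrion(
                    id=rec["id"], x=rec["x"], y=rec["y"], w=rec["w"], h=rec["h"], motion=motion
                )
            )
        return cls(
            grid_width=d["grid_width"],
            grid_height=d["grid_height"],
            mitochondria=mitos,
            margin=d.get("margin", MARGIN),
            layout_name=d.get("layout_name", "custom"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CellGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compartment_of(point: Sequence[float], geometry: CellGeometry, t: int = 0) -> int:
    """Compartment of a point: a mitochondrion id, or ``CYTOSOL`` (-1).

    Membership uses the half-open convention: a point on a rectangle's
    top/left edge belongs to it, one on the bottom/right edge does not.
    Raises :class:`DomainError` for points outside the grid.
    """
    x, y = float(point[0]), float(point[1])
    if not (0 <= x < geometry.grid_width and 0 <= y < geometry.grid_height):
        raise DomainError(f"point ({x}, {y}) lies outside the grid")
    for m, (rx, ry, rw, rh) in zip(geometry.mitochondria, geometry.rects_at(t)):
        if rx <= x < rx + rw and ry <= y < ry + rh:
            return m.id
    return CYTOSOL


def _rects_overlap(a: tuple, b: tuple) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


# -- layout constructors ----------------------------------------------------


def make_regular_layout(
    rows: int = 9,
    cols: int = 9,
    mito_side: int = MITO_SIDE,
    vgap: int = VGAP,
    hgap: int = HGAP,
    margin: int = MARGIN,
) -> CellGeometry:
    """Rectangular lattice of ``rows`` x ``cols`` mitochondria.

    Defaults give the cardiomyocyte model: 81 mitochondria of 54 px with
    18 px vertical and 54 px horizontal gaps on a 972 x 684 px grid.
    """
    if mito_side <= 0:
        raise ParameterError("mito_side must be positive")
    if rows < 1 or cols < 1:
        raise ParameterError("rows and cols must be >= 1")
    if vgap < 0 or hgap < 0 or margin < 0:
        raise ParameterError("gaps and margin must be >= 0")
    width = cols * mito_side + (cols - 1) * hgap + 2 * margin
    height = rows * mito_side + (rows - 1) * vgap + 2 * margin
    mitos = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            mitos.append(
                Mitochondrion(
                    id=k,
                    x=margin + c * (mito_side + hgap),
                    y=margin + r * (mito_side + vgap),
                    w=mito_side,
                    h=mito_side,
                )
            )
            k += 1
    return CellGeometry(width, height, mitos, margin=margin, layout_name="regular")


def make_low_density_layout(rows: int = 5, cols: int = 5) -> CellGeometry:
    """Low-density lattice on the *same* cell dimensions as the 9x9 layout.

    Spacing is rescaled so the reduced number of mitochondria fills the cell
    uniformly: a change in cytosolic density, not in cell size.
    """
    ref = make_regular_layout()
    width, height = ref.grid_width, ref.grid_height
    side, margin = MITO_SIDE, MARGIN
    if cols < 1 or rows < 1:
        raise ParameterError("rows and cols must be >= 1")
    hgap = (width - 2 * margin - cols * side) / (cols - 1) if cols > 1 else 0
    vgap = (height - 2 * margin - rows * side) / (rows - 1) if rows > 1 else 0
    if hgap < 0 or vgap < 0:
        raise ParameterError("too many mitochondria for the reference cell size")
    mitos = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            mitos.append(
                Mitochondrion(
                    id=k,
                    x=margin + int(round(c * (side + hgap))),
                    y=margin + int(round(r * (side + vgap))),
                )
            )
            k += 1
    return CellGeometry(width, height, mitos, margin=margin, layout_name="low_density")


_MAX_PLACEMENT_ATTEMPTS = 100_000


def _place_random(
    n: int,
    sampler,
    width: int,
    height: int,
    side: int,
    layout_name: str,
) -> CellGeometry:
    """Seeded rejection sampling of ``n`` non-overlapping squares."""
    placed: list[tuple[int, int, int, int]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise CapacityError(
                f"could not place {n} mitochondria of side {side} within "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        attempts += 1
        xy = sampler()
        if xy is None:
            continue
        x, y = xy
        if not (0 <= x <= width - side and 0 <= y <= height - side):
            continue
        rect = (x, y, side, side)
        if any(_rects_overlap(rect, p) for p in placed):
            continue
        placed.append(rect)
    mitos = [Mitochondrion(id=i, x=r[0], y=r[1], w=side, h=side) for i, r in enumerate(placed)]
    return CellGeometry(width, height, mitos, margin=0, layout_name=layout_name)


def make_irregular_layout(
    n: int = 81,
    seed: int = 0,
    grid: tuple[int, int] | None = None,
    mito_side: int = MITO_SIDE,
) -> CellGeometry:
    """Uniform random non-overlapping placement of ``n`` mitochondria.

    Identical seeds yield identical layouts. Defaults use the cardiomyocyte
    cell dimensions so density is matched to the regular layout.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if grid is None:
        ref = make_regular_layout()
        grid = (ref.grid_width, ref.grid_height)
    width, height = grid
    rng = np.random.default_rng(seed)

    def sampler():
        return (
            int(rng.integers(0, width - mito_side + 1)),
            int(rng.integers(0, height - mito_side + 1)),
        )

    return _place_random(n, sampler, width, height, mito_side, "irregular")


def make_gradient_layout(
    n: int = 81,
    sigma: float | None = None,
    seed: int = 0,
    grid: tuple[int, int] | None = None,
    mito_side: int = MITO_SIDE,
) -> CellGeometry:
    """Center-oriented (perinuclear) clustering of ``n`` mitochondria.

    Centers are drawn from an isotropic Gaussian at the grid center
    (default ``sigma = grid_width / 6``), truncated to placements that fit
    inside the grid, with non-overlap enforced by rejection.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if grid is None:
        ref = make_regular_layout()
        grid = (ref.grid_width, ref.grid_height)
    width, height = grid
    if sigma is None:
        sigma = width / 6.0
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    cx, cy = width / 2.0, height / 2.0
    rng = np.random.default_rng(seed)

    def sampler():
        mx, my = rng.normal(cx, sigma), rng.normal(cy, sigma)
        return (int(round(mx - mito_side / 2)), int(round(my - mito_side / 2)))

    return _place_random(n, sampler, width, height, mito_side, "gradient")


def make_moving_layout(amplitude: float = VGAP, speed: float = 1.0) -> CellGeometry:
    """Cardiomyocyte lattice whose peripheral ring oscillates vertically.

    The 32 outer-ring mitochondria of the 9x9 lattice carry a vertical
    triangle-wave motion (default amplitude one vertical gap, 1 px/step);
    interior mitochondria are static.
    """
    geo = make_regular_layout()
    rows = cols = 9
    motion = MotionSpec(amplitude=amplitude, speed=speed)
    mitos = []
    for m in geo.mitochondria:
        r, c = divmod(m.id, cols)
        peripheral = r in (0, rows - 1) or c in (0, cols - 1)
        mitos.append(
            Mitochondrion(id=m.id, x=m.x, y=m.y, w=m.w, h=m.h, motion=motion if peripheral else None)
        )
    geo.mitochondria = mitos
    geo.layout_name = "moving"
    return geo


_LAYOUT_BUILDERS = {
    "regular": make_regular_layout,
    "low_density": make_low_density_layout,
    "irregular": make_irregular_layout,
    "gradient": make_gradient_layout,
    "moving": make_moving_layout,
}


def make_layout(name: str, **kwargs) -> CellGeometry:
    """Dispatch to a layout constructor by name."""
    try:
        builder = _LAYOUT_BUILDERS[name]
    except KeyError:
        raise ParameterError(
            f"unknown layout {name!r}; choose from {sorted(_LAYOUT_BUILDERS)}"
        ) from None
    return builder(**kwargs)
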