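"""Raster snapshots of the simulated cell.

Color conventions: black background, red mitochondria, white H2O2
particles, green O2- particles. Enzymes can optionally be drawn in dim
colors. The image has exactly the grid's pixel dimensions and is a pure
function of the world state.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from . import particles as pt

MITO_COLOR = (200, 0, 0)
H2O2_COLOR = (255, 255, 255)
O2_COLOR = (0, 220, 0)
ENZYME_COLORS = {
    pt.MNSOD: (90, 90, 0),
    pt.CUZNSOD: (0, 70, 90),
    pt.GPX_MITO: (90, 0, 90),
    pt.GPX_CYTO: (60, 60, 60),
    pt.CATALASE: (90, 45, 0),
}


def _paint(img: np.ndarray, positions: np.ndarray, color) -> None:
    if positions.shape[0] == 0:
        return
    ix = positions[:, 0].astype(np.int64)
    iy = positions[:, 1].astype(np.int64)
    img[iy, ix] = color


def render_snapshot(world, show_enzymes: bool = False) -> Image.Image:
    """Render a :class:`~rirrsim.engine.World` at its current step."""
    geo = world.geometry
    img = np.zeros((geo.grid_height, geo.grid_width, 3), dtype=np.uint8)
    for x, y, w, h in geo.rects_at(world.t):
        img[y : y + h, x : x + w] = MITO_COLOR
    if show_enzymes:
        for species, color in ENZYME_COLORS.items():
            _paint(img, world.population(species).positions, color)
    _paint(img, world.population(pt.H2O2).positions, H2O2_COLOR)
    _paint(img, world.population(pt.O2MINUS).positions, O2_COLOR)
    return Image.fromarray(img)
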