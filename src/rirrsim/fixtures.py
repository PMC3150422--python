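"""Miniature worlds for fast tests and demos.

The mini fixture is a 3x3 lattice of 12x12 px mitochondria (gaps 6/12 px,
margin 6 -> 72x60 px grid) run for 200 steps with 2 replicates and a
300-agent H2O2 bolus in a 24 px injection square. Enzyme concentrations
keep their default percent values, so absolute counts scale with the tiny
grid. Two observables are rescaled with the mitochondrion area (144 px vs
2916 px) so the fixture exhibits the same qualitative dynamics as the
full-size cell instead of being trivially inert: the reactive threshold
(50 -> 6 agents) and, with it, the leakage sigmoid's half-rise
(0.09 * 2 * 6 = 1.08). A full fixture run takes well under five seconds.
"""

from __future__ import annotations

from .config import LayoutConfig, RunConfig
from .engine import SimulationParams
from .geometry import CellGeometry, make_regular_layout
from .respiration import LeakageRuleParams

MINI_MITO_SIDE = 12
MINI_VGAP = 6
MINI_HGAP = 12
MINI_MARGIN = 6
MINI_REACTIVE_THRESHOLD = 6


def make_mini_geometry() -> CellGeometry:
    geo = make_regular_layout(
        rows=3,
        cols=3,
        mito_side=MINI_MITO_SIDE,
        vgap=MINI_VGAP,
        hgap=MINI_HGAP,
        margin=MINI_MARGIN,
    )
    geo.layout_name = "mini_regular"
    return geo


def make_mini_params(**overrides) -> SimulationParams:
    params = SimulationParams(
        leakage=LeakageRuleParams(center=0.09 * 2 * MINI_REACTIVE_THRESHOLD),
        initial_h2o2=300,
        injection_side=24,
        reactive_threshold=MINI_REACTIVE_THRESHOLD,
        n_steps=200,
        n_replicates=2,
        base_seed=0,
    )
    for k, v in overrides.items():
        setattr(params, k, v)
    return params


def make_mini_fixture(**overrides) -> tuple[RunConfig, CellGeometry]:
    """Mini run configuration plus its geometry."""
    cfg = RunConfig(
        layout=LayoutConfig(
            name="regular",
            options={
                "rows": 3,
                "cols": 3,
                "mito_side": MINI_MITO_SIDE,
                "vgap": MINI_VGAP,
                "hgap": MINI_HGAP,
                "margin": MINI_MARGIN,
            },
        ),
        params=make_mini_params(**overrides),
    )
    return cfg, make_mini_geometry()
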