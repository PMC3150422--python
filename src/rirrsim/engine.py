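"""Simulation engine: initialization, the per-step loop, and replicates.

The per-step update order is fixed (sources -> transport -> reactions ->
sinks -> classification) so runs are bit-reproducible under a seed:

1. mitochondrial motion (moving layouts only; confined enzymes ride along,
   swept cytosolic enzymes are pushed ahead of the advancing membrane);
2. per-mitochondrion ROS tally;
3. respiration with the electron-leakage rule (new O2- agents);
4. random-walk diffusion of every species;
5. membrane crossing / compartment confinement;
6. pixel-co-location enzymatic reactions (SOD, Gpx);
7. spontaneous decay;
8. reactive classification and metrics recording.

Concentrations from the kinetic tables are percent of whole-grid pixels;
``initialize`` converts them to agent counts, allocates mitochondrial
enzymes across mitochondria proportionally to area (largest-remainder
rounding, so the total is exact) and scatters cytosolic enzymes uniformly
over the cytosol. Oxidative stress is an initial bolus of H2O2 agents in a
centered square of the cytosol.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import particles as pt
from .exceptions import ParameterError
from .geometry import CYTOSOL, CellGeometry
from .particles import KineticParams, ParticlePopulation
from .respiration import LeakageRuleParams, classify_reactive, leakage_probability

#: Table of enzyme concentrations, percent of whole-grid pixels.
DEFAULT_CONCENTRATIONS = {
    pt.MNSOD: 0.769,
    pt.CUZNSOD: 0.914,
    pt.GPX_MITO: 0.3,
    pt.GPX_CYTO: 0.549,
    pt.CATALASE: 0.0,  # optional species, disabled by default
}


def _default_multipliers() -> dict[str, float]:
    return {s: 1.0 for s in DEFAULT_CONCENTRATIONS}


@dataclass
class SimulationParams:
    """Everything a run needs besides the geometry.

    ``initial_h2o2`` is an agent count (the model has no volume
    calibration); ``injection_side`` the side of the centered square the
    bolus lands in; ``reactive_threshold`` the strict O2--count bound for
    the reactive classification.
    """

    kinetics: KineticParams = field(default_factory=KineticParams)
    leakage: LeakageRuleParams = field(default_factory=LeakageRuleParams)
    concentrations: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    multipliers: dict[str, float] = field(default_factory=_default_multipliers)
    initial_h2o2: int = 10_000
    injection_side: int = 108
    reactive_threshold: int = 50
    respiration_rate: float = 0.01
    respiration_size_mode: str = "area"  # or "length"
    n_steps: int = 3000
    n_replicates: int = 5
    base_seed: int = 0
    debug_checks: bool = False

    def validate(self, geometry: CellGeometry | None = None) -> None:
        self.kinetics.validate()
        self.leakage.validate()
        if any(v < 0 for v in self.concentrations.values()):
            raise ParameterError("concentrations must be >= 0")
        if any(v < 0 for v in self.multipliers.values()):
            raise ParameterError("multipliers must be >= 0")
        if self.initial_h2o2 < 0:
            raise ParameterError("initial_h2o2 must be >= 0")
        if self.n_steps < 1 or self.n_replicates < 1:
            raise ParameterError("n_steps and n_replicates must be >= 1")
        if self.respiration_size_mode not in ("area", "length"):
            raise ParameterError("respiration_size_mode must be 'area' or 'length'")
        if geometry is not None and (
            self.injection_side > geometry.grid_width or self.injection_side > geometry.grid_height
        ):
            raise ParameterError("injection square larger than the grid")


@dataclass
class StepMetrics:
    """Scalar observables of one step of one replicate."""

    step: int
    reactive_fraction: float  # percent of mitochondria
    n_o2minus: int
    n_h2o2: int
    leak_events: int
    sod_conversions: int
    gpx_removals: int
    o2_decays: int
    h2o2_decays: int


class World:
    """Mutable state of one simulation replicate."""

    def __init__(self, geometry: CellGeometry, params: SimulationParams, rng: np.random.Generator):
        self.geometry = geometry
        self.params = params
        self.rng = rng
        self.t = 0
        self.pops: dict[str, ParticlePopulation] = {}
        self.label_map = geometry.label_map(0)
        self.metrics: list[StepMetrics] = []
        self.loads: list[np.ndarray] = []  # per-step per-mito O2- counts

    def population(self, species: str) -> ParticlePopulation:
        return self.pops.get(species, ParticlePopulation.empty(species))

    def mito_counts(self, species: str) -> np.ndarray:
        """Agent count of ``species`` inside each mitochondrion's rect."""
        lab = pt.pixel_labels(self.population(species).positions, self.label_map)
        n = self.geometry.n_mitochondria
        inside = lab[lab != CYTOSOL]
        return np.bincount(inside, minlength=n) if n else np.zeros(0, dtype=np.int64)


def _largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing exactly to total."""
    if total == 0 or weights.size == 0:
        return np.zeros(weights.size, dtype=np.int64)
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def _uniform_in_rects(rects: np.ndarray, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    parts = []
    for (x, y, w, h), c in zip(rects, counts):
        if c == 0:
            continue
        u = rng.uniform(size=(c, 2))
        u[:, 0] = x + u[:, 0] * w
        u[:, 1] = y + u[:, 1] * h
        parts.append(u)
    return np.vstack(parts) if parts else np.empty((0, 2))


def _uniform_in_cytosol(
    n: int, geometry: CellGeometry, label_map: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions over the cytosol by rejection from the full grid."""
    out = np.empty((0, 2))
    while out.shape[0] < n:
        batch = max(64, int((n - out.shape[0]) * 1.8))
        cand = rng.uniform(size=(batch, 2))
        cand[:, 0] *= geometry.grid_width
        cand[:, 1] *= geometry.grid_height
        keep = pt.pixel_labels(cand, label_map) == CYTOSOL
        out = np.vstack([out, cand[keep]])
    return out[:n]


def enzyme_count(concentration_pct: float, multiplier: float, total_pixels: int) -> int:
    """Agent count under the percent-of-whole-grid-pixels convention."""
    return int(round(concentration_pct * multiplier * total_pixels / 100.0))


def initialize(
    params: SimulationParams, geometry: CellGeometry, rng: np.random.Generator
) -> World:
    """Build the step-0 world: enzymes at their home stations, H2O2 bolus."""
    params.validate(geometry)
    world = World(geometry, params, rng)
    total_px = geometry.total_pixels
    rects = geometry.rects_at(0)
    sizes = geometry.sizes.astype(np.float64)

    for species in pt.ENZYME_SPECIES:
        conc = params.concentrations.get(species, 0.0)
        mult = params.multipliers.get(species, 1.0)
        n = enzyme_count(conc, mult, total_px)
        if n == 0:
            world.pops[species] = ParticlePopulation.empty(species)
            continue
        if pt.HOME_COMPARTMENT[species] == "mitochondria":
            if geometry.n_mitochondria == 0:
                raise ParameterError(f"{species} requires at least one mitochondrion")
            alloc = _largest_remainder_allocation(sizes, n)
            pos = _uniform_in_rects(rects, alloc, rng)
        else:
            pos = _uniform_in_cytosol(n, geometry, world.label_map, rng)
        world.pops[species] = ParticlePopulation(species, pos)

    # centered injection square of initial oxidative stress
    side = params.injection_side
    n = params.initial_h2o2
    if n > 0:
        x0 = (geometry.grid_width - side) / 2.0
        y0 = (geometry.grid_height - side) / 2.0
        pos = rng.uniform(size=(n, 2)) * side
        pos[:, 0] += x0
        pos[:, 1] += y0
        world.pops[pt.H2O2] = ParticlePopulation(pt.H2O2, pos)
    else:
        world.pops[pt.H2O2] = ParticlePopulation.empty(pt.H2O2)
    world.pops[pt.O2MINUS] = ParticlePopulation.empty(pt.O2MINUS)
    return world


def _apply_motion(world: World) -> None:
    """Advance moving mitochondria; keep confined agents consistent."""
    geo = world.geometry
    prev_offsets = np.array(
        [0 if m.motion is None else round(m.motion.offset(world.t - 1)) for m in geo.mitochondria]
    )
    offsets = np.array(
        [0 if m.motion is None else round(m.motion.offset(world.t)) for m in geo.mitochondria]
    )
    dy = offsets - prev_offsets
    if not dy.any():
        return
    # mitochondrial enzymes ride with their mitochondrion
    for species in pt.ENZYME_SPECIES:
        pop = world.population(species)
        if pop.n == 0 or pop.home_compartment != "mitochondria":
            continue
        lab = pt.pixel_labels(pop.positions, world.label_map)
        moved = dy[lab] != 0
        if moved.any():
            pop.positions[moved, 1] += dy[lab[moved]]
    world.label_map = geo.label_map(world.t)
    # cytosolic enzymes swept over by an advancing membrane are pushed ahead
    # of it; one caught between closing membranes keeps sliding in the
    # direction of motion until it reaches cytosol again
    height = geo.grid_height
    for species in pt.ENZYME_SPECIES:
        pop = world.population(species)
        if pop.n == 0 or pop.home_compartment != "cytosol":
            continue
        for _ in range(2 * height):
            lab = pt.pixel_labels(pop.positions, world.label_map)
            inside = lab != CYTOSOL
            if not inside.any():
                break
            shift = dy[lab[inside]]
            shift[shift == 0] = dy[dy != 0][0]  # swept into a static rect
            pop.positions[inside, 1] = np.clip(
                pop.positions[inside, 1] + shift, 0.0, np.nextafter(height, 0.0)
            )


def step(world: World) -> StepMetrics:
    """Advance the world by one step and record metrics."""
    params = world.params
    geo = world.geometry
    rng = world.rng
    world.t += 1

    if geo.has_motion:
        _apply_motion(world)

    # --- tally & respiration -------------------------------------------
    o2_counts = world.mito_counts(pt.O2MINUS)
    h2o2_counts = world.mito_counts(pt.H2O2)
    sizes = geo.sizes if params.respiration_size_mode == "area" else np.array(
        [m.w for m in geo.mitochondria]
    )
    leaks = np.zeros(0, dtype=np.int64)
    n_leaked = 0
    if geo.n_mitochondria:
        events = rng.poisson(params.respiration_rate * sizes.astype(np.float64))
        p_leak = leakage_probability(h2o2_counts, o2_counts, params.leakage)
        leaks = rng.binomial(events, p_leak)
        n_leaked = int(leaks.sum())
        if n_leaked:
            new_o2 = _uniform_in_rects(geo.rects_at(world.t), leaks, rng)
            o2 = world.population(pt.O2MINUS)
            world.pops[pt.O2MINUS] = ParticlePopulation(
                pt.O2MINUS, np.vstack([o2.positions, new_o2])
            )

    # --- transport ------------------------------------------------------
    for species, pop in world.pops.items():
        if pop.n == 0:
            continue
        proposed = pt.propose_moves(
            pop.positions,
            params.kinetics.max_speed[species],
            geo.grid_width,
            geo.grid_height,
            rng,
        )
        if species in pt.ROS_SPECIES:
            newpos, _ = pt.resolve_membrane(
                pop.positions,
                proposed,
                world.label_map,
                params.kinetics.membrane_cross[species],
                rng,
            )
        else:
            newpos = pt.confine_to_home(
                pop.positions, proposed, world.label_map, pop.home_compartment
            )
        world.pops[species] = ParticlePopulation(species, newpos)

    # --- reactions ------------------------------------------------------
    o2_before = world.population(pt.O2MINUS).n
    h2o2_before = world.population(pt.H2O2).n
    o2, h2o2, rxn = pt.react(
        world.population(pt.O2MINUS),
        world.population(pt.H2O2),
        {s: world.population(s) for s in pt.ENZYME_SPECIES},
        params.kinetics,
        geo,
        rng,
    )
    world.pops[pt.O2MINUS] = o2
    world.pops[pt.H2O2] = h2o2

    # --- sinks ----------------------------------------------------------
    o2, n_o2_dec = pt.decay(world.population(pt.O2MINUS), params.kinetics, rng)
    h2o2, n_h_dec = pt.decay(world.population(pt.H2O2), params.kinetics, rng)
    world.pops[pt.O2MINUS] = o2
    world.pops[pt.H2O2] = h2o2

    if params.debug_checks:
        _debug_invariants(world, o2_before, h2o2_before, rxn, n_o2_dec, n_h_dec)

    # --- classification & metrics ---------------------------------------
    final_o2_counts = world.mito_counts(pt.O2MINUS)
    frac = (
        classify_reactive(final_o2_counts, params.reactive_threshold)
        if geo.n_mitochondria
        else 0.0
    )
    m = StepMetrics(
        step=world.t,
        reactive_fraction=frac,
        n_o2minus=o2.n,
        n_h2o2=h2o2.n,
        leak_events=n_leaked,
        sod_conversions=rxn["sod_conversions"],
        gpx_removals=rxn["gpx_removals"],
        o2_decays=n_o2_dec,
        h2o2_decays=n_h_dec,
    )
    world.metrics.append(m)
    world.loads.append(final_o2_counts)
    return m


def _debug_invariants(world, o2_before, h2o2_before, rxn, n_o2_dec, n_h_dec):
    """Exact count bookkeeping and compartment confinement (debug mode)."""
    o2_now = world.population(pt.O2MINUS).n
    h2o2_now = world.population(pt.H2O2).n
    assert o2_now == o2_before - rxn["sod_o2_consumed"] - n_o2_dec, "O2- bookkeeping broken"
    assert h2o2_now == h2o2_before + rxn["sod_conversions"] - rxn["gpx_removals"] - n_h_dec, (
        "H2O2 bookkeeping broken"
    )
    for species in pt.ENZYME_SPECIES:
        pop = world.population(species)
        if pop.n == 0:
            continue
        lab = pt.pixel_labels(pop.positions, world.label_map)
        if pop.home_compartment == "mitochondria":
            assert (lab != CYTOSOL).all(), f"{species} escaped the mitochondria"
        else:
            assert (lab == CYTOSOL).all(), f"{species} entered a mitochondrion"


def metrics_frame(world: World) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in world.metrics])


def populations_frame(world: World) -> pd.DataFrame:
    """Debug dump of every agent as (species, x, y) rows."""
    frames = [
        pd.DataFrame({"species": s, "x": p.positions[:, 0], "y": p.positions[:, 1]})
        for s, p in world.pops.items()
        if p.n > 0
    ]
    if not frames:
        return pd.DataFrame(columns=["species", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def run(params: SimulationParams, geometry: CellGeometry, seed: int) -> World:
    """One full replicate with its own seeded generator."""
    rng = np.random.default_rng(seed)
    world = initialize(params, copy.deepcopy(geometry), rng)
    for _ in range(params.n_steps):
        step(world)
    return world


@dataclass
class RunResult:
    """Replicate ensemble: per-step metrics, per-replicate finals, mean/sd."""

    params: SimulationParams
    geometry: CellGeometry
    replicates: list[pd.DataFrame]
    loads: list[np.ndarray]  # each (n_steps, n_mitochondria)
    seeds: list[int]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def final_reactive_fractions(self) -> np.ndarray:
        return np.array([df["reactive_fraction"].iloc[-1] for df in self.replicates])

    def mean_series(self, column: str = "reactive_fraction") -> pd.DataFrame:
        """Per-step mean and (population) sd across replicates."""
        stacked = np.stack([df[column].to_numpy() for df in self.replicates])
        return pd.DataFrame(
            {
                "step": self.replicates[0]["step"].to_numpy(),
                "mean": stacked.mean(axis=0),
                "sd": stacked.std(axis=0),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format metrics: one row per (replicate, step)."""
        frames = []
        for i, df in enumerate(self.replicates):
            d = df.copy()
            d.insert(0, "replicate", i)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def run_replicates(params: SimulationParams, geometry: CellGeometry) -> RunResult:
    """Independent replicates seeded ``base_seed .. base_seed + n - 1``."""
    params.validate(geometry)
    seeds = [params.base_seed + i for i in range(params.n_replicates)]
    worlds = [run(params, geometry, s) for s in seeds]
    return RunResult(
        params=params,
        geometry=geometry,
        replicates=[metrics_frame(w) for w in worlds],
        loads=[np.stack(w.loads) if w.loads else np.zeros((0, geometry.n_mitochondria)) for w in worlds],
        seeds=seeds,
    )
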