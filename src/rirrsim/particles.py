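"""Particle populations: random-walk diffusion, membranes, decay, reactions.

All mobile entities -- the two ROS species and the antioxidant enzymes --
are point agents with continuous 2D positions, stored as (n, 2) float64
arrays of (x, y). Each step an agent is displaced per axis by
``max_speed * u`` with ``u ~ Uniform(-0.5, 0.5)`` drawn independently per
axis, and reflects off the grid walls. Mitochondrial membranes are
probabilistic barriers for ROS (a crossing attempt succeeds with a
direction-dependent probability, otherwise the whole move is cancelled) and
hard walls for compartment-confined enzymes.

Enzymatic reactions are resolved by pixel co-location: a substrate reacts,
with a fixed per-step probability, whenever at least one matching enzyme
occupies the same pixel (SOD converts O2- to H2O2; Gpx removes H2O2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CYTOSOL, CellGeometry

O2MINUS = "O2minus"
H2O2 = "H2O2"
MNSOD = "MnSOD"
CUZNSOD = "CuZnSOD"
GPX_MITO = "GpxMito"
GPX_CYTO = "GpxCyto"
CATALASE = "Catalase"  # optional, Gpx-like mechanism, disabled by default

ROS_SPECIES = (O2MINUS, H2O2)
ENZYME_SPECIES = (MNSOD, CUZNSOD, GPX_MITO, GPX_CYTO, CATALASE)
SOD_SPECIES = (MNSOD, CUZNSOD)
PEROXIDASE_SPECIES = (GPX_MITO, GPX_CYTO, CATALASE)

#: Home compartment per species: "mitochondria", "cytosol" or "anywhere".
HOME_COMPARTMENT = {
    O2MINUS: "anywhere",
    H2O2: "anywhere",
    MNSOD: "mitochondria",
    CUZNSOD: "cytosol",
    GPX_MITO: "mitochondria",
    GPX_CYTO: "cytosol",
    CATALASE: "cytosol",
}

_ENZYME_SPEED = 1.414  # px/step, all antioxidant enzymes

#: Per-encounter reaction probabilities. Only the ratio of the two catalytic
#: rate constants (2.3e9 vs 5e7 /M/s) is identifiable at the model's
#: resolution, so the faster reaction (SOD) saturates at 1 and Gpx gets the
#: ratio.
P_SOD_DEFAULT = 1.0
P_GPX_DEFAULT = 5e7 / 2.3e9


def _default_speeds() -> dict[str, float]:
    d = {H2O2: 11.31, O2MINUS: 11.66}
    d.update({s: _ENZYME_SPEED for s in ENZYME_SPECIES})
    return d


def _default_decay() -> dict[str, float]:
    d = {H2O2: 1e-5, O2MINUS: 7.69e-3}
    d.update({s: 0.0 for s in ENZYME_SPECIES})
    return d


def _default_crossing() -> dict[str, tuple[float, float]]:
    # (in -> out, out -> in). H2O2 is the more membrane-permeant species;
    # the O2- value is set so a reactive mitochondrion's exported superoxide
    # can reach a lattice neighbour within its lifetime while staying well
    # below the H2O2 permeability.
    return {H2O2: (0.5, 0.5), O2MINUS: (0.25, 0.25)}


@dataclass
class KineticParams:
    """Per-species transport and reaction constants.

    ``max_speed`` is the multiplier of the uniform(-0.5, 0.5) per-axis draw,
    in px/step; ``spontaneous_decay`` a per-step removal probability;
    ``membrane_cross`` per-ROS-species (in->out, out->in) acceptance
    probabilities; ``p_sod``/``p_gpx`` per-encounter reaction probabilities;
    ``sod_stoichiometry`` 1 for the count-conserving 1 O2- -> 1 H2O2 rule,
    2 for the biological 2 -> 1.
    """

    max_speed: dict[str, float] = field(default_factory=_default_speeds)
    spontaneous_decay: dict[str, float] = field(default_factory=_default_decay)
    membrane_cross: dict[str, tuple[float, float]] = field(default_factory=_default_crossing)
    p_sod: float = P_SOD_DEFAULT
    p_gpx: float = P_GPX_DEFAULT
    sod_stoichiometry: int = 1

    def validate(self) -> None:
        for s, v in self.max_speed.items():
            if v < 0:
                raise ValueError(f"max_speed[{s}] must be >= 0")
        for s, v in self.spontaneous_decay.items():
            if not 0 <= v <= 1:
                raise ValueError(f"spontaneous_decay[{s}] must be in [0, 1]")
        for s, (a, b) in self.membrane_cross.items():
            if not (0 <= a <= 1 and 0 <= b <= 1):
                raise ValueError(f"membrane_cross[{s}] must be probabilities")
        if not (0 <= self.p_sod <= 1 and 0 <= self.p_gpx <= 1):
            raise ValueError("reaction probabilities must be in [0, 1]")
        if self.sod_stoichiometry not in (1, 2):
            raise ValueError("sod_stoichiometry must be 1 or 2")


@dataclass
class ParticlePopulation:
    """Positions of every agent of one species."""

    species: str
    positions: np.ndarray  # (n, 2) float64

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def home_compartment(self) -> str:
        return HOME_COMPARTMENT[self.species]

    @classmethod
    def empty(cls, species: str) -> "ParticlePopulation":
        return cls(species, np.empty((0, 2)))


# -- elementary array operations (used by the engine's hot loop) ------------


def reflect(coords: np.ndarray, width: float, height: float) -> np.ndarray:
    """Reflect positions at the grid walls, in place; returns its input.

    Single reflection per axis suffices because per-step displacements are
    far smaller than the grid.
    """
    for axis, bound in ((0, width), (1, height)):
        c = coords[:, axis]
        np.abs(c, out=c)
        over = c >= bound
        if over.any():
            c[over] = 2.0 * bound - c[over]
        # guard against landing exactly on the excluded upper edge
        np.clip(c, 0.0, np.nextafter(bound, 0.0), out=c)
    return coords


def propose_moves(
    positions: np.ndarray, max_speed: float, width: float, height: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk proposal: displacement = max_speed * Uniform(-0.5, 0.5)."""
    if positions.shape[0] == 0 or max_speed == 0.0:
        return positions.copy()
    disp = rng.random(positions.shape, dtype=np.float64)
    disp -= 0.5
    disp *= max_speed
    disp += positions
    return reflect(disp, width, height)


def pixel_labels(positions: np.ndarray, label_map: np.ndarray) -> np.ndarray:
    """Compartment label of each agent (mitochondrion id or CYTOSOL)."""
    if positions.shape[0] == 0:
        return np.empty(0, dtype=np.int32)
    ix = positions[:, 0].astype(np.int64)
    iy = positions[:, 1].astype(np.int64)
    return label_map[iy, ix]


def pixel_index(positions: np.ndarray, width: int) -> np.ndarray:
    """Flat pixel index (floor binning) of each agent."""
    if positions.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    return positions[:, 1].astype(np.int64) * width + positions[:, 0].astype(np.int64)


def resolve_membrane(
    old: np.ndarray,
    proposed: np.ndarray,
    label_map: np.ndarray,
    crossing: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Accept or cancel compartment-changing ROS moves.

    Returns (new positions, number of accepted crossings). Moves that leave
    a mitochondrion are accepted with ``crossing[0]``, moves that enter with
    ``crossing[1]``; the rare direct mitochondrion-to-mitochondrion hop
    crosses two membranes and needs both. A rejected crossing cancels the
    whole move.
    """
    if old.shape[0] == 0:
        return proposed, np.int64(0)
    lab_old = pixel_labels(old, label_map)
    lab_new = pixel_labels(proposed, label_map)
    idx = np.flatnonzero(lab_old != lab_new)
    if idx.size == 0:
        return proposed, np.int64(0)
    p_out, p_in = crossing
    p = np.ones(idx.size)
    p[lab_old[idx] != CYTOSOL] *= p_out
    p[lab_new[idx] != CYTOSOL] *= p_in
    reject = idx[rng.random(idx.size) >= p]
    out = proposed.copy()
    out[reject] = old[reject]
    return out, int(idx.size - reject.size)


def confine_to_home(
    old: np.ndarray, proposed: np.ndarray, label_map: np.ndarray, home: str
) -> np.ndarray:
    """Cancel enzyme moves that would exit the species' home compartment."""
    if old.shape[0] == 0 or home == "anywhere":
        return proposed
    lab_new = pixel_labels(proposed, label_map)
    exits = lab_new == CYTOSOL if home == "mitochondria" else lab_new != CYTOSOL
    if exits.any():
        proposed = proposed.copy()
        proposed[exits] = old[exits]
    return proposed


# -- public single-population operations ------------------------------------


def diffuse(
    pop: ParticlePopulation,
    params: KineticParams,
    geometry: CellGeometry,
    rng: np.random.Generator,
) -> ParticlePopulation:
    """One unconstrained random-walk step (no membranes)."""
    new = propose_moves(
        pop.positions, params.max_speed[pop.species], geometry.grid_width, geometry.grid_height, rng
    )
    return ParticlePopulation(pop.species, new)


def apply_membrane(
    pop: ParticlePopulation,
    proposed: np.ndarray,
    geometry: CellGeometry,
    params: KineticParams,
    rng: np.random.Generator,
    label_map: np.ndarray | None = None,
) -> ParticlePopulation:
    """Apply membrane rules to proposed positions for one population."""
    if label_map is None:
        label_map = geometry.label_map()
    if pop.species in ROS_SPECIES:
        new, _ = resolve_membrane(
            pop.positions, proposed, label_map, params.membrane_cross[pop.species], rng
        )
    else:
        new = confine_to_home(pop.positions, proposed, label_map, pop.home_compartment)
    return ParticlePopulation(pop.species, new)


def decay(
    pop: ParticlePopulation, params: KineticParams, rng: np.random.Generator
) -> tuple[ParticlePopulation, int]:
    """Remove each agent independently with its species' per-step probability.

    Returns the surviving population and the number removed.
    """
    p = params.spontaneous_decay[pop.species]
    if p <= 0 or pop.n == 0:
        return pop, 0
    if p >= 1:
        return ParticlePopulation.empty(pop.species), pop.n
    keep = rng.random(pop.n) >= p
    return ParticlePopulation(pop.species, pop.positions[keep]), int(pop.n - keep.sum())


def _paired_conversion_mask(conv_pix: np.ndarray) -> np.ndarray:
    """For 2->1 stoichiometry: keep one converted O2- per pixel pair.

    Among agents flagged for conversion, each pixel converts them two at a
    time; an odd leftover stays O2-. Returns a boolean mask over the flagged
    agents selecting those that are actually consumed (pairs), with every
    second consumed agent becoming the H2O2 product.
    """
    order = np.argsort(conv_pix, kind="stable")
    sorted_pix = conv_pix[order]
    new_group = np.ones(sorted_pix.size, dtype=bool)
    new_group[1:] = sorted_pix[1:] != sorted_pix[:-1]
    # position within the pixel group
    idx_in_group = np.arange(sorted_pix.size) - np.maximum.accumulate(
        np.where(new_group, np.arange(sorted_pix.size), 0)
    )
    group_id = np.cumsum(new_group) - 1
    counts = np.bincount(group_id)
    pair_count = (counts // 2 * 2)[group_id]
    consumed_sorted = idx_in_group < pair_count
    consumed = np.zeros(conv_pix.size, dtype=bool)
    consumed[order] = consumed_sorted
    return consumed


def react(
    o2: ParticlePopulation,
    h2o2: ParticlePopulation,
    enzymes: dict[str, ParticlePopulation],
    params: KineticParams,
    geometry: CellGeometry,
    rng: np.random.Generator,
) -> tuple[ParticlePopulation, ParticlePopulation, dict[str, int]]:
    """Pixel-co-location enzymatic reactions.

    Every O2- sharing a pixel with >= 1 SOD agent converts to H2O2 (same
    position) with probability ``p_sod``; every H2O2 sharing a pixel with
    >= 1 peroxidase (Gpx, or catalase if enabled) is removed with
    probability ``p_gpx``. Enzyme multiplicity within a pixel does not raise
    the per-step probability, and enzymes are never consumed.

    Returns the updated ROS populations and event counters
    ``{"sod_conversions", "gpx_removals"}``.
    """
    width = geometry.grid_width
    n_pix = width * geometry.grid_height
    counters = {"sod_conversions": 0, "sod_o2_consumed": 0, "gpx_removals": 0}

    def occupied(species_list):
        """Boolean occupancy bitmap over pixels (fast substrate lookup)."""
        pix = [
            pixel_index(enzymes[s].positions, width)
            for s in species_list
            if s in enzymes and enzymes[s].n > 0
        ]
        if not pix:
            return None
        bitmap = np.zeros(n_pix, dtype=bool)
        bitmap[np.concatenate(pix)] = True
        return bitmap

    sod_pix = occupied(SOD_SPECIES)
    if sod_pix is not None and o2.n > 0 and params.p_sod > 0:
        o2_pix = pixel_index(o2.positions, width)
        hit = sod_pix[o2_pix]
        if params.p_sod < 1.0:
            hit &= rng.random(o2.n) < params.p_sod
        if hit.any():
            if params.sod_stoichiometry == 1:
                produced = o2.positions[hit]
                o2 = ParticlePopulation(O2MINUS, o2.positions[~hit])
                counters["sod_o2_consumed"] = int(produced.shape[0])
            else:
                consumed_local = _paired_conversion_mask(o2_pix[hit])
                consumed_idx = np.flatnonzero(hit)[consumed_local]
                consumed = np.zeros(o2.n, dtype=bool)
                consumed[consumed_idx] = True
                # one product per consumed pair, within-pixel pairing
                by_pixel = consumed_idx[np.argsort(o2_pix[consumed_idx], kind="stable")]
                produced = o2.positions[by_pixel[::2]]
                o2 = ParticlePopulation(O2MINUS, o2.positions[~consumed])
                counters["sod_o2_consumed"] = int(consumed_idx.size)
            counters["sod_conversions"] = int(produced.shape[0])
            if produced.shape[0]:
                h2o2 = ParticlePopulation(H2O2, np.vstack([h2o2.positions, produced]))

    gpx_pix = occupied(PEROXIDASE_SPECIES)
    if gpx_pix is not None and h2o2.n > 0 and params.p_gpx > 0:
        h_pix = pixel_index(h2o2.positions, width)
        hit = gpx_pix[h_pix]
        if params.p_gpx < 1.0:
            hit &= rng.random(h2o2.n) < params.p_gpx
        if hit.any():
            counters["gpx_removals"] = int(hit.sum())
            h2o2 = ParticlePopulation(H2O2, h2o2.positions[~hit])

    return o2, h2o2, counters
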