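"""Dose-response sweeps, threshold regression, and messenger kinetics.

The RIRR threshold of a cell is read off a dose-response curve: sweep the
initial H2O2 bolus (or an antioxidant multiplier), record the final-step
reactive fraction (mean +/- sd over replicates), fit a second- or
third-order polynomial ``y = A + Bx + Cx^2 (+ Dx^3)`` by least squares,
and solve for the dose at which the fitted curve reaches 20% reactive
mitochondria.

The messenger-kinetics calculator turns per-step loss probabilities into a
lifetime ``N = 1 / p_total`` (steps) and a diffusive reach
``sqrt(2 N L^2)`` (pixels, from the mean-square displacement law of the 2D
fixed-step random walk), quantifying why O2- is a short-range and H2O2 a
long-range messenger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import particles as pt
from .engine import SimulationParams, run_replicates
from .exceptions import FitError, LifetimeError, ParameterError
from .geometry import CellGeometry

SWEEP_VARIABLES = ("initial_H2O2", "MnSOD_mult", "CuZnSOD_mult", "Gpx_mult")


@dataclass
class DoseResponseCurve:
    """Final-step reactive fraction versus a swept variable."""

    variable: str
    points: pd.DataFrame  # columns: x, mean, sd, n

    @property
    def x(self) -> np.ndarray:
        return self.points["x"].to_numpy(dtype=float)

    @property
    def mean(self) -> np.ndarray:
        return self.points["mean"].to_numpy(dtype=float)

    @classmethod
    def from_table(cls, df: pd.DataFrame, variable: str = "initial_H2O2") -> "DoseResponseCurve":
        """Wrap a user-supplied (x, mean[, sd, n]) table."""
        df = df.copy()
        for col, default in (("sd", 0.0), ("n", 1)):
            if col not in df:
                df[col] = default
        if not np.all(np.diff(df["x"].to_numpy(dtype=float)) > 0):
            raise ParameterError("x values must be strictly increasing")
        return cls(variable, df[["x", "mean", "sd", "n"]])


@dataclass
class ThresholdEstimate:
    """Dose at which the fitted dose-response curve reaches the target."""

    order: int
    coefficients: np.ndarray  # ascending: A, B, C[, D]
    target: float
    threshold_x: float | None
    valid: bool


@dataclass
class MessengerKinetics:
    """Lifetime and diffusive reach of one ROS messenger."""

    species: str
    p_total: float  # per-step total loss probability
    lifetime: float  # steps, 1 / p_total
    step_scale: float  # L, px
    reach: float  # px, sqrt(2 * lifetime * L^2)


def _with_variable(params: SimulationParams, variable: str, value: float) -> SimulationParams:
    p = replace(params)
    p.multipliers = dict(params.multipliers)
    if variable == "initial_H2O2":
        p.initial_h2o2 = int(round(value))
    elif variable == "MnSOD_mult":
        p.multipliers[pt.MNSOD] = value
    elif variable == "CuZnSOD_mult":
        p.multipliers[pt.CUZNSOD] = value
    elif variable == "Gpx_mult":
        # the cytosolic pool is the modulated one; mitochondrial Gpx stays put
        p.multipliers[pt.GPX_CYTO] = value
    else:
        raise ParameterError(f"unknown sweep variable {variable!r}; use one of {SWEEP_VARIABLES}")
    return p


def sweep(
    params: SimulationParams,
    variable: str,
    values: Sequence[float],
    geometry: CellGeometry,
) -> DoseResponseCurve:
    """Run replicate ensembles along ``values`` of ``variable``.

    Records the mean and sd over replicates of the final-step reactive
    fraction at each value.
    """
    if len(values) == 0:
        raise ParameterError("values must be non-empty")
    vals = list(values)
    if sorted(vals) != vals:
        raise ParameterError("values must be sorted ascending")
    rows = []
    for v in vals:
        res = run_replicates(_with_variable(params, variable, v), geometry)
        finals = res.final_reactive_fractions
        rows.append(
            {"x": float(v), "mean": float(finals.mean()), "sd": float(finals.std()), "n": len(finals)}
        )
    return DoseResponseCurve(variable, pd.DataFrame(rows))


def fit_polynomial(points: Sequence[tuple[float, float]], order: int) -> np.ndarray:
    """Unweighted least-squares polynomial fit; ascending coefficients."""
    if order not in (2, 3):
        raise ParameterError("order must be 2 or 3")
    arr = np.asarray(points, dtype=float).reshape(-1, 2)
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < order + 1:
        raise FitError(f"need at least {order + 1} distinct x values for order {order}")
    # fit in a scaled domain for conditioning, then convert back
    try:
        poly = np.polynomial.Polynomial.fit(x, y, order).convert()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise FitError(f"polynomial fit failed: {exc}") from exc
    coeffs = np.zeros(order + 1)
    coeffs[: poly.coef.size] = poly.coef
    return coeffs


def rirr_threshold(
    curve: DoseResponseCurve, order: int = 3, target: float = 20.0
) -> ThresholdEstimate:
    """Dose at which the fitted polynomial reaches ``target`` percent.

    Fits on (x, mean), solves ``fitted(x) = target`` over the real roots,
    and keeps the smallest root inside the sampled range. ``valid`` is
    False when no such root exists.
    """
    coeffs = fit_polynomial(np.column_stack([curve.x, curve.mean]), order)
    shifted = coeffs.copy()
    shifted[0] -= target
    roots = np.polynomial.polynomial.polyroots(shifted)
    xmin, xmax = curve.x.min(), curve.x.max()
    span = max(xmax - xmin, 1.0)
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    inside = real[(real >= xmin - 1e-9 * span) & (real <= xmax + 1e-9 * span)]
    if inside.size == 0:
        return ThresholdEstimate(order, coeffs, target, None, False)
    return ThresholdEstimate(order, coeffs, target, float(inside.min()), True)


def enzyme_occupancy(
    n_enzymes: int, total_pixels: int, exact: bool = False
) -> float:
    """Fraction of pixels holding >= 1 enzyme.

    Sparse approximation ``n / total`` by default; ``exact=True`` uses the
    Poisson occupancy ``1 - exp(-n/total)``.
    """
    lam = n_enzymes / total_pixels
    return float(1.0 - np.exp(-lam)) if exact else float(lam)


def messenger_lifetime(
    species: str,
    params: pt.KineticParams,
    occupancies: dict[str, float] | None = None,
    exact: bool = False,
) -> MessengerKinetics:
    """Lifetime and reach of a ROS messenger from model parameters.

    ``occupancies`` maps enzyme species to the fraction of pixels they
    occupy in the messenger's environment; each contributes
    ``occupancy * reaction probability`` to the per-step loss. With no
    enzymes the lifetime is set by spontaneous decay alone.
    """
    occupancies = occupancies or {}
    p_total = params.spontaneous_decay[species]
    for enz, occ in occupancies.items():
        if enz in pt.SOD_SPECIES and species == pt.O2MINUS:
            p_total += occ * params.p_sod
        elif enz in pt.PEROXIDASE_SPECIES and species == pt.H2O2:
            p_total += occ * params.p_gpx
    if p_total <= 0:
        raise LifetimeError(f"{species} has no decay channel: infinite lifetime")
    lifetime = 1.0 / p_total
    L = params.max_speed[species]
    return MessengerKinetics(
        species=species,
        p_total=float(p_total),
        lifetime=float(lifetime),
        step_scale=float(L),
        reach=float(np.sqrt(msd_theory(lifetime, L))),
    )


def msd_theory(n_steps: float, step_length: float) -> float:
    """Mean-square displacement of the 2D fixed-step diagonal walk: 2NL^2."""
    if n_steps < 0 or step_length < 0:
        raise ParameterError("N and L must be >= 0")
    return 2.0 * n_steps * step_length**2


def diagonal_walk_squared_displacements(
    n_walkers: int, n_steps: int, step_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Squared displacements of independent 2D fixed-step diagonal walkers.

    Each step displaces each axis by +/- L with equal probability (a
    diagonal hop of length L*sqrt(2)), the walk whose closed-form MSD is
    ``2NL^2``. Returns one squared displacement per walker, for
    Monte-Carlo validation of the closed form.
    """
    signs = rng.integers(0, 2, size=(n_walkers, n_steps, 2)) * 2 - 1
    final = signs.sum(axis=1) * step_length
    return (final**2).sum(axis=1).astype(float)
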