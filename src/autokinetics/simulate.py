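"""Mass-action reaction networks and their integration to concentration traces.

The kinetic object everything downstream consumes is a
:class:`ConcentrationTrace`: time-stamped species concentrations in mM on a
strictly increasing time grid in minutes.  Traces come either from
:func:`simulate_network` (numerical integration of a
:class:`ReactionNetwork`) or, for real data, from spectral processing.

Units are fixed throughout the package: concentrations in mM, time in
minutes, rate constants in mM^(1-n) min^-1 for molecularity n.  Sampling
intervals are the one place seconds are accepted, at the
:func:`sample_schedule` boundary, because bench instruments are configured
in seconds while rate constants are conventionally per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ConcentrationTrace",
    "simulate_network",
    "closed_form_pseudo_first_order",
    "sample_schedule",
]


@dataclass(frozen=True)
class Reaction:
    """One elementary (or empirically lumped) reaction.

    Parameters
    ----------
    reactants, products
        Stoichiometry maps, species name -> positive integer coefficient.
    k
        Rate constant, mM^(1-n) min^-1 where n is the molecularity implied
        by the rate law.  Must be >= 0.
    orders
        Optional per-species exponent overrides for the rate law.  By
        default the rate is k * prod [R]^stoich over the reactants; an entry
        here replaces that species' exponent, which is how empirical
        fractional orders (e.g. ~0.7 in an arylamine) are emulated without
        modelling the full catalytic network.
    """

    reactants: dict[str, float]
    products: dict[str, float]
    k: float
    orders: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.k}")
        if not self.reactants and not self.products:
            raise ValueError("reaction with no species")
        for name, exp in self.orders.items():
            if not np.isfinite(exp):
                raise ValueError(f"order override for {name!r} is not finite")

    def exponent(self, species: str) -> float:
        """Rate-law exponent for *species* (override or stoichiometry)."""
        if species in self.orders:
            return self.orders[species]
        return self.reactants.get(species, 0.0)


@dataclass(frozen=True)
class ReactionNetwork:
    """A set of species and the reactions coupling them."""

    species: list[str]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError("network must contain at least one reaction")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        known = set(self.species)
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products, *rxn.orders):
                if name not in known:
                    raise ValueError(f"reaction references unknown species {name!r}")

    def index(self, species: str) -> int:
        return self.species.index(species)


@dataclass(frozen=True)
class ConcentrationTrace:
    """Species concentrations (mM) sampled on a common time grid (minutes)."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if times[0] < 0:
            raise ValueError("times must start at >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        concs = {}
        for name, values in self.concentrations.items():
            values = np.asarray(values, dtype=float)
            if values.shape != times.shape:
                raise ValueError(f"trace for {name!r} has wrong length")
            if np.any(values < 0):
                raise ValueError(f"negative concentration in trace for {name!r}")
            concs[name] = values
        object.__setattr__(self, "concentrations", concs)

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    @property
    def species(self) -> list[str]:
        return list(self.concentrations)


def _rhs(network: ReactionNetwork, t: float, y: np.ndarray) -> np.ndarray:
    """Mass-action right-hand side with optional fractional orders.

    Concentrations are floored at 0 inside the rate evaluation so that
    fractional exponents never see tiny negative integrator excursions.
    """
    c = np.maximum(y, 0.0)
    dydt = np.zeros_like(y)
    for rxn in network.reactions:
        rate = rxn.k
        for name in set(rxn.reactants) | set(rxn.orders):
            exp = rxn.exponent(name)
            if exp != 0.0:
                rate *= c[network.index(name)] ** exp
        for name, stoich in rxn.reactants.items():
            dydt[network.index(name)] -= stoich * rate
        for name, stoich in rxn.products.items():
            dydt[network.index(name)] += stoich * rate
    return dydt


def simulate_network(
    network: ReactionNetwork,
    initial: dict[str, float],
    times: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationTrace:
    """Integrate the network's rate laws and sample at the given times.

    Parameters
    ----------
    network
        The reaction network.
    initial
        Initial concentration (mM) for every species in the network.
        Species omitted here are an error, not an implicit zero, to catch
        typos in species names.
    times
        Strictly increasing sample times in minutes; the integration starts
        at t = 0 with *initial* regardless of ``times[0]``.
    rtol, atol
        Integrator tolerances.  The defaults are tight because complexation
        networks with well-separated rate constants can be stiff; the LSODA
        integrator switches method automatically.

    Returns
    -------
    ConcentrationTrace
        Concentrations clipped at 0, one column per network species.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must start at >= 0")
    unknown = set(initial) - set(network.species)
    if unknown:
        raise ValueError(f"initial concentrations for unknown species: {sorted(unknown)}")
    missing = set(network.species) - set(initial)
    if missing:
        raise ValueError(f"missing initial concentrations: {sorted(missing)}")
    y0 = np.array([float(initial[s]) for s in network.species])
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be >= 0")

    t_end = float(times[-1])
    if t_end == 0.0:
        y = np.repeat(y0[:, None], times.size, axis=1)
    else:
        sol = solve_ivp(
            lambda t, y: _rhs(network, t, y),
            (0.0, t_end),
            y0,
            method="LSODA",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y
    y = np.maximum(y, 0.0)
    return ConcentrationTrace(
        times=times,
        concentrations={s: y[i] for i, s in enumerate(network.species)},
    )


def closed_form_pseudo_first_order(
    A0: float, k2: float, B0: float, t: np.ndarray | float
) -> np.ndarray | float:
    """Closed form [A](t) = A0 * exp(-k2*B0*t) for B in large excess.

    The reference oracle for pseudo-first-order conditions: with the excess
    reagent B effectively constant, the limiting reagent decays
    exponentially with observed constant k_obs = k2 * B0 (min^-1).

    All arguments must be >= 0 (k2 in mM^-1 min^-1, concentrations in mM,
    t in minutes).
    """
    if A0 < 0 or k2 < 0 or B0 < 0:
        raise ValueError("A0, k2 and B0 must all be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = A0 * np.exp(-k2 * B0 * t)
    return out if out.ndim else float(out)


def sample_schedule(interval_s: float, n_points: int, t0_min: float = 0.0) -> np.ndarray:
    """Arithmetic acquisition schedule in minutes.

    Bench instruments are configured with a sampling interval in seconds
    (e.g. one spectrum every 82 s or 112 s); this converts to the package's
    internal minutes.

    Returns ``t0_min + arange(n_points) * interval_s / 60``.
    """
    if interval_s <= 0:
        raise ValueError("interval must be > 0 seconds")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return t0_min + np.arange(n_points, dtype=float) * (interval_s / 60.0)
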