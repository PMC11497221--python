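"""Parameter-recovery harnesses: run the full pipeline on synthetic data
generated at the studies' printed designs and measure what comes back.

Each harness returns per-replicate estimates so callers can report means
and Monte-Carlo spread.  All randomness derives from a single seed via
``numpy.random.SeedSequence`` spawning, so a harness is reproducible from
(design, seed) alone.
"""

from __future__ import annotations

import numpy as np

from . import studies
from .campaign import hammett_campaign, pseudo_first_order_series, run_campaign
from .kinetics import HANSCH_SIGMA, fit_initial_rate, loglog_order

__all__ = [
    "recover_k2",
    "recover_rho",
    "recover_order",
    "recover_order_from_campaign",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def recover_k2(
    n_replicates: int = 50,
    seed: int = 0,
    *,
    k2_true: float = studies.IEDDA_K2,
    relative_sigma: float = 0.01,
) -> np.ndarray:
    """k2 estimates from the IEDDA pseudo-first-order pipeline.

    Per replicate: simulate the three excess experiments (1.5 mM limiting
    reagent; 100/150/200 mM excess; 20 points at 82 s) with 1% spectral
    noise, render and process the UV-Vis stream, fit initial rates,
    regress k_obs against excess concentration.  Returns the slope
    (mM^-1 min^-1) per replicate.
    """
    out = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        plans = pseudo_first_order_series(
            k2=k2_true, relative_sigma=relative_sigma, seed=s
        )
        result = run_campaign(plans, "initial_rates_k2")
        out[i] = result.inference.slope
    return out


def recover_rho(
    n_replicates: int = 50,
    seed: int = 0,
    *,
    rho_true: float = -0.98,
    rate_noise: float = 0.05,
    relative_sigma: float = 0.01,
    substituents: list[str] | None = None,
) -> np.ndarray:
    """rho estimates from the full Hammett campaign pipeline.

    Per replicate: simulate 8 substituents x 5 concentrations x 15
    timepoints of NMR-monitored tosylation with substituent rate ratios
    following log10(kX/kH) = rho_true * sigma, 5% lognormal rate noise and
    1% spectral noise; run conversion -> initial rate -> log-ratio ->
    sigma regression.  Returns the fitted rho per replicate.
    """
    subs = list(HANSCH_SIGMA) if substituents is None else substituents
    out = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        plans = hammett_campaign(
            subs,
            list(studies.TOSYL_AMINE_MM),
            rho_true=rho_true,
            rate_noise=rate_noise,
            relative_sigma=relative_sigma,
            seed=s,
        )
        result = run_campaign(plans, "hammett")
        out[i] = result.inference.rho
    return out


def recover_order(
    n_true: float,
    n_replicates: int = 50,
    seed: int = 0,
    *,
    rate_noise: float = 0.05,
    concentrations_mM: tuple[float, ...] = studies.TOSYL_AMINE_MM,
) -> np.ndarray:
    """Reaction-order estimates from the log-log design.

    Per replicate: initial rates proportional to [amine]^n_true at the
    five printed concentrations, perturbed by 5% lognormal noise, fitted
    as log10(rate) vs log10(conc).  Returns the slope per replicate.

    This harness probes the log-log estimator itself on its stated noise
    model; :func:`recover_order_from_campaign` runs the same question
    through the whole spectral pipeline.
    """
    rng = np.random.default_rng(seed)
    k = 8.0e-4  # arbitrary prefactor; slopes in log-log space ignore it
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        pairs = [
            (c, k * c**n_true * rng.lognormal(0.0, rate_noise)) for c in concentrations_mM
        ]
        out[i] = loglog_order(pairs).order
    return out


def recover_order_from_campaign(
    n_true: float,
    n_replicates: int = 10,
    seed: int = 0,
    *,
    rate_noise: float = 0.05,
    relative_sigma: float = 0.01,
) -> np.ndarray:
    """Order estimates via simulate -> render -> integrate -> rate -> log-log.

    The end-to-end variant of :func:`recover_order`: conversion traces of
    the tosylation network with the amine order set to ``n_true`` are
    pushed through the full NMR pipeline for a single substituent, and
    the five initial rates fitted in log-log space.
    """
    from .campaign import _initial_rate_of, execute_plan

    out = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        # a single substituent: the Hammett regression needs >= 3, so the
        # order is fitted directly from the five per-concentration rates
        plans = hammett_campaign(
            ["H"],
            list(studies.TOSYL_AMINE_MM),
            amine_order=n_true,
            rate_noise=rate_noise,
            relative_sigma=relative_sigma,
            seed=s,
        )
        pairs = []
        for plan in plans:
            fit = _initial_rate_of(execute_plan(plan))
            pairs.append((plan.meta["concentration_mM"], fit.slope))
        out[i] = loglog_order(pairs).order
    return out
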