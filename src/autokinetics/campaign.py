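"""Experiment plans and campaign runners.

An :class:`ExperimentPlan` is the machine-readable encoding of one
monitored experiment — reagents and concentrations, sampling schedule or
stop condition, spectral signature, processing recipe and noise seed — a
lightweight JSON stand-in for an executable synthesis procedure.  The
plan generators encode the package's three studies; :func:`run_campaign`
executes simulate -> render -> integrate -> fit for every plan and then
the campaign-level inference (k2 regression, VTNA scan, Hammett fit, or
monitored endpoint detection), fully reproducible from (plans, seed).

A monitored run's realized endpoint can be frozen into a
:class:`StaticProtocol` — a fixed-duration plan that replays the same
chemistry without any feedback, the bridge from a dynamic, instrument-
driven procedure to a static one reusable on platforms without analytics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .kinetics import (
    HANSCH_SIGMA,
    HammettResult,
    OrderFit,
    RateFit,
    fit_initial_rate,
    hammett_fit,
    kobs_from_trace,
    kobs_to_k2,
    loglog_order,
)
from .monitor import MonitorConfig, MonitorRecord, run_monitor
from .processing import ProcessingRecipe, trace_from_spectra
from .simulate import ConcentrationTrace, ReactionNetwork, sample_schedule, simulate_network
from .spectra import NoiseModel, SpectralSignature, render_spectrum
from .vtna import VTNAResult, vtna_order_scan
from . import studies

__all__ = [
    "ExperimentPlan",
    "CampaignResult",
    "StaticProtocol",
    "hammett_campaign",
    "pseudo_first_order_series",
    "excess_screen",
    "monitored_plan",
    "run_campaign",
    "freeze_protocol",
    "replay_static",
]

#: Default initial-rate window: the full 15-datapoint acquisition, further
#: shortened by the 20% conversion guard where the observable is a
#: conversion fraction.
DEFAULT_RATE_WINDOW = 15
MAX_CONVERSION_FOR_RATE = 0.20


@dataclass(frozen=True)
class ExperimentPlan:
    """One monitored experiment, fully specified and replayable."""

    id: str
    network: ReactionNetwork
    initial: dict[str, float]
    signature: SpectralSignature
    recipe: ProcessingRecipe
    schedule: tuple[float, int, float] | None = None  # (interval_s, n_points, t0_min)
    monitor: MonitorConfig | None = None
    relative_sigma: float = 0.0
    seed: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.schedule is None) == (self.monitor is None):
            raise ValueError("plan needs exactly one of a fixed schedule or a monitor config")
        if any(v < 0 for v in self.initial.values()):
            raise ValueError("initial concentrations must be >= 0")

    def times(self) -> np.ndarray:
        """Sampling times in minutes (for monitored plans, the worst case)."""
        if self.schedule is not None:
            interval_s, n_points, t0 = self.schedule
            return sample_schedule(interval_s, n_points, t0)
        cfg = self.monitor
        return cfg.dead_time_min + np.arange(cfg.max_measurements) * cfg.interval_min

    def describe(self) -> dict[str, Any]:
        """JSON-able description with step vocabulary close to a synthesis DSL."""
        steps: list[dict[str, Any]] = [
            {"step": "Add", "species": s, "concentration_mM": c}
            for s, c in sorted(self.initial.items())
        ]
        if self.schedule is not None:
            interval_s, n_points, t0 = self.schedule
            steps.append(
                {
                    "step": "MonitorSchedule",
                    "interval_s": interval_s,
                    "n_points": n_points,
                    "t0_min": t0,
                }
            )
        else:
            steps.append(
                {
                    "step": "MonitorUntilPlateau",
                    "window": self.monitor.window,
                    "threshold": self.monitor.threshold,
                    "max_measurements": self.monitor.max_measurements,
                    "interval_min": self.monitor.interval_min,
                }
            )
        return {
            "id": self.id,
            "steps": steps,
            "relative_sigma": self.relative_sigma,
            "seed": self.seed,
            "meta": {k: v for k, v in sorted(self.meta.items())},
        }


@dataclass(frozen=True)
class StaticProtocol:
    """A monitored plan with its realized fixed duration and point count."""

    plan_id: str
    interval_min: float
    n_measurements: int
    duration_min: float
    final_conversion: float
    threshold: float

    def describe(self) -> dict[str, Any]:
        return {
            "plan_id": self.plan_id,
            "interval_min": self.interval_min,
            "n_measurements": self.n_measurements,
            "duration_min": self.duration_min,
            "final_conversion": self.final_conversion,
            "threshold": self.threshold,
        }


@dataclass
class CampaignResult:
    """Per-experiment traces and fits plus the campaign-level inference."""

    analysis: str
    plans: list[ExperimentPlan]
    traces: dict[str, Any]  # plan id -> ConcentrationTrace or conversion DataFrame
    fits: dict[str, RateFit]
    inference: Any  # RateFit | HammettResult | dict[str, VTNAResult] | (MonitorRecord, StaticProtocol)
    orders: dict[str, OrderFit] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        def series(tr: Any) -> Any:
            if isinstance(tr, ConcentrationTrace):
                return {
                    "times_min": tr.times.tolist(),
                    "concentrations_mM": {s: tr[s].tolist() for s in tr.species},
                }
            if isinstance(tr, pd.DataFrame):
                return tr.to_dict(orient="list")
            return tr

        def fit(f: RateFit) -> dict[str, Any]:
            return {
                "slope": f.slope,
                "intercept": f.intercept,
                "stderr_slope": f.stderr_slope,
                "r_squared": f.r_squared,
                "window": list(f.window),
            }

        payload: dict[str, Any] = {
            "analysis": self.analysis,
            "plans": [p.describe() for p in self.plans],
            "traces": {k: series(v) for k, v in self.traces.items()},
            "fits": {k: fit(v) for k, v in self.fits.items()},
            "provenance": self.provenance,
        }
        inf = self.inference
        if isinstance(inf, RateFit):
            payload["inference"] = fit(inf)
        elif isinstance(inf, HammettResult):
            payload["inference"] = {
                "rho": inf.rho,
                "stderr_rho": inf.stderr_rho,
                "intercept": inf.intercept,
                "r_squared": inf.r_squared,
                "points": {k: list(v) for k, v in inf.points.items()},
            }
        elif isinstance(inf, dict):
            payload["inference"] = {
                k: {
                    "best_alpha": v.best_alpha,
                    "grid": v.grid.tolist(),
                    "scores": v.scores.tolist(),
                }
                for k, v in inf.items()
            }
        elif isinstance(inf, tuple):
            record, protocol = inf
            payload["inference"] = {
                "monitor_record": json.loads(record.to_json()),
                "static_protocol": protocol.describe() if protocol else None,
            }
        if self.orders:
            payload["orders"] = {
                k: {"order": v.order, "stderr": v.stderr} for k, v in self.orders.items()
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_hash(plans: list[ExperimentPlan]) -> str:
    blob = json.dumps([p.describe() for p in plans], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Plan generators for the three studies
# ---------------------------------------------------------------------------


def hammett_campaign(
    substituents: list[str],
    concentrations_mM: list[float],
    n_points: int = studies.TOSYL_N_POINTS,
    interval_s: float = studies.TOSYL_INTERVAL_S,
    *,
    rho_true: float = 0.0,
    sigmas: dict[str, float] | None = None,
    k_ref: float = studies.TOSYL_K_REF,
    amine_order: float = 0.7,
    tscl0_mM: float = studies.TOSYL_TSCL0_MM,
    rate_noise: float = 0.0,
    relative_sigma: float = 0.0,
    seed: int = 0,
) -> list[ExperimentPlan]:
    """Plans for the tosylation Hammett campaign.

    One plan per (substituent, amine concentration), substituent-major
    order — each arylamine's experiments run back-to-back, as required
    when a shared catalyst stock degrades over time.  Substituent rate
    constants follow log10(k_X / k_ref) = rho_true * sigma_X, optionally
    perturbed per experiment by lognormal noise of width ``rate_noise``
    (the run-to-run irreproducibility of a real platform).
    """
    if not substituents or not concentrations_mM:
        raise ValueError("substituents and concentrations must be non-empty")
    if len(set(substituents)) != len(substituents) or len(set(concentrations_mM)) != len(
        concentrations_mM
    ):
        raise ValueError("duplicate substituent or concentration in campaign")
    sigmas = HANSCH_SIGMA if sigmas is None else sigmas
    missing = sorted(set(substituents) - set(sigmas))
    if missing:
        raise ValueError(f"no sigma constant for substituents: {missing}")
    signature = studies.tosylation_signature()
    recipe = studies.tosylation_recipe()
    rng = np.random.default_rng(seed)
    plans = []
    for sub in substituents:
        k_sub = k_ref * 10.0 ** (rho_true * sigmas[sub])
        for conc in concentrations_mM:
            k_eff = k_sub * (rng.lognormal(0.0, rate_noise) if rate_noise > 0 else 1.0)
            plan_seed = int(rng.integers(0, 2**31 - 1))
            plans.append(
                ExperimentPlan(
                    id=f"tosylation[{sub}]@{conc:g}mM",
                    network=studies.tosylation_network(k=k_eff, amine_order=amine_order),
                    initial={"TsCl": tscl0_mM, "ArNH2": conc, "TsNHAr": 0.0},
                    signature=signature,
                    recipe=recipe,
                    schedule=(interval_s, n_points, 0.0),
                    relative_sigma=relative_sigma,
                    seed=plan_seed,
                    meta={"substituent": sub, "concentration_mM": conc, "sigma": sigmas[sub]},
                )
            )
    return plans


def pseudo_first_order_series(
    A0_mM: float = studies.IEDDA_A0_MM,
    excess_levels_mM: list[float] | tuple[float, ...] = studies.IEDDA_EXCESS_MM,
    n_points: int = studies.IEDDA_N_POINTS,
    interval_s: float = studies.IEDDA_INTERVAL_S,
    *,
    k2: float = studies.IEDDA_K2,
    relative_sigma: float = 0.0,
    seed: int = 0,
) -> list[ExperimentPlan]:
    """Plans for the IEDDA pseudo-first-order excess series."""
    if not excess_levels_mM:
        raise ValueError("excess_levels_mM must be non-empty")
    if len(set(excess_levels_mM)) != len(tuple(excess_levels_mM)):
        raise ValueError("duplicate excess level")
    signature = studies.iedda_signature()
    recipe = studies.iedda_recipe()
    rng = np.random.default_rng(seed)
    plans = []
    for excess in excess_levels_mM:
        plans.append(
            ExperimentPlan(
                id=f"iedda@{excess:g}mM",
                network=studies.iedda_network(k2=k2),
                initial={"Tz": A0_mM, "EVE": float(excess), "Pz": 0.0},
                signature=signature,
                recipe=recipe,
                schedule=(interval_s, n_points, 0.0),
                relative_sigma=relative_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                meta={"excess_mM": float(excess)},
            )
        )
    return plans


def excess_screen(
    standard_equivalents: dict[str, float],
    excess_factor: float = 1.2,
    duration_min: float = studies.IRON_DURATION_MIN,
    interval_s: float = studies.IRON_INTERVAL_S,
    *,
    network: ReactionNetwork | None = None,
    base_mM: float = 1.0,
    signature: SpectralSignature | None = None,
    recipe: ProcessingRecipe | None = None,
    relative_sigma: float = 0.0,
    seed: int = 0,
) -> list[ExperimentPlan]:
    """Standard experiment plus one excess experiment per reagent.

    Each extra plan multiplies one reagent's initial concentration by
    ``excess_factor`` (> 1); overlaying each pair against the standard is
    the VTNA read-out of that reagent's order.
    """
    if excess_factor <= 1.0:
        raise ValueError("excess_factor must be > 1")
    if not standard_equivalents:
        raise ValueError("standard_equivalents must be non-empty")
    network = studies.iron_network() if network is None else network
    signature = studies.iron_signature() if signature is None else signature
    recipe = studies.iron_recipe() if recipe is None else recipe
    n_points = int(np.floor(duration_min * 60.0 / interval_s)) + 1
    rng = np.random.default_rng(seed)

    def build(tag: str, varied: str | None) -> ExperimentPlan:
        initial = {s: 0.0 for s in network.species}
        for s, eq in standard_equivalents.items():
            initial[s] = eq * base_mM
        if varied is not None:
            initial[varied] *= excess_factor
        return ExperimentPlan(
            id=f"excess-screen[{tag}]",
            network=network,
            initial=initial,
            signature=signature,
            recipe=recipe,
            schedule=(interval_s, n_points, 0.0),
            relative_sigma=relative_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
            meta={"varied": varied or "none"},
        )

    plans = [build("standard", None)]
    plans.extend(build(reagent, reagent) for reagent in standard_equivalents)
    return plans


def monitored_plan(
    network: ReactionNetwork,
    initial: dict[str, float],
    signature: SpectralSignature,
    recipe: ProcessingRecipe,
    config: MonitorConfig,
    *,
    relative_sigma: float = 0.0,
    seed: int = 0,
    plan_id: str = "monitored",
) -> ExperimentPlan:
    """A single plan whose schedule is a plateau-terminated monitor loop."""
    return ExperimentPlan(
        id=plan_id,
        network=network,
        initial=initial,
        signature=signature,
        recipe=recipe,
        monitor=config,
        relative_sigma=relative_sigma,
        seed=seed,
        meta={},
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _grid_for(plan: ExperimentPlan) -> np.ndarray:
    if plan.signature.modality == "nmr":
        return studies.tosylation_grid()
    centers = [p.center for p in plan.signature.all_peaks()]
    widths = [p.width for p in plan.signature.all_peaks()]
    lo = min(c - 6 * w for c, w in zip(centers, widths))
    hi = max(c + 6 * w for c, w in zip(centers, widths))
    return np.arange(lo, hi + 1.0, 1.0)


def execute_plan(plan: ExperimentPlan) -> Any:
    """simulate -> render -> integrate for one fixed-schedule plan.

    Returns the kinetic series the plan's recipe produces: a
    ConcentrationTrace (calibrated absorbance mode) or a conversion
    DataFrame (NMR mode).
    """
    if plan.schedule is None:
        raise ValueError("execute_plan handles fixed schedules; use run_monitor for monitored plans")
    times = plan.times()
    trace = simulate_network(plan.network, plan.initial, times)
    noise = NoiseModel(relative_sigma=plan.relative_sigma, seed=plan.seed)
    grid = _grid_for(plan)
    spectra = [
        render_spectrum(trace, i, plan.signature, grid, noise) for i in range(len(trace))
    ]
    return trace_from_spectra(spectra, plan.recipe)


def _simulated_stream(plan: ExperimentPlan):
    """Lazy spectrum stream for a monitored plan (the in-process simulator)."""
    times = plan.times()
    trace = simulate_network(plan.network, plan.initial, times)
    noise = NoiseModel(relative_sigma=plan.relative_sigma, seed=plan.seed)
    grid = _grid_for(plan)
    for i in range(len(trace)):
        yield render_spectrum(trace, i, plan.signature, grid, noise)


def _initial_rate_of(series: Any) -> RateFit:
    if isinstance(series, ConcentrationTrace):
        species = series.species[0]
        return fit_initial_rate(series.times, series[species], window=min(DEFAULT_RATE_WINDOW, len(series)))
    conv = series["conversion"].to_numpy()
    times = series["time_min"].to_numpy()
    return fit_initial_rate(
        times,
        conv,
        window=min(DEFAULT_RATE_WINDOW, times.size),
        max_conversion=MAX_CONVERSION_FOR_RATE,
    )


def _reagent_traces_from_product(
    plan: ExperimentPlan, product_trace: ConcentrationTrace
) -> ConcentrationTrace:
    """Reconstruct reagent time courses from the monitored product.

    With only the product observable (the usual UV-Vis situation), every
    reagent's concentration follows from stoichiometric bookkeeping:
    [R](t) = [R]0 - nu_R * [P](t).  Reconstruction keeps the whole
    pipeline honest about what the instrument actually measured.
    """
    product = product_trace.species[0]
    p = product_trace[product]
    concs: dict[str, np.ndarray] = {product: p}
    rxn = plan.network.reactions[0]
    nu_p = rxn.products.get(product, 1.0)
    for reagent, nu_r in rxn.reactants.items():
        concs[reagent] = np.maximum(plan.initial[reagent] - (nu_r / nu_p) * p, 0.0)
    return ConcentrationTrace(times=product_trace.times, concentrations=concs)


def run_campaign(plans: list[ExperimentPlan], analysis: str) -> CampaignResult:
    """Execute every plan and the requested campaign-level inference.

    analysis is one of ``initial_rates_k2``, ``vtna``, ``hammett`` or
    ``monitor``; an incompatible plan/analysis pairing is rejected with an
    explanation.
    """
    ids = [p.id for p in plans]
    if len(set(ids)) != len(ids):
        raise ValueError("plan ids must be unique within a campaign")
    if analysis not in ("initial_rates_k2", "vtna", "hammett", "monitor"):
        raise ValueError(f"unknown analysis {analysis!r}")

    provenance = {
        "config_hash": _config_hash(plans),
        "seeds": {p.id: p.seed for p in plans},
        "analysis": analysis,
    }

    if analysis == "monitor":
        if len(plans) != 1 or plans[0].monitor is None:
            raise ValueError("monitor analysis needs exactly one monitored plan")
        plan = plans[0]
        record = run_monitor(_simulated_stream(plan), plan.recipe, plan.monitor)
        protocol = freeze_protocol(record, plan) if record.stop_reason == "plateau" else None
        conv = pd.DataFrame(
            {
                "time_min": [p.time for p in record.conversions],
                "conversion": [p.conversion for p in record.conversions],
            }
        )
        return CampaignResult(
            analysis=analysis,
            plans=plans,
            traces={plan.id: conv},
            fits={},
            inference=(record, protocol),
            provenance=provenance,
        )

    if any(p.schedule is None for p in plans):
        raise ValueError(f"analysis {analysis!r} needs fixed-schedule plans")

    traces = {p.id: execute_plan(p) for p in plans}

    if analysis == "initial_rates_k2":
        fits: dict[str, RateFit] = {}
        pairs = []
        for plan in plans:
            series = traces[plan.id]
            if not isinstance(series, ConcentrationTrace):
                raise ValueError("initial_rates_k2 needs concentration traces (calibrated UV-Vis)")
            species = series.species[0]
            window = min(DEFAULT_RATE_WINDOW, len(series))
            kobs, fit = kobs_from_trace(series.times, series[species], window=window)
            fits[plan.id] = fit
            pairs.append((plan.meta["excess_mM"], kobs))
        inference = kobs_to_k2(pairs)
        return CampaignResult(analysis, plans, traces, fits, inference, provenance=provenance)

    if analysis == "vtna":
        by_varied: dict[str, ExperimentPlan] = {}
        standard = None
        full_traces: dict[str, ConcentrationTrace] = {}
        for plan in plans:
            series = traces[plan.id]
            if not isinstance(series, ConcentrationTrace):
                raise ValueError("vtna needs concentration traces (calibrated UV-Vis)")
            full_traces[plan.id] = _reagent_traces_from_product(plan, series)
            varied = plan.meta.get("varied", "none")
            if varied == "none":
                standard = plan
            else:
                by_varied[varied] = plan
        if standard is None or not by_varied:
            raise ValueError("vtna needs one standard plan plus >= 1 excess plan")
        observed = plans[0].recipe.species
        inference_v: dict[str, VTNAResult] = {}
        for varied, plan in by_varied.items():
            inference_v[varied] = vtna_order_scan(
                [full_traces[standard.id], full_traces[plan.id]],
                observed=observed,
                varied=varied,
                grid=np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10),
            )
        return CampaignResult(analysis, plans, traces, {}, inference_v, provenance=provenance)

    # hammett
    fits = {}
    rates_by_sub: dict[str, dict[float, float]] = {}
    sigmas: dict[str, float] = {}
    for plan in plans:
        series = traces[plan.id]
        if isinstance(series, ConcentrationTrace):
            raise ValueError("hammett needs conversion series (NMR mode)")
        fit = _initial_rate_of(series)
        fits[plan.id] = fit
        sub = plan.meta["substituent"]
        sigmas[sub] = plan.meta["sigma"]
        rates_by_sub.setdefault(sub, {})[plan.meta["concentration_mM"]] = fit.slope
    orders = {
        sub: loglog_order(sorted(rates.items())) for sub, rates in rates_by_sub.items()
    }
    reference_conc = max(next(iter(rates_by_sub.values())))
    rates_at_ref = {sub: rates[reference_conc] for sub, rates in rates_by_sub.items()}
    inference_h = hammett_fit(rates_at_ref, sigmas, reference="H")
    return CampaignResult(
        analysis, plans, traces, fits, inference_h, orders=orders, provenance=provenance
    )


def freeze_protocol(record: MonitorRecord, plan: ExperimentPlan) -> StaticProtocol:
    """Freeze a plateau-terminated run into a fixed-duration protocol."""
    if record.stop_reason != "plateau" or record.stopped_at is None:
        raise ValueError("cannot verify endpoint: monitored run did not reach plateau")
    cfg = plan.monitor
    n = record.stopped_at + 1
    return StaticProtocol(
        plan_id=plan.id,
        interval_min=cfg.interval_min,
        n_measurements=n,
        duration_min=record.conversions[-1].time,
        final_conversion=record.conversions[-1].conversion,
        threshold=cfg.threshold,
    )


def replay_static(protocol: StaticProtocol, plan: ExperimentPlan, seed: int | None = None) -> float:
    """Re-run the frozen protocol without monitoring; return final conversion.

    The replay uses the same chemistry on a fixed schedule of
    ``n_measurements`` points; a fresh noise seed emulates a fresh run.
    """
    cfg = plan.monitor
    replay = ExperimentPlan(
        id=f"{plan.id}-replay",
        network=plan.network,
        initial=plan.initial,
        signature=plan.signature,
        recipe=plan.recipe,
        schedule=(protocol.interval_min * 60.0, protocol.n_measurements, cfg.dead_time_min),
        relative_sigma=plan.relative_sigma,
        seed=plan.seed if seed is None else seed,
        meta=dict(plan.meta),
    )
    series = execute_plan(replay)
    return float(series["conversion"].to_numpy()[-1])
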