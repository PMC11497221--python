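"""Windowed plateau detection and the monitored-acquisition loop.

Emulates the dynamic stop condition of a feedback-controlled synthesis:
spectra are acquired one at a time, reduced to a conversion value, and the
run terminates once the spread (max - min) of the most recent W values
falls below a threshold epsilon — a while-loop whose exit condition is
measured, not scheduled.  A raw-spectrum mode is available behind a config
switch for analytes without a clean conversion observable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np

from .processing import ConversionPoint, ProcessingRecipe
from .spectra import Spectrum

__all__ = [
    "MonitorConfig",
    "MonitorRecord",
    "plateau_reached",
    "run_monitor",
    "directory_stream",
]


@dataclass(frozen=True)
class MonitorConfig:
    """Stop-condition parameters.

    window
        W, the number of most-recent measurements compared.
    threshold
        epsilon, the maximum allowed spread (conversion units, or AU in
        raw-spectrum mode) within the window.
    max_measurements
        Hard cap on acquisitions; the safety net when no plateau arrives.
    interval_min
        Minutes between acquisitions (bookkeeping for frozen protocols).
    metric
        "conversion" (default; decide on the derived conversion value) or
        "spectrum_linf" (decide on the max pointwise distance between raw
        spectra in the window).
    dead_time_min
        Delay before the first measurement; mixing-to-instrument transfer
        on a real platform, 0 in simulation.
    """

    window: int
    threshold: float
    max_measurements: int
    interval_min: float = 7.5
    metric: str = "conversion"
    dead_time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.max_measurements < self.window:
            raise ValueError("max_measurements must be >= window")
        if self.metric not in ("conversion", "spectrum_linf"):
            raise ValueError("metric must be 'conversion' or 'spectrum_linf'")


@dataclass(frozen=True)
class MonitorRecord:
    """The decision trail of one monitored run."""

    conversions: list[ConversionPoint]
    stopped_at: int | None
    stop_reason: str  # "plateau" | "max_reached"
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "conversions": [
                    {"time_min": p.time, "conversion": p.conversion}
                    for p in self.conversions
                ],
                "stopped_at": self.stopped_at,
                "stop_reason": self.stop_reason,
                "warnings": self.warnings,
            },
            indent=2,
        )


def plateau_reached(values: list[float] | np.ndarray, window: int, threshold: float) -> bool:
    """True iff >= window values exist and the last window of them spans <= threshold."""
    if window < 2:
        raise ValueError("window must be >= 2")
    values = np.asarray(values, dtype=float)
    if values.size < window:
        return False
    recent = values[-window:]
    return float(np.max(recent) - np.min(recent)) <= threshold


def run_monitor(
    stream: Iterator[Spectrum] | Callable[[], Spectrum | None],
    recipe: ProcessingRecipe,
    config: MonitorConfig,
) -> MonitorRecord:
    """Acquire, convert and test after every measurement until plateau.

    ``stream`` yields spectra in time order (an iterator, or a callable
    returning None when exhausted).  Stops at the first window whose spread
    is within threshold, or at ``max_measurements``; premature stream
    exhaustion is recorded as ``max_reached`` with a warning.
    """
    if callable(stream) and not hasattr(stream, "__next__"):
        source = iter(stream, None)
    else:
        source = iter(stream)

    points: list[ConversionPoint] = []
    observables: list[float] = []
    raw: list[np.ndarray] = []
    warnings_log: list[str] = []
    last_time = -np.inf
    for i in range(config.max_measurements):
        try:
            spectrum = next(source)
        except StopIteration:
            warnings_log.append(
                f"stream exhausted after {i} measurements, before a plateau decision"
            )
            return MonitorRecord(points, None, "max_reached", warnings_log)
        if spectrum.timestamp <= last_time:
            raise ValueError("stream yielded spectra out of time order")
        last_time = spectrum.timestamp
        conversion = recipe.conversion_of(spectrum)
        points.append(ConversionPoint(time=spectrum.timestamp, conversion=conversion))
        if config.metric == "conversion":
            observables.append(conversion)
            if plateau_reached(observables, config.window, config.threshold):
                return MonitorRecord(points, i, "plateau", warnings_log)
        else:
            raw.append(spectrum.y)
            if len(raw) >= config.window:
                block = np.vstack(raw[-config.window :])
                spread = float(np.max(block.max(axis=0) - block.min(axis=0)))
                if spread <= config.threshold:
                    return MonitorRecord(points, i, "plateau", warnings_log)
    if len(points) < config.window:
        warnings_log.append("fewer measurements than the window size")
    return MonitorRecord(points, None, "max_reached", warnings_log)


def directory_stream(path: str | Path) -> Iterator[Spectrum]:
    """Yield spectra from a directory of CSV+JSON files, sorted by timestamp."""
    from .io import load_spectrum

    files = sorted(Path(path).glob("*.csv"))
    spectra = [load_spectrum(f) for f in files]
    spectra.sort(key=lambda s: s.timestamp)
    yield from spectra
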