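"""Turning spectra into kinetic observables.

Region integration with an optional linear endpoint baseline, conversion
from integral ratios, absorbance lookup, and the assembly of a time series
from a stack of monitored spectra.  Conversion follows the standard NMR
bookkeeping: product peak integral over the sum of integrals of all
related species, which needs no calibration because NMR signals are
directly proportional to concentration.  UV-Vis traces instead take a
linear response factor (AU per mM) when concentrations are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .simulate import ConcentrationTrace
from .spectra import Spectrum

__all__ = [
    "Region",
    "SpectrumSegment",
    "IntegrationResult",
    "ConversionPoint",
    "ProcessingRecipe",
    "baseline_correct",
    "integrate_region",
    "conversion_from_integrals",
    "absorbance_at",
    "trace_from_spectra",
]


@dataclass(frozen=True)
class Region:
    """A labelled x-axis window (ppm or nm), lo < hi."""

    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region {self.label!r}: lo must be < hi")
        if not self.label:
            raise ValueError("region label must be non-empty")


class SpectrumSegment(NamedTuple):
    """An ascending-x slice of a spectrum (orientation normalized)."""

    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class IntegrationResult:
    region: Region
    value: float
    baseline_method: str
    timestamp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("integral is not finite")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")


@dataclass(frozen=True)
class ConversionPoint:
    """Conversion fraction in [0, 1] at a time in minutes."""

    time: float
    conversion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion <= 1.0:
            raise ValueError("conversion must lie in [0, 1]")


def _segment(spectrum: Spectrum, region: Region) -> SpectrumSegment:
    """Ascending-x slice of the spectrum inside the region."""
    x, y = spectrum.x, spectrum.y
    if x[0] > x[-1]:  # descending ppm axis
        x, y = x[::-1], y[::-1]
    if region.lo < x[0] or region.hi > x[-1]:
        raise ValueError(
            f"region {region.label!r} [{region.lo}, {region.hi}] outside "
            f"spectrum range [{x[0]}, {x[-1]}]"
        )
    mask = (x >= region.lo) & (x <= region.hi)
    return SpectrumSegment(x[mask], y[mask])


def baseline_correct(spectrum: Spectrum, region: Region) -> SpectrumSegment:
    """Subtract a straight line through the region's endpoint intensities.

    Returns the region's samples (ascending x) with the chord between the
    first and last intensity removed — the simplest correction that zeros
    both a constant offset and a linear drift under an isolated peak.
    """
    seg = _segment(spectrum, region)
    if seg.x.size < 3:
        raise ValueError(f"region {region.label!r} must contain >= 3 samples")
    slope = (seg.y[-1] - seg.y[0]) / (seg.x[-1] - seg.x[0])
    baseline = seg.y[0] + slope * (seg.x - seg.x[0])
    return SpectrumSegment(seg.x, seg.y - baseline)


def integrate_region(
    spectrum: Spectrum, region: Region, baseline: str = "none"
) -> IntegrationResult:
    """Trapezoidal area of the (optionally baseline-corrected) region.

    The segment is taken in ascending-x order regardless of the stored axis
    direction, so a positive peak always yields a positive area.
    ``baseline`` is ``"none"`` or ``"linear"`` (endpoint chord subtraction).
    """
    if baseline not in ("none", "linear"):
        raise ValueError("baseline must be 'none' or 'linear'")
    if baseline == "linear":
        seg = baseline_correct(spectrum, region)
    else:
        seg = _segment(spectrum, region)
    if seg.x.size < 2:
        raise ValueError(f"region {region.label!r} contains fewer than 2 samples")
    area = float(np.trapezoid(seg.y, seg.x))
    return IntegrationResult(
        region=region, value=area, baseline_method=baseline, timestamp=spectrum.timestamp
    )


def conversion_from_integrals(product_area: float, total_areas: list[float]) -> float:
    """Conversion = product integral / sum of all related-species integrals.

    Small negative areas (noise around an empty region) are clipped to 0
    before the ratio; the result is clipped to [0, 1].  A vanishing total
    means no diagnostic signal at all and is rejected.
    """
    product_area = max(float(product_area), 0.0)
    totals = [max(float(a), 0.0) for a in total_areas]
    total = sum(totals)
    if total <= 0.0:
        raise ValueError("no tosyl signal: total integral is zero")
    return float(np.clip(product_area / total, 0.0, 1.0))


def absorbance_at(spectrum: Spectrum, wavelength: float) -> float:
    """Linearly interpolated absorbance at a wavelength (nm)."""
    x, y = spectrum.x, spectrum.y
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    if wavelength < x[0] or wavelength > x[-1]:
        raise ValueError(f"wavelength {wavelength} outside spectrum range [{x[0]}, {x[-1]}]")
    return float(np.interp(wavelength, x, y))


@dataclass(frozen=True)
class ProcessingRecipe:
    """How to reduce one spectrum to one kinetic observable.

    mode="conversion" (NMR): ``product_region`` over the sum of
    ``total_regions`` after the chosen baseline correction.
    mode="absorbance" (UV-Vis): absorbance at ``wavelength`` nm, optionally
    divided by ``calibration`` (AU per mM) to yield a concentration for
    ``species``.
    """

    mode: str
    product_region: Region | None = None
    total_regions: tuple[Region, ...] = ()
    baseline: str = "linear"
    wavelength: float | None = None
    calibration: float | None = None
    species: str = "analyte"

    def __post_init__(self) -> None:
        if self.mode not in ("conversion", "absorbance"):
            raise ValueError("mode must be 'conversion' or 'absorbance'")
        if self.mode == "conversion" and (
            self.product_region is None or not self.total_regions
        ):
            raise ValueError("conversion mode needs product_region and total_regions")
        if self.mode == "absorbance" and self.wavelength is None:
            raise ValueError("absorbance mode needs a wavelength")

    def conversion_of(self, spectrum: Spectrum) -> float:
        product = integrate_region(spectrum, self.product_region, self.baseline).value
        totals = [
            integrate_region(spectrum, r, self.baseline).value for r in self.total_regions
        ]
        return conversion_from_integrals(product, totals)


def trace_from_spectra(
    spectra: list[Spectrum], recipe: ProcessingRecipe
) -> pd.DataFrame | ConcentrationTrace:
    """Reduce a time-ordered stack of spectra to a kinetic series.

    Conversion mode returns a DataFrame with columns ``time_min`` and
    ``conversion``; absorbance mode returns a calibrated
    :class:`ConcentrationTrace` when a response factor is set, else a
    DataFrame with ``time_min`` and ``absorbance``.
    """
    if not spectra:
        return pd.DataFrame(
            columns=["time_min", "conversion" if recipe.mode == "conversion" else "absorbance"]
        )
    modalities = {s.modality for s in spectra}
    if len(modalities) > 1:
        raise ValueError(f"mixed modalities in spectrum stack: {sorted(modalities)}")
    times = np.array([s.timestamp for s in spectra])
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("spectrum timestamps must be strictly increasing")

    if recipe.mode == "conversion":
        conv = [recipe.conversion_of(s) for s in spectra]
        return pd.DataFrame({"time_min": times, "conversion": conv})

    values = np.array([absorbance_at(s, recipe.wavelength) for s in spectra])
    if recipe.calibration is not None:
        conc = np.maximum(values / recipe.calibration, 0.0)
        return ConcentrationTrace(times=times, concentrations={recipe.species: conc})
    return pd.DataFrame({"time_min": times, "absorbance": values})
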