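"""Rendering concentration traces into synthetic NMR / UV-Vis spectra.

A :class:`SpectralSignature` maps each species to a set of peaks; a trace
snapshot is rendered onto an instrument grid by summing lineshapes scaled
by concentration.  NMR peaks are Lorentzian (the natural lineshape of a
well-shimmed magnet) and UV-Vis bands Gaussian; absorbances are additive
per Beer-Lambert.  For NMR, a peak's *response* is its integral per mM
(proportional to proton count); for UV-Vis it is the peak absorbance per
mM at unit path length.

Axis conventions follow the instruments: NMR spectra are stored with ppm
descending, UV-Vis with nm ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ConcentrationTrace

__all__ = [
    "Peak",
    "SpectralSignature",
    "NoiseModel",
    "Spectrum",
    "render_spectrum",
    "render_series",
]

MODALITIES = ("nmr", "uvvis")


@dataclass(frozen=True)
class Peak:
    """One spectral line: center (ppm or nm), HWHM width, response per mM."""

    center: float
    width: float
    response: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.response < 0:
            raise ValueError("peak response must be >= 0")


@dataclass(frozen=True)
class SpectralSignature:
    """Per-species peak lists plus the modality they are rendered as."""

    modality: str
    peaks: dict[str, list[Peak]]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    def all_peaks(self) -> list[Peak]:
        return [p for peaks in self.peaks.values() for p in peaks]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise scaled to the maximum clean signal.

    ``relative_sigma`` is the noise standard deviation as a fraction of the
    spectrum's maximum noiseless intensity; ``baseline_drift`` adds a
    constant offset of ``baseline_drift * index`` per spectrum, emulating a
    slowly wandering baseline over a monitoring run.  The same
    ``(seed, index)`` pair always yields the identical noise realization.
    """

    relative_sigma: float = 0.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


@dataclass(frozen=True)
class Spectrum:
    """One x/y array with a timestamp (minutes) and modality tag."""

    x: np.ndarray
    y: np.ndarray
    modality: str
    timestamp: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.size < 2 or x.shape != y.shape:
            raise ValueError("x and y must be equal-length 1-D arrays with >= 2 points")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        diffs = np.diff(x)
        if self.modality == "nmr" and not np.all(diffs < 0):
            raise ValueError("NMR x-axis must be strictly descending (ppm)")
        if self.modality == "uvvis" and not np.all(diffs > 0):
            raise ValueError("UV-Vis x-axis must be strictly ascending (nm)")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    # unit-area Lorentzian: integral over the real line is 1
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def _gaussian_peak(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    # unit-height Gaussian parameterized by half-width at half-max
    sigma = hwhm / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def clean_signal(
    concentrations: dict[str, float], signature: SpectralSignature, grid: np.ndarray
) -> np.ndarray:
    """Noiseless spectrum intensities on an ascending grid.

    NMR: each peak contributes integral = concentration * response.
    UV-Vis: each band contributes peak absorbance = concentration * response.
    """
    y = np.zeros_like(grid, dtype=float)
    for species, peaks in signature.peaks.items():
        conc = concentrations.get(species, 0.0)
        if conc == 0.0:
            continue
        for p in peaks:
            if signature.modality == "nmr":
                y += conc * p.response * _lorentzian(grid, p.center, p.width)
            else:
                y += conc * p.response * _gaussian_peak(grid, p.center, p.width)
    return y


def render_spectrum(
    trace: ConcentrationTrace,
    index: int,
    signature: SpectralSignature,
    grid: np.ndarray,
    noise: NoiseModel | None = None,
) -> Spectrum:
    """Render the trace snapshot at ``index`` into a noisy spectrum.

    The grid must cover every signature peak center +/- 5 widths so no
    appreciable peak area falls off the edge.  The returned spectrum carries
    the trace timestamp and the signature's modality, with the axis flipped
    to descending order for NMR.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise ValueError("grid needs >= 2 points")
    if not 0 <= index < len(trace):
        raise IndexError(f"index {index} out of range for trace of length {len(trace)}")
    for p in signature.all_peaks():
        if p.center - 5 * p.width < grid[0] or p.center + 5 * p.width > grid[-1]:
            raise ValueError(
                f"peak at {p.center} (width {p.width}) falls outside grid "
                f"[{grid[0]}, {grid[-1]}]"
            )
    snapshot = {s: trace[s][index] for s in trace.species}
    y = clean_signal(snapshot, signature, grid)
    if noise is not None and (noise.relative_sigma > 0 or noise.baseline_drift != 0):
        scale = noise.relative_sigma * np.max(np.abs(y))
        rng = np.random.default_rng([noise.seed, index])
        y = y + rng.normal(0.0, scale, size=y.shape) if scale > 0 else y.copy()
        y = y + noise.baseline_drift * index
    if signature.modality == "nmr":
        grid, y = grid[::-1], y[::-1]
    return Spectrum(x=grid, y=y, modality=signature.modality, timestamp=float(trace.times[index]))


def render_series(
    trace: ConcentrationTrace,
    signature: SpectralSignature,
    grid: np.ndarray,
    noise: NoiseModel | None = None,
) -> list[Spectrum]:
    """Render every snapshot of the trace, emulating a monitoring run."""
    return [render_spectrum(trace, i, signature, grid, noise) for i in range(len(trace))]
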