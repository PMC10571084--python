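"""Species spectra, channel composition, and ratiometric calibration.

Each emissive species carries a band-sum emission model (Gaussian bands)
and a relative brightness proportional to its extinction coefficient
times quantum yield. Channel intensities are concentration-weighted sums
of per-species band integrals over the channel passband; the readout is
the ratio of two named channels, which cancels sensor concentration and
instrument gain. The inversion from ratio to free metal follows the
standard ratiometric calibration

    [M]_free = Kd * beta * (R - R_min) / (R_max - R),

with beta the denominator-channel brightness of the metal-free form
divided by that of the metal-bound form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .equilibria import (
    Component,
    EquilibriumSystem,
    Reaction,
    SpeciationResult,
    solve_speciation,
)

__all__ = [
    "SpeciesSpectrum",
    "Channel",
    "ChannelSet",
    "RatioMeasurement",
    "evaluate_spectrum",
    "compose_channel_intensities",
    "ratio_isotherm",
    "ratio_to_free_metal",
]


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Emission model for one species.

    ``emission_bands`` is a list of ``(center_nm, width_nm, amplitude)``
    Gaussian bands, with ``width_nm`` the Gaussian sigma. ``brightness``
    scales all bands and is proportional to epsilon * phi.
    """

    species_name: str
    emission_bands: list[tuple[float, float, float]]
    brightness: float = 1.0
    absorption_max: float | None = None
    emission_max: float | None = None

    def __post_init__(self) -> None:
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        for center, width, amplitude in self.emission_bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
            if amplitude < 0:
                raise ValueError(f"band amplitude must be >= 0, got {amplitude}")


@dataclass(frozen=True)
class Channel:
    """A detection passband: ``center_nm`` +/- ``bandwidth_nm``/2."""

    name: str
    center: float
    bandwidth: float

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def grid(self) -> np.ndarray:
        """1 nm wavelength grid across the passband (>= 2 points)."""
        lo = self.center - self.bandwidth / 2.0
        hi = self.center + self.bandwidth / 2.0
        n = max(int(round(self.bandwidth)) + 1, 2)
        return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class ChannelSet:
    """Excitation wavelength (metadata) plus >= 2 detection channels."""

    excitation: float
    channels: list[Channel]

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("a ratio requires at least 2 channels")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def __getitem__(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def parse(cls, spec: str, excitation: float = 390.0) -> "ChannelSet":
        """Build from a compact string like ``"F500:500/1,F530:530/1"``."""
        channels = []
        for part in spec.split(","):
            name, _, rest = part.strip().partition(":")
            center, _, bw = rest.partition("/")
            channels.append(Channel(name, float(center), float(bw or 1.0)))
        return cls(excitation=excitation, channels=channels)


@dataclass(frozen=True)
class RatioMeasurement:
    """Two-channel intensities and their ratio at one titration point.

    ``ratio`` is NaN when the denominator intensity is <= 0; the
    measurement is then flagged via ``ratio_defined``.
    """

    x: float
    intensities: dict[str, float]
    numerator: str
    denominator: str
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        den = self.intensities[self.denominator]
        if den <= 0:
            return float("nan")
        return self.intensities[self.numerator] / den

    @property
    def ratio_defined(self) -> bool:
        return self.intensities[self.denominator] > 0


def evaluate_spectrum(
    spectrum: SpeciesSpectrum, wavelength_grid: np.ndarray
) -> np.ndarray:
    """Evaluate the band-sum emission model on a wavelength grid (nm)."""
    grid = np.asarray(wavelength_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid must be non-empty")
    out = np.zeros_like(grid)
    for center, width, amplitude in spectrum.emission_bands:
        out += amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return spectrum.brightness * out


def channel_signal(spectrum: SpeciesSpectrum, channel: Channel) -> float:
    """Band integral of one species over one passband (trapezoid, 1 nm)."""
    grid = channel.grid()
    return float(np.trapezoid(evaluate_spectrum(spectrum, grid), grid))


def compose_channel_intensities(
    speciation: SpeciationResult,
    spectra: dict[str, SpeciesSpectrum],
    channels: ChannelSet,
    numerator: str,
    denominator: str,
    x: float = float("nan"),
    replicate_id: int = 0,
) -> RatioMeasurement:
    """Concentration-weighted channel intensities for a speciation state.

    A species with nonzero concentration but no spectrum entry is treated
    as non-emissive (brightness 0) with a warning.
    """
    all_conc = dict(speciation.free)
    all_conc.update(speciation.complexes)
    intensities = {c.name: 0.0 for c in channels.channels}
    for species, conc in all_conc.items():
        if conc <= 0:
            continue
        spec = spectra.get(species)
        if spec is None:
            warnings.warn(
                f"species {species!r} has no spectrum; treated as non-emissive",
                stacklevel=2,
            )
            continue
        for ch in channels.channels:
            intensities[ch.name] += conc * channel_signal(spec, ch)
    return RatioMeasurement(
        x=x,
        intensities=intensities,
        numerator=numerator,
        denominator=denominator,
        replicate_id=replicate_id,
    )


def binding_system(
    kd: float,
    s_total: float,
    m_total: float,
    sensor_name: str = "sensor",
    metal_name: str = "Mg",
    complex_name: str | None = None,
) -> EquilibriumSystem:
    """A 1:1 sensor + metal system at the given totals."""
    complex_name = complex_name or f"{sensor_name}_{metal_name}"
    return EquilibriumSystem(
        components=[
            Component(sensor_name, "sensor", s_total),
            Component(metal_name, "metal", m_total),
        ],
        reactions=[
            Reaction(complex_name, {sensor_name: 1, metal_name: 1}, kd)
        ],
    )


def ratio_isotherm(
    kd: float,
    s_total: float,
    metal_grid,
    spectra: dict[str, SpeciesSpectrum],
    channels: ChannelSet,
    numerator: str,
    denominator: str,
    sensor_name: str = "sensor",
    metal_name: str = "Mg",
) -> list[RatioMeasurement]:
    """Predicted ratio vs total metal for a 1:1 titration.

    Composes the speciation solve (ligand depletion included) with the
    channel model at every grid point.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    metal_grid = list(metal_grid)
    if len(metal_grid) < 2:
        raise ValueError("metal grid must have at least 2 points")
    out = []
    for m_total in metal_grid:
        result = solve_speciation(
            binding_system(kd, s_total, m_total, sensor_name, metal_name)
        )
        out.append(
            compose_channel_intensities(
                result, spectra, channels, numerator, denominator, x=m_total
            )
        )
    return out


def ratio_to_free_metal(
    ratio: float, r_min: float, r_max: float, kd: float, beta: float
) -> float:
    """Invert a ratio to free metal: Kd * beta * (R - Rmin) / (Rmax - R).

    ``beta`` is the denominator-channel brightness of the metal-free form
    over that of the metal-bound form; under this convention the
    half-saturation ratio is (R_max + beta * R_min) / (1 + beta).
    """
    if kd <= 0 or beta <= 0:
        raise ValueError("kd and beta must be > 0")
    if not (r_min < ratio < r_max):
        side = "metal-free (ratio <= R_min)" if ratio <= r_min else "saturated (ratio >= R_max)"
        raise ValueError(
            f"ratio {ratio} outside the invertible range "
            f"({r_min}, {r_max}): {side}"
        )
    return kd * beta * (ratio - r_min) / (r_max - ratio)
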