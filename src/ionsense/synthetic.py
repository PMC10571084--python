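"""Synthetic study-data generators with known ground truth.

Every generator composes the forward model (speciation + channel
composition) on a deterministic grid and, when asked for noise, adds
seeded Gaussian noise to the channel intensities with SD expressed as a
fraction of the channel's dynamic range (1% by default, three
replicates — the replicate convention of independent titrations).
Each generator returns ``(table, truth)`` where ``truth`` is a
machine-readable sidecar of the generating parameters; recovery tests
read the truth only from that sidecar.

Generators are pure functions of their arguments: the same seed gives a
byte-identical table. A seed is mandatory whenever noise_sd > 0.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import presets
from .equilibria import Component, EquilibriumSystem, Reaction, solve_speciation
from .photophysics import ChannelSet, channel_signal, compose_channel_intensities

__all__ = [
    "GeneratorConfig",
    "gen_titration_series",
    "gen_ph_series",
    "gen_mgatp_series",
    "gen_cell_population",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared noise/replicate settings for the titration generators."""

    seed: int | None = None
    noise_sd: float = 0.01       # fraction of each channel's dynamic range
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic output")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _default_channels() -> ChannelSet:
    return presets.cuvette_channels()


def _noisy_table(
    x: np.ndarray,
    clean: dict[str, np.ndarray],
    config: GeneratorConfig,
    numerator: str,
    denominator: str,
    x_name: str = "x",
    ratio_floor: float = 1e-3,
) -> pd.DataFrame:
    """Replicate the clean channel traces with seeded Gaussian noise.

    The ratio is set to NaN (flagged undefined) where the denominator
    falls below ``ratio_floor`` times its maximum.
    """
    rng = np.random.default_rng(config.seed) if config.seed is not None else None
    rows = []
    scales = {
        ch: config.noise_sd * (vals.max() - vals.min())
        for ch, vals in clean.items()
    }
    floor = ratio_floor * clean[denominator].max()
    for rep in range(config.replicates):
        for i, xv in enumerate(x):
            row = {x_name: xv, "replicate": rep}
            for ch, vals in clean.items():
                v = vals[i]
                if rng is not None and scales[ch] > 0:
                    v = v + rng.normal(0.0, scales[ch])
                row[ch] = v
            den = row[denominator]
            row["ratio"] = row[numerator] / den if den > floor else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def gen_titration_series(
    kd: float,
    s_total: float = 10e-6,
    config: GeneratorConfig | None = None,
    n_points: int = 15,
    metal_grid=None,
    spectra=None,
    channels: ChannelSet | None = None,
    metal_name: str = "Mg",
) -> tuple[pd.DataFrame, dict]:
    """1:1 metal titration: ratio vs total metal with known Kd.

    Default grid: ``n_points`` log-spaced totals from kd/30 to 30 kd,
    the informative region of the isotherm.
    """
    config = config or GeneratorConfig(noise_sd=0.0)
    spectra = spectra or presets.magzet1_spectra()
    channels = channels or _default_channels()
    num, den = "F530", "F500"
    if metal_grid is None:
        metal_grid = np.logspace(np.log10(kd / 30), np.log10(30 * kd), n_points)
    metal_grid = np.asarray(metal_grid, float)

    clean = {c.name: np.empty(len(metal_grid)) for c in channels.channels}
    for i, m in enumerate(metal_grid):
        system = EquilibriumSystem(
            components=[
                Component("sensor", "sensor", s_total),
                Component(metal_name, "metal", m),
            ],
            reactions=[
                Reaction(f"sensor_{metal_name}", {"sensor": 1, metal_name: 1}, kd)
            ],
        )
        meas = compose_channel_intensities(
            solve_speciation(system), spectra, channels, num, den, x=m
        )
        for ch in clean:
            clean[ch][i] = meas.intensities[ch]

    table = _noisy_table(metal_grid, clean, config, num, den, x_name="x")
    sensor_spec = spectra["sensor"]
    bound_spec = spectra[f"sensor_{metal_name}"]
    den_ch, num_ch = channels[den], channels[num]
    truth = {
        "kd": kd,
        "s_total": s_total,
        "metal": metal_name,
        "r_min": channel_signal(sensor_spec, num_ch) / channel_signal(sensor_spec, den_ch),
        "r_max": channel_signal(bound_spec, num_ch) / channel_signal(bound_spec, den_ch),
        "beta": channel_signal(sensor_spec, den_ch) / channel_signal(bound_spec, den_ch),
        **asdict(config),
    }
    return table, truth


def gen_ph_series(
    pka: float = presets.PKA,
    kd_mg: float = presets.KD_MG_25C,
    mg_total: float = 0.0,
    s_total: float = 10e-6,
    config: GeneratorConfig | None = None,
    ph_grid=None,
    spectra=None,
    channels: ChannelSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """pH titration of the three-species model (SH+, S, and S·Mg).

    Default grid: pH 5 to 8 in 0.25 steps. The protonated form is nearly
    non-emissive, so both channels collapse toward zero at acidic pH and
    the ratio is flagged undefined below the intensity floor.
    """
    config = config or GeneratorConfig(noise_sd=0.0)
    spectra = spectra or presets.magzet1_spectra()
    channels = channels or _default_channels()
    num, den = "F530", "F500"
    if ph_grid is None:
        ph_grid = np.arange(5.0, 8.01, 0.25)
    ph_grid = np.asarray(ph_grid, float)
    if ph_grid.min() < 3 or ph_grid.max() > 10:
        raise ValueError("pH grid must lie within 3-10")

    clean = {c.name: np.empty(len(ph_grid)) for c in channels.channels}
    for i, ph in enumerate(ph_grid):
        components = [Component("sensor", "sensor", s_total), Component("H", "proton")]
        reactions = [Reaction("sensor_H", {"sensor": 1, "H": 1}, 10.0 ** -pka)]
        if mg_total > 0:
            components.append(Component("Mg", "metal", mg_total))
            reactions.append(Reaction("sensor_Mg", {"sensor": 1, "Mg": 1}, kd_mg))
        system = EquilibriumSystem(components, reactions, ph=ph)
        meas = compose_channel_intensities(
            solve_speciation(system), spectra, channels, num, den, x=ph
        )
        for ch in clean:
            clean[ch][i] = meas.intensities[ch]

    table = _noisy_table(ph_grid, clean, config, num, den, x_name="ph")
    truth = {"pka": pka, "kd_mg": kd_mg, "mg_total": mg_total,
             "s_total": s_total, **asdict(config)}
    return table, truth


def gen_mgatp_series(
    kd_sm: float = presets.KD_MG_25C,
    kd_mgatp: float = presets.KD_MGATP,
    kd_ternary: float | None = presets.KD_TERNARY,
    ternary_scale: float = 1.0,
    s_total: float = 20e-6,
    config: GeneratorConfig | None = None,
    mgatp_grid=None,
    spectra=None,
    channels: ChannelSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """MgATP competition series: equimolar Mg/ATP totals per point.

    ``kd_ternary=None`` disables the ternary sensor·Mg·ATP reaction
    (pure-competition limit). Default grid: 12 log-spaced equimolar
    totals from 0.1 to 50 mM.
    """
    config = config or GeneratorConfig(noise_sd=0.0)
    spectra = dict(spectra or presets.magzet1_spectra())
    if ternary_scale != 1.0:
        base = spectra["sensor_Mg_ATP"]
        spectra["sensor_Mg_ATP"] = type(base)(
            base.species_name, base.emission_bands,
            brightness=base.brightness * ternary_scale,
        )
    channels = channels or _default_channels()
    num, den = "F530", "F500"
    if mgatp_grid is None:
        mgatp_grid = np.logspace(np.log10(0.1e-3), np.log10(50e-3), 12)
    mgatp_grid = np.asarray(mgatp_grid, float)

    clean = {c.name: np.empty(len(mgatp_grid)) for c in channels.channels}
    for i, tot in enumerate(mgatp_grid):
        components = [
            Component("sensor", "sensor", s_total),
            Component("Mg", "metal", tot),
            Component("ATP", "ligand", tot),
        ]
        reactions = [
            Reaction("sensor_Mg", {"sensor": 1, "Mg": 1}, kd_sm),
            Reaction("MgATP", {"Mg": 1, "ATP": 1}, kd_mgatp),
        ]
        if kd_ternary is not None:
            reactions.append(
                Reaction("sensor_Mg_ATP", {"sensor": 1, "MgATP": 1}, kd_ternary)
            )
        system = EquilibriumSystem(components, reactions)
        meas = compose_channel_intensities(
            solve_speciation(system), spectra, channels, num, den, x=tot
        )
        for ch in clean:
            clean[ch][i] = meas.intensities[ch]

    table = _noisy_table(mgatp_grid, clean, config, num, den, x_name="x")
    truth = {
        "kd_sm": kd_sm, "kd_mgatp": kd_mgatp, "kd_ternary": kd_ternary,
        "ternary_scale": ternary_scale, "s_total": s_total, **asdict(config),
    }
    return table, truth


def gen_cell_population(
    n_cells: int,
    free_mg_median: float,
    free_mg_cv: float = 0.1,
    kd: float = presets.KD_MG_25C,
    loading_sigma_log: float = 0.5,
    additive_noise_sd: float = 0.0,
    group: str = "",
    seed: int | None = None,
    spectra=None,
    channels: ChannelSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell two-channel intensities for a free-Mg population.

    Per cell: dye loading L is log-normal (sigma of log = 0.5 by
    default, emulating AM-ester loading heterogeneity), free Mg is
    log-normal around ``free_mg_median`` with the given CV, and each
    channel reads L x (band-integrated signal of the free/bound sensor
    mix at that free Mg) plus optional additive Gaussian noise (clipped
    at zero). Loading cancels in the ratio.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if free_mg_median < 0 or free_mg_cv < 0 or loading_sigma_log < 0:
        raise ValueError("distribution parameters must be >= 0")
    stochastic = (
        free_mg_cv > 0 or loading_sigma_log > 0 or additive_noise_sd > 0
    )
    if stochastic and seed is None:
        raise ValueError("a seed is mandatory for stochastic output")
    spectra = spectra or presets.magzet1_spectra()
    channels = channels or presets.flow_channels()
    rng = np.random.default_rng(seed)

    loading = np.exp(rng.normal(0.0, loading_sigma_log, n_cells))
    if free_mg_median > 0 and free_mg_cv > 0:
        sigma = np.sqrt(np.log(1 + free_mg_cv**2))
        mg = free_mg_median * np.exp(rng.normal(0.0, sigma, n_cells))
    else:
        mg = np.full(n_cells, free_mg_median)

    frac = mg / (kd + mg)  # fractional saturation at each cell's free Mg
    sig_free = {c.name: channel_signal(spectra["sensor"], c) for c in channels.channels}
    sig_bound = {
        c.name: channel_signal(spectra["sensor_Mg"], c) for c in channels.channels
    }
    data = {"event_id": np.arange(n_cells)}
    for ch in channels.channels:
        clean = loading * ((1 - frac) * sig_free[ch.name] + frac * sig_bound[ch.name])
        if additive_noise_sd > 0:
            clean = np.clip(clean + rng.normal(0, additive_noise_sd, n_cells), 0, None)
        data[ch.name] = clean
    table = pd.DataFrame(data)
    table["group"] = group
    truth = {
        "free_mg_median": free_mg_median, "free_mg_cv": free_mg_cv, "kd": kd,
        "loading_sigma_log": loading_sigma_log,
        "additive_noise_sd": additive_noise_sd, "n_cells": n_cells,
        "seed": seed, "group": group,
    }
    num, den = channels.channels[1].name, channels.channels[0].name
    truth["r_min"] = sig_free[num] / sig_free[den]
    truth["r_max"] = sig_bound[num] / sig_bound[den]
    return table, truth
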