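"""Bundled MagZet1 / MagDMA constants and synthetic spectra fixtures.

The dissociation constants, pKa, and emission maxima/quantum yields here
are the measured characterization values for the quinoline-dicarboxylate
ratiometric Mg2+ indicators (apparent constants in 50 mM PIPES, 100 mM
KCl, pH 7.0). Band shapes are NOT measured: emission band widths, and
the brightness of the Ca- and Zn-bound forms, were never determined, so
the spectra built here are synthetic fixtures whose maxima and (where
known) brightness match the measured values.
"""

from __future__ import annotations

from .equilibria import Component, EquilibriumSystem, Reaction
from .photophysics import Channel, ChannelSet, SpeciesSpectrum

# Apparent dissociation constants, molar.
KD_MG_25C = 0.14e-3    # Mg2+, 25 C
KD_MG_37C = 0.088e-3   # Mg2+, 37 C
KD_CA_25C = 1.7e-3     # Ca2+, 25 C
KD_CA_37C = 1.7e-3     # Ca2+, 37 C
KD_ZN = 2.6e-9         # Zn2+, 25 C
KD_MGATP = 50e-6       # Mg2+ + ATP <-> MgATP (literature value)
KD_TERNARY = 100e-3    # sensor + MgATP <-> sensor.Mg.ATP
PKA = 7.1              # sensor protonation

# MagDMA (the precursor dimethylamino sensor), 25 C.
MAGDMA_KD_MG = 0.22e-3
MAGDMA_KD_CA = 2.2e-3

MEDIUM = "50 mM PIPES, 100 mM KCl, pH 7.0"

# Quantum yields of the emissive forms (fractional).
PHI_FREE = 0.404
PHI_MG = 0.76

#: Synthetic Gaussian band sigma, nm. Not a measured width.
BAND_SIGMA = 25.0


def magzet1_spectra() -> dict[str, SpeciesSpectrum]:
    """Synthetic single-band spectra fixture for every MagZet1 species.

    Emission maxima: free 500 nm, Mg-bound 530 nm, Ca-bound 520 nm,
    Zn-bound 545 nm, protonated 630 nm. Brightness follows quantum yield
    where measured (free 40.4%, Mg-bound 76%); the Ca- and Zn-bound and
    protonated brightnesses are fixture choices (the protonated form is
    essentially non-emissive). The ternary sensor.Mg.ATP species reuses
    the Mg-bound band by default.
    """
    return {
        "sensor": SpeciesSpectrum(
            "sensor", [(500.0, BAND_SIGMA, 1.0)], brightness=PHI_FREE,
            absorption_max=490.0, emission_max=500.0,
        ),
        "sensor_Mg": SpeciesSpectrum(
            "sensor_Mg", [(530.0, BAND_SIGMA, 1.0)], brightness=PHI_MG,
            absorption_max=395.0, emission_max=530.0,
        ),
        "sensor_Ca": SpeciesSpectrum(
            "sensor_Ca", [(520.0, BAND_SIGMA, 1.0)], brightness=PHI_FREE,
            absorption_max=383.0, emission_max=520.0,
        ),
        "sensor_Zn": SpeciesSpectrum(
            "sensor_Zn", [(545.0, BAND_SIGMA, 1.0)], brightness=0.6,
            absorption_max=410.0, emission_max=545.0,
        ),
        "sensor_H": SpeciesSpectrum(
            "sensor_H", [(630.0, 25.0, 1.0)], brightness=0.02,
            absorption_max=480.0, emission_max=630.0,
        ),
        "sensor_Mg_ATP": SpeciesSpectrum(
            "sensor_Mg_ATP", [(530.0, BAND_SIGMA, 1.0)], brightness=PHI_MG,
            absorption_max=395.0, emission_max=530.0,
        ),
        # non-emissive free metals/ligands and the MgATP complex
        **{
            name: SpeciesSpectrum(name, [], brightness=0.0)
            for name in ("Mg", "Ca", "Zn", "ATP", "MgATP", "H")
        },
    }


def cuvette_channels() -> ChannelSet:
    """F500/F530 single-wavelength channels (1 nm passbands), 390 nm exc."""
    return ChannelSet(
        excitation=390.0,
        channels=[Channel("F500", 500.0, 1.0), Channel("F530", 530.0, 1.0)],
    )


def flow_channels() -> ChannelSet:
    """Flow-cytometry bandpass pair: 450/50 and 530/30, 405 nm excitation."""
    return ChannelSet(
        excitation=405.0,
        channels=[Channel("BP450", 450.0, 50.0), Channel("BP530", 530.0, 30.0)],
    )


def magzet1_system(
    s_total: float,
    mg_total: float = 0.0,
    ca_total: float = 0.0,
    zn_total: float = 0.0,
    atp_total: float = 0.0,
    ph: float | None = None,
    include_ternary: bool = True,
    temperature: str = "25C",
) -> EquilibriumSystem:
    """Build the MagZet1 equilibrium system for the requested totals.

    Only components with nonzero totals (plus the proton when ``ph`` is
    given) and the reactions they support are included. ``temperature``
    selects the 25 C or 37 C Mg2+/Ca2+ constants.
    """
    if temperature not in ("25C", "37C"):
        raise ValueError("temperature must be '25C' or '37C'")
    kd_mg = KD_MG_25C if temperature == "25C" else KD_MG_37C
    kd_ca = KD_CA_25C if temperature == "25C" else KD_CA_37C
    t_label = "25 °C" if temperature == "25C" else "37 °C"

    components = [Component("sensor", "sensor", s_total)]
    reactions: list[Reaction] = []
    if mg_total or atp_total:
        components.append(Component("Mg", "metal", mg_total))
        reactions.append(
            Reaction("sensor_Mg", {"sensor": 1, "Mg": 1}, kd_mg, t_label, MEDIUM)
        )
    if ca_total:
        components.append(Component("Ca", "metal", ca_total))
        reactions.append(
            Reaction("sensor_Ca", {"sensor": 1, "Ca": 1}, kd_ca, t_label, MEDIUM)
        )
    if zn_total:
        components.append(Component("Zn", "metal", zn_total))
        reactions.append(
            Reaction("sensor_Zn", {"sensor": 1, "Zn": 1}, KD_ZN, t_label, MEDIUM)
        )
    if atp_total:
        components.append(Component("ATP", "ligand", atp_total))
        reactions.append(
            Reaction("MgATP", {"Mg": 1, "ATP": 1}, KD_MGATP, t_label, MEDIUM)
        )
        if include_ternary:
            reactions.append(
                Reaction(
                    "sensor_Mg_ATP", {"sensor": 1, "MgATP": 1},
                    KD_TERNARY, t_label, MEDIUM,
                )
            )
    if ph is not None:
        components.append(Component("H", "proton"))
        reactions.append(
            Reaction("sensor_H", {"sensor": 1, "H": 1}, 10.0 ** -PKA, t_label, MEDIUM)
        )
    return EquilibriumSystem(components=components, reactions=reactions, ph=ph)
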