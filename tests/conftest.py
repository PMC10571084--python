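import pytest

from ionsense import presets


@pytest.fixture(scope="session")
def spectra():
    return presets.magzet1_spectra()


@pytest.fixture(scope="session")
def channels():
    return presets.cuvette_channels()


@pytest.fixture(scope="session")
def flow_channels():
    return presets.flow_channels()


@pytest.fixture(scope="session")
def limiting_ratios(spectra, channels):
    """R_min / R_max / beta implied by the spectra fixture (F530/F500)."""
    from ionsense.photophysics import channel_signal

    f500, f530 = channels["F500"], channels["F530"]
    free, bound = spectra["sensor"], spectra["sensor_Mg"]
    return {
        "r_min": channel_signal(free, f530) / channel_signal(free, f500),
        "r_max": channel_signal(bound, f530) / channel_signal(bound, f500),
        "beta": channel_signal(free, f500) / channel_signal(bound, f500),
    }
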