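# MagZet1 system preset.
# Apparent dissociation constants measured in 50 mM PIPES, 100 mM KCl,
# pH 7.0 (averages of three independent titrations). Spectral band
# shapes are synthetic fixtures: only the emission maxima and the
# quantum yields of the free (40.4%) and Mg-bound (76%) forms are
# measured values; band widths and the Ca/Zn-bound and protonated
# brightnesses were never determined.
components:
  - {name: sensor, role: sensor, total: 10, unit: uM}
  - {name: Mg, role: metal, total: 0, unit: mM}
  - {name: Ca, role: metal, total: 0, unit: mM}
  - {name: Zn, role: metal, total: 0, unit: nM}
  - {name: ATP, role: ligand, total: 0, unit: mM}
reactions:
  # sensor + Mg <-> sensor.Mg, 25 C (0.088 mM at 37 C)
  - {product: sensor_Mg, stoichiometry: {sensor: 1, Mg: 1}, kd: 0.14, unit: mM,
     temperature: "25 °C", medium: "50 mM PIPES, 100 mM KCl, pH 7.0"}
  # sensor + Ca <-> sensor.Ca, 25 C
  - {product: sensor_Ca, stoichiometry: {sensor: 1, Ca: 1}, kd: 1.7, unit: mM,
     temperature: "25 °C", medium: "50 mM PIPES, 100 mM KCl, pH 7.0"}
  # sensor + Zn <-> sensor.Zn (nanomolar affinity)
  - {product: sensor_Zn, stoichiometry: {sensor: 1, Zn: 1}, kd: 2.6, unit: nM,
     temperature: "25 °C", medium: "50 mM PIPES, 100 mM KCl, pH 7.0"}
  # Mg + ATP <-> MgATP (literature constant)
  - {product: MgATP, stoichiometry: {Mg: 1, ATP: 1}, kd: 50, unit: uM,
     temperature: "25 °C"}
  # sensor + MgATP <-> sensor.Mg.ATP (weak ternary complex)
  - {product: sensor_Mg_ATP, stoichiometry: {sensor: 1, MgATP: 1}, kd: 100,
     unit: mM, temperature: "25 °C"}
spectra:
  sensor:        {bands: [[500, 25, 1.0]], brightness: 0.404}
  sensor_Mg:     {bands: [[530, 25, 1.0]], brightness: 0.76}
  sensor_Ca:     {bands: [[520, 25, 1.0]], brightness: 0.404}
  sensor_Zn:     {bands: [[545, 25, 1.0]], brightness: 0.6}
  sensor_H:      {bands: [[630, 25, 1.0]], brightness: 0.02}
  sensor_Mg_ATP: {bands: [[530, 25, 1.0]], brightness: 0.76}
  Mg:    {bands: [], brightness: 0}
  Ca:    {bands: [], brightness: 0}
  Zn:    {bands: [], brightness: 0}
  ATP:   {bands: [], brightness: 0}
  MgATP: {bands: [], brightness: 0}
  H:     {bands: [], brightness: 0}
channels:
  excitation: 390
  list:
    - {name: F500, center: 500, bandwidth: 1}
    - {name: F530, center: 530, bandwidth: 1}
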