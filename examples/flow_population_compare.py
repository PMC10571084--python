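"""Flow-style per-cell populations and the chi-square comparison.

Three conditions emulating an in-situ calibration: chelator-loaded
cells (free Mg ~ 0), untreated vehicle (~0.5 mM), and ionophore +
50 mM Mg (saturated). Dye loading varies log-normally per cell but
cancels in the per-cell ratio.
"""

import numpy as np

from ionsense import compare_populations_chi2, gen_cell_population
from ionsense.cellstats import CellEvent, per_cell_ratio


def ratios(df):
    events = [
        CellEvent(int(r["event_id"]), {"BP530": r["BP530"], "BP450": r["BP450"]})
        for _, r in df.iterrows()
    ]
    table, qc = per_cell_ratio(events, "BP530", "BP450")
    return table["ratio"].to_numpy()


chelated, _ = gen_cell_population(1000, free_mg_median=1e-8, seed=1, group="EDTA")
vehicle, _ = gen_cell_population(1000, free_mg_median=0.5e-3, seed=2, group="vehicle")
saturated, truth = gen_cell_population(1000, free_mg_median=50e-3, seed=3, group="Mg+ionophore")

rv = ratios(vehicle)
for name, df in [("EDTA-loaded", chelated), ("Mg+ionophore", saturated)]:
    r = ratios(df)
    comp = compare_populations_chi2(r, rv, group_names=(name, "vehicle"))
    print(f"{name:>13s} vs vehicle: median {np.median(r):8.2f} vs {np.median(rv):6.2f}, "
          f"chi2 = {comp.statistic:8.1f} (df {comp.dof}), p = {comp.p_value:.3g}")

print(f"\nfully bound limit R_max = {truth['r_max']:.1f}; the saturated "
      "population sits near it, the chelated one far below the vehicle — "
      "the ratio tracks intracellular free Mg in both directions.")
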