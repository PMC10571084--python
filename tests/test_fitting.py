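"""Titration fitting: noiseless and seed-pinned stochastic recovery."""

import numpy as np
import pytest

from ionsense import presets
from ionsense.fitting import (
    UninformativeDataError,
    fit_kd_ratio,
    fit_pka,
    fit_ternary,
    selectivity_panel,
    selectivity_ratio,
)
from ionsense.synthetic import (
    GeneratorConfig,
    gen_mgatp_series,
    gen_ph_series,
    gen_titration_series,
)


def depletion_grid(s_total, n=15):
    """Metal grid bracketing the equivalence point for sub-uM Kd fits."""
    return np.logspace(np.log10(s_total / 100), np.log10(100 * s_total), n)


class TestFitKdRatio:
    @pytest.mark.parametrize(
        "kd", [0.14e-3, 0.088e-3, 1.7e-3, 0.22e-3, 2.2e-3]
    )
    def test_noiseless_recovery_mm_range(self, kd):
        table, truth = gen_titration_series(kd, s_total=10e-6)
        res = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"])
        assert res.converged
        assert res.params["kd"] == pytest.approx(truth["kd"], rel=0.01)

    def test_noiseless_recovery_nanomolar_with_depletion(self):
        """Zn-affinity regime: Kd (2.6 nM) far below the 10 uM sensor, so
        nearly all added metal is bound; the fit must model depletion."""
        kd, s_total = 2.6e-9, 10e-6
        table, truth = gen_titration_series(
            kd, s_total=s_total, metal_grid=depletion_grid(s_total)
        )
        res = fit_kd_ratio(table[["x", "ratio"]], s_total)
        assert res.params["kd"] == pytest.approx(truth["kd"], rel=0.02)

    def test_limiting_ratios_recovered(self, limiting_ratios):
        table, truth = gen_titration_series(0.14e-3, s_total=10e-6)
        res = fit_kd_ratio(table[["x", "ratio"]], 10e-6)
        assert res.params["r_min"] == pytest.approx(truth["r_min"], rel=0.01)
        assert res.params["r_max"] == pytest.approx(truth["r_max"], rel=0.01)

    def test_zero_metal_everywhere_uninformative(self):
        pairs = [(0.0, 0.5)] * 3 + [(0.0, 0.5000001)] * 12
        with pytest.raises((UninformativeDataError, ValueError)):
            fit_kd_ratio(pairs, 10e-6)

    def test_flat_ratios_uninformative(self):
        x = np.logspace(-6, -3, 10)
        with pytest.raises(UninformativeDataError):
            fit_kd_ratio(list(zip(x, np.full(10, 0.7))), 10e-6)

    def test_noisy_recovery_within_three_se(self):
        """1% noise, three replicates, fixed seed: truth inside 3 SE."""
        table, truth = gen_titration_series(
            0.14e-3, s_total=10e-6,
            config=GeneratorConfig(seed=7, noise_sd=0.01, replicates=3),
        )
        res = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"])
        assert res.stderr["kd"] is not None and res.stderr["kd"] > 0
        assert abs(res.params["kd"] - truth["kd"]) <= 3 * res.stderr["kd"]

    def test_calibrated_beta_sharpens_noisy_kd(self):
        """Without depletion only Kd*beta is identified; fixing beta at
        its calibration value makes the noisy Kd fit well-conditioned."""
        table, truth = gen_titration_series(
            0.14e-3, s_total=10e-6,
            config=GeneratorConfig(seed=1, noise_sd=0.01, replicates=3),
        )
        free = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"])
        fixed = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"], beta=truth["beta"])
        assert fixed.stderr["kd"] < free.stderr["kd"]
        assert fixed.params["kd"] == pytest.approx(truth["kd"], rel=0.05)
        assert fixed.fixed["beta"] == truth["beta"]

    def test_coverage_of_three_se_interval(self):
        """Across seeds, the 3 SE interval covers truth ~99.7% nominally;
        demand >= 90% at 50 repetitions."""
        hits = 0
        for seed in range(50):
            table, truth = gen_titration_series(
                0.14e-3, s_total=10e-6,
                config=GeneratorConfig(seed=seed, noise_sd=0.01, replicates=3),
            )
            res = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"])
            if res.stderr["kd"] and abs(res.params["kd"] - truth["kd"]) <= 3 * res.stderr["kd"]:
                hits += 1
        assert hits >= 45

    def test_doubling_noise_does_not_bias_estimate(self):
        """Median Kd over seeds moves < 1 median-SE when noise SD doubles."""
        def medians(noise):
            est, ses = [], []
            for seed in range(30):
                table, truth = gen_titration_series(
                    0.14e-3, s_total=10e-6,
                    config=GeneratorConfig(seed=seed, noise_sd=noise, replicates=3),
                )
                res = fit_kd_ratio(table[["x", "ratio"]], truth["s_total"])
                est.append(res.params["kd"])
                ses.append(res.stderr["kd"] or np.inf)
            return np.median(est), np.median(ses)

        m1, _ = medians(0.01)
        m2, se2 = medians(0.02)
        assert abs(m2 - m1) <= se2


class TestFitPka:
    def test_noiseless_recovery(self):
        table, truth = gen_ph_series()
        res = fit_pka(list(zip(table["ph"], table["F500"])))
        assert res.converged
        assert res.params["pka"] == pytest.approx(truth["pka"], abs=0.01)

    def test_flat_series_rejected(self):
        ph = np.linspace(5, 8, 13)
        with pytest.raises(UninformativeDataError):
            fit_pka(list(zip(ph, np.ones(13))))

    def test_unbracketed_inflection_warns(self):
        table, _ = gen_ph_series(pka=8.8, ph_grid=np.linspace(5.0, 7.0, 9))
        res = fit_pka(list(zip(table["ph"], table["F500"])))
        assert res.warnings

    def test_noisy_recovery_seed_pinned(self):
        table, truth = gen_ph_series(
            pka=6.0,
            config=GeneratorConfig(seed=11, noise_sd=0.01, replicates=3),
        )
        res = fit_pka(list(zip(table["ph"], table["F500"])))
        assert abs(res.params["pka"] - truth["pka"]) <= 3 * res.stderr["pka"]


class TestFitTernary:
    def test_noiseless_recovery(self):
        table, truth = gen_mgatp_series()
        res = fit_ternary(list(zip(table["x"], table["ratio"])), s_total=truth["s_total"])
        assert res.converged
        assert not res.non_identifiable
        assert res.params["kd_ternary"] == pytest.approx(truth["kd_ternary"], rel=0.05)

    def test_pure_competition_flagged_non_identifiable(self):
        table, truth = gen_mgatp_series(kd_ternary=None)
        res = fit_ternary(list(zip(table["x"], table["ratio"])), s_total=truth["s_total"])
        assert res.non_identifiable
        assert "kd_ternary_lower_bound" in res.params

    def test_noisy_recovery_seed_pinned(self):
        table, truth = gen_mgatp_series(
            config=GeneratorConfig(seed=3, noise_sd=0.01, replicates=3)
        )
        res = fit_ternary(list(zip(table["x"], table["ratio"])), s_total=truth["s_total"])
        assert abs(res.params["kd_ternary"] - truth["kd_ternary"]) <= 3 * res.stderr["kd_ternary"]


class TestSelectivity:
    def test_magzet1_calcium_selectivity_exceeds_tenfold(self):
        ratio = selectivity_ratio(presets.KD_CA_25C, presets.KD_MG_25C)
        assert ratio == pytest.approx(12.14, rel=0.01)
        assert ratio >= 10

    def test_identity(self):
        assert selectivity_ratio(1e-3, 1e-3) == 1.0

    def test_magdma_selectivity(self):
        assert selectivity_ratio(presets.MAGDMA_KD_CA, presets.MAGDMA_KD_MG) == pytest.approx(10.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            selectivity_ratio(0.0, 1e-3)


@pytest.fixture(scope="module")
def panel():
    conditions = {
        "blank": {},
        "+50 uM Ca": {"ca_total": 50e-6},
        "+1 mM Mg": {"mg_total": 1e-3},
        "+1 mM Mg +50 uM Ca": {"mg_total": 1e-3, "ca_total": 50e-6},
        "saturating Mg": {"mg_total": 50e-3},
    }
    df = selectivity_panel(conditions, 10e-6)
    return dict(zip(df["condition"], df["ratio"]))


class TestSelectivityPanel:
    def test_calcium_alone_barely_shifts_ratio(self, panel):
        dyn = panel["saturating Mg"] - panel["blank"]
        assert abs(panel["+50 uM Ca"] - panel["blank"]) < 0.05 * dyn

    def test_magnesium_raises_ratio(self, panel):
        assert panel["+1 mM Mg"] > panel["blank"]

    def test_calcium_does_not_perturb_magnesium_reading(self, panel):
        dyn = panel["saturating Mg"] - panel["blank"]
        assert abs(panel["+1 mM Mg +50 uM Ca"] - panel["+1 mM Mg"]) < 0.05 * dyn
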