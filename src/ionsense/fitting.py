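"""Nonlinear least-squares estimation of binding and protonation constants.

Titration fits minimize squared residuals of the speciation-composed
ratio model, so ligand depletion is handled exactly — required when the
dissociation constant (nM for Zn2+) is far below the sensor
concentration. Positive parameters (Kd, beta) are fit on a log10 scale
to stay well-conditioned across the nM–100 mM range. Standard errors
come from the Jacobian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from . import presets
from .equilibria import closed_form_1to1, solve_speciation
from .photophysics import (
    ChannelSet,
    RatioMeasurement,
    SpeciesSpectrum,
    compose_channel_intensities,
)

__all__ = [
    "FitResult",
    "UninformativeDataError",
    "fit_kd_ratio",
    "fit_pka",
    "fit_ternary",
    "selectivity_ratio",
    "selectivity_panel",
]


class UninformativeDataError(ValueError):
    """The data cannot constrain the requested parameters."""


@dataclass
class FitResult:
    """Parameter estimates with uncertainties from one least-squares fit."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    covar: np.ndarray | None
    rss: float
    converged: bool
    n_points: int
    fixed: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    non_identifiable: bool = False

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _as_xy(titration) -> tuple[np.ndarray, np.ndarray]:
    """Extract (x, ratio) arrays from RatioMeasurements or a DataFrame."""
    if isinstance(titration, pd.DataFrame):
        return titration["x"].to_numpy(float), titration["ratio"].to_numpy(float)
    xs, ys = [], []
    for m in titration:
        if isinstance(m, RatioMeasurement):
            xs.append(m.x)
            ys.append(m.ratio)
        else:
            x, y = m
            xs.append(x)
            ys.append(y)
    return np.asarray(xs, float), np.asarray(ys, float)


def _replicate_noise_sd(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled within-x standard deviation (0 when no replicates)."""
    df = pd.DataFrame({"x": x, "y": y})
    sds = df.groupby("x")["y"].std(ddof=1).dropna()
    ns = df.groupby("x")["y"].count()
    ns = ns[ns > 1]
    if sds.empty:
        return 0.0
    w = (ns - 1).reindex(sds.index)
    return float(np.sqrt((w * sds**2).sum() / w.sum()))


def _ratio_model_1to1(
    x: np.ndarray, kd: float, s_total: float, r_min: float, r_max: float, beta: float
) -> np.ndarray:
    """Ratio vs total metal for 1:1 binding with depletion.

    The bound fraction comes from the exact quadratic mass balance (equal
    to the full speciation solve for a 1:1 system); the ratio mixes the
    two limiting ratios weighted by denominator-channel brightness:
    R = (beta (1-f) R_min + f R_max) / (beta (1-f) + f).
    """
    f = np.array([closed_form_1to1(s_total, m, kd) for m in x]) / s_total
    return (beta * (1 - f) * r_min + f * r_max) / (beta * (1 - f) + f)


def _result_from_minimizer(out, n_points, fixed=None, extra_warnings=None):
    params = {name: float(p.value) for name, p in out.params.items() if p.vary}
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else None)
        for name, p in out.params.items()
        if p.vary
    }
    return FitResult(
        params=params,
        stderr=stderr,
        covar=getattr(out, "covar", None),
        rss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        n_points=n_points,
        fixed=dict(fixed or {}),
        warnings=list(extra_warnings or []),
    )


def fit_kd_ratio(
    titration,
    s_total: float,
    beta: float | None = None,
    noise_sd: float | None = None,
) -> FitResult:
    """Fit Kd, R_min, R_max and beta to a ratio-vs-total-metal titration.

    ``titration`` is a list of RatioMeasurements (or (x, ratio) pairs, or
    a DataFrame with ``x``/``ratio`` columns), x in molar total metal.
    Raises UninformativeDataError when the ratio dynamic range is below
    three times the replicate noise SD, or when no point carries metal.

    When sensor depletion is negligible (s_total << Kd) the ratio curve
    constrains only the product Kd * beta, so fitting both is
    ill-conditioned on noisy data. Pass ``beta`` (the denominator-channel
    brightness ratio of the free over the bound form, measured from the
    pure-form spectra) to hold it fixed as a calibration constant; leave
    it None to fit it, which is reliable only when depletion or very low
    noise breaks the degeneracy.
    """
    x, y = _as_xy(titration)
    if not np.all(np.isfinite(y)):
        raise ValueError("titration contains non-finite ratios")
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct metal concentrations")
    span = float(y.max() - y.min())
    sd = _replicate_noise_sd(x, y) if noise_sd is None else noise_sd
    if x.max() <= 0 or span <= 3 * sd or span == 0:
        raise UninformativeDataError(
            "ratio dynamic range does not exceed 3x the noise SD; "
            "the titration cannot constrain Kd"
        )

    # kd0: metal concentration nearest the half-range ratio.
    order = np.argsort(x)
    xo, yo = x[order], y[order]
    half = 0.5 * (yo.min() + yo.max())
    kd0 = float(xo[np.argmin(np.abs(yo - half))])
    if kd0 <= 0:
        kd0 = float(np.median(xo[xo > 0]))

    p = lmfit.Parameters()
    p.add("log10_kd", value=np.log10(kd0))
    p.add("r_min", value=float(yo[0]))
    p.add("r_max", value=float(yo[-1]))
    p.add("log10_beta", value=0.0 if beta is None else np.log10(beta),
          vary=beta is None)

    def resid(pars):
        model = _ratio_model_1to1(
            x,
            10.0 ** pars["log10_kd"].value,
            s_total,
            pars["r_min"].value,
            pars["r_max"].value,
            10.0 ** pars["log10_beta"].value,
        )
        return model - y

    out = lmfit.minimize(resid, p)
    res = _result_from_minimizer(out, len(x))
    res.params["kd"] = 10.0 ** res.params.pop("log10_kd")
    if beta is None:
        res.params["beta"] = 10.0 ** res.params.pop("log10_beta")
    else:
        res.fixed["beta"] = beta
    # delta-method SEs on the natural scale
    ln10 = np.log(10.0)
    for name, lname in (("kd", "log10_kd"), ("beta", "log10_beta")):
        if name not in res.params:
            continue
        se = res.stderr.pop(lname, None)
        res.stderr[name] = None if se is None else se * ln10 * res.params[name]
    return res


def fit_pka(ph_series, noise_sd: float | None = None) -> FitResult:
    """Fit pKa from single-channel intensity vs pH.

    Model: I(pH) = (I_acid + I_base 10^(pH-pKa)) / (1 + 10^(pH-pKa)).
    A warning is attached when the pH range does not bracket the fitted
    inflection; flat data raise UninformativeDataError.
    """
    ph, y = _as_xy(ph_series)
    if len(np.unique(ph)) < 5:
        raise ValueError("need >= 5 distinct pH points")
    if ph.max() - ph.min() < 2:
        raise ValueError("pH range must span >= 2 units")
    span = float(y.max() - y.min())
    sd = _replicate_noise_sd(ph, y) if noise_sd is None else noise_sd
    if span == 0 or span <= 3 * sd:
        raise UninformativeDataError(
            "intensity is flat across the pH series (I_acid = I_base); "
            "pKa is not identifiable"
        )

    half = 0.5 * (y.min() + y.max())
    pka0 = float(ph[np.argmin(np.abs(y - half))])
    p = lmfit.Parameters()
    p.add("pka", value=pka0)
    p.add("i_acid", value=float(y[np.argmin(ph)]))
    p.add("i_base", value=float(y[np.argmax(ph)]))

    def resid(pars):
        t = 10.0 ** (ph - pars["pka"].value)
        model = (pars["i_acid"].value + pars["i_base"].value * t) / (1 + t)
        return model - y

    out = lmfit.minimize(resid, p)
    warns = []
    pka_hat = float(out.params["pka"].value)
    if not (ph.min() <= pka_hat <= ph.max()):
        warns.append(
            f"fitted pKa {pka_hat:.2f} lies outside the measured pH range "
            f"[{ph.min():.1f}, {ph.max():.1f}]; the inflection is not bracketed"
        )
    return _result_from_minimizer(out, len(ph), extra_warnings=warns)


#: Fixed 40-point log grid (molar) for the ternary-Kd identifiability profile.
_TERNARY_PROFILE_GRID = np.logspace(-3, 4, 40)


def _ternary_ratio_model(
    x: np.ndarray,
    kd_ternary: float,
    ternary_scale: float,
    s_total: float,
    kd_sm: float,
    kd_mgatp: float,
    spectra: dict[str, SpeciesSpectrum],
    channels: ChannelSet,
    numerator: str,
    denominator: str,
) -> np.ndarray:
    """Ratio vs equimolar MgATP total under the binary+ternary model."""
    base = spectra["sensor_Mg_ATP"]
    scaled = SpeciesSpectrum(
        base.species_name,
        base.emission_bands,
        brightness=base.brightness * ternary_scale,
        absorption_max=base.absorption_max,
        emission_max=base.emission_max,
    )
    spectra = {**spectra, "sensor_Mg_ATP": scaled}
    out = np.empty(len(x))
    for i, tot in enumerate(x):
        system = presets.magzet1_system(
            s_total, mg_total=tot, atp_total=tot, include_ternary=True
        )
        reactions = []
        for r in system.reactions:
            if r.product_name == "sensor_Mg":
                r = type(r)(r.product_name, r.stoichiometry, kd_sm)
            elif r.product_name == "MgATP":
                r = type(r)(r.product_name, r.stoichiometry, kd_mgatp)
            elif r.product_name == "sensor_Mg_ATP":
                r = type(r)(r.product_name, r.stoichiometry, kd_ternary)
            reactions.append(r)
        system = type(system)(system.components, reactions, system.ph)
        sol = solve_speciation(system)
        out[i] = compose_channel_intensities(
            sol, spectra, channels, numerator, denominator
        ).ratio
    return out


def fit_ternary(
    mgatp_series,
    s_total: float = 20e-6,
    fixed: dict[str, float] | None = None,
    spectra: dict[str, SpeciesSpectrum] | None = None,
    channels: ChannelSet | None = None,
    numerator: str = "F530",
    denominator: str = "F500",
) -> FitResult:
    """Fit the ternary-complex dissociation constant from a MgATP series.

    Each point of ``mgatp_series`` carries the equimolar Mg/ATP total (x,
    molar) and the observed ratio. The binary constants (sensor·Mg and
    MgATP) are held fixed; free parameters are the ternary Kd and the
    ternary-species brightness scale. The objective runs the full
    three-reaction speciation per point. A 1-D profile over the ternary
    Kd screens for non-identifiability: when the profile is flat (RSS
    changes < 1% across the top two decades of the grid) the estimate is
    flagged and reported as a lower bound.
    """
    fixed = {"kd_SM": presets.KD_MG_25C, "kd_MgATP": presets.KD_MGATP, **(fixed or {})}
    spectra = spectra or presets.magzet1_spectra()
    channels = channels or presets.cuvette_channels()
    x, y = _as_xy(mgatp_series)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct MgATP totals")

    def model(kd_t, scale):
        return _ternary_ratio_model(
            x, kd_t, scale, s_total, fixed["kd_SM"], fixed["kd_MgATP"],
            spectra, channels, numerator, denominator,
        )

    # Identifiability profile over the fixed log grid (scale held at 1).
    # At very large ternary Kd the model degenerates to pure competition,
    # so the profile always plateaus at the top; the constant is
    # identifiable only when the minimum beats that plateau by > 1%.
    profile = np.array(
        [np.sum((model(kd_t, 1.0) - y) ** 2) for kd_t in _TERNARY_PROFILE_GRID]
    )
    top = _TERNARY_PROFILE_GRID >= _TERNARY_PROFILE_GRID.max() / 100.0
    plateau = float(profile[top].min())
    flat = (plateau - profile.min()) <= 0.01 * plateau + 1e-300

    kd0 = float(_TERNARY_PROFILE_GRID[np.argmin(profile)])
    p = lmfit.Parameters()
    p.add("log10_kd_ternary", value=np.log10(kd0), min=-4, max=5)
    # The ternary species emits like the binary Mg-bound form (the high-
    # MgATP response is a red-shifted intensity increase); bounding its
    # brightness scale to a fivefold window excludes the degenerate
    # "strongly formed but dark complex" branch of the objective.
    p.add("ternary_scale", value=1.0, min=0.2, max=5.0)

    def resid(pars):
        return model(
            10.0 ** pars["log10_kd_ternary"].value, pars["ternary_scale"].value
        ) - y

    out = lmfit.minimize(resid, p)
    warns = []
    res = _result_from_minimizer(out, len(x), fixed=fixed, extra_warnings=warns)
    res.params["kd_ternary"] = 10.0 ** res.params.pop("log10_kd_ternary")
    se = res.stderr.pop("log10_kd_ternary", None)
    res.stderr["kd_ternary"] = (
        None if se is None else se * np.log(10.0) * res.params["kd_ternary"]
    )
    if flat:
        res.non_identifiable = True
        lower = float(_TERNARY_PROFILE_GRID[top][0])
        res.params["kd_ternary_lower_bound"] = lower
        res.warnings.append(
            "ternary Kd profile is flat over the top two decades; the data "
            f"only support a lower bound of ~{lower:g} M (no ternary complex "
            "detectable)"
        )
    return res


def selectivity_ratio(kd_competitor: float, kd_target: float) -> float:
    """Fold-selectivity: Kd(competitor) / Kd(target)."""
    if kd_competitor <= 0 or kd_target <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_competitor / kd_target


def selectivity_panel(
    conditions: dict[str, dict[str, float]],
    s_total: float,
    spectra: dict[str, SpeciesSpectrum] | None = None,
    channels: ChannelSet | None = None,
    numerator: str = "F530",
    denominator: str = "F500",
    temperature: str = "25C",
) -> pd.DataFrame:
    """Predicted ratio for each named total-concentration condition.

    ``conditions`` maps condition names to total-concentration dicts with
    keys among {mg_total, ca_total, zn_total, atp_total} (molar), e.g.
    ``{"blank": {}, "+1 mM Mg": {"mg_total": 1e-3}}``.
    """
    spectra = spectra or presets.magzet1_spectra()
    channels = channels or presets.cuvette_channels()
    rows = []
    for name, totals in conditions.items():
        system = presets.magzet1_system(s_total, temperature=temperature, **totals)
        sol = solve_speciation(system)
        if not sol.converged:
            raise RuntimeError(f"speciation failed for condition {name!r}")
        m = compose_channel_intensities(
            sol, spectra, channels, numerator, denominator
        )
        rows.append({"condition": name, "ratio": m.ratio})
    return pd.DataFrame(rows)
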