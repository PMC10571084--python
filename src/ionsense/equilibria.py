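"""Multi-component chemical equilibrium speciation.

A system is a set of components (sensor, metals, ligands, proton) with
total concentrations, and a set of association products each defined by a
stepwise assembly reaction with a dissociation constant

    Kd = (product of free reactant concentrations) / [product],

where a reactant may be a component or a previously defined product
(e.g. the ternary sensor·Mg·ATP complex assembled as sensor + MgATP).
Stepwise constants are folded into overall formation constants over the
elemental components, and the coupled mass balances

    free_i + sum_p  n_{p,i} [p]  =  total_i

are solved by damped Newton iteration on the logarithms of the free
concentrations (which keeps every concentration positive), with a
per-component bracketed-bisection fallback for pathological starts.

pH is handled by clamping the free proton concentration to 10^-pH; the
proton has no mass balance. Dissociation constants are apparent
(conditional) constants valid at the stated buffer/temperature, carried
as metadata labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Component",
    "Reaction",
    "EquilibriumSystem",
    "SpeciationResult",
    "solve_speciation",
    "closed_form_1to1",
    "fraction_bound",
]

_ROLES = ("sensor", "metal", "ligand", "proton")

#: Convergence tolerance on the relative mass-balance residual.
TOL = 1e-9
#: Newton iteration cap.
MAX_ITER = 200


@dataclass(frozen=True)
class Component:
    """A conserved chemical component with a total concentration in molar.

    A component with role ``"proton"`` has no mass balance: its free
    concentration is clamped from the system pH and ``total_concentration``
    is ignored.
    """

    name: str
    role: str
    total_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.role != "proton" and self.total_concentration < 0:
            raise ValueError(
                f"total_concentration of {self.name!r} must be >= 0, "
                f"got {self.total_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """A stepwise assembly reaction defining one product species.

    ``stoichiometry`` maps reactant names (components or previously
    defined products) to positive integer counts. ``kd`` is the
    dissociation constant of this assembly step, in molar.
    """

    product_name: str
    stoichiometry: dict[str, int]
    kd: float
    temperature_label: str = ""
    medium_label: str = ""

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd of {self.product_name!r} must be > 0, got {self.kd}")
        if not self.stoichiometry:
            raise ValueError(f"stoichiometry of {self.product_name!r} is empty")
        for name, count in self.stoichiometry.items():
            if int(count) != count or count < 1:
                raise ValueError(
                    f"stoichiometric count of {name!r} in {self.product_name!r} "
                    f"must be a positive integer, got {count}"
                )


@dataclass(frozen=True)
class EquilibriumSystem:
    """Components plus reactions, with an optional fixed pH.

    ``ph`` clamps the free proton concentration to ``10**-ph``; it is
    required whenever a proton component participates in a reaction.
    """

    components: list[Component]
    reactions: list[Reaction] = field(default_factory=list)
    ph: float | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        known = set(names)
        for rxn in self.reactions:
            if rxn.product_name in known:
                raise ValueError(
                    f"product name {rxn.product_name!r} collides with an "
                    "existing component or product"
                )
            unknown = set(rxn.stoichiometry) - known
            if unknown:
                raise ValueError(
                    f"reaction {rxn.product_name!r} references undefined "
                    f"species {sorted(unknown)}; products may only be built "
                    "from components or previously defined products"
                )
            known.add(rxn.product_name)
        protons = [c for c in self.components if c.role == "proton"]
        if len(protons) > 1:
            raise ValueError("at most one proton component is allowed")
        if protons and self.ph is None:
            raise ValueError("a proton component requires the system pH to be set")

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


@dataclass(frozen=True)
class SpeciationResult:
    """Solved free and complexed concentrations (molar) with diagnostics."""

    free: dict[str, float]
    complexes: dict[str, float]
    residuals: dict[str, float]
    converged: bool
    iterations: int

    def species_concentration(self, name: str) -> float:
        if name in self.free:
            return self.free[name]
        return self.complexes[name]

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)


def _expand_products(system: EquilibriumSystem):
    """Fold stepwise reactions into overall formation constants.

    Returns, per product, its elemental composition over components and
    log(beta) with beta = [product] / prod_i free_i^n_i.
    """
    comp_names = set(system.component_names)
    compositions: dict[str, dict[str, int]] = {}
    log_betas: dict[str, float] = {}
    for rxn in system.reactions:
        comp: dict[str, int] = {}
        log_beta = -np.log(rxn.kd)
        for name, count in rxn.stoichiometry.items():
            if name in comp_names:
                comp[name] = comp.get(name, 0) + count
            else:  # previously defined product
                log_beta += count * log_betas[name]
                for el, n in compositions[name].items():
                    comp[el] = comp.get(el, 0) + count * n
        compositions[rxn.product_name] = comp
        log_betas[rxn.product_name] = log_beta
    return compositions, log_betas


def solve_speciation(system: EquilibriumSystem) -> SpeciationResult:
    """Solve the coupled mass-balance equilibria of ``system``.

    Returns free concentrations for every component and concentrations for
    every reaction product, with per-component relative mass-balance
    residuals. Non-convergence is reported through ``converged=False``
    with the last residuals attached, never silently.
    """
    compositions, log_betas = _expand_products(system)
    product_names = [r.product_name for r in system.reactions]

    # Totals below ~one molecule anywhere (1e-30 M) are chemically zero;
    # treating them as such also keeps log-space iteration finite.
    zero_total = 1e-30
    fixed_free: dict[str, float] = {}
    for c in system.components:
        if c.role == "proton":
            fixed_free[c.name] = 10.0 ** (-float(system.ph))
        elif c.total_concentration <= zero_total:
            fixed_free[c.name] = 0.0

    active = [
        c for c in system.components
        if c.role != "proton" and c.total_concentration > zero_total
    ]
    totals = np.array([c.total_concentration for c in active])
    names = [c.name for c in active]
    index = {n: i for i, n in enumerate(names)}

    # Products are expressed as log[p] = log(beta) + sum n_i * log(free_i).
    # Products containing a zero-concentration species are identically zero.
    live_products: list[str] = []
    prod_matrix_rows: list[np.ndarray] = []
    prod_const: list[float] = []
    for p in product_names:
        comp = compositions[p]
        if any(fixed_free.get(el, 1.0) == 0.0 for el in comp):
            continue
        row = np.zeros(len(active))
        const = log_betas[p]
        for el, n in comp.items():
            if el in index:
                row[index[el]] = n
            else:
                const += n * np.log(fixed_free[el])
        live_products.append(p)
        prod_matrix_rows.append(row)
        prod_const.append(const)
    N = (
        np.array(prod_matrix_rows)
        if prod_matrix_rows
        else np.zeros((0, len(active)))
    )
    c0 = np.array(prod_const)

    def residual(logf: np.ndarray):
        conc_p = np.exp(c0 + N @ logf) if len(c0) else np.zeros(0)
        bal = np.exp(logf) + (N.T @ conc_p if len(c0) else 0.0) - totals
        return bal, conc_p

    converged = True
    iterations = 0
    if len(active) == 0:
        logf = np.zeros(0)
        bal, conc_p = residual(logf)
    else:
        logf = np.log(totals * 0.5)
        bal, conc_p = residual(logf)
        err = np.max(np.abs(bal) / totals)
        for iterations in range(1, MAX_ITER + 1):
            if err <= TOL:
                break
            free = np.exp(logf)
            # J_ij = d bal_i / d logf_j = delta_ij f_i + sum_p n_pi n_pj [p]
            J = np.diag(free)
            if len(conc_p):
                J = J + N.T @ (conc_p[:, None] * N)
            try:
                step = np.linalg.solve(J, -bal)
            except np.linalg.LinAlgError:
                step = None
            improved = False
            if step is not None:
                step = np.clip(step, -5.0, 5.0)
                lam = 1.0
                for _ in range(40):
                    trial = logf + lam * step
                    tbal, tconc = residual(trial)
                    terr = np.max(np.abs(tbal) / totals)
                    if terr < err:
                        logf, bal, conc_p, err = trial, tbal, tconc, terr
                        improved = True
                        break
                    lam *= 0.5
            if not improved:
                logf, bal, conc_p, err = _bisection_sweep(
                    logf, totals, N, c0, residual
                )
        converged = err <= TOL

    free_out = dict(fixed_free)
    for i, n in enumerate(names):
        free_out[n] = float(np.exp(logf[i]))
    complexes = {p: 0.0 for p in product_names}
    for j, p in enumerate(live_products):
        complexes[p] = float(conc_p[j])
    residuals = {
        n: float(abs(bal[index[n]]) / totals[index[n]]) for n in names
    }
    for c in system.components:
        residuals.setdefault(c.name, 0.0)
    return SpeciationResult(
        free=free_out,
        complexes=complexes,
        residuals=residuals,
        converged=converged,
        iterations=iterations,
    )


def _bisection_sweep(logf, totals, N, c0, residual):
    """One Gauss-Seidel sweep solving each component's own mass balance.

    With the other free concentrations held fixed, a component's mass
    balance is strictly increasing in its own free concentration and
    brackets a root in (0, total]; brentq is applied per component.
    """
    logf = logf.copy()
    for i in range(len(totals)):
        def g(x):
            trial = logf.copy()
            trial[i] = x
            bal, _ = residual(trial)
            return bal[i]

        hi = np.log(totals[i])
        lo = hi - 80.0
        if g(lo) < 0 <= g(hi):
            logf[i] = brentq(g, lo, hi, xtol=1e-14)
    bal, conc_p = residual(logf)
    err = np.max(np.abs(bal) / totals)
    return logf, bal, conc_p, err


def closed_form_1to1(s_total: float, m_total: float, kd: float) -> float:
    """Bound-complex concentration for 1:1 binding, by the quadratic root.

    Solves [SM]^2 - (S_t + M_t + Kd)[SM] + S_t M_t = 0 and returns the
    physically valid root, 0 <= [SM] <= min(S_t, M_t). Written in the
    numerically stable form that avoids cancellation when Kd is tiny.
    """
    if s_total < 0 or m_total < 0:
        raise ValueError("totals must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    b = s_total + m_total + kd
    disc = np.sqrt(b * b - 4.0 * s_total * m_total)
    # smaller quadratic root via the product form (stable for b >> disc)
    return float(2.0 * s_total * m_total / (b + disc))


def fraction_bound(kd: float, free_metal: float) -> float:
    """Fractional saturation f = [M] / (Kd + [M]) for 1:1 binding."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if free_metal < 0:
        raise ValueError("free_metal must be >= 0")
    return free_metal / (kd + free_metal)
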