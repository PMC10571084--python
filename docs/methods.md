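# Methods

## Equilibrium speciation

A system is a list of conserved components — sensor, metals, ligands,
and optionally the proton — plus assembly reactions, each defined by a
dissociation constant for one stepwise association. Reactions may build
on earlier products (the ternary complex is assembled as
S + MgATP ⇌ S·Mg·ATP), and the solver folds the steps into overall
formation constants over the elemental components before solving.

The unknowns are the free concentrations of the non-proton components
with nonzero totals. The solver runs damped Newton iteration on the
logarithms of the free concentrations, which keeps every concentration
strictly positive and is well-conditioned across the nine orders of
magnitude spanned by the bundled constants (2.6 nM for Zn²⁺ to 100 mM
for the ternary complex). The Jacobian is analytic
(`J_ij = δ_ij·f_i + Σ_p n_pi·n_pj·[p]`). Steps are clipped to ±5 log
units and backtracked by halving until the residual decreases; if no
Newton step improves, the solver falls back to a Gauss–Seidel sweep of
bracketed root-finding (Brent) on each component's own mass balance,
which is strictly monotone in that component's free concentration.

Convergence demands a relative mass-balance residual ≤ 1e−9 for every
component, with a 200-iteration cap and the initial guess at half the
totals. Non-convergence is reported explicitly (`converged=False` with
the last residuals), never silently. pH enters as a clamp on free
[H⁺] = 10^−pH; the proton has no mass balance. All constants are
treated as apparent (conditional) constants valid at their stated
buffer and temperature, carried as text labels — there is no
ionic-strength correction, no multi-protic ATP speciation, and no
van't Hoff temperature interpolation (only 25 °C and 37 °C point values
exist).

Assumption made explicit: protonation (SH⁺) and metal binding compete
for the same free sensor pool. A strictly competitive scheme does not
fully reproduce the observed flatness of the metal-present ratio at the
acidic end (pH ≈ 5–5.5), where partial-site independence may
contribute; this is a known model limitation, not resolved here.

The ternary assembly convention — Kd = 100 mM for S + MgATP ⇌
S·Mg·ATP, not for S·Mg + ATP ⇌ S·Mg·ATP — is a documented choice; the
two conventions differ numerically and the source measurement does not
distinguish them.

## Spectra and channel composition

Each species' emission is a sum of Gaussian bands times a brightness
∝ ε·φ. Channel intensities are concentration-weighted band integrals
(trapezoid on a 1 nm grid across the passband); single-wavelength
cuvette channels (F500, F530) are 1 nm-wide passbands, flow channels
are the 450/50 and 530/30 bandpasses. Excitation wavelength is metadata
only: in vitro work fixes excitation at the 390 nm isosbestic point, so
excitation-dependent brightness differences fold into the per-species
brightness.

The bundled spectra are **synthetic fixtures**: emission maxima (free
500 nm, Mg-bound 530 nm, Ca-bound 520 nm, Zn-bound 545 nm, protonated
630 nm) and the two measured quantum yields (free 40.4%, Mg-bound 76%)
are real characterization values, but band widths and the Ca/Zn-bound
and protonated brightnesses were never determined and are fixture
choices. The common band σ is 25 nm (FWHM ≈ 59 nm), picked once as
representative of this dye family's emission widths: it yields a ~4×
F530/F500 dynamic range in the cuvette and a realistic (non-blind)
450/50 response to the bound form in flow. The protonated form gets
brightness 0.02 ("essentially non-emissive") at 630 nm, spectrally
resolved from both channels — which is exactly why the ratio is
pH-stable while single-channel intensity is not.

The ratiometric inversion uses
`[M] = Kd·β·(R − Rmin)/(Rmax − R)` with β the denominator-channel
brightness of the free form over that of the bound form; under this
convention the half-saturation ratio is `(Rmax + β·Rmin)/(1 + β)`, and
the inversion is algebraically exact for 1:1 binding.

## Titration fitting

All fits are trust-region nonlinear least squares (lmfit) with positive
parameters (Kd, β) on a log₁₀ scale. Standard errors come from the
Jacobian at the optimum; with replicated data the replicate scatter
additionally sets the "uninformative data" screen (dynamic range must
exceed 3× the noise SD).

- **Kd from ratio titrations** fits the speciation-composed 1:1 model,
  so ligand depletion is exact; initialization takes Kd₀ from the
  half-range point and Rmin/Rmax from the extreme points. One caveat
  matters scientifically: when depletion is negligible (s_total ≪ Kd)
  the ratio curve constrains only the product Kd·β, so the
  four-parameter fit is degenerate in that regime. The `beta` argument
  fixes β at its calibration value (measured from pure-form spectra),
  which restores conditioning; noiseless fits at 10 μM sensor recover
  Kd with β free because mild depletion breaks the tie in exact data.
  The fit always models *total* metal on the x-axis; at 10 μM sensor
  the free/total distinction is negligible for mM constants but not for
  the nM Zn²⁺ constant, which is exactly why the speciation-based
  objective is used.
- **pKa** fits the two-state Henderson–Hasselbalch sigmoid
  `I(pH) = (I_acid + I_base·10^(pH−pKa)) / (1 + 10^(pH−pKa))` to
  single-channel intensity; a warning is attached when the fitted
  inflection lies outside the measured pH range.
- **Ternary constant** fits the full three-reaction speciation per
  point with the two binary constants fixed (sensor·Mg 0.14 mM, MgATP
  50 μM), with the ternary Kd and a ternary brightness scale free. The
  brightness scale is bounded to [0.2, 5]: the high-MgATP response is a
  red-shifted intensity *increase*, i.e. the ternary species emits like
  the bound form, and the bound excludes a degenerate
  strongly-formed-but-dark branch of the objective. Identifiability is
  screened with a 1-D profile over a fixed 40-point log grid
  (1 mM–10 kM): since the model degenerates to pure competition at
  large ternary Kd, the profile always plateaus at the top, and the
  constant is declared non-identifiable when the minimum fails to beat
  the plateau by >1% — in that case the estimate is reported as a lower
  bound and flagged.

## Population statistics

Per-cell ratios are `(I_num − bg_num)/(I_den − bg_den)` with a single
scalar background per channel; events with non-positive corrected
denominator are excluded and counted in a QC report. Ratios are
invariant to any global gain applied to both channels. The χ²
homogeneity test bins both groups on shared edges (64 equal-width bins
over the pooled central 99% range, out-of-range events folded into the
edge bins), merges adjacent bins until every expected count is ≥ 5, and
refers the statistic to χ² with (bins − 1) degrees of freedom. This
construction is a declared convention of this package — the original
flow analyses do not specify theirs — so agreement is claimed for the
statistical behavior (calibrated null, direction and detectability of
median shifts), not for reproducing particular χ² values. Small imaging
samples use Welch's two-sided t test, with the zero-variance/equal-mean
corner defined as p = 1. No scatter-based gating is implemented; a QC
hook point exists but shape/granularity gating is out of scope.

## Synthetic data

Generators compose the forward model on deterministic grids and add
seeded Gaussian noise on channel intensities, SD expressed as a
fraction of the channel's dynamic range (default 1%, three replicates —
the replicate convention of independent titrations; per-point noise
magnitudes are declared defaults, as no measured values exist). Every
generator is a pure function of its arguments: one seed, byte-identical
output, and a machine-readable truth sidecar that recovery tests read
instead of hard-coding values. Defaults: 15 log-spaced titration points
from Kd/30 to 30·Kd (the isotherm's informative region; nM-affinity
fits instead bracket the equivalence point around the sensor
concentration); pH 5–8 in 0.25 steps; 12 equimolar MgATP totals from
0.1 to 50 mM at 20 μM sensor; cell populations with log-normal dye
loading (σ_log = 0.5, AM-loading heterogeneity being unquantified),
log-normal free Mg (CV 10%), and optional additive channel noise.

What the generators deliberately do not emulate: autofluorescence and
spectral spillover, photobleaching, instrument drift, scatter-based
event quality, inner-filter effects, and any kinetics. Passing
recovery tests therefore demonstrate the correctness and conditioning
of the estimators under the stated noise model, not robustness to every
artifact of real acquisitions.

## Problem sizes

The default test and acceptance runs use 15–45 titration points per
fit, 12-point competition series, 400-point solver-vs-oracle grids, 50
random ternary-system oracle draws, and 100 repetitions of n = 1000
population comparisons — sizes chosen so the full suite runs in well
under a minute while every check retains its statistical meaning.
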