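# Methods

This note records the models implemented in `coacervkit`, their
assumptions, the defaults and why, and what the synthetic-data tests do
and do not demonstrate.

## Ionization and speciation (`seq_props`)

Each peptide is a set of independent two-state titratable sites: the
N-terminal amine, the C-terminal carboxylate, and one site per ionizable
side chain. A base carries +1 when protonated, an acid −1 when
deprotonated; the protonated fraction at pH is the Henderson–Hasselbalch
logistic 1/(1 + 10^(pH − pKa)). Under site independence the distribution
over integer net charges is the convolution of per-site Bernoulli
variables, which coincides exactly with a Boltzmann enumeration over the
2^N protonation microstates; the test suite checks this identity to
1e−9 against a brute-force enumeration. Net charge is the expectation of
that distribution and is strictly decreasing in pH, so the isoelectric
point is its unique zero (Brent root-finding to |charge| < 1e−6).

*Assumption*: no site–site interactions and no environment-dependent pKa
shifts. Real coacervates violate this (crowding and burial shift pKas);
the framework therefore takes the pKa table as a named, swappable input
(CSV: `group,pKa,charge_when_protonated`). The default table is a
conventional free-amino-acid set (N-term 9.0, C-term 3.2, Asp 3.9,
Glu 4.1, Cys 8.3, Tyr 10.5, His 6.0, Lys 10.5, Arg 12.5, pH units).
Published isoelectric points computed from *measured* peptide pKas will
differ from the defaults' predictions; the package reproduces the
procedure, not unpublished constants.

Titration arithmetic solves the electroneutrality balance
[Na⁺] + [H⁺] + C_p·z(pH) = [OH⁻] + [TFA⁻] with Kw = 1e−14 and, by
default, one trifluoroacetate counterion per basic group (peptides are
supplied as TFA salts, neutral as shipped). The forward pH solve is a
monotone root-find; the base-to-reach-pH inverse is closed-form from the
same balance and errors when the target sits below the un-titrated pH.

## Formulation (`formulation`)

wt % is defined as g solute per 100 mL at an assumed solution density of
1 g/mL, so molarity = 10·wt %/M. Charge-matched compositions dose the
partner at (peptide molarity × peptide charge × ratio)/|partner charge|.
ATP is treated as the disodium salt (551.14 g mol⁻¹, working charge −2
near neutral pH); the free-acid mass is available as a constant.
Compositions are rounded half-up to one decimal, the convention used on
sample labels; an unrounded value is available via `rounded=False`.
Peptide molar masses use IUPAC average atomic weights via pyteomics,
matching how material is weighed out.

Turbidity uses the attenuation definition T = ln 10 · A/L (cm⁻¹) from
decadic absorbance at 500 nm, a wavelength where these peptides do not
absorb, so attenuation is scattering. A phase map is bookkeeping, not
prediction: points are flagged LLPS when T ≥ threshold (inclusive), and
duplicate grid coordinates are rejected.

## Droplet electrostatics (`droplet_electrostatics`)

The interfacial-tension estimate assumes (i) the zeta potential equals
the surface potential ψ₀ (no slip-plane correction — at ~1 mV and
κ⁻¹ ≈ 2.4 nm the distinction is below measurement noise), (ii) the
linearized Grahame relation σ = εε₀κψ₀ holds (|ψ₀| ≪ 25 mV; the full
1:1-electrolyte sinh form is available via `mode="full_1to1"` and agrees
to first order, tested at 1 mV to 1e−4), and (iii) observed droplets sit
at the Rayleigh stability limit, where the charge q = π√(8ε₀γd³) a
droplet can hold is exactly balanced. Then d = 8ε₀γ/σ² and
γ = dσ²/(8ε₀); the two forms are algebraically consistent with
q = σπd², which the tests verify to 1e−9 across a (d, γ) log grid.

Assumption (iii) is the strong one: droplets below the limit would give
an *underestimate* of γ by this route, and the large droplet-size
dispersity of a kinetically arrested phase separation propagates linearly
into γ. Defaults: ε = 78.4 (water, 298.15 K), ε₀ = 8.8541878128e−12 F/m
(CODATA). The Debye length is an input (the full ionic composition of a
pH-12, TFA-containing sample is rarely known); it can alternatively be
derived from an ionic strength via κ⁻¹ = √(εε₀k_BT/(2N_Ae²·10³I)), and
the environment object cross-checks the two to 1e−6 relative if both are
given.

## SAXS model and fitting (`saxs`)

The coacervate variant is I(q) = I_s q⁻ⁿ + scale·P(q) + b: a power law
for the droplet interfaces (n fixed at 4 by default — Porod scattering
from sharp interfaces of discrete objects — releasable by flag) plus the
generalized Gaussian coil for the dissolved monomer. P(q) is the
excluded-volume chain form factor, evaluated with lower incomplete gamma
functions in U = q²R_g²(2ν+1)(2ν+2)/6:

    P(q) = γ(1/(2ν), U)/(ν U^(1/(2ν))) − γ(1/ν, U)/(ν U^(1/ν))

with P(0) = 1 and high-q decay q^(−1/ν). The prefactor (2ν+1)(2ν+2)/6
follows from R_g² = a²n^(2ν)/((2ν+1)(2ν+2)) for a chain with Flory
exponent ν, and is what makes ν = ½ reduce exactly to the Debye function
2(e^(−x) − 1 + x)/x², x = q²R_g² — an identity the tests check to 1e−6
against the closed form. For U < 1e−12 the evaluation short-circuits to
the q → 0 limit. The monomer variant multiplies the coil by an empirical
correlation-peak factor S(q) = 1 + c/(1 + (|q − q₀|ξ)^m) (m defaults to
2); this is a generic descriptor of an intermolecular-correlation peak,
not a liquid-state theory structure factor.

Fitting is lmfit Levenberg–Marquardt least squares, weighted 1/σ² when
the curve carries uncertainties and unweighted otherwise, with bounds
enforcing R_g > 0, ν ∈ [0.2, 1], n ∈ [0.5, 8] and non-negative
amplitudes. Any parameter can be frozen by name. Non-convergence sets a
flag on the result rather than raising. q is fixed to Å⁻¹ at the I/O
boundary (2- or 3-column ASCII, `#` comments, comma or whitespace
separated, rows sorted on read).

## DLS inversion (`dls`)

Forward model: g₁(τ) = Σᵢ wᵢ exp(−Dᵢq²τ) over an intensity-weighted
R_H grid, Dᵢ = k_BT/(6πη R_H,i) (Stokes–Einstein),
q = 4πn sin(θ/2)/λ, and the Siegert relation g₂ − 1 = β g₁². Defaults
match a standard goniometer: λ = 632.8 nm, θ = 90°, water at 298.15 K
(n = 1.33, η = 0.89 mPa·s); all overridable.

Inversion solves min_{w≥0} ‖W(Aw − g₁)‖² + α²‖Lw‖² on a 60-point
log-spaced R_H grid (1 nm–10 μm default) with L the second-difference
operator — the same constrained-regularization strategy as CONTIN, with
scipy NNLS on the augmented system. Two numerical choices matter and are
deliberate:

* g₁ is obtained from the measured g₂ − 1 by a *signed* square root, and
  the rows are weighted by W = diag(max(|g₁|, 0.05)). Additive noise on
  g₂ − 1 propagates to g₁ with standard deviation ∝ 1/|g₁|, so the
  noise-only baseline at long lags is strongly down-weighted; without
  this, rectified baseline noise feeds spurious slow modes and biases
  the recovered mean diameter upward by several percent.
* α = 'auto' picks the largest α on a log grid (1e−4–10, 21 points)
  whose weighted residual is within 0.2 % of the minimum achievable —
  the smoothest solution the data permit, a discrepancy-type rule. An
  L-curve corner was evaluated and rejected: at these noise levels the
  residual-vs-α curve is flat until regularization bites, the curve has
  no corner, and corner picks over-smoothed (merging clearly separated
  bimodal populations). A numeric α overrides the rule.

The output distribution is intensity-weighted (no Mie/Rayleigh-Gans
conversion to volume or number — out of scope), non-negative and
normalized; the intensity-weighted mean diameter is 2Σwᵢ R_H,i.

## Synthetic data (`synthetic`)

Generators return (data, truth) pairs in the same types the analysis
stages consume. Noise structure: multiplicative Gaussian for SAXS
(relative error is what beamline reduction reports), additive Gaussian
for DLS correlograms (correlator noise is roughly lag-independent),
optional Gaussian pH-meter noise for titrations. All randomness flows
from one integer seed per call (numpy default_rng).

Default scenarios pin the study conditions the toolkit targets: SAXS
coacervate curves on q ∈ [0.004, 0.4] Å⁻¹ (200 log-spaced points) with
R_g = 9.23 Å (tetrapeptide) or 18.95 Å (hexapeptide), ν = 0.4 (a
compressed coil, below the θ-solvent value of ½), n = 4, 2 % noise; DLS
ensembles log-normal in R_H with intensity-weighted mean diameter
1.3 μm, σ_g = 1.1, β = 0.9, noise 1e−3; the log-normal median is
corrected once for grid discretization so the discrete mean hits the
target. The turbidity grid uses a linear LLPS onset pH*(c) = 12.5 − 0.2c
over c ∈ [0.5, 5] wt %, pH ∈ [9, 13], with a sigmoidal rise of width
0.15 pH and amplitude 2 cm⁻¹ — the shape of a concentration-dependent
pH-triggered coacervation boundary.

What passing these tests shows: the estimators are unbiased and
well-conditioned *under the stated noise models and the assumed forward
models*. What they do not show: robustness to the pathologies of real
data — SAXS buffer-subtraction artefacts, capillary scattering,
inter-droplet structure factors at low q; DLS number fluctuations,
multiple scattering and sedimentation of μm-scale droplets; pKa shifts
in the dense phase. Recovery percentages quoted in the tests (e.g. the
median R_g error < 2 % over 20 seeds, or the mean diameter within 10 %
in ≥ 90 % of seeds) are properties of these synthetic conditions.

## Problem sizes and tolerances

Recovery suites use 20 seeded replicates per condition — enough for a
stable median while keeping the full test suite in a few seconds. SAXS
fits start from ×1.5-perturbed truth (a deliberately poor but realistic
initialization); DLS inversions run the α grid per correlogram.
Tolerances in tests mirror the derivation that justifies them: algebraic
identities at 1e−9–1e−12, special-function limits at 1e−6, stochastic
recoveries at the 2 %/10 % levels the estimator design targets.

## Known limitations

* Speciation ignores site coupling; for peptides with adjacent ionizable
  groups (not the WR family) the microstate identity still holds but the
  physics may not.
* The tension estimate is conditional on the Rayleigh-limit assumption
  and is a point estimate; no uncertainty propagation from the zeta and
  size measurements is implemented.
* The DLS inversion reports the grid-discretized intensity-weighted
  distribution; peak *positions* are reliable to about one grid cell
  (factor 1.17 in R_H on the default grid).
* The SAXS correlation-peak factor is empirical; its parameters are not
  interpretable as liquid-structure quantities.
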