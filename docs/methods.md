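# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Binding thermodynamics (itc)

A 1:1 association M + X ⇌ MX measured by titration calorimetry follows the
Wiseman differential isotherm

    dQ/d[X_tot] = ΔH·V₀·[ ½ + (1 − (1+r)/2 − R_m/2)
                          / √(R_m² − 2R_m(1−r) + (1+r)²) ]

with r = K_d/M_tot (the inverse of the Wiseman c-value) and R_m the running
molar ratio.  Per-injection heats integrate this differential between the
pre- and post-injection ligand concentrations by the midpoint rule; the
discriminant is non-negative for r ≥ 0 and the tight-binding corner
(R_m = 1, r = 0) is a removable 0/0 evaluated by its limit (½).  Dilution
uses standard perfusion-cell algebra: an injection of volume v displaces a
fraction v/V₀ of the cell contents, so both the macromolecule and previously
injected ligand are diluted by (1 − v/V₀) before the new ligand is added.

The fit optimizes (ln K_d, ΔH) — plus an optional constant heat-of-dilution
offset when no blank has been subtracted — by Levenberg–Marquardt from three
starting c-values; parameter uncertainties come from the Jacobian covariance
at the optimum and propagate first-order into ΔG and TΔS.  Derived
quantities use ΔG = RT ln(K_d in molar units) with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 300 K by default, TΔS = ΔH − ΔG
exactly, and σ = K_d(apo)/K_d(nucleotide-saturated), σ > 1 meaning positive
K-type cooperativity.  A c-value above 1000 triggers an ill-conditioning
warning; a flat isotherm returns ΔH ≈ 0 with K_d flagged unidentifiable.

Noise calibration of the generator: additive Gaussian noise in µcal with
standard deviation `noise_frac` × the mean absolute injection heat.
Calorimeter baseline-integration noise is roughly constant across a run and
is naturally quoted relative to the typical injection signal; at the default
design (13 µM cell, 200 µM syringe, 28 × 10 µL into 1.4 mL) 2 % corresponds
to ≈ 0.4 µcal, a realistic instrument figure.  At this level a single fit
determines K_d to ≈ 4 % (Cramér–Rao); recovery is therefore assessed on
triplicates, matching how such titrations are actually acquired (n = 3).

## Methyl order parameters (fast_dynamics)

The forbidden (triple-quantum-filtered) over allowed
(single-quantum-filtered) intensity ratio builds up with relaxation delay T
as

    I_a/I_b = (3/4) η tanh(λT) / (λ − δ tanh(λT)),   λ = √(η² + δ²)

where η is the intra-methyl ¹H–¹H dipolar cross-correlated relaxation rate
and δ ≥ 0 absorbs couplings to external protons (fitted per methyl; no
literature value is assumed).  The curve rises strictly monotonically to the
plateau (3/4)η/(λ − δ).  Nonlinear least squares on the 9-point 3–35 ms
delay grid recovers (η, δ); uncertainties come from Monte-Carlo resampling
of the ratios (default 500 draws).  Degenerate, delay-independent data are
flagged unusable rather than assigned a rate.

η converts to the methyl-axis order parameter through

    η ≈ (9/10)(μ₀/4π)² [P₂(cos θ_HH)]² O² γ_H⁴ ħ² τ_c / r_HH⁶

with the standard methyl geometry θ_HH = 90° (so P₂² = ¼),
r_HH = 1.813 Å, γ_H = 2.6752×10⁸ rad s⁻¹ T⁻¹, ħ = 1.0546×10⁻³⁴ J s,
μ₀/4π = 10⁻⁷ T² J⁻¹ m³, packaged as an overridable constant set.  O² is
linear in η and inverse in τ_c; raw inversions above 1.2 are flagged
implausible and the reported value is clipped to [0, 1] (the raw value is
kept).  τ_c comes from dynamic light scattering through Stokes–Einstein,
τ_c = 4πη_visc r³/(3k_BT) (water viscosity at 300 K by default); the study
values are 29.6 ns (ADP-bound) and 25.3 ns (ternary complexes).

ΔO² is later-state minus earlier-state along the declared cycle order, so
rigidification upon binding is positive.  The covariance network correlates
each methyl's O² profile across ≥4 ligation states (Pearson; edges above
0.9 by default).  Profiles are ordered series: the matrix is invariant to a
state reordering only if applied to every methyl consistently.
Zero-variance profiles are masked, not forced to a coefficient.

The conversion of ΔO² to an entropy in physical units requires an empirical
calibration that is deliberately out of scope; only ΔO²/ΔΔO² statistics are
reported.

## CPMG dispersion (cpmg)

Constant-time intensities convert via R2,eff = −(1/T_cp) ln(I/I₀) with
T_cp = 40 ms; intensities implying R2,eff ≤ −1/T_cp are flagged.  Replicate
frequencies (50, 200, 1000 Hz) are retained as separate points and their
pooled spread sets the per-point uncertainty for the field.

Two-state exchange A ⇌ B (p_A > p_B, k_ex = k_AB + k_BA) follows the
standard Carver–Richards closed form

    R₂ = R₂⁰ + ½[k_ex − (1/τ_cp)·acosh(D₊cosh η₊ − D₋cos η₋)]
    D± = ½[±1 + (ψ + 2Δω²)/√(ψ² + ξ²)]
    η± = (τ_cp/√2)·√(±ψ + √(ψ² + ξ²))
    ψ  = k_ex² − Δω²,  ξ = −2Δω k_ex (p_A − p_B)

with τ_cp = 1/(2ν_CPMG) and Δω in rad s⁻¹ (ppm values scale by the ¹³C
Larmor frequency, γ_C/γ_H = 0.25144).  This form reduces exactly to R₂⁰ at
Δω = 0 and is even in Δω, so |Δω| is reported.  Large η₊ uses the
asymptotic acosh to avoid overflow.

The independent oracle propagates complex two-state transverse
magnetization numerically through the echo train (free precession with
exchange between ideal 180° pulses implemented as conjugation).  The
effective rate is measured over the second constant-time period of an
established train, −(1/T_cp) ln(|M_A(2T_cp)|/|M_A(T_cp)|): the first period
carries a duration-independent amplitude transient (the equilibrium initial
state is not an eigenvector of the echo propagator) that is not part of the
dispersion rate the closed form describes.  With this readout the two
routes agree to better than 0.5 % of R_ex over
p_B ∈ {0.02, 0.05, 0.1} × k_ex ∈ {200, 1000, 3000} s⁻¹ × Δω ∈ {1, 2, 3} ppm
at 850 MHz (observed ≈ 0.006 %).  In slow exchange (k_ex ≪ Δω) both routes
show genuine few-percent ripples of R2,eff versus ν where the pulsing rate
resonates with Δω — the dispersion is only approximately monotone there.

Fitting shares (p_B, k_ex, Δω_ppm) across fields with a per-field R₂⁰,
weights by per-point uncertainty, and restarts local optimization from a
log-spaced k_ex grid {100, 300, 1000, 3000} × p_B grid {0.01, 0.05, 0.15}
because the χ² surface is multimodal.  Exchange is declared detected when
the exchange model beats the flat model by an F-test (α = 0.01, three extra
parameters) *and* the fitted dispersion amplitude exceeds 0.5 s⁻¹ — the
second condition stops noiseless flat curves from registering spurious
detections.  Single-field fits are allowed but flagged weakly identified;
in fast exchange the robust combination is p_B·Δω², not the individual
factors.  Monte-Carlo resampling supplies parameter uncertainties.

## DyCorr synchrony maps (dycorr)

Exchange-detected methyls map to points (k_on, k_off) = (p_E k_ex, p_G k_ex)
with p_E = p_B the excited-state population.  For a pair, the relative
distance is the separation normalized by the distance from the origin to the
pair midpoint, κ = |r_i − r_j| / |(r_i + r_j)/2|; this is invariant to a
global rescaling of all rates, so no log transform is applied (documented
switch-free: the geometry already removes scale).  Over the closed
non-negative quadrant κ has supremum 2, attained by two points on the axes
equidistant from the origin.  Proximity uses the dataset maximum κ_m (not
the theoretical 2):

    nonlinear: η = (κ_m − κ)/(κ_m(κ + 1));   linear: η = 1 − κ/2

η = 1 marks co-moving (synchronous) pairs, η = 0 the most asynchronous one;
the nonlinear form is strictly decreasing in κ.  Synchrony clusters are
connected components of the η > 0.9 graph.  Methyls without detected
exchange are excluded and listed.  The normalization "distance to the
midpoint from the origin" is pinned by the analytic bound: only this reading
makes the diagonal-pair supremum exactly 2.

## Chemical-shift statistics (shifts)

CSP: √(Δδ_H² + c Δδ_X²), c = 0.25 (¹³C) or 0.154 (¹⁵N).  The CHESCA filter
uses the maximum pairwise vector distance across states,
max √((0.25 ΔδC)² + ΔδH²); the carbon dimension is scaled by 0.25 in all
response vectors and PCA clouds so both dimensions sit on comparable scales.

CONCISE runs a PCA per methyl (states as observations, the two shift axes
as variables).  Linear responders have SD(PC1)/SD(PC2) ≥ 3.0; methyls with
maximum CSP < 0.05 ppm are discarded as silent.  Kept methyls' PC1 scores
are affinely normalized so the open basis state maps to 0 and the closed
basis to 1; a state's equilibrium position is the mean normalized score and
its spread is summarized as a Gaussian (the per-state distribution is kept
for resampling).  Read as a closed-state population p, positions convert to
binding free energies by the two-state log-odds
ΔΔG = −RT[ln(p/(1−p)) − ln(p_ref/(1−p_ref))], with a 90 % confidence
interval from bootstrap over methyls; positions at exactly 0 or 1 give an
unbounded log-odds and are reported censored.

CHESCA centers each methyl's δH and δC trajectories on their own means
before concatenation — the response is the change across states, and
block-wise baseline offsets would otherwise contaminate the Pearson
coefficient.  Pairs with r > 0.9 form the network; average-linkage
hierarchical clustering of 1 − r gives the dendrogram.

## Configurational entropy (entropy)

Per degree of freedom (residue, atom role, axis), the first-order
differential entropy is the Shannon entropy of a uniform histogram (24 bins
by default, switchable; at least ~10 samples per bin recommended) plus
ln(bin width), with the Miller–Madow (m−1)/(2n) bias correction.  Constant
series are censored (−∞).  Mutual information uses the discrete convention
(bin widths cancel), I = H(x) + H(y) − H(x, y) from 1-D/2-D histograms,
minus the mean MI of permutation-shuffled pairs — finite independent samples
show nonzero apparent MI, and the permutation null estimates that bias
directly — clipped at zero.  A residue's corrected entropy is the sum of its
marginal entropies minus the sum of pairwise corrected MIs; triplet and
higher orders are omitted.  Totals are reported in nats and in
cal mol⁻¹ K⁻¹ (× R).  An optional frame stride mimics the decorrelation
subsampling applied to trajectory data; synthetic samples are i.i.d., so the
default stride is 1.

## Synthetic data: what it does and does not emulate

Generators reproduce the statistical structure each analysis assumes:
population-weighted fast-exchange shift titrations (12 states by default —
titration-series granularity typical of NMR work and necessary for the
PC-ratio filter to have statistical power; non-linear decoys move
isotropically and independently per state), exact TQ/SQ build-up ratios
under a monoexponential envelope, closed-form or oracle-propagated
dispersion curves, midpoint-integrated Wiseman heats, latent-factor O²
tables, and multivariate Gaussian coordinates with analytic entropies.
They do **not** emulate spectrometer artifacts, peak overlap or picking
errors, baseline drifts, heteroscedastic heats, three-state exchange, or
anharmonic/multimodal coordinate distributions.  Passing recovery tests
therefore demonstrates correctness of the estimators under their own model
assumptions, not robustness to the systematic errors of real spectra.
All generators are deterministic given (parameters, seed); seeds are
explicit arguments.

## Problem sizes and runtime choices

Test and driver problem sizes are chosen to exercise the statistics at
desk scale: 10⁵ samples for entropy closed forms, 10⁶ random pairs for the
κ bound, 20 noise replicates for dispersion recovery, triplicates for ITC,
50–100 methyls for the shift-statistics filters.  These keep the full suite
under a minute per module while leaving the estimators' error bars well
inside the asserted tolerances.

## Known limitations

* The Carver–Richards fit assumes equal intrinsic rates in both states and
  ideal refocusing pulses; off-resonance and multiple-quantum effects are
  out of scope.
* Histogram MI underestimates strong dependencies (a duplicated coordinate
  yields the discrete marginal entropy, which differs from the differential
  one by ln(bin width)); the expansion is reliable for the weak-to-moderate
  correlations it is meant to remove.
* The CONCISE population→ΔΔG conversion assumes a global two-state
  equilibrium; positions outside (0, 1) (possible with noisy normalization)
  are censored rather than extrapolated.
* K_d from a single isotherm at realistic noise is ~4 % precise at best;
  conclusions about cooperativity ratios should use replicate means, as the
  drivers do.
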