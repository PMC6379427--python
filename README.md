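# kinetropy

Quantitative analysis of how conformational dynamics drive binding
cooperativity along a protein kinase catalytic cycle, built around the
catalytic subunit of protein kinase A (PKA-C) as the model system.

During turnover the kinase visits apo, nucleotide-bound, ternary
(nucleotide + substrate), exit (ADP + phospho-product) and ADP-bound states.
Nucleotide and substrate bind with positive K-type cooperativity, ADP and
phospho-product with negative cooperativity.  This package implements the
full quantitative chain that connects calorimetry, chemical shifts, and
spin relaxation to that thermodynamic picture, with synthetic ground-truth
generators so every stage is testable end to end:

* **ITC binding thermodynamics** — 1:1 Wiseman isotherm fits,
  ΔG = RT ln K_d, TΔS = ΔH − ΔG, cooperativity σ = K_d(apo)/K_d(nucleotide),
  cumulative ΔΔG ladders along the cycle (`kinetropy.itc`).
* **Methyl order parameters** — intra-methyl cross-correlated relaxation:
  TQ/SQ intensity ratios (3/4)η tanh(√(η²+δ²)T)/(√(η²+δ²) − δ tanh(√(η²+δ²)T))
  fitted for η, inverted to O² through
  η ≈ (9/10)(μ₀/4π)²[P₂(cos θ_HH)]² O² γ_H⁴ ħ² τ_c / r_HH⁶, plus ΔO² and the
  Pearson covariance network of O² across ligation states
  (`kinetropy.fast_dynamics`).
* **CPMG relaxation dispersion** — R2,eff = −(1/T_cp) ln(I/I₀), two-state
  Carver–Richards fits (joint across 700/850 MHz), validated against an
  independent numerical Bloch–McConnell propagator (`kinetropy.cpmg`).
* **DyCorr synchrony maps** — each exchanging methyl becomes a point
  (k_on, k_off) = (p_E k_ex, p_G k_ex); pairwise relative distance
  κ = |r_i − r_j| / |(r_i + r_j)/2| (supremum 2 over the non-negative
  quadrant) maps to a relative proximity η ∈ [0, 1] whose >0.9 graph
  separates synchronous from asynchronous motions (`kinetropy.dycorr`).
* **Chemical-shift statistics** — CSP √(Δδ_H² + c Δδ_X²), CONCISE
  (per-methyl PCA linearity filter, equilibrium positions, two-state
  log-odds ΔΔG) and CHESCA covariance with the maximum-vector-distance
  filter (`kinetropy.shifts`).
* **Configurational entropy** — histogram entropy expansion per residue with
  pairwise mutual-information correction and a permutation-null bias
  baseline (`kinetropy.entropy`).

`kinetropy.synthetic` generates every input with a serialized `TruthRecord`
(the exact generating parameters), and `kinetropy.data_io` reads/writes the
four plain-CSV dialects all stages consume.

## Worked example

The `analysis/` directory holds the numbered pipeline drivers.  Stage 01
writes all synthetic inputs under `results/data/`; each later stage reads
them back through `data_io` and reports recovery against truth:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_binding_thermodynamics.py
```

prints

```
itc_rep1.csv: Kd = 0.819 +/- 0.020 uM, dH = -19.19 +/- 0.07 kcal/mol
itc_rep2.csv: Kd = 0.778 +/- 0.019 uM, dH = -19.07 +/- 0.06 kcal/mol
itc_rep3.csv: Kd = 0.804 +/- 0.013 uM, dH = -19.14 +/- 0.04 kcal/mol
triplicate mean: Kd = 0.800 uM (truth 0.8), dH = -19.13 kcal/mol (truth -19.1)
cooperativity sigma: 2.8 (ATPgC-saturated), 4.4 (ATPgN-saturated); phospho-product: sigma = 0.47 (2.1-fold negative)
cumulative ddG ladder: {'apo': 0.0, 'binary(ATPgN)': -6.0, 'ternary(+PKS)': -15.27}
```

Three replicate titrations (K_d = 0.8 µM, ΔH = −19.1 kcal mol⁻¹, 2 % heat
noise) are fit individually; the triplicate mean recovers the truth to three
digits.  The σ values come from the measured dissociation constants of the
substrate for the apo versus nucleotide-saturated enzyme (positive
cooperativity: nucleotide tightens substrate binding 2.8–4.4×; the
phosphorylated product binds ~2× weaker once ADP is bound).  The ladder
accumulates stepwise binding free energies from the apo reference, giving
about −15 kcal mol⁻¹ for the ternary complex.

The remaining drivers cover order parameters (03), dispersion fitting plus
the DyCorr map (04), CONCISE/CHESCA (05) and entropy estimation (06); each
prints the recovered-versus-true quantities and writes tables under
`results/`.

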