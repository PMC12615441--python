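# phosphoshift

³¹P-MRSI chemical-shift analysis of glioma tissue: time-domain spectral
quantification of the Pi and ATP resonances with Cramér–Rao quality
control, ROI-wise chemical-shift statistics across tumor sub-compartments
and IDH groups, and grid look-up inversion of intracellular pH, MgATP-bound
fraction and an ionic-strength surrogate.

## Who this is for

In vivo ³¹P MR spectroscopic imaging resolves the resonances of
phosphocreatine (PCr), inorganic phosphate (Pi) and the three phosphate
groups of ATP (γ, α, β).  Their chemical shifts respond to the cellular
microenvironment: δPi tracks intracellular pH through the phosphate
titration equilibrium, the ATP shifts move between free-ATP and MgATP
positions with the Mg²⁺-bound fraction, and all respond (unequally) to the
ionic composition.  This package is for spectroscopists who want to turn
voxel-wise ³¹P FIDs into per-region shift signatures and biochemical
estimates, and to compare those between tissue compartments (contrast-
enhancing tumor, edema, non-enhancing tumor, normal-appearing white matter)
and between patient groups (high/low grade, IDH-wildtype/mutant) — plus a
synthetic cohort generator so the whole chain can be exercised and
validated without patient data.

## The model

Quantification fits each voxel's FID with a sum of Lorentzian singlets
(AMARES-style prior-knowledge nonlinear least squares, analytic Jacobian,
bounded shifts, shared zero-order phase):

    y(tₙ) = Σₖ Aₖ exp(i(2π fₖ tₙ + φₖ)) exp(−dₖ tₙ) + ε(tₙ)

Cramér–Rao lower bounds come from the Fisher matrix of the complex Gaussian
noise model; voxels enter the analysis only when the amplitude CRLBs of
Pi, γ-, α- and β-ATP are all strictly below 35 %.

Forward chemistry maps a biochemical state (pH, Mg-bound fraction m,
ionic-strength surrogate *Ion*) to shifts (ppm relative to PCr, downfield
positive):

    δPi  = δ_acid + (δ_base − δ_acid) / (1 + 10^(pKa − pH)) + c_ion,Pi·ΔIon
    δ_k  = δ_free,k + m·(δ_Mg,k − δ_free,k) + c_pH,k·ΔpH + c_ion,k·ΔIon ,  k ∈ {γ, α, β}

The modified Henderson–Hasselbalch inverse gives the conventional pH from
δPi alone; the look-up inversion instead matches the α-referenced triple
(δPi−δα, δγ−δα, δβ−δα) against a precomputed grid over (pH, Mg, Ion) by
exact nearest-neighbour search, returning all three parameters at once.

## Worked example

```python
from phosphoshift import (ShiftConstants, BiochemState, pi_shift_from_ph,
                          atp_shifts_from_state, build_table, invert)

c = ShiftConstants()
state = BiochemState(ph=7.10, mg_fraction=0.85, ion=0.12)
d_pi = pi_shift_from_ph(state.ph, c, ion=state.ion)
g, a, b = atp_shifts_from_state(state, c)
print(f"d_pi={d_pi:.4f} d_gamma={g:.4f} d_alpha={a:.4f} d_beta={b:.4f}")

table = build_table(c)                      # 181 × 101 × 41 nodes
r = invert((d_pi - a, g - a, b - a), table)
print(f"pH={r.ph} Mg={r.mg_fraction} Ion={r.ion} residual={r.residual:.2e} ppm")
```

prints

```
d_pi=4.9140 d_gamma=-2.5160 d_alpha=-7.5255 d_beta=-16.5640
pH=7.1 Mg=0.85 Ion=0.12 residual=0.00e+00 ppm
```

i.e. a mildly alkaline tumor-like voxel (δPi 4.914 ppm downfield of PCr,
β-ATP pulled downfield by Mg binding) whose α-referenced shift triple
inverts exactly back to the state that produced it.

The full chain — simulate an 11-patient cohort (8 HGG with CE and edema
compartments, 2 LGG with a non-enhancing compartment, 1 unclassified),
preprocess (Casorati low-rank filter, spatial zero-filling, 15-Hz Gaussian
apodization), fit every in-mask voxel, gate on CRLBs, average shifts per
ROI, invert to (pH, Mg, Ion), and compare groups with power-gated tests —
runs from the shell:

```
phosphoshift run-all --seed 1 --outdir run
```

which writes per-patient fit tables, the ROI shift means, the biochemical
estimates, all pairwise comparisons with significance flags (`*` p < 0.05,
`**` p < 0.001, each requiring post-hoc power > 0.8), box-plot figures and
a reproducibility manifest into `run/`.

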