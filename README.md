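# stoichspindle

A mechanistic simulator of mitotic-spindle positioning, elongation, and
scaling in single-cell nematode embryos, built on a stoichiometric model
of cortical pulling forces, together with the trait-extraction and
correlation machinery used to discriminate competing models of spindle
size control.

## Who this is for

Cell biophysicists and quantitative cell biologists studying how the
first mitotic spindle of *C. elegans*-like embryos finds its final
length and asymmetric position, and how those traits scale with cell
size — without invoking microtubule pushing, spindle elasticity, or a
limiting pool of components.

## The model

Astral microtubules (MTs) nucleate from each centrosome at rate γ, grow
at speed V_g, and undergo catastrophe at rate λ, giving the steady-state
length density ψ(l) = (γ/V_g) e^(−lλ/V_g) and N_MT = γ/λ microtubules.
A cortical force generator (CFG) is a disk of capture radius r on the
cell surface; growing MTs impinge on it at rate

    Ω(d) = γ χ(d) e^(−dλ/V_g),    χ(d) = (ξ̂·n̂)/2 · (1 − 1/√(1+(r/d)²)),

where d is the centrosome–CFG distance, ξ̂ the unit vector from
centrosome to CFG and n̂ the outward surface normal (for r ≪ d this is
the familiar Ω ≈ (γ/4)(r/d)² e^(−λd/V_g)).  Each CFG binds **one MT at a
time** — the stoichiometric rule — and pulls on it with force f₀ along
the MT until detachment at rate κ.  With n centrosomes competing for a
CFG, the quasi-steady attachment probabilities are

    P_i = Ω(d_i) / (Σ_j Ω(d_j) + κ),

so the mean force from one CFG on centrosome i is f₀ P_i ξ̂_i, bounded
by f₀.  This bound removes the destabilizing feedback of
non-stoichiometric pulling (mean force f₀ Ω/κ, divergent near the
cortex), and the centrosome–centrosome competition for shared CFGs gives
single asters their centering behaviour.  Centrosome motion is
overdamped,

    η Ẋ₁ + ν ((Ẋ₁−Ẋ₂)·Ŝ) Ŝ = F₁,    η Ẋ₂ − ν ((Ẋ₁−Ẋ₂)·Ŝ) Ŝ = F₂,

with drag η, central-spindle viscosity ν, and spindle axis Ŝ.  The cell
is a superellipsoid (default 50 × 30 × 30 μm ellipsoid); ~100 CFGs are
placed area-uniformly, 60 on the posterior half and 40 on the anterior,
mirroring the posterior enrichment of force generators in vivo.

Defaults: γ = 250 s⁻¹, V_g = 0.5 μm/s, λ = 0.025 s⁻¹, κ = 0.1 s⁻¹,
r = 1.5 μm, f₀ = 10 pN, η = 150 pN·s/μm, ν = 100 pN·s/μm.

## Worked example

```sh
python examples/wildtype_spindle.py
```

```
termination:       converged at t = 178 s
final length:      22.93 um (starts at 11 um)
pole positions x:  anterior -8.92 um, posterior +14.00 um
spindle centre x:  +2.54 um (posterior shift from the cell centre)
```

The two centrosomes start 11 μm apart at the cell centre, separate, and
converge to a stable interior force balance: a final pole-to-pole length
of ~23 μm with the posterior pole displaced farther than the anterior —
the asymmetric division geometry of the one-cell embryo.  Other
examples: `single_aster_centering.py` (ablation analogue),
`stoichiometry_matters.py` (instability without the one-MT-per-CFG
rule), `spindle_scaling.py` (length scaling with cell size),
`model_signatures.py` and `extract_spindle_traits.py` (trait fitting and
Timer / Limiting-Component / Boundary signature tests).

A thin CLI exposes the same operations:
`stoichspindle simulate`, `scenario`, `sweep-cell-size`, `sweep-cfg`,
`fit-traits`, `analyze-scaling`, `test-models`, `gen-traits`.

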