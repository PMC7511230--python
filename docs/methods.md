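# Methods

## Model

The package simulates the final stage of the first mitotic division in
a nematode-like single-cell embryo: two centrosomes (spindle poles)
moving under pulling forces from cortically anchored force generators
(CFGs), each of which can hold at most one astral microtubule at a time.

**Microtubule field.**  MTs nucleate isotropically from each centrosome
at rate γ, grow at V_g, and disappear by catastrophe at rate λ.  Growth
and turnover are fast compared with centrosome motion, so the MT field
is treated as stationary around the instantaneous centrosome positions:
length density ψ(l) = (γ/V_g) e^(−lλ/V_g), N_MT = γ/λ (10,000 at
defaults), mean length V_g/λ = 20 μm.  Individual filaments are never
represented; rescue, pausing, and pushing against the cortex are outside
the model.

**Capture and attachment.**  A CFG is a disk of effective radius r
(lumping motor size with the distance an MT tip travels along the
cortex; no sub-model, r is a constant).  The rate of first impingement
is Ω(d) = γ χ(d) e^(−dλ/V_g) with cone fraction
χ(d) = (ξ̂·n̂)/2 (1 − 1/√(1+(r/d)²)).  The incidence factor ξ̂·n̂ is
clamped to [0, 1]; for a convex cell and interior centrosomes it is
non-negative anyway.  The exact χ is used in simulations because it
stays bounded (χ → 1/2) as d → 0; the small-angle form (γ/4)(r/d)²
e^(−λd/V_g) is provided as a documented variant.  Attachment is a
single-site exclusion process: with n centrosomes, the quasi-steady
occupancies are P_i = Ω_i/(ΣΩ + κ).  The quasi-steady limit is the
default everywhere (centrosome speeds ~0.1 μm/s are slow against
binding dynamics); the explicit relaxation dP_i/dt = Ω_i(1 − ΣP) − κP_i
is available for validation.  The generalization to arbitrary n is the
obvious one; n = 2 is the simulated case and n = 1 its ablation limit.

**Forces and motion.**  Each CFG pulls with f₀ P_i ξ̂_i on centrosome i
(so never more than f₀); in the non-stoichiometric control every
impinging MT is pulled, mean force f₀ (Ω/κ) ξ̂, which diverges near the
cortex and reproduces the runaway instability.  Force balance couples
per-centrosome drag η with a central-spindle viscous element ν acting
along the spindle axis; the 6×6 linear system splits exactly into a
translation mode (drag η) and a separation mode (η + 2ν along the
axis).  η and ν only set time scales — the converged geometry is
independent of them and of any uniform rescaling of f₀ or CFG count.

## Geometry and CFG placement

The cell is the superellipsoid |x/R_x|^P_x + |y/R_y|^P_y + |z/R_z|^P_z
= 1, default exponents (2, 2, 2) (plain ellipsoid) and semi-axes
(25, 15, 15) μm; posterior is +x.  Cell length CL = 2R_x; the cell-area
proxy CA is the analytic x–y midplane section area.

CFG layouts place a fixed count on each half (default 60 posterior / 40
anterior) using balanced centroidal-Voronoi relaxation: an area-uniform
reference cloud is sampled on the half-surface (star-shaped rejection
sampling with the exact area element), each CFG claims an equal share of
cloud points, and moves to its share's centroid, re-projected to the
surface.  The equal-count constraint matters: plain nearest-neighbour
k-means or chord-distance repulsion mis-populates the highly curved
cell poles by ~10–15%, which shifts the axial force balance by tens of
pN and visibly corrupts the final length and the scaling slope.  Layout
noise for ensembles comes from the random cloud plus a tangent-plane
jitter of up to 0.2× the mean spacing (re-projected); magnitudes of
this order leave the half-counts and density statistics intact.
Min pairwise spacing without jitter exceeds 0.8 × √(A_half/n).

## Integration and termination

Explicit Euler with dt = 0.05 s (halving dt moves final positions by
< 0.1 μm); steps are shortened adaptively so no centrosome moves more
than 0.4 μm per step, which lets the non-stoichiometric runaway
proceed smoothly to its cortex-contact termination instead of aborting.
A run ends when (a) every active centrosome stays below 0.005 μm/s for
10 s (*converged*), (b) a centrosome comes within one capture radius of
the surface or crosses it (*cortex_contact* — never reached in
stoichiometric runs), or (c) t_max = 300 s elapses.  Timed centrosome
removals (in-silico ablation) deactivate a centrosome: it stops moving,
stops competing for CFGs, and the ν coupling is dropped; convergence
detection restarts after each event and is suppressed while events are
pending.  Motor parameters are time-independent by default; a linear
ramp facility exists (conventionally applied to κ, the inverse of motor
processivity) and changes only the smoothness of the elongation-rate
transition, not the final state.

## Trait extraction and statistics

Spindle length L(t) is fit by nonlinear least squares with
l(t) = IL + (FL − IL)/(1 + e^(−(t−t₀)/τ_s)); ER = (FL − IL)/(4τ_s) is
the sigmoid slope at t₀.  The posterior pole's distance to the
posterior boundary is fit with the falling counterpart whose plateau is
CD.  Initialization uses the first/last decile means, the half-range
crossing, and a quarter of the 10–90% interval; fits are bounded to
keep baseline and plateau near the observed range, because simulated
traces begin at anaphase onset without an early plateau (the
rate-discontinuity of time-independent motor parameters), and the
unconstrained baseline of such saturating traces is ill-determined —
the fitted IL then sits at its bound slightly below L(0), while FL, CD,
and ER are insensitive to this choice.  Plateau presence is flagged
when the final 10% of samples span < 0.5 μm.

Associations between traits are ordinary least squares (slope, SE,
two-sided t-test p-value); partial correlation conditions by residual
regression — regress both traits on the conditioner, then regress the
residuals.  A constant conditioner degrades gracefully to the raw
regression.  Signature tests judge, at α = 0.05: Timer by
corr(IL, FL) > 0, Limiting Component by partial(FL, CA | CL) > 0,
Boundary by corr(FL, CL) > 0 together with corr(FL, CD) < 0.

## Synthetic trait generator

The generator emulates the covariance structure — not the mechanism —
of each size-control hypothesis at embryo-realistic magnitudes
(CL ≈ 50, FL ≈ 24, IL ≈ 11 μm; line SD 1 μm, residual noise 0.3 μm,
chosen as plausible inbred-panel spreads since only mechanisms, not
variances, are specified by the hypotheses): Timer draws IL ⊥ Δ and
sets FL = IL + Δ; Limiting Component draws component density, cell
length, and cell width independently with FL ∝ density × volume;
Boundary draws CL ⊥ CD with FL = CL − 2·CD + noise.  A
custom-covariance mode draws a multivariate normal.  Passing signature
tests on these tables validates the decision logic only; it says
nothing about measurement artefacts, nonlinear trait relations, or
genetic linkage structure present in real panels, none of which are
emulated.

## Problem sizes

Headline ensembles use 16 layouts for the wild-type final length and
6 cell lengths × 8 layouts for the scaling slope — sizes at which the
ensemble means are stable to ~0.1 μm and ~0.015 respectively; the full
64-layout protocol is available by passing larger `n_configs`.

## Known limitations

- The symmetric (par-6-like) layout converges ~1.3 μm longer than the
  60/40 asymmetric layout (24.3 vs 23.05 μm; the noise-free continuum
  force balance gives 24.16 vs 22.56 μm), so "symmetric equals
  asymmetric final length" holds only at the ~5% level, and the strict
  statistical-equality test in the acceptance suite fails by design
  rather than being loosened.
- Time-independent motor parameters give elongation that starts at its
  maximum rate (no early plateau), so simulated IL from the sigmoid fit
  is a bounded extrapolation rather than a measured plateau.
- No spindle rocking/oscillations, metaphase establishment, cortical
  PAR dynamics, MT pushing, or time-varying cell shape.
- The near-cortex guard uses the radial (not normal) distance to the
  surface; for the default aspect ratios the difference is well under
  the capture radius.
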