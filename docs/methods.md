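# Methods

## Model overview

The package couples two fields on a shared uniform grid:

* a complex neural activity field ψ(x, t) obeying the Schrödinger-type
  equation i D ∂t ψ + D² Δψ − Φ(x, t) ψ = 0, where D (dimensionless
  diffusion-like coefficient, default 1.0) sets both the dispersive
  scale and the phase sensitivity to the potential Φ;
* a real synaptic weight field W(x, t) obeying the logistic
  reaction–diffusion law ∂W/∂t = ρW(1 − W/K) + s·α_W|ψ|²W + D_W ΔW.

In the scenario runner the activity field is *prescribed* from the
closed-form traveling solutions of the profile equation
Φ'' = αΦ + βΦ² rather than integrated through the PDE; the PDE
integrator exists alongside as an independent component and as a
cross-check of the traveling ansatz. Prescribed drivers make the
scenarios exactly reproducible and keep the plasticity layer — the
object of study — insulated from integrator error.

### Traveling-wave branches

For α > 0, β < 0 the first integral (Φ')² = αΦ² + (2/3)βΦ³ + C₁ has
three real roots Φ₁ ≤ Φ₂ ≤ Φ₃ for C₁ ∈ (−α³/3β², 0), and the bounded
solution oscillates on [Φ₂, Φ₃]:

    Φ(ξ) = Φ₂ + (Φ₃ − Φ₂) cn²(νξ | m),
    m = (Φ₃ − Φ₂)/(Φ₃ − Φ₁),  ν = sqrt(−β(Φ₃ − Φ₁)/6),

with wavelength 2K(m)/ν. Cnoidal parameters are always constructed
through the root triple (from C₁, or from a requested modulus m by
solving for the consistent C₁), so the first-integral residual vanishes
by construction. The m → 1 limit (C₁ → 0⁻) degenerates to the soliton
A sech²(√α ξ/2), A = −3α/2β; the m → 0 limit is a small cosine ripple
around the cubic's local maximum.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| D | activity-field diffusion coefficient | 1.0 | must be > 0 |
| c | wave propagation speed | 1.0 | sign = direction |
| α, β | linear / quadratic profile coefficients | 0.8, −1.2 | soliton amplitude −3α/2β = 1 |
| ρ | intrinsic weight growth rate | 1.0 | relaxation time 1/ρ |
| K | carrying capacity | 1.0 | saturation scale of W |
| α_W | activity-coupling gain | 1.0 | `alpha_plast` in code |
| D_W | weight diffusion | 0.5 | CFL bound dx²/(2·d·D_W) |
| s | coupling sign | −1 | +1 in potentiation presets |

All quantities are in the model's dimensionless units. The 1D domain is
[−50, 50] with 500 nodes (dx = 0.2, periodic for waves); 2D runs use
[−10, 10]² with 200 × 200 nodes (dx = 0.1). Time step dt = 0.01 and
durations T = 50 or 100.

### The coupling-sign ambiguity

The weight equation as printed carries a suppressive drive term
(−α_W|ψ|²W), yet the localized-potentiation phenomenology (place-field
/ grid-field imprints) requires activity to *increase* weights. Both
regimes are implemented behind one switch. The metric-level presets
(interference analysis, hysteresis protocol) keep s = −1; the
imprinting presets (`soliton_1d`, `cnoidal_1d`, 2D lattice scenarios)
use s = +1, where the logistic term saturates growth at the elevated
fixed point K(1 + α_W I/ρ) instead of K.

## Numerical schemes

* **Grids.** Periodic grids exclude the duplicate endpoint
  (dx = L/n, exact for FFTs); no-flux grids include both endpoints
  (dx = L/(n−1)). 1D arrays are indexed by x; 2D arrays are row-major
  (y, x). Laplacians use the 3-point / 5-point second-order stencils.
* **No-flux closure.** Mirror ghost nodes (f[−1] = f[1]). This closure
  conserves the *trapezoid-weighted* discrete mass (half-weight
  endpoints) exactly under pure diffusion, which is the invariant the
  tests assert; the plain node sum drifts by the boundary flux error.
* **Wave evolution.** Forward Euler is unconditionally unstable for the
  free Schrödinger operator, so the integrator uses Strang split-step
  Fourier on periodic grids (exact free propagator) and implicit-
  midpoint Crank–Nicolson on no-flux grids. Both preserve the discrete
  norm to round-off for real potentials; time-dependent potentials are
  sampled at step midpoints.
* **Plasticity evolution.** Forward Euler with the no-flux closure,
  refused above the explicit-diffusion CFL bound dx²/(2·d·D_W) and for
  dt·ρ ≥ 1. The coupled runner sub-steps automatically when the nominal
  dt exceeds the bound (the 2D reference step 0.01 is twice the 2D
  bound 0.005); the drive intensity is held fixed across sub-steps.
  Negative undershoots (possible only for extreme drives) clamp to zero
  with a warning. W = 0 and W = K are exact fixed points of the
  discrete update.
* **Profile ODE cross-check.** Fixed-step RK4 on (Φ, Φ'), flagging
  |Φ| > 10⁶ as divergent (the quadratic nonlinearity has genuine
  blow-up orbits). Against the closed forms it agrees to ~1e−8 over
  ξ ∈ [0, 20] at step 1e−3 and conserves the first integral to ~1e−14.

## Scenario presets and the synthetic drive conditions

Named presets cover the simulation study: `soliton_1d`, `cnoidal_1d`
(m = 0.9), `interference_noise_1d` (cnoidal m = 0.9 plus cnoidal
m = 0.5 offset by x₀ = 5, background noise σ = 0.05),
`temporal_snapshots` (T = 100 time course), `hysteresis_reversal`,
`theta_gamma`, `grid_2wave_2d` (0°/90°), `grid_3wave_2d` (0°/60°/120°),
`gaussian_place_1d` (soliton under a static Gaussian envelope of width
one-tenth the domain), and the sweeps `noise_sweep`, `complexity_sweep`,
`phase_speed_sweep`. Cnoidal moduli, the component offset and the noise
amplitude are package choices (the source study does not print them):
m = 0.9 gives a visibly nonlinear periodic wave, m = 0.5 a clearly
different wavelength for beat structure, and σ = 0.05 is "low" relative
to the O(1) wave amplitudes.

**Noise model.** Background noise is *frozen*: one seeded complex
Gaussian field drawn per run and added to the drive at every time step,
representing quenched environmental heterogeneity. A per-step redraw
would time-average out of the weight field almost completely (the
imprint integrates thousands of steps), making even large noise
amplitudes inconsequential — contradicting the observed erasure of
encoding at high noise. With frozen noise the correlation between the
noisy imprint and its noiseless reference falls monotonically
(1.00 → 0.995 → 0.87 → 0.03 for σ = 0 → 0.05 → 0.2 → 1.0, five seeds
per level).

**Theta–gamma driver.** ψ = (1 + A sin(2π f_θ t))·sin(ω_γ(x − ct)) with
ω_γ = 1, f_θ = 0.02 ≈ one envelope cycle per eight carrier cycles, and
envelope depth A ∈ {0 (carrier only), 0.5, 1.0}. The envelope is pure
amplitude modulation — a deliberate simplification of physiological
phase–amplitude coupling.

**Seeding.** One master seed per run feeds the single stochastic
component (the frozen noise field). Sweep cells derive seeds as
`SeedSequence([master, value_index, replicate])`, keeping cells
independent but reproducible.

What the synthetic conditions do *not* emulate: spiking discreteness,
neuromodulatory gating, synaptic tagging, glial dynamics, heterogeneous
or 3D geometry, and empirically calibrated oscillation frequencies.
Passing tests certify the mathematical pipeline and its internal
consistency, not biological fidelity.

## Analysis conventions

* **Spectral entropy.** Shannon entropy of the normalized Fourier power
  spectrum. Default convention: log base 2 (bits), one-sided spectrum,
  DC excluded — a pure tone scores exactly 0 and a flat N-bin spectrum
  exactly log2 N. Every metric row records the convention used, since
  the numeric value depends strongly on sidedness, DC handling and
  base. Under this convention *blurring* a patterned weight field
  narrows its spectrum and lowers its entropy; analyses that include a
  noise floor can move in the opposite direction.
* **Cross-correlation.** Default mode is the unnormalized circular
  mean-product (peak can exceed 1); lagged Pearson mode is available
  for bounded comparisons. Lags are reported signed in (−N/2, N/2],
  ties resolved toward zero lag.
* **Field summary.** Population (1/N) standard deviation.
* **Hysteresis.** Loop area by trapezoid sum Σ½(W̄ₖ₊₁+W̄ₖ)(Iₖ₊₁−Iₖ)
  over the closed drive loop (identical to the polygon shoelace area up
  to sign); H_norm = |H| divided by the bounding-box area of the loop;
  R = 1 − ‖W_rev−W₀‖₂/‖W_fwd−W₀‖₂ (R = 1 when the forward epoch itself
  caused no change); Ω = cosine similarity of the endpoint fields; H_x
  is the per-node trapezoid loop area, whose spatial mean equals the
  global signed area identically.
* **Lattice spacing.** Local maxima over a 7 × 7 neighborhood above
  70% of the field range, plateau components merged to centroids,
  spacing = median nearest-neighbor distance. The +inf boundary padding
  suppresses spurious edge maxima. The 70% prominence default was
  calibrated against the exact interference geometry: three equal waves
  at 0°/60°/120° with k = 1 produce a triangular lattice of spacing
  4π/√3 ≈ 7.255, recovered to −0.8% on the 200² grid and to within 5%
  under ±5–10° angular perturbation, while 45° separations break the
  hexagonal structure (spacing estimate off by ~47%, rectangular
  motifs).

## The hysteresis protocol

Default (ramp) mode: the drive amplitude I multiplies the traveling
cnoidal field, ramping 0 → 1 over one epoch of T = 50 and 1 → 0 over a
second epoch of equal length (direction +c throughout); the monotone
ramp avoids the spurious signed-area inflation an oscillating drive
variable would cause. Direction mode (constant amplitude, +c then −c)
is available as the alternative protocol.

The protocol starts from the *undriven equilibrium* W₀ = K. Starting
below capacity would superimpose the intrinsic logistic transient on
the drive response: W̄ keeps rising through the reverse epoch, the
"recovery" denominator measures growth rather than learning, and R
leaves [0, 1]. From equilibrium, the loop area and R quantify drive
path-dependence alone.

**Known limitation — quasi-static saturation of R.** With ρ = 1 the
weight relaxation time (1/ρ = 1) is tiny against the epoch length
(T = 50), so the ramp is quasi-static: by the end of the reverse epoch
the field has recovered essentially fully and R sits at ≈ 0.999
regardless of D_W. Conversely, direction mode ends with the drive still
on, pinning R near 0. Intermediate reversibility values — and a
resolvable effect of weight diffusion on R — would require epochs
comparable to 1/ρ, i.e. a ramp fast enough to leave the field
mid-recovery at the endpoint. This saturation is why the package
asserts the D_W-dependence of the loop area (H_norm shrinks as D_W
grows, 0.0489 → 0.0468 for D_W 0.5 → 1.0) but cannot resolve a
monotone D_W effect on R under the reference protocol.

## Problem sizes

The quantitative scenarios run the full reference resolution (500 nodes,
5 000–10 000 time steps; the 2D geometry checks use the full 200 × 200
grid). Unit and property tests use reduced grids and durations chosen
to keep each check sharp while the whole suite completes in well under
two minutes; the grid-refinement test verifies that halving dx and dt
moves the final weight field by ≈ 0.13% in relative L2, so the reduced
configurations operate in the converged regime.
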