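# Methods

## Model

The package simulates small homonuclear ¹⁹F spin systems (n ≤ 6, in
practice 2 or 4) that exist in two copies — inside and outside a cell
membrane — and interconvert by first-order translocation. States are
density-matrix deviations from the high-temperature thermal equilibrium,
vectorised column-major, so a system of n spins occupies a Liouville space
of dimension 2·4ⁿ. The full generator is

    L = -i Ĥ + R + K,

assembled from the following blocks.

**Coherent part.** Per compartment, H = Σᵢ Ωᵢ L_iz + Σᵢ<ⱼ 2π Jᵢⱼ (Lᵢ·Lⱼ)
in the ¹⁹F rotating frame, with the full isotropic coupling (no
weak-coupling truncation): strong-coupling (AB) effects are exact. Offsets
are Ωᵢ = 2π ν₀ (δᵢ − carrier)·10⁻⁶. J-couplings are taken identical in
both compartments (solvent perturbs shifts far more strongly than J; this
halves the parameter count), while shifts may differ. Protons are not part
of the spin system — experimentally they are decoupled — but an optional
per-compartment random-field rate (R1_ext/R2_ext, default 0) can represent
their residual relaxation contribution without biasing the fitted
correlation times silently.

**Relaxation.** Semi-classical Redfield theory for isotropic rotational
diffusion at correlation time τ_c, fitted independently per compartment.
Every dipole–dipole (from the molecular geometry) and CSA (axiality Δσ,
asymmetry η, Euler angles) interaction is decomposed into rank-2
irreducible spherical tensors; the superoperator is assembled in the
eigenbasis of the lab-frame static Hamiltonian with the reduced spectral
density j(ω) = τ_c/(1+(ωτ_c)²) sampled at the transition eigenfrequencies.
All auto- and cross-correlations (DD–DD, CSA–CSA, DD–CSA) are kept; a
secular filter drops elements bridging eigenfrequency gaps beyond a cutoff
(default 10³ rad/s), except that the zero-quantum/longitudinal block is
always retained whole, because its internal couplings (flip-flop terms,
partner flips) generate exactly the NOE and J-type mixing-time effects the
method exists to model. The assembled superoperator is Hermitised (the
semi-classical R is self-adjoint in the Hilbert–Schmidt inner product; the
explicit symmetrisation removes round-off asymmetry) and transformed back
to the product basis. With this convention the closed forms hold exactly
when the spins sit at the carrier: the Solomon rates
ρ = (b²/10)(j(0)+3j(ω₀)+6j(2ω₀)), σ = (b²/10)(6j(2ω₀)−j(0)) with
b = −(μ₀/4π)γ²ħ/r³, the CSA rate R₁ = (2/15)(Δσω₀)²(1+η²/3)j(ω₀), the
partner-flip rate W₁ = (3/20)b²j(ω₀), and the NOE zero crossing at
ω₀τ_c = √5/2. Off carrier, rates differ from these forms at the 10⁻⁶
level because j(ω) is evaluated at the true eigenfrequencies — a feature,
not an error; exact-equality tests therefore place spins on resonance.

**Kinetics.** Exchange is the 2×2 kinetic matrix [[−k_io, k_oi],
[k_io, −k_oi]] tensored with the spin-space identity. States are
amount-weighted (populations live in the state, not the generator), so the
kinetic matrix's columns sum to zero — amounts are conserved exactly — and
peak volumes are directly proportional to compartment amounts. The
equilibrium constraint k_oi = k_io·pop_in/pop_out is applied by default
during fitting (it is exact at equilibrium and reflects that efflux is the
haematocrit-independent quantity); fitting k_oi freely is possible by
disabling the constraint on the assembly.

Because Ĥ conserves the total magnetic quantum number, K is
spin-coordinate-blind, and the secularised R never connects coherence
orders, L is block-diagonal over coherence order p. Propagators are
computed per block by eigendecomposition — at n = 4 this is roughly an
order of magnitude cheaper than exponentiating the full 512-dimensional
generator, and it is what keeps the 4-spin fits tractable on one CPU. A
stability guard rejects generators with growing modes.

## The simulated experiment

90° – t₁ – 90° – t_m – 90° – acquire, with ideal (infinitely hard,
perfectly calibrated) pulses; hardware imperfections are nuisance effects
outside scope. F1 quadrature uses the States method (first pulse x for the
cosine set, y for the sine set) and a two-step phase cycle on the first
pulse (±phase, receiver inversion) cancels magnetisation recovered during
t_m, suppressing axial peaks. Each transient starts from exact equilibrium
(the inter-transient delay of 8 s is far longer than T₁). Crucially, no
coherence-order filtering is applied during t_m: zero-quantum and
J-coupling artefact peaks survive, as they do in the modelled experiment,
and are part of what the fit fits. Deviation states make thermal
equilibrium exact: pulses act affinely (χ → Pχ + Pσ_eq − σ_eq) and L
annihilates the equilibrium itself under detailed balance.

Processing: cosine-squared window in both dimensions (1 at the first
point, 0 at the last), first-point scaling by ½, zero-filling (the
experiment's linear-prediction extension of t₁ is replaced by plain
zero-filling: synthetic data have no SNR motive for LP, and LP would add an
unverifiable algorithmic dependency), complex FT in t₂, States
recombination of the two real parts, real FT in t₁. Conventions are fixed
and oracle-tested rather than asserted to match any instrument: detection
is of Σᵢ Lᵢ⁺, FIDs are conjugated before the forward FFT so that a spin
with offset +ν appears at +ν on the ascending axis (ppm axes stored
ascending, rendered descending), and zero-order phases of 90° (F2) / 0°
(F1) with a global sign flip give positive absorption diagonals.

## Classical comparator

Peak volumes are rectangle sums × pixel area over labelled regions; the
2×2 per-anomer volume matrix is normalised by reference amounts M0 taken
from a simulated short-mixing-time experiment (keeping the pipeline
self-contained), and rates follow from the principal matrix logarithm,
L = (1/t_m)·logm(V·diag(M0)⁻¹). Eigenvalues with non-positive real part
flag a branch ambiguity in the result rather than raising. Because the
geminal splitting (≈0.66 ppm at 376 MHz) far exceeds the inside/outside
shift separation (≈0.2 ppm), multiplet-group rectangles would mix the
compartments; the default regions are therefore one rectangle per resolved
doublet component. No lineshape deconvolution is attempted — the point of
the comparator is to mirror what standard processing software does, and
the bias probe quantifies (rather than resolves) the resulting
contamination by NOE/J pathways. Note that relaxation pathways that act
symmetrically on both compartments only rescale the volume matrix and
cancel from the extracted rates; the observable bias is driven by the
asymmetry between the compartments (different τ_c) and by integration
overlap, which is why it is modest (~2 %) on the clean synthetic fixtures
and larger in crowded experimental spectra.

## Fitting

The objective is the squared Frobenius norm of the difference between
simulated and target spectra over unmasked pixels. Minimisation is
Nelder–Mead over transformed coordinates: softplus for rates and
amplitudes (positivity), log₁₀ seconds for correlation times. Convergence
requires simplex size < 10⁻⁴ (internal coordinates) and an objective
spread below 10⁻⁶ of the initial objective, floored at the round-off scale
of the data so a start at an exact optimum terminates. Non-finite
objectives are replaced by a large penalty, which rejects the offending
vertex. The canonical parameter layout (rates, correlation times,
amplitudes, populations, shifts, couplings — 18 parameters for the 2-spin
fixture, 34 for the 4-spin one) is documented in `fitting.pack_parameters`;
the standard recovery protocol frees {k_io(α), k_io(β), log₁₀τ_c(in),
log₁₀τ_c(out)} and freezes the rest at truth, which keeps the acceptance
runs fast while exercising the parameters the study actually reports.

Uncertainties come from a dropout bootstrap: each round masks a fresh
random half of the pixels (seeded, fully reproducible) and refits from the
full-data optimum — restarting from the initial guess instead would
multiply the cost without changing the spread, since the dropout optimum
lies near the full-data one. Refits use a smaller initial simplex and a
slightly looser tolerance (10⁻³) than the main fit; rounds that fail to
converge are excluded and counted.

## Synthetic data

The two fixtures emulate the study systems: `fdg33` (one geminal CF₂, two
spins per anomer) and `fdg2233` (CF₂CF₂, four spins per anomer), each as
an α/β anomer pair (amplitudes 1.0/1.6, near the anomeric equilibrium of
glucose) in two compartments with amount ratio 1.86 (haematocrit ≈ 65 %).
Kinetic and correlation-time truths are the published fitted values
(k_io(α)/k_io(β) = 0.23/0.79 s⁻¹ and 0.94/0.87 s⁻¹; τ_c(in)/τ_c(out) =
10⁻⁹·⁰³/10⁻⁹·²⁸ s and 10⁻⁸·⁴⁶/10⁻⁹·⁰⁹ s). Everything else is a
literature-plausible placeholder, chosen once and documented: geminal
²J_FF ≈ 250 Hz, vicinal ³J_FF 5–14 Hz, geminal F–F distance 2.16 Å, CSA
Δσ = 60 ppm with η = 0.3, inside/outside shift separations ≈ 0.2 ppm, and
shift ladders spaced so every doublet component of every species resolves
on the reduced grids. Recovery tests target only the kinetic/τ_c truth,
never the placeholders. Acquisition defaults are reduced from the
experiment's 512×1024 complex grid to 128×256 (and 64×128 for the 4-spin
recovery runs) with matching spectral widths of 6–7 kHz; this keeps a full
4-parameter fit at minutes on one CPU while leaving the inside/outside
splitting marginally resolved in F1, which is the regime the method is for.

Noise is additive white Gaussian in the time domain, injected before
processing so apodisation shapes it as in real data; its amplitude is
calibrated against a processed unit-noise realisation to hit a target
spectral SNR (default 50, swept in tests). Every dataset is fully
determined by (fixture name, overrides, seed).

What the synthetic data do not emulate: B₀/B₁ inhomogeneity, baseline and
solvent artefacts, temperature drift, haematocrit variation between
samples, and binding-induced changes of τ_c during the experiment. Passing
recovery tests therefore demonstrate the estimator's correctness and
conditioning, not robustness to instrumental systematics.

## Numerical choices and limitations

- Tolerances: Liouvillian off-block residuals ≤ 10⁻⁸ of the generator
  scale; growing modes above ~10⁻⁶ of scale raise; matrix-log round trips
  hold to 10⁻⁸ over rates in [0.01, 5] s⁻¹.
- Windowed, truncated spectra put a floor under "zero": dispersive
  phase-twist tails of coherent pathways and apodisation sidelobes leave
  relative region-volume residuals of order 10⁻⁴–10⁻³ even where the
  physical transfer amplitude is exactly zero (verified at the generator
  level, where the inhibited k = 0 limit is block-diagonal to machine
  precision). Tests of "no cross-peaks" are therefore phrased against
  these measured processing floors, with the exact statement pinned on the
  generator.
- The volume-matrix comparisons against the analytic two-site solution use
  a pair of mixing times (0.15/0.5 s) and a transverse dephasing rate so
  the coherent (echo) pathway — which survives t_m when nothing relaxes —
  does not contaminate the longitudinal bookkeeping.
- Degenerate shifts are handled by diagonalising the static Hamiltonian
  within total-M sectors, keeping coherence-order bookkeeping sharp under
  accidental degeneracies.
- Correlation times are compartment properties shared between anomers, as
  in the modelled study; substrate-specific binding would break this and
  is out of scope.
- Only two compartments and first-order (non-saturable) exchange are
  supported; anomer interconversion is neglected (slow on the EXSY
  timescale).
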