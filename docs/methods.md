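# Methods

This note records the model as implemented, the defaults and why, the
numerical choices, and what the synthetic studies do and do not show.

## Model summary and assumptions

The axon network is idealized as a genus-`g` hyperelliptic Riemann
surface `w² = P(z) = Π(z − x_i)` with spin-½ surface particles. The
package implements the *quantitative* layer of that picture:

1. bookkeeping of theta characteristics `(α_i, β_i) ∈ {0, ½}` and the
   spin topology number `W = 4Σα_iβ_i` (parity = parity of `W`);
2. sech soliton pulse trains parameterized by pinch parameters
   `(a, b, c)` with spin phase `cos πW` and travelling speed `v = b/a`;
3. the Schwarz-tiling origin of the EEG bands and the fractional
   Legendre modes of the sphere wave equation;
4. the CGS spin-memory ledger (fields, alignment, binding, engrams);
5. the modal Green's-function response and closed-form K-complex /
   spindle waveforms.

The exact algebro-geometric N-soliton solutions are out of scope; the
sech envelope is the canonical one-soliton modulus and carries the same
parameter structure, which is what the fitting and memory layers
consume.

## Parameters and defaults

CGS units throughout the memory module (values are the model's standard
estimates): proton moment `μ = 10⁻²³` erg/G, `ħ = 10⁻²⁷` erg·s, medium
light speed `c = 10¹⁰` cm/s, proton spacing `d = 10⁻⁸` cm, axon
circumference `2πr_a = 10⁻³` cm (so `N_c = 10⁵` spins per circle),
pulse duration `Δt = 10⁻³` s, `kT = 10⁻¹⁴` erg, `e = 4.8×10⁻¹⁰` esu,
field per unit charge `B₀ = 10⁻⁹` G. Strand defaults `N₀ = 10` charge
units per pulse (chosen so the excitation frequency lands in the
spindle band) and `N_s = 10³` pulses (the alignment minimum).

Tiling scale: the wave equation fixes only ratios ("the scale of these
frequencies is not fixed"), so the band table pins the uniform sphere
mode to frequency 1 and 200 µV; amplitudes are rounded to the nearest
microvolt, which reproduces the published 33 (= 200/6) and 17
(≈ 200/12). Both frequency conventions are exposed: `frequency`
(tile-count scale, used for band prediction) and
`eigenvalue`/`omega = √λ` (wave-equation scale).

Soliton trains are dimensionless (`z/z₀`, `t/t₀`).

## Numerical choices

**Theta sums.** Truncated over the hypercube `|n_i| ≤ R`, default
`R = 10` for `g ≤ 3`; the tail is bounded by the Gaussian decay
`exp(−πλ_min R²)` with `λ_min` the smallest eigenvalue of `Im Ω`.
"Imaginary part positive" is implemented as positive definiteness of
`Im Ω` — the actual convergence condition; entrywise positivity is
neither necessary nor sufficient.

**One-forms and pinch coefficients.** `z^{j−1}/√P(z)` uses the
principal square-root branch; continuity along a path is a documented
convention, not enforced (the global branch is genuinely
underdetermined). Taylor coefficients about the pinch point come from
the series recurrence `P h′ = −½ P′ h` for `h = P^{−1/2}`, and are
cross-checked in the tests against a Cauchy contour-integral (FFT)
oracle.

**Fractional Legendre modes.** For `μ = ±½` the closed trigonometric
forms are used; general `(ν, μ)` goes through `2F1`. The eigenfunction
of the associated Legendre operator at `λ_n = (2n)² − ¼` is
`sin(2nθ)/√sinθ` (trig argument `(ν+½)θ` with `ν = 2n−½`); this is the
profile used for eigenvalue checks and the Green's-function basis
(orthonormalized to `√(2/π) sin(2nθ)/√sinθ`). The display harmonic
keeps the printed profile `cos((2n−½)θ)`; note its trig argument is the
degree rather than `ν+½`, so it is *not* the eigenfunction at `λ_n` —
the two roles are deliberately separated in the API
(`fractional_harmonic` vs `mode_profile`).

**Mode norm.** The pairing integral `∫ sinθ P_ν^{μ}P_ν^{−μ} dθ`
vanishes identically under the standard closed forms (the integrand is
the full-period harmonic `∝ sin 4nθ`), so it cannot normalize anything.
`norm_P` therefore computes the sphere-surface L² norm of the
unnormalized harmonic by composite Simpson quadrature (normative), and
the ambiguous printed Γ-factor closed form is evaluated alongside with
its relative discrepancy reported, never asserted.

**Tiling solution weight.** `S(θ′,φ′) = (1/n) cos(nφ′) cos((4n−1)θ′)
/ √(sin 2θ′)`. The weight is the sphere harmonic's radial factor
`(sinθ)^{−1/2}` under `θ = 2θ′`. With this weight all three triangle
sides vanish genuinely: the cosine zero at `θ′ = π/2` is linear while
the weight diverges only like `(π/2 − θ′)^{−1/2}`, so the product tends
to 0 and the boundary value is implemented as the continuous extension.
(The alternative grouping `√sinθ′/sin 2θ′` would give a finite nonzero
boundary limit and was rejected for violating the boundary-zero
contract.) The colatitude factor has `2n − 1` interior nodal
latitudes; "localized single-sign" behavior holds within the
fundamental sub-tile below the first nodal latitude, and that is what
the tests assert.

**Soliton fitting.** Levenberg–Marquardt least squares on
`Σ_j V0_j sech(b_j t − c_j)`; initialization by Gaussian-smoothed peak
detection (maxima above 3× MAD, minimum separation a quarter of the
per-pulse record, leftmost-first tie-break) with widths from the
half-maximum span (`FWHM = 2 arccosh(2)/b`). No parameter is shared
across pulses. A single-site recording cannot identify the spatial
scale `a` (only `bt − c` enters the data), so `a` is placed by the
nondimensionalization convention `z₀ = v t₀` (unit speed, `a = b`)
unless a `known_speed` is supplied; the generator draws trains under
the same convention. When over-parameterized, the fitter may split a
true pulse between two components rather than shrinking the extra one
— the invariant that holds (and is tested) is that the extra component
improves the residual by no more than a fraction of the noise floor.

**Modal response.** Eigenfunction-expansion Green's function for the
sphere-surface wave equation (uniquely determined by the wave equation
plus completeness of the tiling basis). Point inputs are mollified to
Gaussians (default width 0.01 rad) whose integral is
width-independent; time integration is trapezoidal with step at most
1/20 of the fastest modal period; spatial projection is trapezoidal
under the `sinθ` measure.

**K-complex glue.** The two lobes are blended by a C¹ cosine smoothstep
on `(T − ε, T + ε)`, `ε = 0.05 T`: continuous by construction, with
matching one-sided slopes at the window edges.

**Spindle spectrum.** `sin(t) sin(ω₀t)` has exact spectral lines at
`ω₀ ± 1`, not at `ω₀`; frequency statements are therefore made on the
power-weighted spectral centroid, which sits at `ω₀` (and `2ω₀` for the
paired structure) to within a frequency bin.

**MRI disruption.** Computed honestly as `cluster·μ·B`; at `μ = 10⁻²³`
erg/G and a few tesla this is ~10⁻¹⁹ erg, and the qualitative contract
is that it never reaches the 10⁻¹² erg binding. The thermal binding is
`(N_c μ)²/d³`, the form consistent with the model's own arithmetic.

## Synthetic data: what it emulates and what it does not

`synth_spike_train` emulates single-electrode spike-train recordings:
a sech train sampled at fixed position with additive white Gaussian
noise, seeded and reproducible. The recovery study draws 20 trains of
2–5 pulses with stratified arrival times, widths 2–6 % of the
inter-pulse spacing, amplitudes 0.5–2, and SNR 20 (noise sd = peak/20)
— deliberately well-separated pulses, as in the thalamic recordings the
model was fitted to. Real data differ in ways the generator ignores:
colored noise, baseline drift, asymmetric after-hyperpolarization,
overlapping pulses, and electrode filtering. Passing the recovery
criterion therefore shows the estimator is consistent and
well-conditioned under the stated conditions, not that real spike
trains are sech solitons. Likewise the modal-response study shows
resonance selectivity of the idealized basis, not agreement with scalp
EEG; the observational claims (thalamic fits, band agreement) are not
reproducible from printed data and are covered only by these property
checks.

## Problem sizes

Defaults used by the shipped studies: theta sums at `R ≤ 12`, `g ≤ 3`;
recovery study 20 trains × ≤ 5 pulses at 200 Hz × 10 s; modal runs with
4 modes, 120 colatitude points and 50 drive periods. These sizes give
results stable to well inside the asserted tolerances while keeping
every study interactive.

## Known limitations

- No exact N-soliton (theta-quotient) waveforms; sech envelopes only.
- The square-root branch of the one-forms is a convention; integrals
  along paths that cross branch cuts need caller-side continuation.
- The Green's function lives on the 1-D colatitude arc of the dihedral
  basis; full 2-D sphere response would need the azimuthal factors.
- The spin-memory layer is closed-form arithmetic, not a quantum
  dynamics simulation; it reproduces ledger-level numbers only.
- Band labels for tilings whose frequency falls on a band edge follow
  the published attribution (e.g. the 6-tile cube is listed under
  alpha) rather than a strict range lookup; `band_name` provides the
  range lookup for arbitrary dihedral orders.
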