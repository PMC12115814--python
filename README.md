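# surfnet

A tested simulator/toolkit for a topological surface-network model of
brain excitations. The model idealizes the axon connectome as a
hyperelliptic Riemann surface carrying spin-½ surface particles:

- **Spike trains.** Local *pinch deformations* of the surface emit
  trains of soliton voltage pulses
  `V_j(z,t) = e^{-iπW} V_j(a_j z − b_j t + c_j)`, modelled with a sech
  envelope. The pinch parameters `(a_j, b_j, c_j)` are the signal's
  own communication code; `surfnet` synthesizes such trains and
  recovers the parameters from recordings by damped least squares.
- **EEG bands from sphere tilings.** Pinched subunits become
  topological spheres whose surface oscillations must tile the sphere
  (Schwarz triangles `(p,q,r)` with `1/p + 1/q + 1/r > 1`). Tile
  count fixes frequency and tile area fixes amplitude, giving the
  inverse law `a_N ν_N = const` and the five EEG bands. The dihedral
  modes are fractional associated Legendre functions with degree
  `ν = 2n − ½`, order `μ = −½` and eigenvalue `λ_n = (2n)² − ¼`.
- **Spin memory.** A moving pulse of charge `Q` and speed `v`
  generates the helical field `B = Qv/(cr²)` (CGS), aligning the `N_c`
  myelin-sheath proton spins per axon circle into a helical structure
  `S(z) = e^{-iκz} S_L`. Excitation frequency `ω = N_c μ N_0 B/ħ`,
  alignment condition `N_s N_0 > ħ/(N_c μ B_0 Δt)`, binding energy
  `(N_c μ)²/d³` vs `kT`, engram size `N_e = W − 1` and creation time
  `τ_e = W N_s t_pulse`.
- **Modal response and sleep events.** The tiling modes give the
  causal Green's function
  `G = Σ_n φ_n(z)φ_n(z′) sin(ω_n(t−t′))/ω_n`; resonant inputs select
  "their" band. K-complexes (glued Gaussian-windowed cosine lobes) and
  sleep spindles (`ΔV = N_s (μB/e) sin t sin ω_0 t`, with a paired
  structure at `2ω_0` and doubled amplitude) are synthesized in closed
  form.

Intended users: computational neuroscientists and biophysicists who
want a runnable, testable rendition of this model's quantitative
claims, either from Python or from the `surfnet` command line.

## Worked example

```sh
$ surfnet tiling-table --dihedral-n 20
name,tile_count,frequency,band,amplitude
sphere,1,1.0,delta,200
tetrahedron,4,4.0,theta,50
cube,6,6.0,alpha,33
octahedron,8,8.0,alpha,25
dodecahedron,12,12.0,beta,17
icosahedron,20,20.0,beta,10
dihedral,40,40.0,gamma,5
```

One row per sphere tiling: the frequency column is the tile count on
the delta-normalized scale (the five EEG bands from delta at 1 to gamma
at 40), and amplitude is 200 µV divided by the tile count — the
inverse amplitude–frequency law.

```sh
$ surfnet memory-ledger --n0 10 --ns 1000 --w 5
{
  "Nc": 100000,
  "memory_frequency_hz": 10.0,
  "paired_frequency_hz": 20.0,
  "alignment_threshold_NsN0": 1000.0000000000001,
  "aligned": true,
  "binding_energy_erg": 9.999999999999996e-13,
  "thermally_stable": true,
  ...
  "engram": { "W": 5, "Ne": 4, "tau_engram_s": 5.0, ... }
}
```

At the default constants a 10-charge-unit pulse train resonates at
10 Hz (20 Hz for the paired-spin structure), needs `N_s N_0 > 10³` to
align spins, is bound at 10⁻¹² erg (two decades above body-heat kT),
and a five-loop engram of 4 neurons forms in 5 s.

The `examples/` directory holds one short narrative script per
capability (band table, spike fitting, memory ledger, modal resonance,
sleep waveforms, theta/pinch bookkeeping); each prints what it computes
and says what the numbers mean.

## Layout

- `src/surfnet/riemann.py` — theta functions with characteristics, spin
  topology numbers, period matrices, one-forms, pinch expansions
- `src/surfnet/tiling.py` — Schwarz triples, band table, fractional
  Legendre modes, tiling solutions and norms
- `src/surfnet/solitons.py` — sech pulse trains, synthesis and fitting
- `src/surfnet/memory.py` — helical fields, spin structures, stability
  ledger
- `src/surfnet/response.py` — modal Green's function, blocking inputs,
  K-complex and spindle synthesis
- `src/surfnet/io.py`, `pipeline.py`, `cli.py` — formats, end-to-end
  runs and the `surfnet` command

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
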