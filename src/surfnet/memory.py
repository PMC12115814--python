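"""Proton-spin memory: helical fields, spin structures and the stability ledger.

A moving soliton pulse carries effective charge and therefore generates
a transient helical magnetic field B = Q v / (c r^2) (CGS) tangent to
the axon tube.  The field acts on the unpaired spin-1/2 protons of the
myelin sheath, aligning the Nc spins on each circumferential circle into
a helical structure S(z) = exp(-i kappa z) S_L whose pitch encodes the
pulse.  The structure resonates at omega = Nc mu N0 B / hbar (a paired
secondary structure at 2 omega), is thermally bound by spin-spin
interaction (Nc mu)^2 / d^3, and is topologically stable only when the
spin topology number W of the supporting neuron loops is non-zero; then
the engram has Ne = W - 1 neurons and forms in time tau_e = W Ns t_pulse.

All arithmetic is CGS, the convention of the underlying estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MemoryConstants",
    "MemoryStrand",
    "Engram",
    "SpinStructure",
    "helical_field",
    "spins_per_circle",
    "memory_frequency",
    "alignment_threshold",
    "spin_structure",
    "thermal_stability",
    "mri_disruption",
    "engram_metrics",
    "engram_firing_count",
    "memory_ledger",
    "order_of_magnitude",
]


@dataclass(frozen=True)
class MemoryConstants:
    """Physical constants of the spin-memory estimates (CGS).

    mu: proton magnetic moment (erg/gauss); hbar (erg s); c_light (cm/s,
    speed of light in the medium); d: inter-proton spacing (cm);
    circumference: 2 pi r_a of the axon (cm); dt_pulse: single-pulse
    duration (s); kT: thermal energy at body temperature (erg);
    e_charge (esu).
    """

    mu: float = 1e-23
    hbar: float = 1e-27
    c_light: float = 1e10
    d: float = 1e-8
    circumference: float = 1e-3
    dt_pulse: float = 1e-3
    kT: float = 1e-14
    e_charge: float = 4.8e-10

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"constant {name} must be positive, got {v}")

    @property
    def axon_radius(self) -> float:
        return self.circumference / (2.0 * math.pi)


@dataclass(frozen=True)
class MemoryStrand:
    """Counts of a memory strand: Nc spins/circle, N0 charge units/pulse,
    Ns pulses, B0 field per unit charge (gauss)."""

    Nc: int = 100_000
    N0: int = 10
    Ns: int = 1000
    B0: float = 1e-9

    def __post_init__(self):
        if min(self.Nc, self.N0, self.Ns) < 1 or self.B0 <= 0:
            raise ValueError("all strand numbers must be positive")


@dataclass(frozen=True)
class Engram:
    """Loop-connected neuron assembly storing one memory (Ne = W - 1)."""

    W: int

    def __post_init__(self):
        if self.W < 1:
            raise ValueError("an engram requires W >= 1 (W=0 is short-term memory)")

    @property
    def Ne(self) -> int:
        return self.W - 1


@dataclass(frozen=True)
class SpinStructure:
    """Helical unit-modulus phase field over 0 <= z <= L."""

    kappa: float
    S_L: complex
    L: float

    def phase(self, z) -> np.ndarray | complex:
        z = np.asarray(z, dtype=float)
        out = np.exp(-1j * self.kappa * z) * self.S_L
        return complex(out) if out.ndim == 0 else out

    @property
    def pitch(self) -> float:
        """Helical pitch 2 pi / kappa."""
        return 2.0 * math.pi / self.kappa


def order_of_magnitude(x: float) -> int:
    """Nearest power of ten, for comparison with order-level estimates."""
    return int(round(math.log10(abs(x))))


def helical_field(Q: float, v: float, r: float, z,
                  consts: MemoryConstants | None = None) -> np.ndarray:
    """Helical field of a moving charge: magnitude Qv/(c r^2), CGS.

    Components (B cos(2 pi z / r), B sin(2 pi z / r), 0): the field is
    tangent to the tube and winds once per axial distance r.
    """
    consts = consts or MemoryConstants()
    if r <= 0:
        raise ValueError("tube radius must be positive")
    B = Q * v / (consts.c_light * r * r)
    z = np.asarray(z, dtype=float)
    ang = 2.0 * math.pi * z / r
    return np.stack([B * np.cos(ang), B * np.sin(ang), np.zeros_like(ang)], axis=-1)


def spins_per_circle(consts: MemoryConstants | None = None) -> int:
    """Nc = circumference / d, the spins aligned simultaneously."""
    consts = consts or MemoryConstants()
    return int(round(consts.circumference / consts.d))


def memory_frequency(strand: MemoryStrand,
                     consts: MemoryConstants | None = None) -> tuple[float, float]:
    """(omega, 2*omega): excitation frequencies of the strand and of the
    paired-spin secondary structure; omega = Nc mu N0 B0 / hbar (Hz)."""
    consts = consts or MemoryConstants()
    omega = strand.Nc * consts.mu * strand.N0 * strand.B0 / consts.hbar
    return omega, 2.0 * omega


def alignment_threshold(strand: MemoryStrand,
                        consts: MemoryConstants | None = None) -> tuple[float, bool]:
    """Alignment condition mu Bs dt > hbar, as a threshold on Ns*N0.

    threshold = hbar / (Nc mu B0 dt); spins align iff Ns*N0 exceeds it.
    With the default constants the threshold is 10^3: a single pulse
    cannot align spins unless it carries 10^3 charge units.
    """
    consts = consts or MemoryConstants()
    thr = consts.hbar / (strand.Nc * consts.mu * strand.B0 * consts.dt_pulse)
    return thr, bool(strand.Ns * strand.N0 > thr)


def spin_structure(strand: MemoryStrand, v: float, B: float, L: float,
                   S_L: complex = 1.0 + 0.0j,
                   consts: MemoryConstants | None = None) -> SpinStructure:
    """Helical spin structure S(z) = exp(-i kappa z) S_L, 0 <= z <= L,
    with kappa = Nc mu N0 B / (hbar v).  kappa * v equals the memory
    frequency when B = B0."""
    consts = consts or MemoryConstants()
    if v <= 0:
        raise ValueError("pulse speed must be positive")
    kappa = strand.Nc * consts.mu * strand.N0 * B / (consts.hbar * v)
    return SpinStructure(kappa=kappa, S_L=complex(S_L), L=L)


def thermal_stability(strand: MemoryStrand,
                      consts: MemoryConstants | None = None) -> tuple[float, bool]:
    """Spin-spin binding (Nc mu)^2 / d^3 vs thermal energy kT.

    Circles of Nc simultaneously aligned spins interact as units, which
    is what lifts the tiny single-proton moment to a binding (1e-12 erg
    at defaults) four decades above kT.
    """
    consts = consts or MemoryConstants()
    binding = (strand.Nc * consts.mu) ** 2 / consts.d**3
    return binding, bool(binding > consts.kT)


def mri_disruption(consts: MemoryConstants | None = None, B_mri: float = 3e4,
                   cluster: int = 1,
                   strand: MemoryStrand | None = None) -> tuple[float, bool]:
    """Zeeman energy cluster * mu * B of an imaging field vs the binding.

    Even at tens of kilogauss the disruption energy is many decades
    below the spin-spin binding: imaging cannot destroy memories.
    """
    consts = consts or MemoryConstants()
    if B_mri <= 0:
        raise ValueError("B_mri must be positive")
    strand = strand or MemoryStrand()
    disruption = cluster * consts.mu * B_mri
    binding, _ = thermal_stability(strand, consts)
    return disruption, bool(disruption > binding)


def engram_metrics(W: int, strand: MemoryStrand,
                   t_pulse: float | None = None,
                   consts: MemoryConstants | None = None) -> dict:
    """Size and creation time of an engram with spin topology number W.

    Ne = W - 1 neurons; strand time tau_s = Ns * t_pulse; engram time
    tau_e = W * tau_s.  W = 0 carries no loops and is flagged as a
    short-term (topologically unstable) memory instead.
    """
    consts = consts or MemoryConstants()
    t_pulse = consts.dt_pulse if t_pulse is None else t_pulse
    if W < 1:
        return {"short_term": True, "W": W}
    tau_s = strand.Ns * t_pulse
    return {
        "short_term": False,
        "W": W,
        "Ne": W - 1,
        "tau_strand_s": tau_s,
        "tau_engram_s": W * tau_s,
    }


def engram_firing_count(cluster_sizes) -> int:
    """Neurons firing when k memory classes activate: the product of the
    class cluster sizes."""
    sizes = [int(x) for x in cluster_sizes]
    if not sizes or min(sizes) < 1:
        raise ValueError("cluster sizes must be a non-empty positive sequence")
    return int(np.prod(sizes, dtype=object))


def memory_ledger(strand: MemoryStrand | None = None,
                  consts: MemoryConstants | None = None,
                  W: int = 5) -> dict:
    """Full stability/size/creation-time ledger in one call.

    Reproduces, from the constants alone, the row-level numbers of the
    stability table: field per pulse, spin-field interaction, alignment
    condition, excitation frequency, spin-spin binding vs kT, and the
    engram metrics for the supplied W.
    """
    consts = consts or MemoryConstants()
    strand = strand or MemoryStrand(Nc=spins_per_circle(consts))
    omega, omega2 = memory_frequency(strand, consts)
    thr, aligned = alignment_threshold(strand, consts)
    binding, stable = thermal_stability(strand, consts)
    interaction = strand.Ns * strand.Nc * strand.N0 * consts.mu * strand.B0
    return {
        "constants": {k: getattr(consts, k) for k in
                      ("mu", "hbar", "c_light", "d", "circumference",
                       "dt_pulse", "kT", "e_charge")},
        "Nc": strand.Nc,
        "N0": strand.N0,
        "Ns": strand.Ns,
        "field_per_pulse_gauss": strand.N0 * strand.B0,
        "spin_field_interaction_erg": interaction,
        "pulse_action_erg_s": interaction * consts.dt_pulse,
        "alignment_threshold_NsN0": thr,
        "aligned": aligned,
        "memory_frequency_hz": omega,
        "paired_frequency_hz": omega2,
        "binding_energy_erg": binding,
        "thermally_stable": stable,
        "kT_erg": consts.kT,
        "engram": engram_metrics(W, strand, consts=consts),
    }
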