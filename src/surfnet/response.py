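"""Modal EEG response and deep-sleep waveform synthesis.

The dihedral tiling modes are a complete orthonormal basis for the
sphere-surface wave equation (1/c^2) d2(phi)/dt2 = Laplacian(phi), so
the causal response to an input s(z', t') is the eigenfunction-expansion
Green's function

    G(z, t; z', t') = sum_n phi_n(z) phi_n(z') sin(omega_n (t - t')) / omega_n

with omega_n = sqrt((2n)^2 - 1/4).  Driving at a modal frequency makes
that mode's amplitude grow secularly while all others stay bounded --
the resonance-selectivity mechanism by which an oscillatory input
reproduces "its" EEG band, and by which memory structures are recalled.

The module also synthesizes the two stereotyped deep-sleep transients:
the K-complex (an antisymmetric pair of Gaussian-windowed cosine lobes
glued C1-continuously at the window boundary) and the sleep spindle
(a sin(t) sin(omega0 t) modulation at the memory excitation frequency,
with the paired-spin secondary structure at twice the frequency and
amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .tiling import (PLATONIC_BANDS, PLATONIC_TILE_COUNTS, TilingClass,
                     band_name, mode_eigenvalue, mode_profile)

__all__ = [
    "ModalBasis",
    "InputSignal",
    "KComplexParams",
    "SpindleParams",
    "ResponseField",
    "greens_function",
    "respond",
    "modal_amplitudes",
    "blocking_excitation",
    "kcomplex_waveform",
    "spindle_modulation",
    "spindle_threshold",
    "dendrite_twists_to_tiling",
]


@dataclass(frozen=True)
class ModalBasis:
    """The first n_max dihedral modes with their wave frequencies."""

    n_max: int

    def __post_init__(self):
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    @property
    def ns(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def omegas(self) -> np.ndarray:
        """sqrt of eigenvalues, strictly increasing."""
        return np.sqrt(np.array([mode_eigenvalue(int(n)) for n in self.ns]))

    def profiles(self, theta: np.ndarray) -> np.ndarray:
        """(n_max, len(theta)) orthonormal colatitude profiles."""
        return np.stack([mode_profile(int(n), theta) for n in self.ns])


@dataclass(frozen=True)
class InputSignal:
    """Localized input on the sphere arc.

    kind ``transient``: V0 delta(theta - theta0) exp(-a0 t);
    kind ``oscillatory``: V0 delta(theta - theta0) cos(omega0 t).
    The delta is mollified to a Gaussian of width ``mollifier_width``
    radians for quadrature; the spatial integral is conserved under
    width refinement.
    """

    kind: str
    theta0: float
    V0: float = 1.0
    a0: float = 1.0
    omega0: float = 1.0
    window: tuple[float, float] = (0.0, math.inf)
    mollifier_width: float = 0.01

    def __post_init__(self):
        if self.kind not in ("transient", "oscillatory"):
            raise ValueError("kind must be 'transient' or 'oscillatory'")

    def spatial(self, theta: np.ndarray) -> np.ndarray:
        w = self.mollifier_width
        prof = np.exp(-0.5 * ((theta - self.theta0) / w) ** 2) / (w * math.sqrt(2 * math.pi))
        return prof / np.sin(np.clip(theta, 1e-12, None))  # delta over the sin(theta) measure

    def temporal(self, t: np.ndarray) -> np.ndarray:
        t0, t1 = self.window
        gate = (t >= t0) & (t <= t1)
        if self.kind == "transient":
            return self.V0 * np.exp(-self.a0 * np.clip(t - t0, 0, None)) * gate
        return self.V0 * np.cos(self.omega0 * (t - t0)) * gate


@dataclass(frozen=True)
class ResponseField:
    """m(theta, t) on a grid, plus per-mode amplitude histories."""

    theta: np.ndarray
    t: np.ndarray
    values: np.ndarray          # (len(t), len(theta))
    modal: np.ndarray           # (n_max, len(t)) modal coefficients
    basis: ModalBasis


def greens_function(basis: ModalBasis, theta: float, t: float,
                    theta_p: float, t_p: float) -> float:
    """Causal modal Green's function; zero for t < t', symmetric in
    (theta <-> theta')."""
    if t < t_p:
        return 0.0
    om = basis.omegas
    ph = np.array([mode_profile(int(n), theta) for n in basis.ns])
    ph_p = np.array([mode_profile(int(n), theta_p) for n in basis.ns])
    return float(np.sum(ph * ph_p * np.sin(om * (t - t_p)) / om))


def respond(basis: ModalBasis, inp: InputSignal, t_final: float,
            n_theta: int = 400, dt: Optional[float] = None) -> ResponseField:
    """Quadrature of m = integral G s over the arc and past times.

    Projects the input on the modal basis (trapezoid in theta with the
    sin(theta) measure), convolves each mode with its causal oscillator
    kernel sin(omega_n (t - t'))/omega_n (trapezoid in t', step at most
    one twentieth of the fastest period), and resums the field.
    Linear in the input amplitude; identically zero before the input
    window opens.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    theta = np.linspace(0.0, math.pi, n_theta + 2)[1:-1]
    om = basis.omegas
    if dt is None:
        dt = (2.0 * math.pi / om[-1]) / 20.0
    t = np.arange(0.0, t_final + dt / 2, dt)
    profiles = basis.profiles(theta)                    # (N, n_theta)
    s_theta = inp.spatial(theta)                        # mollified delta
    w_theta = np.sin(theta)
    s_n = np.trapezoid(profiles * s_theta * w_theta, theta, axis=1)  # (N,)
    s_t = inp.temporal(t)                               # (n_t,)
    modal = np.zeros((basis.n_max, t.size))
    for k, omega in enumerate(om):
        kern = np.sin(omega * t) / omega
        # causal convolution integral_0^t kern(t - t') s(t') dt'
        conv = np.convolve(kern, s_t)[: t.size] * dt
        # trapezoid end-correction
        conv -= 0.5 * dt * (kern * s_t[0] + np.sin(omega * 0.0) / omega * s_t)
        modal[k] = s_n[k] * conv
    values = modal.T @ profiles
    return ResponseField(theta=theta, t=t, values=values, modal=modal, basis=basis)


def modal_amplitudes(fieldr: ResponseField, t_min: float = 0.0) -> np.ndarray:
    """Peak |coefficient| of each mode over t >= t_min."""
    sel = fieldr.t >= t_min
    return np.max(np.abs(fieldr.modal[:, sel]), axis=1)


def blocking_excitation(t, theta, phi, theta0: float, phi0: float,
                        omega_n: float, alpha: float, delta: float = 0.1,
                        mollifier_width: float = 0.01) -> np.ndarray:
    """Blocking input: a Gaussian-enveloped transient at (theta0, phi0)
    minus a finite-window term at the shifted site (theta0+Delta,
    phi0+Delta).

    psi = delta2(theta-theta0, phi-phi0) exp(-(omega_n t)^2) H(t)
          - [H(t) - H(t - 1/alpha)] delta2(theta-theta1, phi-phi1)

    with point masses mollified to 2-D Gaussians of width
    ``mollifier_width`` whose spatial integral is width-independent.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    w = mollifier_width

    def moll(th0, ph0):
        return (np.exp(-0.5 * (((theta - th0) / w) ** 2 + ((phi - ph0) / w) ** 2))
                / (2 * math.pi * w * w))

    heav = (t > 0).astype(float)
    gate = heav - (t > 1.0 / alpha).astype(float)
    first = moll(theta0, phi0) * np.exp(-((omega_n * t) ** 2)) * heav
    second = gate * moll(theta0 + delta, phi0 + delta)
    return first - second


@dataclass(frozen=True)
class KComplexParams:
    """Amplitude scale A, mode index n, half-window T and taper half-width."""

    A: float = 1.0
    n: int = 1
    T: float = 5.0
    glue_eps_frac: float = 0.05

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def omega_n(self) -> float:
        return math.sqrt(mode_eigenvalue(self.n))


def kcomplex_waveform(p: KComplexParams, t) -> np.ndarray:
    """Biphasic K-complex: two opposite Gaussian-windowed cosine lobes.

    M1 = -(A/n) exp(-(w t)^2) cos(w t) on (-T, T);
    M2 = +(A/n) exp(-(w (t-2T))^2) cos(w t) on (T, 3T);
    blended by a C1 cosine taper on (T - eps, T + eps), eps = 0.05 T,
    and zero outside (-T, 3T).
    """
    t = np.asarray(t, dtype=float)
    w = p.omega_n
    amp = p.A / p.n
    m1 = -amp * np.exp(-((w * t) ** 2)) * np.cos(w * t)
    m2 = amp * np.exp(-((w * (t - 2 * p.T)) ** 2)) * np.cos(w * t)
    eps = p.glue_eps_frac * p.T
    x = np.clip((t - (p.T - eps)) / (2 * eps), 0.0, 1.0)
    s = 0.5 * (1.0 - np.cos(math.pi * x))  # C1 smoothstep: s'(0)=s'(1)=0
    out = (1.0 - s) * m1 + s * m2
    out = np.where((t <= -p.T) | (t >= 3 * p.T), 0.0, out)
    return out


@dataclass(frozen=True)
class SpindleParams:
    """Spindle drive: cluster size Ns, Zeeman product mu*B (erg), memory
    frequency omega0 (rad/s) and duration T (s)."""

    Ns: int = 1000
    mu_B_product: float = 1e-23 * 1e-9
    omega0: float = 12.0
    T: float = 6.0
    e_charge: float = 4.8e-10

    def __post_init__(self):
        if self.T <= 0 or self.omega0 <= 0 or self.Ns < 1:
            raise ValueError("invalid spindle parameters")


def spindle_modulation(p: SpindleParams, t) -> tuple[np.ndarray, np.ndarray]:
    """(dV, dV2): spindle modulations of the slow wave.

    dV  = Ns (mu B / e) sin(t) sin(omega0 t) on [0, T];
    dV2 = the paired-spin secondary structure, same envelope at doubled
    frequency and doubled amplitude.  The unit-frequency sin(t) envelope
    is the delta waveform carrier (omega1 ~ 1 on this scale).  Zero
    outside [0, T].
    """
    t = np.asarray(t, dtype=float)
    gate = (t >= 0.0) & (t <= p.T)
    amp = p.Ns * p.mu_B_product / p.e_charge
    dv = amp * np.sin(t) * np.sin(p.omega0 * t) * gate
    dv2 = 2.0 * amp * np.sin(t) * np.sin(2.0 * p.omega0 * t) * gate
    return dv, dv2


def spindle_threshold(electron_energy: float, N: int, omega0: float,
                      hbar: float = 1e-27) -> bool:
    """True iff the electron drive energy exceeds the memory excitation
    barrier N * hbar * omega0 (strict)."""
    if min(electron_energy, N, omega0, hbar) <= 0:
        raise ValueError("all inputs must be positive")
    return electron_energy > N * hbar * omega0


def dendrite_twists_to_tiling(w1: int, w2: int, w3: int) -> Optional[TilingClass]:
    """Map three dendrite spin topology numbers to the tiling they select.

    (2, 2, 2n) fixes a dihedral tiling of frequency 2n; (2, 3, 3),
    (2, 3, 4), (2, 3, 5) patterns select the tetrahedral, octahedral
    and icosahedral classes.  Anything else fixes no tiling.
    """
    if min(w1, w2, w3) < 1:
        raise ValueError("spin topology numbers must be positive")
    trip = tuple(sorted((w1, w2, w3)))
    platonic = {(2, 3, 3): "tetrahedron", (2, 3, 4): "octahedron",
                (2, 3, 5): "icosahedron"}
    if trip in platonic:
        name = platonic[trip]
        count = PLATONIC_TILE_COUNTS[name]
        return TilingClass(name, count, float(count), round(200.0 / count),
                           PLATONIC_BANDS[name])
    if trip[0] == 2 and trip[1] == 2 and trip[2] >= 2:
        count = trip[2]  # (2, 2, 2n) -> dihedral with 2n tiles, frequency 2n
        return TilingClass("dihedral", count, float(count), round(200.0 / count),
                           band_name(count))
    return None
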