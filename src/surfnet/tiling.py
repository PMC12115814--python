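"""Schwarz tilings of the sphere and the EEG band table they predict.

A spherical triangle with angles (pi/p, pi/q, pi/r) tiles the sphere
iff 1/p + 1/q + 1/r > 1.  Besides the dihedral family (2, 2, n) there
are exactly three such triples, tied to the Platonic solids.  Because a
tiling waveform is confined to one tile, its amplitude is proportional
to the tile area and its frequency to the tile count: the inverse
amplitude-frequency law ``a_N * nu_N = const`` that maps tilings onto
the five EEG bands (delta through gamma).

The dihedral tiling waveforms are fractional-degree associated Legendre
modes with degree nu = 2n - 1/2 and order mu = -1/2, eigenvalue
lam = nu*(nu+1) = (2n)^2 - 1/4.  For |mu| = 1/2 they have elementary
trigonometric closed forms; general (nu, mu) is evaluated through the
Gauss hypergeometric representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, special

__all__ = [
    "SchwarzTriple",
    "TilingClass",
    "FractionalMode",
    "SphericalPoint",
    "enumerate_schwarz_triples",
    "spherical_triangle_area",
    "hypergeometric_params",
    "platonic_tiling_table",
    "mode_eigenvalue",
    "fractional_legendre",
    "fractional_harmonic",
    "tiling_solution",
    "norm_P",
    "norm_closed_form",
    "norm_report",
    "mode_profile",
    "PLATONIC_TILE_COUNTS",
]

#: tile counts of the symmetric sphere tilings used for band prediction
PLATONIC_TILE_COUNTS = {
    "sphere": 1,
    "tetrahedron": 4,
    "cube": 6,
    "octahedron": 8,
    "dodecahedron": 12,
    "icosahedron": 20,
}

#: EEG band attributed to each symmetric tiling (delta-scaled frequencies
#: compared against the observed band edges, which straddle some rows)
PLATONIC_BANDS = {
    "sphere": "delta",
    "tetrahedron": "theta",
    "cube": "alpha",
    "octahedron": "alpha",
    "dodecahedron": "beta",
    "icosahedron": "beta",
}

#: EEG band name by frequency in the Table-1 (delta == 1) scale
_BANDS = (
    (0.5, 3.0, "delta"),
    (3.0, 8.0, "theta"),
    (8.0, 13.0, "alpha"),
    (13.0, 30.0, "beta"),
    (30.0, math.inf, "gamma"),
)


def band_name(frequency: float) -> str:
    for lo, hi, name in _BANDS:
        if lo <= frequency < hi:
            return name
    return "sub-delta"


@dataclass(frozen=True)
class SchwarzTriple:
    """Integer triangle angles (pi/p, pi/q, pi/r) with angle excess."""

    p: int
    q: int
    r: int

    def __post_init__(self):
        if min(self.p, self.q, self.r) < 2:
            raise ValueError("p, q, r must all be >= 2")
        if self.excess <= 0:
            raise ValueError(f"({self.p},{self.q},{self.r}) does not tile the sphere")

    @property
    def excess(self) -> float:
        return 1.0 / self.p + 1.0 / self.q + 1.0 / self.r - 1.0

    @property
    def is_dihedral(self) -> bool:
        return sorted((self.p, self.q, self.r))[:2] == [2, 2]


@dataclass(frozen=True)
class TilingClass:
    """One row of the tiling band table."""

    name: str
    tile_count: int
    frequency: float
    amplitude: float  # microvolt
    band: str


@dataclass(frozen=True)
class FractionalMode:
    """Dihedral tiling mode n: degree 2n-1/2, order -1/2."""

    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("mode index n must be >= 1")

    @property
    def nu(self) -> float:
        return 2 * self.n - 0.5

    @property
    def mu(self) -> float:
        return -0.5

    @property
    def eigenvalue(self) -> float:
        return mode_eigenvalue(self.n)

    @property
    def omega(self) -> float:
        """Wave-equation angular frequency sqrt(eigenvalue)."""
        return math.sqrt(self.eigenvalue)


@dataclass(frozen=True)
class SphericalPoint:
    """Colatitude/azimuth point with the primed (tile) coordinates.

    theta is measured from the north pole in [0, pi]; phi in (-pi, pi].
    The primed chart used by the tiling solutions is theta' = theta/2,
    phi' = phi/(2n).
    """

    theta: float
    phi: float

    def __post_init__(self):
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError("theta must lie in [0, pi]")
        if not -math.pi < self.phi <= math.pi + 1e-12:
            raise ValueError("phi must lie in (-pi, pi]")

    @property
    def theta_primed(self) -> float:
        return self.theta / 2.0

    def phi_primed(self, n: int) -> float:
        return self.phi / (2 * n)


def enumerate_schwarz_triples(r_max: int) -> list[SchwarzTriple]:
    """All triples p <= q <= r <= r_max with 1/p + 1/q + 1/r > 1.

    The dihedral family (2, 2, n) appears for every n <= r_max; beyond
    it only (2,3,3), (2,3,4) and (2,3,5) survive the strict inequality.
    """
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    out = []
    for p in range(2, r_max + 1):
        for q in range(p, r_max + 1):
            for r in range(q, r_max + 1):
                if 1 / p + 1 / q + 1 / r > 1.0:
                    out.append(SchwarzTriple(p, q, r))
    return out


def spherical_triangle_area(alpha: float, beta: float, gamma: float, R: float = 1.0) -> float:
    """Area R^2 * (alpha + beta + gamma - pi) of a spherical triangle."""
    excess = alpha + beta + gamma - math.pi
    if excess <= 0:
        raise ValueError("angle sum must exceed pi on the sphere")
    return R * R * excess


def hypergeometric_params(triple: SchwarzTriple) -> tuple[float, float, float]:
    """Hypergeometric (a, b, c) whose index differences give the tile angles.

    Solves |1-c| = 1/p, |c-a-b| = 1/q, |a-b| = 1/r on the branch
    c = 1 - 1/p, c - a - b = 1/q, a - b = 1/r with a >= b.  Any branch
    reproduces the same angle multiset.
    """
    c = 1.0 - 1.0 / triple.p
    s = c - 1.0 / triple.q  # a + b
    d = 1.0 / triple.r      # a - b
    a = (s + d) / 2.0
    b = (s - d) / 2.0
    return a, b, c


def platonic_tiling_table(
    base_frequency: float = 1.0,
    base_amplitude: float = 200.0,
    dihedral_n: Optional[int] = 20,
) -> list[TilingClass]:
    """Band table: frequency = tile count, amplitude = base / tile count.

    The scale is fixed by assigning the uniform sphere excitation
    (delta) frequency ``base_frequency`` and amplitude ``base_amplitude``
    microvolts; amplitudes are rounded to the nearest microvolt, which
    reproduces the printed 33 (= 200/6) and 17 (~ 200/12).  If
    ``dihedral_n`` is given, a dihedral row with 2n tiles is appended.
    """
    if base_frequency <= 0 or base_amplitude <= 0:
        raise ValueError("scales must be positive")
    rows = []
    for name, count in PLATONIC_TILE_COUNTS.items():
        freq = count * base_frequency
        amp = round(base_amplitude / count)
        rows.append(TilingClass(name, count, freq, amp, PLATONIC_BANDS[name]))
    if dihedral_n is not None:
        count = 2 * dihedral_n
        freq = count * base_frequency
        rows.append(
            TilingClass("dihedral", count, freq, round(base_amplitude / count), band_name(freq))
        )
    return rows


def mode_eigenvalue(n: int) -> float:
    """Laplacian eigenvalue (2n)^2 - 1/4 = nu*(nu+1), nu = 2n - 1/2."""
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    return (2 * n) ** 2 - 0.25


def fractional_legendre(nu: float, mu: float, x) -> np.ndarray | float:
    """Associated Legendre function P_nu^mu(x) of fractional degree on (-1, 1).

    For mu = +-1/2 the elementary closed forms are used:

        P_nu^{ 1/2}(cos t) = sqrt(2/(pi sin t)) * cos((nu+1/2) t)
        P_nu^{-1/2}(cos t) = sqrt(2/(pi sin t)) * sin((nu+1/2) t) / (nu+1/2)

    otherwise the Gauss hypergeometric representation
    P_nu^mu(x) = ((1+x)/(1-x))^(mu/2) / Gamma(1-mu)
                 * 2F1(-nu, nu+1; 1-mu; (1-x)/2).
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= 1.0):
        raise ValueError("x must lie strictly inside (-1, 1)")
    if mu in (0.5, -0.5):
        t = np.arccos(x)
        pref = np.sqrt(2.0 / (np.pi * np.sin(t)))
        k = nu + 0.5
        if mu == 0.5:
            val = pref * np.cos(k * t)
        else:
            val = pref * np.sin(k * t) / k
    else:
        val = (
            ((1.0 + x) / (1.0 - x)) ** (mu / 2.0)
            / special.gamma(1.0 - mu)
            * special.hyp2f1(-nu, nu + 1.0, 1.0 - mu, (1.0 - x) / 2.0)
        )
    if val.ndim == 0:
        return float(val)
    return val


def mode_profile(n: int, theta) -> np.ndarray | float:
    """Normalized colatitude profile of the n-th dihedral mode.

    phi_n(theta) = sqrt(2/pi) * sin(2n theta)/sqrt(sin theta), the
    closed-form eigenfunction of the associated Legendre operator with
    mu^2 = 1/4 at eigenvalue (2n)^2 - 1/4; orthonormal under
    integral_0^pi phi_n phi_m sin(theta) d(theta) = delta_nm.
    """
    theta = np.asarray(theta, dtype=float)
    return np.sqrt(2.0 / np.pi) * np.sin(2 * n * theta) / np.sqrt(np.sin(theta))


def norm_P(n: int, num_points: int = 4001) -> float:
    """Quadrature L2 norm (squared) of the unnormalized mode n on the sphere.

    Integrates |Y|^2 over the sphere for the unnormalized harmonic
    (8 pi sin theta)^(-1/2) e^(-i phi/2) cos((2n - 1/2) theta) using
    composite Simpson quadrature in theta and the exact 2*pi azimuthal
    factor.  The printed Gamma-function closed form is reported by
    :func:`norm_report`, never asserted.
    """
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    theta = np.linspace(0.0, np.pi, num_points)
    integrand = np.cos((2 * n - 0.5) * theta) ** 2 / (8.0 * np.pi)
    return float(2.0 * np.pi * integrate.simpson(integrand, x=theta))


def norm_closed_form(n: int) -> float:
    """Printed Gamma-factor expression for the mode norm (reported only).

    The grouping of the printed factors is ambiguous; the reading
    2*pi*Gamma(3/4)*Gamma(5/4)*(4n+2)/((2n+1/2)(2n+3/4)) is evaluated
    for comparison.
    """
    return float(
        2.0
        * np.pi
        * special.gamma(0.75)
        * special.gamma(1.25)
        * (4 * n + 2)
        / ((2 * n + 0.5) * (2 * n + 0.75))
    )


def norm_report(n: int) -> dict:
    """Quadrature norm, printed closed form and their relative discrepancy."""
    q = norm_P(n)
    cf = norm_closed_form(n)
    return {
        "n": n,
        "quadrature": q,
        "closed_form": cf,
        "relative_discrepancy": abs(q - cf) / abs(cf),
    }


def fractional_harmonic(n: int, pt: SphericalPoint) -> complex:
    """Fractional spherical harmonic of mode n at a sphere point.

    Y_n(theta, phi) = N(n) e^(-i phi/2) (8 pi sin theta)^(-1/2)
                      cos((2n - 1/2) theta),
    with N(n) = norm_P(n)^(-1/2) so the harmonic has unit L2 norm on
    the sphere.  Singular at the poles.
    """
    if not 0.0 < pt.theta < math.pi:
        raise ValueError("theta must lie strictly inside (0, pi) (pole singularity)")
    N = norm_P(n) ** -0.5
    return (
        N
        * np.exp(-0.5j * pt.phi)
        / math.sqrt(8.0 * math.pi * math.sin(pt.theta))
        * math.cos((2 * n - 0.5) * pt.theta)
    )


def tiling_solution(n: int, theta_primed: float, phi_primed: float) -> float:
    """Dihedral tiling waveform on the primed tile chart.

    S(theta', phi') = (1/n) cos(n phi') cos((4n-1) theta') / sqrt(sin 2 theta')

    vanishing on all three sides of the fundamental spherical triangle:
    the meridians phi' = +-pi/(2n) (cosine zero) and the latitude
    theta' = pi/2, where the cosine zero is linear while the weight
    diverges only like (pi/2 - theta')^(-1/2); the product tends to 0
    and the boundary value is the continuous extension.
    """
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    if not 0.0 < theta_primed <= math.pi / 2 + 1e-12:
        raise ValueError("theta' must lie in (0, pi/2]")
    lim = math.pi / (2 * n)
    if not -lim - 1e-12 <= phi_primed <= lim + 1e-12:
        raise ValueError(f"phi' must lie in [-pi/{2*n}, pi/{2*n}]")
    s2 = math.sin(2.0 * theta_primed)
    if s2 <= 1e-15:  # boundary theta' = pi/2: limit value 0
        return 0.0
    return (
        (1.0 / n)
        * math.cos(n * phi_primed)
        * math.cos((4 * n - 1) * theta_primed)
        / math.sqrt(s2)
    )
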