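"""Riemann-surface bookkeeping: theta functions with characteristics,
spin topology numbers, period matrices and pinch-expansion coefficients.

The surface network idealizes the axon connectome as a hyperelliptic
Riemann surface of genus ``g``.  Its spin structure is encoded by
half-integer characteristics ``(alpha_i, beta_i)`` attached to the 2g
homology loops; the integer ``W = 4 sum_i alpha_i beta_i`` (the spin
topology number) controls the parity of the associated theta function
and, downstream, the size of memory engrams.  Pinch deformations --
shrinking a handle loop to a point -- are parameterized by the Taylor
coefficients of the holomorphic one-forms ``z**(j-1)/sqrt(P(z))`` about
the pinch point; these coefficients are the model's elementary signal
parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "Characteristics",
    "PeriodMatrix",
    "ThetaArgs",
    "HyperellipticCurve",
    "spin_topology_number",
    "characteristic_parity",
    "reduce_characteristic",
    "validate_period_matrix",
    "theta_with_characteristics",
    "one_form",
    "pinch_expansion",
]

_HALF_VALUES = (0.0, 0.5)


@dataclass(frozen=True)
class Characteristics:
    """Half-integer theta characteristics ``(alpha, beta)`` of genus ``g``.

    Every entry is 0 or 1/2; ``alpha_i`` labels the handle loop ``a_i``
    and ``beta_i`` the dual loop ``b_i``.
    """

    alpha: tuple[float, ...]
    beta: tuple[float, ...]

    def __init__(self, alpha: Sequence[float], beta: Sequence[float]):
        alpha = tuple(float(a) for a in alpha)
        beta = tuple(float(b) for b in beta)
        if len(alpha) != len(beta) or not alpha:
            raise ValueError("alpha and beta must be non-empty and of equal length")
        for v in alpha + beta:
            if v not in _HALF_VALUES:
                raise ValueError(f"characteristic entries must be 0 or 1/2, got {v}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def g(self) -> int:
        return len(self.alpha)

    def concat(self, other: "Characteristics") -> "Characteristics":
        """Block-concatenate two characteristic sets (genus adds)."""
        return Characteristics(self.alpha + other.alpha, self.beta + other.beta)


def reduce_characteristic(n: int, value: float) -> float:
    """Multiply a half-integer label by an integer loop count ``n``.

    Traversing a loop ``n`` times multiplies its label; because the
    labels live on a double cover the product is reduced mod 1, so even
    ``n`` annihilates the label and odd ``n`` preserves it.
    """
    return float(Fraction(n) * Fraction(value).limit_denominator(2) % 1)


def spin_topology_number(chars: Characteristics) -> int:
    """W = 4 * sum_i alpha_i * beta_i; a non-negative integer."""
    w = 4.0 * sum(a * b for a, b in zip(chars.alpha, chars.beta))
    w_int = int(round(w))
    assert abs(w - w_int) < 1e-12
    return w_int


def characteristic_parity(chars: Characteristics) -> str:
    """``"even"`` or ``"odd"`` according to the sign of exp(i*pi*W)."""
    return "even" if spin_topology_number(chars) % 2 == 0 else "odd"


@dataclass(frozen=True)
class PeriodMatrix:
    """Complex symmetric g x g period matrix with Im(Omega) > 0."""

    omega: np.ndarray

    def __init__(self, omega):
        omega = np.asarray(omega, dtype=complex)
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
            raise ValueError(f"period matrix must be square, got shape {omega.shape}")
        object.__setattr__(self, "omega", omega)

    @property
    def g(self) -> int:
        return self.omega.shape[0]


def validate_period_matrix(pm: PeriodMatrix, tol: float = 1e-10) -> bool:
    """True iff Omega is symmetric to ``tol`` and Im(Omega) is positive definite.

    Positive definiteness of the imaginary part is the convergence
    condition for the theta series (entrywise positivity would not be
    sufficient).
    """
    om = pm.omega
    if np.max(np.abs(om - om.T)) > tol:
        return False
    eigs = np.linalg.eigvalsh(om.imag)
    return bool(eigs.min() > 0.0)


@dataclass(frozen=True)
class ThetaArgs:
    """Argument vector z and lattice truncation radius for a theta sum."""

    z: tuple[complex, ...]
    truncation_radius: int = 10

    def __init__(self, z: Sequence[complex], truncation_radius: int = 10):
        z = tuple(complex(v) for v in np.atleast_1d(np.asarray(z, dtype=complex)))
        if truncation_radius < 1:
            raise ValueError("truncation_radius must be >= 1")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "truncation_radius", int(truncation_radius))

    @property
    def g(self) -> int:
        return len(self.z)


def theta_with_characteristics(
    args: ThetaArgs, pm: PeriodMatrix, chars: Characteristics
) -> complex:
    """Truncated Riemann theta sum with half-integer characteristics.

    Theta = sum_n exp[i*pi*(n+alpha)^T Omega (n+alpha)
                      + 2*i*pi*(z+beta)^T (n+alpha)]
    over integer vectors with each |n_i| <= truncation_radius.  The
    neglected tail is bounded by the Gaussian decay exp(-pi*lam*R^2)
    with ``lam`` the smallest eigenvalue of Im(Omega); R=10 leaves a
    tail far below double precision for lam >= 0.1.
    """
    if not validate_period_matrix(pm):
        raise ValueError("invalid period matrix (must be symmetric with Im > 0)")
    g = pm.g
    if args.g != g or chars.g != g:
        raise ValueError("genus mismatch between z, Omega and characteristics")
    R = args.truncation_radius
    alpha = np.asarray(chars.alpha)
    beta = np.asarray(chars.beta)
    z = np.asarray(args.z)
    grid = np.array(list(itertools.product(range(-R, R + 1), repeat=g)), dtype=float)
    na = grid + alpha  # (M, g)
    quad = np.einsum("mi,ij,mj->m", na, pm.omega, na)
    lin = na @ (z + beta)
    return complex(np.sum(np.exp(1j * np.pi * quad + 2j * np.pi * lin)))


@dataclass(frozen=True)
class HyperellipticCurve:
    """Curve w^2 = P(z) = prod_i (z - x_i) with 2g+2 roots.

    Roots must be real or occur in complex-conjugate pairs (the curve
    has real coefficients), checked to ``tol``.
    """

    roots: tuple[complex, ...]
    tol: float = field(default=1e-9, compare=False)

    def __init__(self, roots: Sequence[complex], tol: float = 1e-9):
        roots = tuple(complex(r) for r in roots)
        if len(roots) < 4 or len(roots) % 2:
            raise ValueError("need 2g+2 roots with g >= 1")
        unmatched = [r for r in roots if abs(r.imag) > tol]
        pool = list(unmatched)
        for r in unmatched:
            if r not in pool:
                continue
            mate = next((s for s in pool if s is not r and abs(s - r.conjugate()) < tol), None)
            if mate is None:
                raise ValueError(f"complex root {r} lacks a conjugate partner")
            pool.remove(r)
            pool.remove(mate)
        object.__setattr__(self, "roots", roots)
        object.__setattr__(self, "tol", tol)

    @property
    def g(self) -> int:
        return len(self.roots) // 2 - 1

    def P(self, z: complex) -> complex:
        return complex(np.prod([z - r for r in self.roots]))


def one_form(curve: HyperellipticCurve, j: int, z: complex) -> complex:
    """Evaluate the j-th holomorphic one-form density z^(j-1)/sqrt(P(z)).

    The square root uses the principal branch (branch cut along the
    negative real axis of P(z)); continuity along a path is the caller's
    concern and is documented rather than enforced.
    """
    if not 1 <= j <= curve.g:
        raise ValueError(f"j must be in 1..g={curve.g}, got {j}")
    pz = curve.P(z)
    if abs(pz) < 1e-300:
        raise ZeroDivisionError(f"z={z} is a branch point of the curve")
    return complex(z) ** (j - 1) / np.sqrt(complex(pz))


def pinch_expansion(curve: HyperellipticCurve, j: int, order: int) -> np.ndarray:
    """Taylor coefficients of the one-form about the pinch point z=0.

    These coefficients are the pinch/distortion parameters of the model:
    a pinch deformation is encoded by how the one-forms behave at the
    shrinking loop.  Requires P(0) != 0.  Returns coefficients c_0..c_order
    of z^(j-1) * P(z)^(-1/2).
    """
    if not 1 <= j <= curve.g:
        raise ValueError(f"j must be in 1..g={curve.g}, got {j}")
    if order < 0:
        raise ValueError("order must be >= 0")
    if abs(curve.P(0.0)) < 1e-300:
        raise ZeroDivisionError("P(0)=0: the pinch point is a branch point")
    n = order + 1
    # Taylor coefficients of P about 0 (monomial expansion of the product).
    p = np.zeros(n, dtype=complex)
    acc = np.zeros(n, dtype=complex)
    acc[0] = 1.0
    for r in curve.roots:
        new = np.zeros(n, dtype=complex)
        new[: n] += -r * acc
        new[1:] += acc[:-1]
        acc = new
    p[:] = acc
    # Series inverse square root h = p^(-1/2) from p*h' = -(1/2) p' h.
    h = np.zeros(n, dtype=complex)
    h[0] = 1.0 / np.sqrt(p[0])
    for k in range(1, n):
        # coefficient of z^(k-1) in p*h' equals that in -(1/2) p'*h
        lhs = sum(p[m] * (k - m) * h[k - m] for m in range(1, k))
        rhs = -0.5 * sum((m + 1) * p[m + 1] * h[k - 1 - m] for m in range(k))
        h[k] = (rhs - lhs) / (k * p[0])
    # multiply by z^(j-1): shift
    out = np.zeros(n, dtype=complex)
    out[j - 1:] = h[: n - (j - 1)]
    return out
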