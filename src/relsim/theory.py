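"""Closed-form inter-crossover / IBD segment length densities.

For two relatives whose common ancestor lived ``T`` generations ago (2T
meioses on the connecting path) the boundaries of shared segments are
crossovers from the superposition of the 2T meioses.  Under a sex-averaged
map with Housworth-Stahl interference the component processes are, per
meiosis, a free Poisson process of rate ``p`` and a gamma(nu, 2*nu*(1-p))
chiasma renewal thinned by 1/2.  The quantities below are (with
``beta = 2*(1-p)*nu`` and all distances in Morgans):

* ``f_reg(x)``  - density of the distance between regulated crossovers,
  a geometric mixture of gamma(k*nu, beta) densities (k chiasmata skipped
  with probability 2**-k);
* ``g_reg(x)``  - density of the distance from a random site to the next
  regulated crossover (stationary renewal forward recurrence time),
  ``(1-p) * (1 - F_reg(x))``;
* ``G_tilde(x)``- upper tail of ``g_reg``;
* ``h(x)``      - density of the distance from a random site to the next
  crossover of any type across the 2T meioses;
* ``phi(x)``    - density of a randomly chosen inter-crossover interval,
  ``-(1/2T) dh/dx`` (Cox & Smith superposition result), with mean 1/(2T);
* ``phi_finite``- the finite-chromosome correction of ``phi`` on [0, L],
  a continuous part plus a point mass at ``x = L`` (a segment spanning the
  whole chromosome).

The sex-specific Poisson counterpart works on the physical axis: given
``n_f`` female and ``2T - n_f`` male transmissions the crossover process is
inhomogeneous Poisson with rate ``lam(x) = lam_f(x)*n_f + lam_m(x)*n_m``
per bp, and the inter-event density follows the standard renewal identity
for inhomogeneous Poisson processes.  Rates are piecewise constant on a
regular grid and integrals become sums over that grid.

Series are truncated at ``k_max`` terms (default 50); the neglected mass is
bounded by ``2**-k_max``.  Incomplete-gamma ratios use the regularized
functions to avoid overflow at large ``k*nu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy.stats import binom

__all__ = [
    "TheorySpec",
    "SSPoissonSpec",
    "f_reg",
    "g_reg",
    "G_tilde",
    "h",
    "phi",
    "phi_poisson",
    "phi_finite",
    "phi_finite_atom",
    "phi_finite_poisson",
    "phi_finite_poisson_atom",
    "ss_poisson_interdensity",
    "ss_poisson_mixture",
    "ss_spec_from_map",
    "meiosis_count_weights",
]


@dataclass(frozen=True)
class TheorySpec:
    """Parameter bundle: generations to the common ancestor ``T`` (2T
    meioses), interference shape ``nu``, escape fraction ``p``, optional
    chromosome length ``L`` in Morgans, series truncation ``k_max``."""

    T: int
    nu: float = 1.0
    p: float = 0.0
    L: float | None = None
    k_max: int = 50

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not self.nu > 0:
            raise ValueError("nu must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.L is not None and not self.L > 0:
            raise ValueError("L must be > 0")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


def _check_regulated(spec: TheorySpec) -> None:
    if spec.p >= 1.0:
        raise ValueError("p = 1 leaves no regulated process; densities are undefined")


def _kgrid(spec: TheorySpec) -> np.ndarray:
    return np.arange(1, spec.k_max + 1, dtype=float)


def f_reg(x, spec: TheorySpec):
    """Density of the distance between regulated crossovers."""
    _check_regulated(spec)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xa < 0):
        raise ValueError("x must be >= 0")
    beta = 2.0 * (1.0 - spec.p) * spec.nu
    k = _kgrid(spec)[:, None]
    a = k * spec.nu
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.where(xa > 0, np.log(np.where(xa > 0, xa, 1.0)), -np.inf)
        logterm = (
            -k * np.log(2.0)
            + (a - 1.0) * logx
            - beta * xa
            + a * np.log(beta)
            - special.gammaln(a)
        )
    terms = np.exp(logterm)
    # x == 0: the k=1 term is beta/2 when nu == 1, diverges for nu < 1, 0 for nu > 1
    if np.any(xa == 0):
        at0 = np.zeros(spec.k_max)
        if spec.nu == 1.0:
            at0[0] = beta / 2.0
        elif spec.nu < 1.0:
            at0[0] = np.inf
        terms[:, xa == 0] = at0[:, None]
    out = terms.sum(axis=0)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def g_reg(x, spec: TheorySpec):
    """Density of the distance from a random site to the next regulated
    crossover; ``g_reg(0) = 1 - p``."""
    _check_regulated(spec)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xa < 0):
        raise ValueError("x must be >= 0")
    beta = 2.0 * (1.0 - spec.p) * spec.nu
    k = _kgrid(spec)[:, None]
    a = k * spec.nu
    out = (1.0 - spec.p) * np.sum(2.0**-k * special.gammaincc(a, beta * xa), axis=0)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def G_tilde(x, spec: TheorySpec):
    """Upper tail of ``g_reg``: ``G_tilde(x) = integral_x^inf g_reg``.

    Evaluated term-wise via ``int_x^inf Q(a, beta*y) dy =
    (a/beta) Q(a+1, beta*x) - x Q(a, beta*x)``, which avoids the
    cancellation of computing ``1 - G_reg(x)`` in the tail.
    """
    _check_regulated(spec)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xa < 0):
        raise ValueError("x must be >= 0")
    beta = 2.0 * (1.0 - spec.p) * spec.nu
    k = _kgrid(spec)[:, None]
    a = k * spec.nu
    z = beta * xa
    tail = (a / beta) * special.gammaincc(a + 1.0, z) - xa * special.gammaincc(a, z)
    out = (1.0 - spec.p) * np.sum(2.0**-k * tail, axis=0)
    out = np.clip(out, 0.0, 1.0)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def h(x, spec: TheorySpec):
    """Density of the distance from a random site to the next crossover
    across 2T meioses; ``h(0) = 2T``."""
    _check_regulated(spec)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    T2 = 2.0 * spec.T
    Gt = np.atleast_1d(G_tilde(xa, spec))
    g = np.atleast_1d(g_reg(xa, spec))
    out = T2 * np.exp(-2.0 * spec.p * spec.T * xa) * Gt ** (T2 - 1.0) * (g + spec.p * Gt)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def phi(x, spec: TheorySpec):
    """Density of the length of a randomly chosen inter-crossover interval
    (infinite chromosome); mean ``1/(2T)``."""
    _check_regulated(spec)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    T = float(spec.T)
    p = spec.p
    Gt = np.atleast_1d(G_tilde(xa, spec))
    g = np.atleast_1d(g_reg(xa, spec))
    f = np.atleast_1d(f_reg(xa, spec))
    n = int(2 * spec.T)
    # expanded form of the four-term density, written without dividing by
    # G_tilde so the tail (G_tilde -> 0) stays finite
    out = np.exp(-2.0 * p * T * xa) * (
        4.0 * p * T * g * Gt ** (n - 1)
        + (n - 1) * g**2 * Gt ** (n - 2)
        + (1.0 - p) * f * Gt ** (n - 1)
        + 2.0 * p**2 * T * Gt**n
    )
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def phi_poisson(x, T: int):
    """Poisson-model counterpart of :func:`phi`: ``2T exp(-2Tx)``."""
    xa = np.asarray(x, dtype=float)
    out = 2.0 * T * np.exp(-2.0 * T * xa)
    return float(out) if np.ndim(x) == 0 else out


def _finite_denominator(spec: TheorySpec) -> float:
    # L + mean segment length; the mean of phi is exactly 1/(2T)
    return spec.L + 1.0 / (2.0 * spec.T)


def phi_finite(x, spec: TheorySpec):
    """Continuous part of the finite-chromosome segment-length density on
    ``[0, L]``; the point mass at ``x = L`` is :func:`phi_finite_atom`.

    Uses ``integral_x^inf phi = h(x)/(2T)``, a consequence of
    ``phi = -(1/2T) h'``.
    """
    if spec.L is None:
        raise ValueError("spec.L is required for the finite-chromosome density")
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xa < 0) or np.any(xa > spec.L + 1e-12):
        raise ValueError("x must lie in [0, L]")
    T2 = 2.0 * spec.T
    upper = np.atleast_1d(h(xa, spec)) / T2
    out = (2.0 * upper + (spec.L - xa) * np.atleast_1d(phi(xa, spec))) / _finite_denominator(spec)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def phi_finite_atom(spec: TheorySpec) -> float:
    """Mass of the point at ``x = L``: the probability that a segment spans
    the whole chromosome."""
    if spec.L is None:
        raise ValueError("spec.L is required for the finite-chromosome density")
    T2 = 2.0 * spec.T
    # integral_L^inf (y - L) phi(y) dy = integral_L^inf h(u)/(2T) du
    val, _ = integrate.quad(
        lambda u: h(u, spec) / T2, spec.L, spec.L + 30.0 / T2, limit=200
    )
    return float(val / _finite_denominator(spec))


def phi_finite_poisson(x, T: int, L: float):
    """Continuous part of the Poisson finite-chromosome density:
    ``2T exp(-2Tx) [2 + 2T(L-x)] / (2TL + 1)``."""
    xa = np.asarray(x, dtype=float)
    out = 2.0 * T * np.exp(-2.0 * T * xa) * (2.0 + 2.0 * T * (L - xa)) / (2.0 * T * L + 1.0)
    return float(out) if np.ndim(x) == 0 else out


def phi_finite_poisson_atom(T: int, L: float) -> float:
    return float(np.exp(-2.0 * T * L) / (2.0 * T * L + 1.0))


# ---------------------------------------------------------------------------
# sex-specific Poisson theory (physical axis, piecewise-constant rates)


@dataclass(frozen=True)
class SSPoissonSpec:
    """Piecewise-constant per-bp crossover rates on a regular grid.

    ``lam_f``/``lam_m`` are arrays of female/male rates (Morgans per bp) on
    intervals of width ``step_bp`` covering ``[0, n*step_bp]``; ``T`` is the
    number of generations to the common ancestor (2T meioses).
    """

    lam_f: np.ndarray
    lam_m: np.ndarray
    step_bp: float
    T: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam_f", np.asarray(self.lam_f, dtype=float))
        object.__setattr__(self, "lam_m", np.asarray(self.lam_m, dtype=float))
        if self.lam_f.shape != self.lam_m.shape or self.lam_f.ndim != 1:
            raise ValueError("lam_f and lam_m must be 1-D arrays of equal length")
        if np.any(self.lam_f < 0) or np.any(self.lam_m < 0):
            raise ValueError("rates must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def length_bp(self) -> float:
        return self.lam_f.size * self.step_bp


def ss_spec_from_map(gmap, chrom: str, T: int, step_bp: float = 10_000.0) -> SSPoissonSpec:
    """Discretize a sex-specific map chromosome onto a regular bp grid."""
    c = gmap.chrom(chrom)
    lo, hi = c.span()
    edges = np.arange(lo, hi + step_bp, step_bp)
    edges[-1] = min(edges[-1], hi)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    lam = {}
    for sex in ("female", "male"):
        g = c.phys_to_gen(edges, sex) / 100.0  # Morgans
        lam[sex] = np.diff(g) / np.diff(edges)
    # resample to exact uniform step for the dataclass contract
    return SSPoissonSpec(lam_f=lam["female"], lam_m=lam["male"], step_bp=step_bp, T=T)


def meiosis_count_weights(T: int) -> np.ndarray:
    """P(n_f female transmissions) for n_f = 0..2T on the path through one
    common ancestor: ``n_f = n_fi + 2*n_fa`` with ``n_fi ~ Binomial(2T-2,
    1/2)`` (intermediate meioses) and ``n_fa ~ Bernoulli(1/2)`` (whether the
    transmitting ancestor is female counts twice)."""
    n = 2 * T
    w = np.zeros(n + 1)
    for a in (0, 1):
        k = np.arange(0, n - 1)  # n_fi support
        w[k + 2 * a] += 0.5 * binom.pmf(k, n - 2, 0.5)
    return w


def _interdensity_grid(spec: SSPoissonSpec, n_f: int) -> tuple[np.ndarray, np.ndarray]:
    """(grid edges in bp, density at segment lengths = multiples of step)."""
    n_m = 2 * spec.T - n_f
    if not 0 <= n_f <= 2 * spec.T:
        raise ValueError("n_f must be in 0..2T")
    lam = spec.lam_f * n_f + spec.lam_m * n_m  # per bp, per interval
    if np.all(lam == 0):
        raise ValueError("all-zero crossover rate")
    step = spec.step_bp
    Lam_edges = np.concatenate([[0.0], np.cumsum(lam * step)])  # at grid edges
    n = lam.size
    Ltot = Lam_edges[-1]
    dens = np.empty(n)
    # density evaluated at x = (j + 1/2) * step via sums over the rate grid
    for j in range(n):
        m = n - j  # number of y-intervals with y + x inside the chromosome
        if m <= 0:
            dens[j] = 0.0
            continue
        ly = lam[:m]
        lyx = lam[j : j + m]
        expo = np.exp(-(Lam_edges[j : j + m] - Lam_edges[:m]))
        first = np.sum(ly * lyx * expo) * step
        second = lam[j] * np.exp(-Lam_edges[j])
        dens[j] = (first + second) / Ltot
    edges = np.arange(n + 1) * step
    return edges, dens


def ss_poisson_interdensity(x, spec: SSPoissonSpec, n_f: int):
    """Inter-crossover distance density (per bp) at physical distance ``x``
    given ``n_f`` female transmissions, rates discretized on the spec grid."""
    edges, dens = _interdensity_grid(spec, n_f)
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > edges[-1]):
        raise ValueError("x outside [0, chromosome length]")
    idx = np.minimum(np.searchsorted(edges, xa, side="right") - 1, dens.size - 1)
    out = dens[idx]
    return float(out) if np.ndim(x) == 0 else out


def ss_poisson_mixture(x, spec: SSPoissonSpec):
    """Inter-crossover density marginalized over the number of female
    transmissions (binomial path mixture)."""
    w = meiosis_count_weights(spec.T)
    xa = np.asarray(x, dtype=float)
    out = np.zeros(xa.shape if xa.ndim else ())
    for n_f, wi in enumerate(w):
        if wi == 0:
            continue
        out = out + wi * ss_poisson_interdensity(xa, spec, n_f)
    return float(out) if np.ndim(x) == 0 else out
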