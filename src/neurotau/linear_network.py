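"""Timescale distributions in linear recurrent (OU) networks.

A linear network of N units driven by white noise,

    tau_syn dx_i/dt = -x_i + g sum_j W_ij x_j + eta_i
                    = -sum_j M_ij x_j + eta_i,   M = I - gW,

has fluctuating fixed-point dynamics when every eigenvalue of the
effective connectivity M has positive real part. The unit
autocorrelations are mixtures of eigenmodes with timescales
tau_p = tau_syn / lambda_p, so the timescale distribution follows from
the eigenvalue density f(lambda) by the reciprocal change of variables

    g(tau) = f(1/tau) / tau^2.

At the edge of instability (smallest eigenvalue -> 0), a density that
behaves as f(lambda) ~ lambda^zeta near zero yields a power-law tail of
timescales with exponent

    gamma = 2 + zeta,

valid above the cutoff timescale 1/lambda_cutoff. Three eigenvalue
families illustrate the theory: uniform (zeta = 0, gamma = 2), semicircle
of radius R (zeta = 1/2, gamma = 2.5, lambda_cutoff = 2R) and gamma-shape
alpha with unit scale (zeta = alpha - 1, gamma = alpha + 1,
lambda_cutoff = ln 2).

The edge of instability is implemented as a one-parameter support shift:
eigenvalues are translated so the minimum equals epsilon, the distance to
the instability threshold (equivalent to controlling the synaptic gain g,
since lambda_min = 1 - g * lambda_w_max; raising epsilon = lowering g
caps the longest timescale at tau_syn / epsilon and collapses the power
law). Timescale distributions are computed from inverse eigenvalues by
default; the full stochastic simulation is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "EigenFamily",
    "LinearNetworkSpec",
    "sample_eigenvalues",
    "timescale_density",
    "predicted_exponent",
    "eigen_to_timescales",
    "analytic_correlation",
    "simulate_linear_network",
    "network_from_eigenvalues",
]


@dataclass(frozen=True)
class EigenFamily:
    """Eigenvalue density family of the effective connectivity.

    ``family`` is one of "uniform" (params: lam_min, lam_max),
    "semicircle" (params: radius R) or "gamma" (params: shape, unit
    scale). ``zeta`` is the exponent of the leading power-series term of
    the density near zero.
    """

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in ("uniform", "semicircle", "gamma"):
            raise ValueError(f"unknown family: {self.family}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.family == "uniform":
            lo, hi = p
            if not 0 <= lo < hi:
                raise ValueError("uniform family needs 0 <= lam_min < lam_max")
        elif self.family == "semicircle":
            (r,) = p
            if r <= 0:
                raise ValueError("semicircle radius must be positive")
        else:
            (shape,) = p
            if shape <= 0:
                raise ValueError("gamma shape must be positive")

    @property
    def zeta(self) -> float:
        if self.family == "uniform":
            return 0.0
        if self.family == "semicircle":
            return 0.5
        return self.params[0] - 1.0

    @property
    def support(self) -> tuple:
        if self.family == "uniform":
            return self.params
        if self.family == "semicircle":
            return (0.0, 2.0 * self.params[0])
        return (0.0, np.inf)

    @property
    def lambda_cutoff(self) -> float:
        """Largest eigenvalue for which the near-zero power series holds."""
        if self.family == "uniform":
            return self.params[1]
        if self.family == "semicircle":
            return 2.0 * self.params[0]
        return float(np.log(2.0))

    def density(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if self.family == "uniform":
            lo, hi = self.params
            return np.where((lam >= lo) & (lam <= hi), 1.0 / (hi - lo), 0.0)
        if self.family == "semicircle":
            (r,) = self.params
            inside = (lam >= 0) & (lam <= 2 * r)
            val = np.zeros_like(lam)
            lam_in = lam[inside]
            val[inside] = (2.0 / (np.pi * r ** 2)
                           * np.sqrt(np.maximum(r ** 2 - (r - lam_in) ** 2, 0.0)))
            return val
        (shape,) = self.params
        from scipy.stats import gamma as gamma_dist
        return gamma_dist.pdf(lam, shape)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        if self.family == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, n)
        if self.family == "semicircle":
            (r,) = self.params
            # semicircle on [0, 2R] is an affine Beta(3/2, 3/2)
            return 2.0 * r * rng.beta(1.5, 1.5, n)
        (shape,) = self.params
        return rng.gamma(shape, 1.0, n)


def sample_eigenvalues(family: EigenFamily, n: int = 1000,
                       seed=None) -> np.ndarray:
    """I.i.d. eigenvalue draws from the family density."""
    return family.sample(n, seed)


def timescale_density(family: EigenFamily):
    """Density g(tau) = f(1/tau)/tau^2 of the inverse eigenvalues.

    Returns a callable vectorized over tau; its support is
    (1/lambda_max, 1/lambda_min) for the family's eigenvalue support.
    """

    def g(tau):
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        pos = tau > 0
        out[pos] = family.density(1.0 / tau[pos]) / tau[pos] ** 2
        return out

    lo, hi = family.support
    g.support = (1.0 / hi if hi > 0 else 0.0,
                 1.0 / lo if lo > 0 else np.inf)
    return g


def predicted_exponent(zeta: float) -> float:
    """Power-law exponent gamma = 2 + zeta of the slow-timescale tail."""
    if zeta <= -1:
        raise ValueError("zeta must exceed -1 (normalizability)")
    return 2.0 + zeta


def eigen_to_timescales(eigenvalues, tau_syn: float = 1.0,
                        epsilon: float | None = None) -> np.ndarray:
    """Timescales tau = tau_syn / lambda, optionally at the instability edge.

    With ``epsilon`` given, the eigenvalue support is shifted so the
    minimum equals epsilon (the distance to the instability threshold);
    epsilon -> 0 is the edge of instability and the longest timescale is
    bounded by tau_syn / epsilon.
    """
    lam = np.asarray(eigenvalues, dtype=float).copy()
    if epsilon is not None:
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        lam = lam - lam.min() + epsilon
    if np.any(lam <= 0):
        raise ValueError("all (shifted) eigenvalues must be positive")
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    return tau_syn / lam


@dataclass(frozen=True)
class LinearNetworkSpec:
    """Linear network specification with effective connectivity M = I - gW."""

    W: np.ndarray
    g: float = 1.0
    tau_syn: float = 1.0
    noise: float = 1.0

    @property
    def n_units(self) -> int:
        return np.asarray(self.W).shape[0]

    @property
    def M(self) -> np.ndarray:
        W = np.asarray(self.W, dtype=float)
        return np.eye(W.shape[0]) - self.g * W

    @property
    def lambda_min(self) -> float:
        return float(np.min(np.real(np.linalg.eigvals(self.M))))


def network_from_eigenvalues(eigenvalues, seed=None,
                             mixing: str = "local") -> np.ndarray:
    """Symmetric effective connectivity M with the given spectrum.

    M = Q diag(lambda) Q^T. With ``mixing="local"`` (default) Q is a
    product of N random Givens rotations, so eigenmodes stay localized
    and each unit predominantly expresses a few modes — the regime in
    which single-unit autocorrelation timescales track the inverse
    eigenvalues. With ``mixing="dense"`` Q is Haar-random orthogonal:
    every mode spreads over all units, each unit's autocorrelation is
    then dominated by the slowest modes (their stationary variance scales
    as 1/lambda), and fitted single-unit timescales concentrate near the
    longest network timescales instead of sampling the spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    n = lam.size
    rng = np.random.default_rng(seed)
    if mixing == "dense":
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
    elif mixing == "local":
        q = np.eye(n)
        for _ in range(n):
            i, j = rng.choice(n, 2, replace=False)
            th = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(th), np.sin(th)
            qi, qj = q[:, i].copy(), q[:, j].copy()
            q[:, i] = c * qi + s * qj
            q[:, j] = -s * qi + c * qj
    else:
        raise ValueError("mixing must be 'local' or 'dense'")
    return (q * lam) @ q.T


def analytic_correlation(M: np.ndarray, D: float, t: float) -> np.ndarray:
    """Stationary lagged correlation matrix C(t) of the OU network.

    For tau_syn = 1 and isotropic noise strength D, with eigen-pairs
    (lambda_p, v_p) and left eigenvectors u_p (normalized u_p^T v_q =
    delta_pq),

        C(t) = D sum_{p,q} (u_q^T u_p) / (lambda_p + lambda_q)
               v_p v_q^T exp(-lambda_p t),   t >= 0.
    """
    M = np.asarray(M, dtype=float)
    if t < 0:
        raise ValueError("t must be >= 0")
    lam, V = np.linalg.eig(M)
    if np.any(np.real(lam) <= 0):
        raise ValueError(
            f"unstable network: min Re(eigenvalue) = {np.real(lam).min():.3g}")
    Vinv = np.linalg.inv(V)
    # u_p is the p-th row of V^{-1} (transpose convention, no conjugation)
    G = Vinv @ Vinv.T          # G[p, q] = u_p^T u_q
    denom = lam[:, None] + lam[None, :]
    A = (G.T / denom) * np.exp(-lam[:, None] * t)   # A[p, q]
    C = V @ A @ V.T
    return np.real(D * C)


def simulate_linear_network(spec: LinearNetworkSpec, T: float, dt: float,
                            seed=None, n_batch: int = 1) -> np.ndarray:
    """Euler-Maruyama integration of the noise-driven linear network.

    Returns traces of shape (n_batch, n_units, n_steps). The white noise
    has intensity D per unit (independent across units), so a single unit
    with eigenvalue lambda has stationary variance D / (2 lambda tau_syn).
    """
    M = spec.M
    lam = np.linalg.eigvals(M)
    lam_min = float(np.real(lam).min())
    if lam_min <= 0:
        raise ValueError(f"unstable network: lambda_min = {lam_min:.3g}")
    lam_max = float(np.real(lam).max())
    if dt > 0.1 * spec.tau_syn / lam_max:
        raise ValueError("dt too large for stable integration "
                         f"(need dt <= {0.1 * spec.tau_syn / lam_max:.3g})")
    n_steps = int(round(T / dt))
    n = spec.n_units
    rng = np.random.default_rng(seed)
    x = np.zeros((n_batch, n))
    out = np.empty((n_batch, n, n_steps))
    drift = dt / spec.tau_syn
    amp = np.sqrt(spec.noise * dt) / spec.tau_syn
    for k in range(n_steps):
        x = x - drift * (x @ M.T) + amp * rng.standard_normal((n_batch, n))
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"divergence during integration (lambda_min = {lam_min:.3g})")
        out[:, :, k] = x
    return out
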