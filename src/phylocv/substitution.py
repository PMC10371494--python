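"""Single-matrix nucleotide substitution processes of the GTR family.

The instantaneous generator is ``Q_ij = rho_ij * pi_j`` for ``i != j``,
where ``pi`` is the stationary nucleotide-frequency profile (a point on the
4-simplex) and ``rho`` the six symmetric exchangeabilities over unordered
nucleotide pairs.  Setting all exchangeabilities equal gives F81; further
setting ``pi`` uniform gives JC.  Every matrix is rescaled so the expected
substitution rate at stationarity is 1, which keeps branch lengths readable
as expected substitutions per site regardless of the profile.

Rate heterogeneity across sites is modelled by a gamma distribution with
mean 1 and variance ``1/alpha``, discretized into ``ncat`` equal-probability
categories represented by their bin means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.special import gammainc, gammaincinv

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

#: unordered nucleotide pairs, in the order the six exchangeabilities use
PAIR_NAMES: tuple[str, ...] = ("AC", "AG", "AT", "CG", "CT", "GT")
PAIR_INDICES: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

PROFILE_FLOOR = 1e-8


@dataclass(frozen=True)
class FrequencyProfile:
    """Stationary nucleotide distribution of one substitution matrix.

    ``pi`` is indexed (A, C, G, T), sums to 1 and every entry is strictly
    positive (entries are floored at 1e-8 by :meth:`from_values`).
    """

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (4,):
            raise ValueError(f"profile must have 4 entries, got shape {pi.shape}")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"profile entries must sum to 1, got {pi.sum()!r}")
        if np.any(pi <= 0):
            raise ValueError("profile entries must be strictly positive")

    @classmethod
    def from_values(cls, values) -> "FrequencyProfile":
        """Build a profile from non-negative weights: floor at 1e-8, renormalize."""
        v = np.maximum(np.asarray(values, dtype=float), PROFILE_FLOOR)
        v = v / v.sum()
        # a second pass makes the sum exact to float rounding
        v = v / v.sum()
        return cls(v)

    @classmethod
    def uniform(cls) -> "FrequencyProfile":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class Exchangeabilities:
    """The six symmetric rate multipliers rho over unordered nucleotide pairs.

    Order (AC, AG, AT, CG, CT, GT).  Normalized so the six values average 1,
    removing the scale redundancy with the overall rate.
    """

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (6,):
            raise ValueError(f"exchangeabilities must have 6 entries, got shape {rho.shape}")
        if np.any(rho <= 0):
            raise ValueError("exchangeabilities must be strictly positive")
        rho = rho / rho.mean()
        object.__setattr__(self, "rho", rho)

    @classmethod
    def equal(cls) -> "Exchangeabilities":
        """All-equal exchangeabilities (the Poisson / F81 case)."""
        return cls(np.ones(6))

    def as_matrix(self) -> np.ndarray:
        """Symmetric 4x4 matrix with rho_ij off-diagonal, 0 diagonal."""
        m = np.zeros((4, 4))
        for r, (i, j) in zip(self.rho, PAIR_INDICES):
            m[i, j] = m[j, i] = r
        return m


@dataclass(frozen=True)
class RateMatrix:
    """A normalized reversible generator with its spectral decomposition.

    ``matrix`` has rows summing to zero and unit expected rate at
    stationarity: ``-sum_i pi_i Q_ii = 1``.  ``scale`` records the expected
    rate of the raw ``rho_ij pi_j`` construction before normalization.

    Because the process is reversible, ``Q`` is similar to a symmetric
    matrix under the ``diag(sqrt(pi))`` transform; its eigenvalues are real
    and ``exp(Qt)`` reduces to scaling the eigenbasis, stored here as
    ``P(t) = left @ diag(exp(w t)) @ right``.
    """

    matrix: np.ndarray
    pi: np.ndarray
    scale: float
    eigenvalues: np.ndarray = field(repr=False)
    _left: np.ndarray = field(repr=False)
    _right: np.ndarray = field(repr=False)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for branch length t >= 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        p = (self._left * np.exp(self.eigenvalues * t)) @ self._right
        return np.clip(p, 0.0, None)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched ``exp(Q t)`` for an array of branch lengths (shape (m, 4, 4))."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        ew = np.exp(np.multiply.outer(ts, self.eigenvalues))  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", self._left, ew, self._right)
        return np.clip(p, 0.0, None)


def build_rate_matrix(profile: FrequencyProfile, rho: Exchangeabilities) -> RateMatrix:
    """Assemble the reversible generator Q_ij = rho_ij * pi_j, unit-rate scaled.

    Time-reversibility (detailed balance pi_i Q_ij = pi_j Q_ji) holds by
    construction because rho is symmetric.
    """
    pi = profile.pi
    q = rho.as_matrix() * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = float(-(pi * np.diag(q)).sum())
    q = q / scale

    # symmetrize under the sqrt(pi) similarity transform for a stable expm
    d = np.sqrt(pi)
    sym = (q * d[:, np.newaxis] / d[np.newaxis, :])
    sym = 0.5 * (sym + sym.T)
    w, v = np.linalg.eigh(sym)
    left = v / d[:, np.newaxis]
    right = (v * d[:, np.newaxis]).T
    return RateMatrix(matrix=q, pi=pi.copy(), scale=scale,
                      eigenvalues=w, _left=left, _right=right)


def stationary_distribution(q: RateMatrix) -> FrequencyProfile:
    """Left null vector of Q, normalized to the simplex."""
    ns = null_space(q.matrix.T)
    if ns.shape[1] != 1:
        raise ArithmeticError(
            f"stationary distribution not unique: null space dimension {ns.shape[1]}"
        )
    v = ns[:, 0]
    v = np.abs(v) / np.abs(v).sum()
    return FrequencyProfile.from_values(v)


def transition_matrix(q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries non-negative."""
    return q.transition_matrix(t)


@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma site-rate model: ``ncat`` equal-weight rate categories.

    The underlying gamma law has mean 1 and variance ``1/alpha``; each
    category's rate is the mean of its equal-probability quantile bin,
    renormalized so the category-weighted mean is exactly 1.
    """

    alpha: float
    ncat: int
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-10:
            raise ValueError("discrete-gamma rates must average to 1")
        if np.any(np.diff(self.rates) <= 0):
            raise ValueError("discrete-gamma rates must be strictly increasing")


def discretize_gamma(alpha: float, ncat: int = 4) -> GammaRates:
    """Equal-probability discretization of Gamma(alpha, rate=alpha) by bin means.

    With shape a and rate a the partial expectation over a quantile bin
    [q_lo, q_hi) is ``gammainc(a+1, a*q_hi) - gammainc(a+1, a*q_lo)`` (the
    regularized lower incomplete gamma), so each bin mean is that difference
    times ``ncat``.  The means are renormalized to average exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if ncat < 1:
        raise ValueError(f"number of rate categories must be >= 1, got {ncat}")
    if ncat == 1:
        return GammaRates(alpha=float(alpha), ncat=1,
                          rates=np.array([1.0]), weights=np.array([1.0]))
    edges = gammaincinv(alpha, np.arange(1, ncat) / ncat) / alpha
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges), [1.0]])
    rates = np.diff(cum) * ncat
    rates = rates / rates.mean()
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRates(alpha=float(alpha), ncat=int(ncat), rates=rates, weights=weights)
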