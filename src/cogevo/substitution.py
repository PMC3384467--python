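"""Time-reversible amino-acid substitution models.

A model is defined by a symmetric exchangeability matrix ``S`` and an
equilibrium frequency vector ``pi``; the instantaneous rate matrix is
``Q_ij = S_ij * pi_j`` (i != j) with rows summing to zero, scaled so one
unit of branch length equals one expected substitution per site.  Because
``diag(sqrt(pi)) @ Q @ diag(1/sqrt(pi))`` is symmetric, transition
probability matrices ``exp(Q t)`` are computed from a single eigendecomposition,
which makes repeated evaluation at many branch lengths cheap and stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wag_data import AMINO_ACIDS, WAG_FREQUENCIES, wag_exchangeabilities

__all__ = [
    "AMINO_ACIDS",
    "SubstitutionModel",
    "wag",
    "wag_f",
    "poisson_model",
]

_N_STATES = 20


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible 20-state substitution model with a normalised rate matrix.

    Parameters
    ----------
    exchangeabilities
        Symmetric non-negative (20, 20) matrix; the diagonal is ignored.
    frequencies
        Equilibrium frequencies, length 20, summing to 1.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    rate_matrix: np.ndarray = field(init=False, repr=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (_N_STATES, _N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (_N_STATES,) or np.any(pi < 0):
            raise ValueError("frequencies must be 20 non-negative values")
        if abs(pi.sum() - 1.0) > 1e-5:
            raise ValueError("frequencies must sum to 1")
        pi = pi / pi.sum()

        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise: expected substitutions per unit time = 1
        mu = -np.dot(pi, np.diag(q))
        q = q / mu

        # symmetrise B = D^{1/2} Q D^{-1/2}; eigh gives orthonormal V
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, np.newaxis]) / sqrt_pi[np.newaxis, :]
        b = 0.5 * (b + b.T)
        w, v = np.linalg.eigh(b)
        right = v / sqrt_pi[:, np.newaxis]      # columns scaled
        left = (v * sqrt_pi[:, np.newaxis]).T   # rows scaled

        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "_eigvals", w)
        object.__setattr__(self, "_left", left)
        object.__setattr__(self, "_right", right)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Return ``P(t) = exp(Q t)``; rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        """Same exchangeabilities, new equilibrium frequencies (the +F step)."""
        return SubstitutionModel(self.exchangeabilities, np.asarray(frequencies))


def wag() -> SubstitutionModel:
    """WAG model with its published equilibrium frequencies."""
    return SubstitutionModel(wag_exchangeabilities(), WAG_FREQUENCIES.copy())


def wag_f(frequencies: np.ndarray) -> SubstitutionModel:
    """WAG+F: published exchangeabilities, data-derived frequencies."""
    return SubstitutionModel(wag_exchangeabilities(), np.asarray(frequencies))


def poisson_model() -> SubstitutionModel:
    """Equal-exchangeability, uniform-frequency model (20-state Poisson).

    Under this model the ML distance for an observed difference fraction *p*
    has the closed form ``-(19/20) ln(1 - 20 p / 19)``, which makes it the
    natural analytic cross-check for the numeric distance optimiser.
    """
    s = np.ones((_N_STATES, _N_STATES))
    np.fill_diagonal(s, 0.0)
    return SubstitutionModel(s, np.full(_N_STATES, 1.0 / _N_STATES))
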