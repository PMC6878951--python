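"""Amino-acid substitution models (time-reversible CTMC on 20 states).

Two named models are provided:

* ``POISSON`` — equal exchangeabilities and uniform frequencies. Under
  this model the probability of observing a different residue after time
  ``t`` has the closed form ``(19/20) * (1 - exp(-20 t / 19))``, which the
  test-suite uses as an analytic oracle.
* ``WAG`` — the Whelan-Goldman empirical matrix.

Rate matrices are normalised to one expected substitution per site per
unit branch length. Transition matrices are computed through the
eigendecomposition of the symmetrised generator, so ``P(t)`` is exact and
cheap to evaluate for many ``t``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._wag import WAG_FREQUENCIES, WAG_LOWER_TRIANGLE, WAG_ORDER

AA_ALPHABET = WAG_ORDER  # PAML residue order
N_STATES = 20

__all__ = ["AA_ALPHABET", "N_STATES", "SubstitutionModel", "get_model"]


def _triangle_to_symmetric(lower: list[float], n: int) -> np.ndarray:
    s = np.zeros((n, n))
    k = 0
    for i in range(n):  # column
        for j in range(i + 1, n):  # row
            s[j, i] = s[i, j] = lower[k]
            k += 1
    return s


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability bins of a Gamma(alpha, 1/alpha)."""
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    # mean of the distribution within each bin, via the incomplete-gamma identity
    upper = _gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = _gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = (upper - lower) * k
    return rates / rates.mean()


class SubstitutionModel:
    """Reversible amino-acid model with optional discrete-gamma rates.

    Parameters
    ----------
    name : str
        Model label.
    exchangeabilities : (20, 20) array
        Symmetric matrix of exchangeability coefficients (diagonal ignored).
    frequencies : (20,) array
        Stationary frequencies, must sum to 1.
    gamma_categories, gamma_alpha :
        If ``gamma_categories`` > 1, site rates follow a discretised
        Gamma(alpha) with that many equal-weight categories (default off).
    """

    def __init__(
        self,
        name: str,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        gamma_categories: int = 1,
        gamma_alpha: float = 1.0,
    ) -> None:
        self.name = name
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        s = np.asarray(exchangeabilities, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        q /= mean_rate
        self.pi = pi
        self.rate_matrix = q

        # eigendecomposition of the pi-symmetrised generator
        sqrt_pi = np.sqrt(pi)
        b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)
        evals, evecs = np.linalg.eigh(b)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]  # T1: P(t) = T1 e^{L t} T2
        self._right = evecs.T * sqrt_pi[None, :]

        if gamma_categories < 1:
            raise ValueError("gamma_categories must be >= 1")
        self.gamma_categories = int(gamma_categories)
        self.gamma_alpha = float(gamma_alpha)
        if self.gamma_categories > 1:
            self.category_rates = discrete_gamma_rates(gamma_alpha, gamma_categories)
        else:
            self.category_rates = np.ones(1)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1, small negative entries clipped."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if t == 0:
            return np.eye(N_STATES)
        p = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    # Decomposition accessors used by the pruning engine for fast repeated
    # P(t) evaluation during branch-length optimisation.
    @property
    def eigen_system(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._evals, self._left, self._right

    def __repr__(self) -> str:  # pragma: no cover
        g = f", gamma(k={self.gamma_categories}, a={self.gamma_alpha})" if self.gamma_categories > 1 else ""
        return f"SubstitutionModel({self.name}{g})"


def get_model(name: str, gamma_categories: int = 1, gamma_alpha: float = 1.0) -> SubstitutionModel:
    """Return a named model (``POISSON`` or ``WAG``)."""
    key = name.upper()
    if key == "POISSON":
        exch = np.ones((N_STATES, N_STATES))
        freqs = np.full(N_STATES, 1.0 / N_STATES)
    elif key == "WAG":
        exch = _triangle_to_symmetric(WAG_LOWER_TRIANGLE, N_STATES)
        freqs = np.asarray(WAG_FREQUENCIES)
    else:
        raise ValueError(f"unknown substitution model: {name!r}")
    return SubstitutionModel(key, exch, freqs, gamma_categories, gamma_alpha)
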