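"""Amino-acid substitution model machinery.

Implements a general-time-reversible amino-acid model built from a table of
symmetric exchangeabilities ``s_ij`` and equilibrium frequencies ``pi``:

    Q_ij = s_ij * pi_j        (i != j),     Q_ii = -sum_{j != i} Q_ij

normalised so that the expected number of substitutions per unit time at
stationarity, ``-sum_i pi_i Q_ii``, equals 1, which makes branch lengths read
as substitutions per site.  Transition matrices ``P(t) = expm(Q t)`` are
computed by symmetric eigendecomposition of the pi-symmetrised generator
``B = D^{1/2} Q D^{-1/2}`` (``D = diag(pi)``); this is numerically exact for
reversible models and lets one decomposition serve every branch length.

The Whelan-Goldman (WAG) empirical model is bundled as a plain-text matrix
file in the standard PAML/PhyML layout (lower-triangle exchangeabilities,
then the 20 frequencies) and is the default model throughout the package.
Residue ordering everywhere is the canonical WAG source ordering
ARNDCQEGHILKMFPSTWYV (see :data:`srpasr.seqio.AA_ORDER`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import DomainError, FormatError

N_STATES = 20


@dataclass
class RateModel:
    """Reversible amino-acid rate model with optional discrete-gamma categories."""

    exchangeabilities: np.ndarray
    eq_freqs: np.ndarray
    n_rate_categories: int = 1
    gamma_shape: Optional[float] = None
    rate_matrix: np.ndarray = field(init=False)
    category_rates: np.ndarray = field(init=False)

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.eq_freqs, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise FormatError("exchangeabilities must be a symmetric 20x20 table")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise FormatError("eq_freqs must be 20 positive probabilities")
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        q[np.diag_indices(N_STATES)] = -q.sum(axis=1)
        mu = -float(np.dot(pi, np.diag(q)))  # expected rate at stationarity
        q /= mu
        self.exchangeabilities = s
        self.eq_freqs = pi
        self.rate_matrix = q

        if self.n_rate_categories < 1:
            raise DomainError("n_rate_categories must be >= 1")
        if self.n_rate_categories > 1:
            if self.gamma_shape is None or self.gamma_shape <= 0:
                raise DomainError("gamma_shape required (and > 0) for >1 rate category")
            self.category_rates = _discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
        else:
            self.category_rates = np.ones(1)

        # Symmetric eigendecomposition of B = D^{1/2} Q D^{-1/2}.
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        b = 0.5 * (b + b.T)  # clean round-off asymmetry
        w, u = np.linalg.eigh(b)
        # Q = D^{-1/2} B D^{1/2}, so expm(Qt) = (D^{-1/2} U) exp(wt) (U^T D^{1/2})
        self._eigvals = w
        self._right = u / sq[:, None]    # D^{-1/2} U
        self._left = u.T * sq[None, :]   # U^T D^{1/2}


def _discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean category rates of the discretised Gamma(shape, 1/shape), mean 1.

    Categories are equal-probability quantile bins; each category rate is the
    conditional mean within its bin (Yang's mean-rate discretisation), so the
    category rates average exactly to 1.
    """
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # E[X; X < c] for Gamma(a, b) via the incomplete-gamma identity.
    partial = gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = (partial[1:] - partial[:-1]) * k
    return rates / rates.mean()


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic P(t) for one branch length (x category rate)."""

    t: float
    probs: np.ndarray


def load_dat(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML/PhyML '.dat' model file: lower triangle then frequencies."""
    values: list[float] = []
    for line in Path(path).read_text().split("\n"):
        values.extend(float(tok) for tok in line.split())
    need = N_STATES * (N_STATES - 1) // 2 + N_STATES
    if len(values) < need:
        raise FormatError(f"{path}: expected at least {need} numbers, found {len(values)}")
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = values[k]
            k += 1
    pi = np.array(values[k : k + N_STATES])
    return s, pi


def wag_model(n_rate_categories: int = 1, gamma_shape: Optional[float] = None) -> RateModel:
    """The published WAG model, normalised to one substitution per unit time."""
    with resources.as_file(resources.files("srpasr.data") / "wag.dat") as p:
        s, pi = load_dat(p)
    return RateModel(exchangeabilities=s, eq_freqs=pi,
                     n_rate_categories=n_rate_categories, gamma_shape=gamma_shape)


def transition_probs(model: RateModel, t: float, category_rate: float = 1.0) -> np.ndarray:
    """P(t * category_rate) as a bare (20, 20) array."""
    if t < 0:
        raise DomainError(f"branch length must be non-negative, got {t}")
    expw = np.exp(model._eigvals * (t * category_rate))
    p = model._right @ (expw[:, None] * model._left)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def transition_matrix(model: RateModel, t: float, category_rate: float = 1.0) -> TransitionMatrix:
    """Matrix exponential of ``rate_matrix * t * category_rate``."""
    return TransitionMatrix(t=t, probs=transition_probs(model, t, category_rate))
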