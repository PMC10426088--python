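"""Goldman–Yang codon rate matrices and transition probabilities.

The instantaneous rate from codon i to codon j is zero unless the codons
differ at exactly one position, and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with rows normalised to sum to zero.  A matrix is conventionally scaled so
that the expected substitution rate  sum_i pi_i sum_{j!=i} q_ij  equals one,
making branch lengths expected substitutions per codon; for mixture models
the scaling uses the mixture-averaged rate so that all site classes share a
single time scale (see :func:`mixture_scale`).

Transition probabilities exp(Qt) are computed through the symmetrised
eigendecomposition that reversibility of the GY94 chain guarantees.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import expm as _scipy_expm

from .geneticcode import (
    N_CODONS,
    SENSE_CODONS,
    STEP_I,
    STEP_IS_SYNONYMOUS,
    STEP_IS_TRANSITION,
    STEP_J,
)

logger = logging.getLogger(__name__)

PI_FLOOR = 1e-10


def uniform_pi() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def floor_pi(pi: np.ndarray) -> np.ndarray:
    """Floor zero frequencies at 1e-10 and renormalise (logged, never silent)."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have length {N_CODONS}, got {pi.shape}")
    if np.any(pi < 0) or not np.isfinite(pi).all():
        raise ValueError("pi entries must be finite and non-negative")
    if np.any(pi < PI_FLOOR):
        logger.info("flooring %d near-zero codon frequencies at %g",
                    int(np.sum(pi < PI_FLOOR)), PI_FLOOR)
        pi = np.maximum(pi, PI_FLOOR)
    return pi / pi.sum()


def f3x4_frequencies(codon_matrix) -> np.ndarray:
    """Codon equilibrium frequencies from position-specific nucleotide counts.

    ``codon_matrix`` is any iterable of iterables of codon strings; gaps and
    ambiguity codes are ignored in the counts.
    """
    counts = np.zeros((3, 4))
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in codon_matrix:
        for codon in row:
            for pos, base in enumerate(codon.upper()):
                k = order.get(base)
                if k is not None:
                    counts[pos, k] += 1
    if counts.sum() == 0:
        return uniform_pi()
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
         for c in SENSE_CODONS]
    )
    return floor_pi(pi)


def rate_matrix_unscaled(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator before any rate scaling; rows sum to zero."""
    if not (np.isfinite(kappa) and kappa > 0):
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if not (np.isfinite(omega) and omega >= 0):
        raise ValueError(f"omega must be >= 0, got {omega}")
    pi = floor_pi(pi)
    rates = pi[STEP_J].copy()
    rates[STEP_IS_TRANSITION] *= kappa
    rates[~STEP_IS_SYNONYMOUS] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[STEP_I, STEP_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time: -sum_i pi_i q_ii."""
    return float(-np.dot(pi, np.diag(Q)))


def nonsyn_rate_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of the total substitution flux that is nonsynonymous."""
    pi = floor_pi(pi)
    rates = pi[STEP_J].copy()
    rates[STEP_IS_TRANSITION] *= kappa
    nonsyn = ~STEP_IS_SYNONYMOUS
    flux = pi[STEP_I] * rates
    syn_flux = flux[~nonsyn].sum()
    nonsyn_flux = (flux[nonsyn] * omega).sum()
    total = syn_flux + nonsyn_flux
    if total <= 0:
        return float("nan")
    return float(nonsyn_flux / total)


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled GY94 generator: expected substitution rate equals 1."""
    pi = floor_pi(pi)
    Q = rate_matrix_unscaled(kappa, omega, pi)
    r = expected_rate(Q, pi)
    if r <= 0:
        raise ValueError("degenerate rate matrix: zero expected rate")
    return Q / r


def mixture_scale(kappa: float, omegas, weights, pi: np.ndarray) -> float:
    """Mixture-averaged expected rate used to put all site classes on one clock."""
    pi = floor_pi(pi)
    omegas = np.asarray(omegas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    r = sum(
        w * expected_rate(rate_matrix_unscaled(kappa, om, pi), pi)
        for om, w in zip(omegas, weights)
    )
    if r <= 0:
        raise ValueError("degenerate mixture: zero expected rate")
    return float(r)


class SpectralQ:
    """Eigendecomposition of a reversible generator for fast exp(Qt).

    Reversibility means S = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric;
    P(t) = diag(1/sqrt(pi)) U exp(L t) U' diag(sqrt(pi)) with S = U L U'.
    Falls back to scipy's scaling-and-squaring expm if the decomposition is
    numerically unusable.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.pi = floor_pi(pi)
        sqrt_pi = np.sqrt(self.pi)
        S = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        try:
            eigval, eigvec = np.linalg.eigh(S)
            self._ok = np.isfinite(eigval).all()
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            self._ok = False
            eigval = eigvec = None
        if self._ok:
            self._eigval = eigval
            # left/right transforms absorbing the pi weighting
            self._right = eigvec / sqrt_pi[:, None]
            self._left = eigvec.T * sqrt_pi[None, :]

    def probs(self, t: float) -> np.ndarray:
        """Row-stochastic P(t) = exp(Qt); t >= 0."""
        return self.probs_batch(np.array([t]))[0]

    def probs_batch(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths at once: shape (len(ts), 61, 61)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0) or not np.isfinite(ts).all():
            raise ValueError("branch lengths must be finite and >= 0")
        if not self._ok:  # pragma: no cover - defensive
            return np.stack([_scipy_expm(self.Q * t) for t in ts])
        e = np.exp(self._eigval[None, :] * ts[:, None])  # (B, 61)
        P = (self._right[None, :, :] * e[:, None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


_SPECTRAL_CACHE: dict = {}


def cached_spectral(kappa: float, omega: float, scale: float,
                    pi: np.ndarray, pi_key=None) -> "SpectralQ":
    """Memoised SpectralQ for Q(kappa, omega, pi)/scale.

    Finite-difference gradients perturb one parameter at a time, so most
    likelihood evaluations reuse generators seen a moment earlier.
    """
    if pi_key is None:
        pi_key = hash(pi.tobytes())
    # exact float keys: a hit must mean bit-identical parameters, otherwise
    # cache contents from earlier fits could perturb optimizer trajectories
    key = (float(kappa), float(omega), float(scale), pi_key)
    sq = _SPECTRAL_CACHE.get(key)
    if sq is None:
        if len(_SPECTRAL_CACHE) >= 1024:
            _SPECTRAL_CACHE.clear()
        sq = SpectralQ(rate_matrix_unscaled(kappa, omega, pi) / scale, pi)
        _SPECTRAL_CACHE[key] = sq
    return sq
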