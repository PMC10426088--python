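"""Felsenstein pruning over the 61 sense-codon states.

Site-class mixtures are evaluated in one batched pass: transition matrices
are a ``(n_classes, n_nodes, 61, 61)`` tensor (one slab per branch, indexed
by the node below it) and conditional likelihoods a ``(n_classes, n_sites,
61)`` array per node.  Per-node max-scaling keeps partials in range; gaps,
ambiguities and species missing from an alignment are missing data (partial
likelihood one in every state).  Identical alignment columns are collapsed
into weighted site patterns before pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignments import CodonAlignment
from .geneticcode import N_CODONS
from .ratematrix import (
    SpectralQ,
    cached_spectral,
    floor_pi,
    mixture_scale,
    rate_matrix_unscaled,
)
from .trees import ArrayTree


class LikelihoodError(ValueError):
    pass


@dataclass
class PatternData:
    """Alignment columns collapsed to unique tip-state patterns."""

    tree: ArrayTree
    tip_states: np.ndarray      # (n_tips_in_tree_order, n_patterns), -1 missing
    counts: np.ndarray          # pattern multiplicities
    inverse: np.ndarray         # original column -> pattern index
    tip_nodes: list[int]        # tree node index per row of tip_states

    @classmethod
    def from_alignment(cls, aln: CodonAlignment, tree: ArrayTree) -> "PatternData":
        tips = tree.tip_indices
        labels = [tree.labels[t] for t in tips]
        extra = set(aln.species) - set(labels)
        if extra:
            raise LikelihoodError(f"alignment species missing from tree: {sorted(extra)}")
        encoded = aln.encoded()
        states = np.full((len(tips), aln.n_columns), -1, dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab in aln.species:
                states[i] = encoded[aln.species.index(lab)]
        patterns, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        return cls(tree=tree, tip_states=patterns.T, counts=counts.astype(float),
                   inverse=inverse, tip_nodes=tips)

    @property
    def n_patterns(self) -> int:
        return self.tip_states.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.inverse)

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector/matrix (last axis = patterns) to per-site."""
        return np.take(per_pattern, self.inverse, axis=-1)


def class_transition_tensor(
    tree: ArrayTree,
    kappa: float,
    pi: np.ndarray,
    classes,
    scale: float | None = None,
) -> np.ndarray:
    """(C, n_nodes, 61, 61) transition tensor for site classes.

    ``classes`` is a sequence of ``(weight, omega_background,
    omega_foreground)``; branches flagged in ``tree.foreground`` get the
    foreground omega.  All generators share one scaling constant: the
    background mixture-averaged rate by default, so branch lengths mean
    expected substitutions per codon under the background process.
    """
    pi = floor_pi(pi)
    pi_key = hash(pi.tobytes())
    weights = [c[0] for c in classes]
    om_bg = [c[1] for c in classes]
    om_fg = [c[2] for c in classes]
    if scale is None:
        scale = mixture_scale(kappa, om_bg, weights, pi)
    lengths = tree.branch_lengths
    fg = tree.foreground
    bg_cache: dict[float, np.ndarray] = {}
    fg_cache: dict[float, np.ndarray] = {}

    n_nodes = tree.n_nodes
    P = np.empty((len(classes), n_nodes, N_CODONS, N_CODONS))
    for c, (ob, of) in enumerate(zip(om_bg, om_fg)):
        if ob not in bg_cache:
            bg_cache[ob] = cached_spectral(kappa, ob, scale, pi,
                                           pi_key).probs_batch(lengths)
        P[c] = bg_cache[ob]
        if of != ob and fg.any():
            if of not in fg_cache:
                fg_cache[of] = cached_spectral(kappa, of, scale, pi,
                                               pi_key).probs_batch(lengths[fg])
            P[c, fg] = fg_cache[of]
    P[:, tree.root] = np.eye(N_CODONS)
    return P


def branch_transition_tensor(
    tree: ArrayTree, kappa: float, pi: np.ndarray, branch_omegas: np.ndarray
) -> np.ndarray:
    """(1, n_nodes, 61, 61) tensor for the free-ratio model: one omega per
    branch, each generator scaled by its own expected rate."""
    pi = floor_pi(pi)
    pi_key = hash(pi.tobytes())
    n_nodes = tree.n_nodes
    P = np.empty((1, n_nodes, N_CODONS, N_CODONS))
    for i in range(n_nodes):
        if i == tree.root:
            P[0, i] = np.eye(N_CODONS)
            continue
        om = float(branch_omegas[i])
        Q = rate_matrix_unscaled(kappa, om, pi)
        r = float(-np.dot(pi, np.diag(Q)))
        P[0, i] = cached_spectral(kappa, om, r, pi, pi_key).probs(
            tree.branch_lengths[i])
    return P


def prune_class_loglik(
    data: PatternData, P: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Per-class, per-pattern log site likelihoods, shape (C, n_patterns)."""
    tree = data.tree
    C = P.shape[0]
    S = data.n_patterns
    tip_row = {node: i for i, node in enumerate(data.tip_nodes)}
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    logscale = np.zeros((C, S))
    eye = np.eye(N_CODONS)
    for node in range(tree.n_nodes):
        if not tree.children[node]:
            states = data.tip_states[tip_row[node]]
            part = np.where(states[:, None] >= 0,
                            eye[np.maximum(states, 0)], 1.0)  # (S, 61)
            partials[node] = np.broadcast_to(part, (C, S, N_CODONS)).copy()
        else:
            acc = np.ones((C, S, N_CODONS))
            for child in tree.children[node]:
                # (C,S,61) x (C,61,61)^T -> (C,S,61), batched over classes
                acc *= partials[child] @ P[:, child].transpose(0, 2, 1)
                partials[child] = None
            m = acc.max(axis=2, keepdims=True)
            safe = np.where(m > 0, m, 1.0)
            acc /= safe
            with np.errstate(divide="ignore"):
                logscale += np.log(safe[..., 0])
            partials[node] = acc
    root_like = partials[tree.root] @ floor_pi(pi)  # (C, S)
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale


def mixture_loglik(
    class_loglik: np.ndarray, weights, counts: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Combine per-class pattern log-likelihoods under mixture weights.

    Returns (total lnL over sites, per-pattern mixture loglik, per-pattern
    class posteriors of shape (C, n_patterns) whose columns sum to one).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) != class_loglik.shape[0]:
        raise LikelihoodError("weights do not match class dimension")
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    per_pattern = logsumexp(class_loglik + logw[:, None], axis=0)
    posteriors = np.exp(class_loglik + logw[:, None] - per_pattern[None, :])
    total = float(np.dot(per_pattern, counts))
    return total, per_pattern, posteriors
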