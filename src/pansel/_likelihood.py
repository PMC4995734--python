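"""Shared phylogenetic-likelihood machinery.

Felsenstein pruning over compressed site patterns, transition matrices via
eigendecomposition of the pi^(1/2)-symmetrised reversible generator, and the
discrete-gamma rate approximation (equal-probability categories represented
by their conditional means).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .tree import PhyloTree

MISSING = -1


def compress_patterns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    ``columns`` is (n_sites, n_taxa) of integer states (MISSING for gaps).
    Returns (patterns (n_pat, n_taxa), weights (n_pat,)).
    """
    patterns, counts = np.unique(columns, axis=0, return_counts=True)
    return patterns, counts.astype(float)


class ReversibleGenerator:
    """Eigendecomposition of a reversible rate matrix for fast P(t)."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        self.freqs = freqs
        sqrt_pi = np.sqrt(freqs)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = (S + S.T) / 2.0  # symmetric up to round-off for reversible Q
        vals, vecs = eigh(S)
        self._vals = vals
        self._left = vecs / sqrt_pi[:, None]      # diag(pi^-1/2) V
        self._right = (vecs * sqrt_pi[:, None]).T  # V^T diag(pi^1/2)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t <= 0:
            return np.eye(len(self.freqs))
        P = (self._left * np.exp(self._vals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of ``k`` equal-probability Gamma(alpha, mean 1) categories."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    return (upper - lower) * k


def leaf_partials(patterns: np.ndarray, taxon_index: int, n_states: int) -> np.ndarray:
    """Partial-likelihood matrix (n_states, n_patterns) for one leaf.

    Missing states (gaps/ambiguities) contribute 1 for every state.
    """
    states = patterns[:, taxon_index]
    L = np.zeros((n_states, patterns.shape[0]))
    miss = states == MISSING
    L[:, miss] = 1.0
    ok = ~miss
    L[states[ok], np.nonzero(ok)[0]] = 1.0
    return L


def pattern_likelihoods(tree: PhyloTree, patterns: np.ndarray, n_states: int,
                        taxon_order: dict[str, int],
                        P_for_branch, root_freqs: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pruning over compressed patterns.

    ``P_for_branch(node)`` returns the transition matrix for the branch above
    ``node``.  Returns (per-pattern likelihood, per-pattern log-scale), i.e.
    the pattern likelihood is ``lik * exp(logscale)``.
    """
    npat = patterns.shape[0]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        L = np.ones((n_states, npat))
        for child in node.children:
            P = P_for_branch(child)
            if child.is_leaf:
                # leaf partials are one-hot columns: P @ L is column selection
                states = patterns[:, taxon_order[child.label]]
                ok = states != MISSING
                Lc = np.ones((n_states, npat))
                Lc[:, ok] = P[:, states[ok]]
                L *= Lc
            else:
                L *= P @ partial.pop(id(child))
        m = L.max(axis=0)
        if m.min() < 1e-120:
            safe = np.where(m > 0, m, 1.0)
            L /= safe
            logscale += np.log(safe)
        partial[id(node)] = L
    if tree.root.is_leaf:  # degenerate single-leaf tree
        L = leaf_partials(patterns, taxon_order[tree.root.label], n_states)
        return root_freqs @ L, logscale
    lik = root_freqs @ partial[id(tree.root)]
    return lik, logscale


def mixture_log_likelihood_batched(tree: PhyloTree, patterns: np.ndarray,
                                   weights: np.ndarray, n_states: int,
                                   taxon_order: dict[str, int],
                                   class_weights: np.ndarray,
                                   P_for_branch, root_freqs: np.ndarray) -> float:
    """Site-mixture log-likelihood with all classes pruned in one traversal.

    ``P_for_branch(node)`` returns a (K, n_states, n_states) stack of the
    per-class transition matrices for the branch above ``node``.
    """
    npat = patterns.shape[0]
    K = len(class_weights)
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        L: np.ndarray | None = None
        for child in node.children:
            P = P_for_branch(child)
            if child.is_leaf:
                states = patterns[:, taxon_order[child.label]]
                if (states != MISSING).all():
                    Lc = P[:, :, states]
                else:
                    ok = states != MISSING
                    Lc = np.ones((K, n_states, npat))
                    Lc[:, :, ok] = P[:, :, states[ok]]
            else:
                Lc = P @ partial.pop(id(child))
            L = Lc if L is None else L * Lc
        m = L.max(axis=(0, 1))
        if m.min() < 1e-120:
            safe = np.where(m > 0, m, 1.0)
            L /= safe
            logscale += np.log(safe)
        partial[id(node)] = L
    per_class = np.einsum("j,kjp->kp", root_freqs, partial[id(tree.root)])
    total = np.clip(class_weights @ per_class, 1e-310, None)
    return float(np.sum(weights * (np.log(total) + logscale)))


def mixture_log_likelihood(tree: PhyloTree, patterns: np.ndarray, weights: np.ndarray,
                           n_states: int, taxon_order: dict[str, int],
                           components) -> float:
    """Log-likelihood of a site mixture.

    ``components`` is a list of (mixture_weight, P_for_branch, root_freqs).
    Per-pattern likelihoods are averaged over components with their weights.
    """
    per_comp = []
    scales = []
    for w, P_fn, freqs in components:
        lik, logscale = pattern_likelihoods(tree, patterns, n_states, taxon_order, P_fn, freqs)
        per_comp.append(w * lik)
        scales.append(logscale)
    scales = np.array(scales)
    ref = scales.max(axis=0)
    total = np.zeros(patterns.shape[0])
    for comp_lik, s in zip(per_comp, scales):
        total += comp_lik * np.exp(s - ref)
    total = np.clip(total, 1e-310, None)
    return float(np.sum(weights * (np.log(total) + ref)))
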