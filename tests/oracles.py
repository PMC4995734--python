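"""Independent reference implementations used only as test oracles.

Deliberately naive and written separately from the package: dense loops,
no shared code, no attention to speed.  Each oracle answers a question the
package answers by a different route, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --------------------------------------------------------------------------- Gotoh alignment
def gotoh_align(a: str, b: str, sub, gap_open: float = -11.0, gap_extend: float = -1.0):
    """Affine-gap global alignment by the three-matrix recurrence.

    Returns (score, aligned_a, aligned_b) from a deterministic traceback
    (diagonal preferred, then up, then left).
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = [M[i, j], X[i, j], Y[i, j]][state]
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sub[a[i - 1]][b[j - 1]]
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            prev = [M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                    Y[i - 1, j] + gap_open]
            state = int(np.argmax(prev))
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            prev = [M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend]
            state = [0, 2][int(np.argmax(prev))]
            j -= 1
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def identity_coverage(aligned_a: str, aligned_b: str) -> tuple[float, float]:
    cols = len(aligned_a)
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    paired = sum(x != "-" and y != "-" for x, y in zip(aligned_a, aligned_b))
    la = sum(x != "-" for x in aligned_a)
    lb = sum(y != "-" for y in aligned_b)
    return 100.0 * matches / cols, 100.0 * min(paired / la, paired / lb)


# --------------------------------------------------------------------------- naive MCL
def naive_mcl(adjacency: np.ndarray, inflation: float = 2.0, max_iter: int = 200,
              tol: float = 1e-6) -> list[set[int]]:
    """Plain-loop Markov clustering with max-incident-weight self-loops."""
    A = np.array(adjacency, dtype=float)
    n = A.shape[0]
    for i in range(n):
        mx = A[i].max()
        A[i, i] = mx if mx > 0 else 1.0
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        M2 = M @ M
        M2 = M2 ** inflation
        M2 = M2 / M2.sum(axis=0)
        M2[M2 < 1e-12] = 0.0
        if np.abs(M2 - M).max() < tol:
            M = M2
            break
        M = M2
    # clusters: connected components of the support
    seen, clusters = set(), []
    support = M > 1e-9
    adj = support | support.T
    for start in range(n):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(int(u) for u in np.nonzero(adj[v])[0])
        seen |= comp
        clusters.append(comp)
    return clusters


# --------------------------------------------------------------------------- likelihood enumeration
def enumerate_tree_likelihood(tree, column: dict[str, int], P_of_node, root_freqs):
    """Column likelihood by explicit summation over internal-node states.

    ``column`` maps leaf label -> observed state (or None for missing).
    ``P_of_node(node)`` gives the branch transition matrix above ``node``.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    n_states = len(root_freqs)
    total = 0.0
    for assignment in itertools.product(range(n_states), repeat=len(internals)):
        state_of = {id(n): s for n, s in zip(internals, assignment)}
        prob = root_freqs[state_of[id(tree.root)]]
        for node in tree.postorder():
            if node is tree.root:
                continue
            parent_state = state_of[id(node.parent)]
            if node.is_leaf:
                obs = column[node.label]
                if obs is None:
                    continue  # missing: sums over states, i.e. contributes 1
                prob_factor = P_of_node(node)[parent_state, obs]
            else:
                prob_factor = P_of_node(node)[parent_state, state_of[id(node)]]
            prob *= prob_factor
        total += prob
    return total


# --------------------------------------------------------------------------- misc
def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Term-by-term exact summation of P(X >= k)."""
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i) for i in range(k, n + 1))


def jaccard(a: set, b: set) -> float:
    union = a | b
    return 1.0 - len(a & b) / len(union) if union else 0.0


def adjusted_rand_index(labels_a: list[int], labels_b: list[int]) -> float:
    from collections import Counter
    n = len(labels_a)
    pairs_a = Counter(labels_a)
    pairs_b = Counter(labels_b)
    joint = Counter(zip(labels_a, labels_b))
    comb = lambda x: x * (x - 1) // 2
    sum_ab = sum(comb(c) for c in joint.values())
    sum_a = sum(comb(c) for c in pairs_a.values())
    sum_b = sum(comb(c) for c in pairs_b.values())
    total = comb(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ab - expected) / (max_index - expected)


# --------------------------------------------------------------------------- codon model
def gy_raw_matrix(kappa: float, omega: float, freqs):
    """Unnormalised Goldman-Yang codon generator, built by explicit loops
    with the genetic code taken from Biopython (independent of the package).

    Returns (Q_raw, mu) with mu the equilibrium substitution rate; in a
    site mixture whose classes share the scale s = sum_k p_k mu_k, the
    class-k transition matrix over branch length t is expm(Q_raw_k * t / s).
    """
    from Bio.Seq import Seq
    stops = {"TAA", "TAG", "TGA"}
    codons = sorted(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in stops)
    aa = {c: str(Seq(c).translate()) for c in codons}
    n = len(codons)
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(codons[i], codons[j]) if x != y]
            if len(diffs) != 1:
                continue
            x, y = diffs[0]
            rate = freqs[j]
            if (x in "AG") == (y in "AG"):
                rate *= kappa
            if aa[codons[i]] != aa[codons[j]]:
                rate *= omega
            Q[i, j] = rate
    for i in range(n):
        Q[i, i] = -Q[i].sum()
    mu = -sum(freqs[i] * Q[i, i] for i in range(n))
    return Q, mu
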