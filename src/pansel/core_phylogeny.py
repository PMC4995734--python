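"""Core-genome phylogeny: per-family alignment, codon back-translation,
supermatrix filtering, and GTR+Gamma4 maximum-likelihood inference.

The chain mirrors the usual bacterial core-genome workflow at gene level:
single-copy core families are aligned as proteins, back-translated to codon
alignments, concatenated, stripped of gapped and hyper-divergent columns,
and a tree is inferred (neighbor-joining topology, maximum-likelihood branch
lengths and GTR+Gamma4 parameters) with bootstrap support from column
resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from ._likelihood import (MISSING, ReversibleGenerator, compress_patterns,
                          discrete_gamma_rates, mixture_log_likelihood)
from ._seq import NUCLEOTIDES, STOP_CODONS, translate_cds
from .gene_content import DistanceMatrix
from .tree import PhyloTree, TreeNode

NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


# --------------------------------------------------------------------------- types
@dataclass
class Msa:
    """Aligned sequences of equal length with '-' as the gap character."""

    labels: list[str]
    rows: list[str]
    alphabet: str = "protein"  # or "nucleotide"

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n{row}\n")


@dataclass
class CodonAlignment:
    labels: list[str]
    rows: list[str]  # length divisible by 3; gaps only as whole '---' codons

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")
        L = next(iter(lengths), 0)
        if L % 3:
            raise ValueError("codon alignment length not divisible by 3")
        for lab, row in zip(self.labels, self.rows):
            for k in range(0, L, 3):
                codon = row[k:k + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(f"partial-codon gap in {lab} at codon {k // 3 + 1}")
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {lab} at codon {k // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon(self, i: int, j: int) -> str:
        return self.rows[i][3 * j:3 * j + 3]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n{row}\n")


@dataclass
class NucModelParams:
    """GTR exchangeabilities (r_GT == 1 for identifiability), base frequencies
    in A,C,G,T order, and the gamma shape of the 4-category rate model."""

    rates: tuple[float, float, float, float, float, float] = (1, 1, 1, 1, 1, 1)
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("GTR exchangeabilities must be positive")
        if abs(sum(self.freqs) - 1) > 1e-8 or any(f <= 0 for f in self.freqs):
            raise ValueError("base frequencies must be a positive simplex")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")


@dataclass
class FilterPolicy:
    drop_gap_columns: bool = True
    divergence_rule: float = 0.5  # minimum majority-residue fraction to keep

    def __post_init__(self) -> None:
        if not 0 < self.divergence_rule <= 1:
            raise ValueError("divergence_rule must lie in (0, 1]")


# --------------------------------------------------------------------------- alignment
_SCORE_MATCH, _SCORE_MISMATCH, _SCORE_GAP = 2.0, -1.0, -2.0


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    union = len(ka | kb)
    return 1.0 - len(ka & kb) / union if union else 0.0


def _profile_score(col_a: list[str], col_b: list[str]) -> float:
    s = 0.0
    for x in col_a:
        for y in col_b:
            if x == "-" or y == "-":
                s += _SCORE_GAP if (x == "-") != (y == "-") else 0.0
            else:
                s += _SCORE_MATCH if x == y else _SCORE_MISMATCH
    return s / (len(col_a) * len(col_b))


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch on column profiles with linear gap costs."""
    cols_a = [[r[j] for r in rows_a] for j in range(len(rows_a[0]))] if rows_a[0] else []
    cols_b = [[r[j] for r in rows_b] for j in range(len(rows_b[0]))] if rows_b[0] else []
    n, m = len(cols_a), len(cols_b)
    F = np.zeros((n + 1, m + 1))
    F[:, 0] = np.arange(n + 1) * _SCORE_GAP
    F[0, :] = np.arange(m + 1) * _SCORE_GAP
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = F[i - 1, j - 1] + _profile_score(cols_a[i - 1], cols_b[j - 1])
            up = F[i - 1, j] + _SCORE_GAP
            left = F[i, j - 1] + _SCORE_GAP
            best = max(diag, up, left)
            F[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append("-")
            i -= 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            j -= 1
    return (["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b])


def progressive_align(sequences: list[tuple[str, str]], alphabet: str = "protein") -> Msa:
    """Progressive multiple alignment: k-mer guide tree + profile merges.

    Deterministic; a single sequence is returned unchanged with a warning.
    """
    if len(sequences) == 1:
        warnings.warn("single sequence: returned unaligned")
        lab, seq = sequences[0]
        return Msa([lab], [seq], alphabet)
    labels = [lab for lab, _ in sequences]
    seqs = {lab: s for lab, s in sequences}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[labels[i]], seqs[labels[j]])
    from .gene_content import upgma  # deferred: avoids import cycle at module load

    guide = upgma(DistanceMatrix(labels, d))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [seqs[node.label]]
        sub = [merge(c) for c in node.children]
        labs, rows = sub[0]
        for labs_b, rows_b in sub[1:]:
            rows, rows_b = _profile_align(rows, rows_b)
            labs = labs + labs_b
            rows = rows + rows_b
        return labs, rows

    labs, rows = merge(guide.root)
    order = {lab: i for i, lab in enumerate(labs)}
    rows = [rows[order[lab]] for lab in labels]
    return Msa(labels, rows, alphabet)


def sum_of_pairs_score(msa: Msa) -> float:
    """Sum over columns and sequence pairs of match/mismatch/gap scores."""
    total = 0.0
    for j in range(msa.n_columns):
        col = msa.column(j)
        for a in range(len(col)):
            for b in range(a + 1, len(col)):
                x, y = col[a], col[b]
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += _SCORE_GAP
                else:
                    total += _SCORE_MATCH if x == y else _SCORE_MISMATCH
    return total


# --------------------------------------------------------------------------- back-translation
def backtranslate(protein_msa: Msa, cds_map: dict[str, str]) -> CodonAlignment:
    """Replace each aligned residue by its codon and each gap by '---'.

    Every CDS must translate exactly to its ungapped protein row (a terminal
    stop codon is allowed and stripped).
    """
    rows = []
    for lab, prow in zip(protein_msa.labels, protein_msa.rows):
        if lab not in cds_map:
            raise ValueError(f"no CDS provided for {lab}")
        cds = cds_map[lab].upper()
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prow.replace("-", "")
        translated = translate_cds(cds, allow_terminal_stop=False)
        if translated != ungapped.upper():
            for k, (x, y) in enumerate(zip(translated, ungapped.upper())):
                if x != y:
                    raise ValueError(
                        f"CDS of {lab} translates to {x!r} but alignment has {y!r} "
                        f"at residue {k + 1}")
            raise ValueError(f"CDS/protein length mismatch for {lab}: "
                             f"{len(translated)} vs {len(ungapped)} residues")
        out, k = [], 0
        for ch in prow:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * k:3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(list(protein_msa.labels), rows)


# --------------------------------------------------------------------------- concatenate + filter
@dataclass
class KeptColumn:
    source_index: int      # which input alignment
    original_column: int   # 1-based within that alignment (codon units for codons)


def concatenate_and_filter(alignments, policy: FilterPolicy | None = None):
    """Concatenate same-label alignments and drop gapped/divergent columns.

    A column is removed if it contains any gap (when ``drop_gap_columns``)
    or if the fraction of rows sharing the majority residue falls below
    ``divergence_rule``.  Returns the filtered supermatrix plus a report
    mapping each kept column to (source alignment, original 1-based column).
    """
    if policy is None:
        policy = FilterPolicy()
    if not alignments:
        raise ValueError("no alignments to concatenate")
    is_codon = isinstance(alignments[0], CodonAlignment)
    base_labels = sorted(alignments[0].labels)
    for k, aln in enumerate(alignments):
        if sorted(aln.labels) != base_labels:
            missing = sorted(set(base_labels) ^ set(aln.labels))
            raise ValueError(f"label set mismatch in alignment {k}: {missing}")

    kept_units: list[list[str]] = [[] for _ in base_labels]
    report: list[KeptColumn] = []
    for src, aln in enumerate(alignments):
        order = [aln.labels.index(lab) for lab in base_labels]
        n_units = aln.n_codons if is_codon else aln.n_columns
        for j in range(n_units):
            if is_codon:
                unit = [aln.codon(i, j) for i in order]
                has_gap = any(u == "---" for u in unit)
            else:
                col = aln.column(j)
                unit = [col[i] for i in order]
                has_gap = "-" in unit
            if policy.drop_gap_columns and has_gap:
                continue
            residues = [u for u in unit if u != ("---" if is_codon else "-")]
            if residues:
                top = max(residues.count(r) for r in set(residues))
                if top / len(residues) < policy.divergence_rule:
                    continue
            for row, u in zip(kept_units, unit):
                row.append(u)
            report.append(KeptColumn(src, j + 1))
    rows = ["".join(r) for r in kept_units]
    if is_codon:
        return CodonAlignment(base_labels, rows), report
    return Msa(base_labels, rows, alignments[0].alphabet), report


# --------------------------------------------------------------------------- NJ
def nj_topology(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining (Q-criterion) tree; negative branch lengths clamped."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(lab) for lab in dm.labels]
    D = dm.d.astype(float).copy()
    active = list(range(n))
    clamped = False
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        parent = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new[:-1]
        D[:-1, -1] = new[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three around an unrooted "root"
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if min(la, lb, lc) < 0:
        clamped = True
    for k, L in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = max(L, 0.0)
        root.add_child(nodes[k])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return PhyloTree(root)


# --------------------------------------------------------------------------- GTR+Gamma
def gtr_rate_matrix(params: NucModelParams) -> np.ndarray:
    """GTR generator in A,C,G,T order, scaled to one expected substitution
    per unit branch length at equilibrium."""
    rAC, rAG, rAT, rCG, rCT, rGT = params.rates
    pi = np.asarray(params.freqs)
    R = np.array([[0, rAC, rAG, rAT],
                  [rAC, 0, rCG, rCT],
                  [rAG, rCG, 0, rGT],
                  [rAT, rCT, rGT, 0]], dtype=float)
    Q = R * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    return Q / mu


def _encode_nuc(msa: Msa) -> np.ndarray:
    cols = np.full((msa.n_columns, len(msa.labels)), MISSING, dtype=np.int64)
    for i, row in enumerate(msa.rows):
        for j, ch in enumerate(row.upper()):
            cols[j, i] = NUC_INDEX.get(ch, MISSING)
    return cols


def gtr_gamma_loglik(alignment: Msa, tree: PhyloTree, params: NucModelParams) -> float:
    """GTR+Gamma4 log-likelihood by pruning over compressed site patterns."""
    if alignment.n_columns == 0:
        raise ValueError("zero-length alignment")
    labels = set(alignment.labels)
    if set(tree.leaf_labels()) != labels:
        raise ValueError("tree leaves do not match alignment labels")
    patterns, weights = compress_patterns(_encode_nuc(alignment))
    return _gtr_gamma_loglik_patterns(patterns, weights, alignment.labels, tree, params)


def _gtr_gamma_loglik_patterns(patterns, weights, labels, tree, params) -> float:
    taxon_order = {lab: i for i, lab in enumerate(labels)}
    Q = gtr_rate_matrix(params)
    gen = ReversibleGenerator(Q, np.asarray(params.freqs))
    rates = discrete_gamma_rates(params.alpha, params.n_rate_categories)
    freqs = np.asarray(params.freqs)
    components = []
    for rate in rates:
        cache: dict[int, np.ndarray] = {}

        def P_fn(node, _rate=rate, _cache=cache):
            key = id(node)
            if key not in _cache:
                _cache[key] = gen.transition_matrix(_rate * (node.length or 0.0))
            return _cache[key]

        components.append((1.0 / len(rates), P_fn, freqs))
    return mixture_log_likelihood(tree, patterns, weights, 4, taxon_order, components)


def optimize_branch_lengths_and_params(alignment: Msa, topology: PhyloTree,
                                       init: NucModelParams | None = None,
                                       *, optimize_freqs: bool = False,
                                       maxiter: int = 200):
    """ML fit of branch lengths, GTR exchangeabilities and gamma shape.

    Frequencies default to their empirical values (optimised only on
    request).  Returns (fitted tree, fitted params, log-likelihood, result).
    """
    if init is None:
        init = NucModelParams()
    counts = np.ones(4)
    for row in alignment.rows:
        for ch in row.upper():
            if ch in NUC_INDEX:
                counts[NUC_INDEX[ch]] += 1
    emp_freqs = tuple(counts / counts.sum())
    if not optimize_freqs:
        init = replace(init, freqs=emp_freqs)

    tree = topology.copy()
    branches = [n for n in tree.postorder() if n is not tree.root]
    for b in branches:
        if b.length is None or b.length <= 0:
            b.length = 0.01
    patterns, weights = compress_patterns(_encode_nuc(alignment))

    def unpack(x):
        bl = np.exp(x[:len(branches)])
        rates = tuple(np.exp(x[len(branches):len(branches) + 5])) + (1.0,)
        alpha = float(np.exp(x[len(branches) + 5]))
        if optimize_freqs:
            raw = np.exp(x[len(branches) + 6:len(branches) + 9])
            f = np.concatenate([raw, [1.0]])
            freqs = tuple(f / f.sum())
        else:
            freqs = emp_freqs
        return bl, NucModelParams(rates, freqs, alpha)

    def negll(x):
        bl, params = unpack(x)
        for b, L in zip(branches, bl):
            b.length = float(L)
        try:
            return -_gtr_gamma_loglik_patterns(patterns, weights, alignment.labels, tree, params)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    x0 = np.concatenate([
        np.log([b.length for b in branches]),
        np.log(np.asarray(init.rates[:5], dtype=float)),
        [np.log(init.alpha)],
        np.zeros(3) if optimize_freqs else [],
    ])
    ll0 = -negll(x0)
    bounds = [(np.log(1e-8), np.log(50.0))] * len(branches) + \
             [(np.log(1e-4), np.log(1e4))] * 5 + [(np.log(0.02), np.log(100.0))] + \
             ([(-20, 20)] * 3 if optimize_freqs else [])
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    x_best = res.x if -res.fun >= ll0 else x0
    ll = max(-res.fun, ll0)
    if not np.isfinite(ll):
        raise RuntimeError(f"non-finite likelihood during optimisation: {res}")
    bl, params = unpack(x_best)
    for b, L in zip(branches, bl):
        b.length = float(L)
    return tree, params, float(ll), res


# --------------------------------------------------------------------------- distances + bootstrap
def jc_distance_matrix(alignment: Msa) -> DistanceMatrix:
    """Jukes-Cantor-corrected pairwise distances (p-distance fallback when
    saturated); pairwise-complete over non-gap columns."""
    n = len(alignment.labels)
    enc = _encode_nuc(alignment).T  # (taxa, sites)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (enc[i] != MISSING) & (enc[j] != MISSING)
            total = ok.sum()
            p = np.mean(enc[i][ok] != enc[j][ok]) if total else 0.0
            if p < 0.7499:
                dij = -0.75 * np.log(1 - 4.0 * p / 3.0)
            else:
                dij = 5.0  # saturated; large but finite
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(alignment.labels), d)


def bootstrap_support(alignment: Msa, tree: PhyloTree, n_replicates: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """Column-resampling bootstrap; support = % replicates containing each
    bipartition of ``tree``.  Replicate trees come from NJ on JC distances."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[k] for k in idx) for row in alignment.rows]
        rep = Msa(list(alignment.labels), rows, alignment.alphabet)
        try:
            rep_tree = nj_topology(jc_distance_matrix(rep))
        except ValueError:
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    out = tree.copy()
    all_leaves = frozenset(out.leaf_labels())
    ref = min(all_leaves)
    for node in out.postorder():
        if node.is_leaf or node is out.root:
            continue
        side = frozenset(l.label for l in PhyloTree(node).leaves())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_replicates
    return out
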