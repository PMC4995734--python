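"""Codon-model positive-selection scan.

Implements Goldman–Yang-style codon substitution models with site-class
mixtures over omega = dN/dS:

* **M1a** ("nearly neutral"): two site classes, omega_0 in (0,1] and
  omega_1 = 1, with proportions p_0 and 1-p_0.
* **M2a** ("positive selection"): adds a third class omega_2 >= 1 with
  proportion p_2; compared to M1a by a chi-square LRT with 2 df.
* **Branch-site model A**: four site classes (0, 1, 2a, 2b).  Background
  branches evolve under omega_0 or 1; on the designated *foreground*
  branch(es), classes 2a/2b evolve under omega_2 >= 1.  The null model
  fixes omega_2 = 1; the LRT has 1 df.

omega > 1 on a class signals positive selection, omega < 1 purifying
selection, omega = 1 neutrality.  Likelihoods use Felsenstein pruning over
compressed codon-site patterns with transition matrices from the
eigendecomposition of the reversible generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ._likelihood import (MISSING, ReversibleGenerator, compress_patterns,
                          mixture_log_likelihood_batched)
from ._seq import CODON_INDEX, NUCLEOTIDES, SENSE_CODONS, is_transition
from .core_phylogeny import CodonAlignment
from .pangenome import GeneFamily, split_qualified
from .tree import PhyloTree

N_CODONS = len(SENSE_CODONS)  # 61


# --------------------------------------------------------------------------- params
@dataclass
class CodonModelParams:
    """kappa, codon equilibrium frequencies, and site classes.

    ``site_classes`` holds (proportion, background omega, foreground omega)
    triples; for the site models the two omegas coincide on every class.
    """

    kappa: float
    freqs: np.ndarray  # 61 sense-codon frequencies
    site_classes: list[tuple[float, float, float]]
    model_tag: str = "custom"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.freqs.shape != (N_CODONS,) or abs(self.freqs.sum() - 1) > 1e-6 \
                or (self.freqs <= 0).any():
            raise ValueError("freqs must be a positive 61-simplex")
        props = [p for p, _, _ in self.site_classes]
        if any(p < -1e-12 for p in props) or abs(sum(props) - 1) > 1e-6:
            raise ValueError("site-class proportions must be a simplex")
        if any(w < 0 for _, wb, wf in self.site_classes for w in (wb, wf)):
            raise ValueError("omega values must be non-negative")


def m1a_params(p0: float, omega0: float, kappa: float, freqs: np.ndarray) -> CodonModelParams:
    return CodonModelParams(kappa, freqs,
                            [(p0, omega0, omega0), (1 - p0, 1.0, 1.0)], "M1a")


def m2a_params(p0: float, p1: float, omega0: float, omega2: float,
               kappa: float, freqs: np.ndarray) -> CodonModelParams:
    p2 = 1.0 - p0 - p1
    return CodonModelParams(kappa, freqs,
                            [(p0, omega0, omega0), (p1, 1.0, 1.0), (p2, omega2, omega2)],
                            "M2a")


def branch_site_params(p0: float, p1: float, omega0: float, omega2: float,
                       kappa: float, freqs: np.ndarray, *, null: bool = False
                       ) -> CodonModelParams:
    """PAML model A: classes 0, 1, 2a, 2b; p2 splits in proportion p0:p1."""
    if null:
        omega2 = 1.0
    p2 = 1.0 - p0 - p1
    denom = p0 + p1
    p2a = p2 * p0 / denom
    p2b = p2 * p1 / denom
    classes = [(p0, omega0, omega0), (p1, 1.0, 1.0),
               (p2a, omega0, omega2), (p2b, 1.0, omega2)]
    return CodonModelParams(kappa, freqs, classes,
                            "branch_site_null" if null else "branch_site_alt")


@dataclass
class LrtResult:
    ll_null: float
    ll_alt: float
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(ll_null: float, ll_alt: float, df: int) -> LrtResult:
    stat = 2.0 * (ll_alt - ll_null)
    if stat < -1e-6:
        raise ValueError(f"LRT statistic {stat:.3g} < -1e-6: alternative fit "
                         "failed to reach the null optimum; refit needed")
    stat = max(stat, 0.0)
    return LrtResult(ll_null, ll_alt, stat, df, float(chi2.sf(stat, df)))


# --------------------------------------------------------------------------- rate matrix
_SINGLE_STEP: list[tuple[int, int, bool, bool]] = []  # (i, j, is_transition, is_synonymous)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        diffs = [(a, b) for a, b in zip(_ci, _cj) if a != b]
        if len(diffs) == 1:
            from ._seq import CODON_TO_AA
            _SINGLE_STEP.append((_i, _j, is_transition(*diffs[0]),
                                 CODON_TO_AA[_ci] == CODON_TO_AA[_cj]))


_STEP_I = np.array([s[0] for s in _SINGLE_STEP])
_STEP_J = np.array([s[1] for s in _SINGLE_STEP])
_STEP_TS = np.array([s[2] for s in _SINGLE_STEP])
_STEP_SYN = np.array([s[3] for s in _SINGLE_STEP])


def _gy_raw(kappa: float, omega: float, freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Unnormalised Goldman–Yang generator and its equilibrium rate mu."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    freqs = np.asarray(freqs, dtype=float)
    rates = freqs[_STEP_J] * np.where(_STEP_TS, kappa, 1.0) \
        * np.where(_STEP_SYN, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_STEP_I, _STEP_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = float(-np.sum(freqs * np.diag(Q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q, mu


def codon_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """61x61 Goldman–Yang generator, one expected substitution per codon.

    Off-diagonal rate to codon j: 0 for multi-nucleotide changes, otherwise
    pi_j x {1, kappa, omega, omega*kappa} for synonymous transversions /
    transitions and nonsynonymous transversions / transitions.

    In site-class mixtures the classes share one time scale (the mixture's
    average rate, computed per branch type), so that high-omega classes
    evolve faster — see :class:`CodonLikelihood`.
    """
    Q, mu = _gy_raw(kappa, omega, freqs)
    return Q / mu


def mixture_scales(params: CodonModelParams) -> tuple[float, float]:
    """Background and foreground average equilibrium rates of the mixture.

    Branch lengths count expected substitutions per codon under the whole
    site mixture; each class k then runs at relative rate mu_k / s.
    """
    s_bg = s_fg = 0.0
    for p, wb, wf in params.site_classes:
        if p <= 0:
            continue
        s_bg += p * _gy_raw(params.kappa, wb, params.freqs)[1]
        s_fg += p * _gy_raw(params.kappa, wf, params.freqs)[1]
    return s_bg, s_fg


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Empirical codon frequencies from position-specific nucleotide counts."""
    counts = np.ones((3, 4))  # +1 pseudo-count keeps the simplex positive
    for row in aln.rows:
        for k in range(0, len(row), 3):
            codon = row[k:k + 3]
            if codon == "---":
                continue
            for pos, ch in enumerate(codon):
                counts[pos, NUCLEOTIDES.index(ch)] += 1
    counts /= counts.sum(axis=1, keepdims=True)
    freqs = np.array([counts[0, NUCLEOTIDES.index(c[0])]
                      * counts[1, NUCLEOTIDES.index(c[1])]
                      * counts[2, NUCLEOTIDES.index(c[2])]
                      for c in SENSE_CODONS])
    return freqs / freqs.sum()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


# --------------------------------------------------------------------------- likelihood
def _encode_codons(aln: CodonAlignment) -> np.ndarray:
    cols = np.full((aln.n_codons, len(aln.labels)), MISSING, dtype=np.int64)
    for i in range(len(aln.labels)):
        for j in range(aln.n_codons):
            codon = aln.codon(i, j)
            if codon != "---":
                if codon not in CODON_INDEX:
                    raise ValueError(f"unexpected codon {codon!r} in {aln.labels[i]} "
                                     f"at codon {j + 1}")
                cols[j, i] = CODON_INDEX[codon]
    return cols


class CodonLikelihood:
    """Pruning likelihood for one codon alignment on a fixed tree.

    Eigensystems of the class generators are cached per (kappa, omega); the
    site classes of a mixture share one time scale per branch type (the
    mixture's average equilibrium rate), so branch lengths are expected
    substitutions per codon under the whole mixture and high-omega classes
    evolve proportionally faster.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 freqs: np.ndarray | None = None):
        if set(tree.leaf_labels()) != set(aln.labels):
            raise ValueError("tree leaves do not match alignment labels")
        self.tree = tree
        self.freqs = f3x4_frequencies(aln) if freqs is None else np.asarray(freqs)
        self.patterns, self.weights = compress_patterns(_encode_codons(aln))
        self.taxon_order = {lab: i for i, lab in enumerate(aln.labels)}
        self.n_codons = aln.n_codons
        self._gen_cache: dict[tuple[float, float], tuple[ReversibleGenerator, float]] = {}

    def _gen(self, kappa: float, omega: float) -> tuple[ReversibleGenerator, float]:
        key = (kappa, omega)
        if key not in self._gen_cache:
            if len(self._gen_cache) > 512:
                self._gen_cache.clear()
            Q, mu = _gy_raw(kappa, omega, self.freqs)
            self._gen_cache[key] = (ReversibleGenerator(Q / mu, self.freqs), mu)
        return self._gen_cache[key]

    def loglik(self, params: CodonModelParams, scale: float = 1.0) -> float:
        gens = {}
        s_bg = s_fg = 0.0
        for p, wb, wf in params.site_classes:
            if p <= 0:
                continue
            for w in (wb, wf):
                if w not in gens:
                    gens[w] = self._gen(params.kappa, w)
            s_bg += p * gens[wb][1]
            s_fg += p * gens[wf][1]
        active = [(p, wb, wf) for p, wb, wf in params.site_classes if p > 0]
        class_weights = np.array([p for p, _, _ in active])
        P_memo: dict[tuple[int, float], np.ndarray] = {}

        def single_P(node, w, rel):
            key = (id(node), w)
            P = P_memo.get(key)
            if P is None:
                P = gens[w][0].transition_matrix(scale * (node.length or 0.0) * rel)
                P_memo[key] = P
            return P

        def P_batched(node):
            if node.foreground:
                return np.stack([single_P(node, wf, gens[wf][1] / s_fg)
                                 for _, _, wf in active])
            return np.stack([single_P(node, wb, gens[wb][1] / s_bg)
                             for _, wb, _ in active])

        return mixture_log_likelihood_batched(
            self.tree, self.patterns, self.weights, N_CODONS, self.taxon_order,
            class_weights, P_batched, self.freqs)


def codon_site_loglik(aln: CodonAlignment, tree: PhyloTree,
                      params: CodonModelParams) -> float:
    """One-shot site/branch-site mixture log-likelihood (convenience wrapper)."""
    if params.model_tag.startswith("branch_site") and \
            not any(n.foreground for n in tree.postorder()):
        raise ValueError("branch-site model requires a marked foreground branch")
    return CodonLikelihood(aln, tree, params.freqs).loglik(params)


# --------------------------------------------------------------------------- fitting
def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-8), 1 - 1e-8)
    return math.log(p / (1 - p))


@dataclass
class ModelFit:
    params: CodonModelParams
    ll: float
    converged: bool


@dataclass
class SiteModelFits:
    m1a: ModelFit
    m2a: ModelFit


@dataclass
class BranchSiteFits:
    null: ModelFit
    alt: ModelFit


def estimate_branch_lengths_m0(aln: CodonAlignment, tree: PhyloTree,
                               freqs: np.ndarray | None = None,
                               maxiter: int = 60, *, _lik: CodonLikelihood | None = None
                               ) -> tuple[PhyloTree, float, float]:
    """Fit a single-omega (M0) model with a global branch-length scale.

    The input tree's relative branch lengths are kept; one scale factor,
    kappa and omega are optimised.  Returns (rescaled tree, kappa, omega).
    """
    if _lik is not None:
        work, lik = _lik.tree, _lik
    else:
        work = tree.copy()
        for n in work.postorder():
            if n is not work.root and (n.length is None or n.length <= 0):
                n.length = 0.02
        lik = CodonLikelihood(aln, work, freqs)

    def negll(x):
        kappa, omega, scale = np.exp(x)
        try:
            params = CodonModelParams(kappa, lik.freqs, [(1.0, omega, omega)], "M0")
            return -lik.loglik(params, scale=scale)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    res = minimize(negll, np.log([2.0, 0.5, 1.0]), method="L-BFGS-B",
                   bounds=[(np.log(0.05), np.log(50)), (np.log(1e-4), np.log(20)),
                           (np.log(1e-3), np.log(1e3))],
                   options={"maxiter": maxiter})
    kappa, omega, scale = np.exp(res.x)
    for n in work.postorder():
        if n is not work.root:
            n.length = float(n.length * scale)
    return work, float(kappa), float(omega)


def _fit(lik: CodonLikelihood, build, x0_list, bounds, maxiter: int = 80
         ) -> tuple[np.ndarray, float, bool]:
    """Maximise loglik(build(x)) from several starts; returns best x, ll, ok."""
    best_x, best_ll, ok = None, -np.inf, False

    def negll(x):
        try:
            return -lik.loglik(build(x))
        except (ValueError, np.linalg.LinAlgError, OverflowError):
            return 1e12

    for x0 in x0_list:
        res = minimize(negll, np.asarray(x0, dtype=float), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-8, "gtol": 1e-4,
                                "eps": 1e-6})
        cand = [(res.x, -res.fun, res.success)]
        cand.append((np.asarray(x0, dtype=float), -negll(np.asarray(x0, dtype=float)), True))
        for x, ll, success in cand:
            if ll > best_ll:
                best_x, best_ll, ok = x, ll, success
    return best_x, best_ll, ok


def fit_site_models(aln: CodonAlignment, tree: PhyloTree, *, n_starts: int = 3,
                    seed: int = 0, freqs: np.ndarray | None = None,
                    maxiter: int = 80, fixed_kappa: float | None = None,
                    _lik: CodonLikelihood | None = None) -> SiteModelFits:
    """ML fits of M1a and M2a on a fixed tree.

    M2a is warm-started from the fitted M1a (its own null), which guarantees
    ll(M2a) >= ll(M1a) up to optimiser tolerance.  ``fixed_kappa`` holds the
    transition/transversion ratio at a given value (e.g. from an M0 fit)
    instead of optimising it per model.
    """
    rng = np.random.default_rng(seed)
    lik = _lik if _lik is not None else CodonLikelihood(aln, tree, freqs)
    F = lik.freqs
    free_kappa = fixed_kappa is None
    kappa_bounds = [(math.log(0.05), math.log(50))] if free_kappa else []

    def kappa_of(x):
        return math.exp(x[-1]) if free_kappa else fixed_kappa

    def build_m1a(x):
        return m1a_params(_sigmoid(x[0]), _sigmoid(x[1]), kappa_of(x), F)

    starts = [[_logit(0.7), _logit(0.2)] + ([math.log(2.0)] if free_kappa else [])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append([_logit(rng.uniform(0.2, 0.95)), _logit(rng.uniform(0.02, 0.8))]
                      + ([math.log(rng.uniform(0.5, 6.0))] if free_kappa else []))
    bounds1 = [(-12, 12), (-12, 12)] + kappa_bounds
    x1, ll1, ok1 = _fit(lik, build_m1a, starts, bounds1, maxiter)
    fit1 = ModelFit(build_m1a(x1), ll1, ok1)
    k1 = [x1[-1]] if free_kappa else []

    # M2a: proportions via stick-breaking (q0 = p0, q1 = p1/(1-p0))
    def build_m2a(x):
        q0, q1 = _sigmoid(x[0]), _sigmoid(x[1])
        p0 = q0
        p1 = (1 - q0) * q1
        return m2a_params(p0, p1, _sigmoid(x[2]), 1.0 + math.exp(x[3]),
                          kappa_of(x), F)

    p0_hat = fit1.params.site_classes[0][0]
    warm = [_logit(p0_hat * 0.98), _logit(0.95), x1[1], math.log(0.05)] + k1
    starts2 = [warm]
    if n_starts > 1:
        starts2.append([_logit(0.6), _logit(0.6), _logit(0.2), math.log(2.0)]
                       + ([math.log(2.0)] if free_kappa else []))
    for _ in range(max(n_starts - 2, 0)):
        starts2.append([_logit(rng.uniform(0.2, 0.9)), _logit(rng.uniform(0.3, 0.95)),
                        _logit(rng.uniform(0.05, 0.8)), math.log(rng.uniform(0.1, 6.0))]
                       + ([math.log(rng.uniform(0.5, 6.0))] if free_kappa else []))
    bounds2 = [(-12, 12), (-12, 12), (-12, 12),
               (math.log(1e-6), math.log(50))] + kappa_bounds
    x2, ll2, ok2 = _fit(lik, build_m2a, starts2, bounds2, maxiter)
    if ll2 < ll1:  # enforce nesting: M2a contains M1a (p2 -> 0)
        x_embed = np.array([_logit(p0_hat), _logit(1 - 1e-7), x1[1],
                            math.log(1e-6)] + k1)
        x2e, ll2e, _ = _fit(lik, build_m2a, [x_embed], bounds2, maxiter)
        if ll2e > ll2:
            x2, ll2 = x2e, ll2e
        ll2 = max(ll2, ll1)
    fit2 = ModelFit(build_m2a(x2), ll2, ok2)
    return SiteModelFits(fit1, fit2)


def site_lrt(fits: SiteModelFits) -> LrtResult:
    """M2a vs M1a likelihood-ratio test, chi-square with 2 df."""
    return likelihood_ratio_test(fits.m1a.ll, fits.m2a.ll, df=2)


def fit_branch_site(aln: CodonAlignment, tree: PhyloTree, *, n_starts: int = 3,
                    seed: int = 0, freqs: np.ndarray | None = None,
                    maxiter: int = 80, fixed_kappa: float | None = None,
                    _lik: CodonLikelihood | None = None) -> BranchSiteFits:
    """ML fits of branch-site model A and its omega_2 = 1 null.

    The tree must carry a foreground mark (see PhyloTree.mark_foreground).
    The alternative is warm-started from the fitted null.
    """
    if not any(n.foreground for n in tree.postorder()):
        raise ValueError("no foreground branch marked on the tree")
    rng = np.random.default_rng(seed)
    lik = _lik if _lik is not None else CodonLikelihood(aln, tree, freqs)
    F = lik.freqs
    free_kappa = fixed_kappa is None
    kstart = [math.log(2.0)] if free_kappa else []
    kappa_bounds = [(math.log(0.05), math.log(50))] if free_kappa else []

    def props(x0, x1):
        q0, q1 = _sigmoid(x0), _sigmoid(x1)
        return q0, (1 - q0) * q1

    def build_null(x):
        p0, p1 = props(x[0], x[1])
        kappa = math.exp(x[3]) if free_kappa else fixed_kappa
        return branch_site_params(p0, p1, _sigmoid(x[2]), 1.0, kappa, F, null=True)

    starts_null = [[_logit(0.65), _logit(0.8), _logit(0.2)] + kstart]
    for _ in range(max(n_starts - 1, 0)):
        starts_null.append(
            [_logit(rng.uniform(0.2, 0.9)), _logit(rng.uniform(0.3, 0.95)),
             _logit(rng.uniform(0.05, 0.8))]
            + ([math.log(rng.uniform(0.5, 6.0))] if free_kappa else []))
    bounds_null = [(-12, 12), (-12, 12), (-12, 12)] + kappa_bounds
    xn, lln, okn = _fit(lik, build_null, starts_null, bounds_null, maxiter)
    null_fit = ModelFit(build_null(xn), lln, okn)
    kn = [xn[3]] if free_kappa else []

    def build_alt(x):
        p0, p1 = props(x[0], x[1])
        kappa = math.exp(x[4]) if free_kappa else fixed_kappa
        return branch_site_params(p0, p1, _sigmoid(x[2]), 1.0 + math.exp(x[3]),
                                  kappa, F)

    warm = [xn[0], xn[1], xn[2], math.log(1e-6)] + kn
    starts_alt = [warm, [xn[0], xn[1], xn[2], math.log(2.0)] + kn]
    for _ in range(max(n_starts - 2, 0)):
        starts_alt.append(
            [_logit(rng.uniform(0.2, 0.9)), _logit(rng.uniform(0.3, 0.95)),
             _logit(rng.uniform(0.05, 0.8)), math.log(rng.uniform(0.1, 8.0))]
            + ([math.log(rng.uniform(0.5, 6.0))] if free_kappa else []))
    bounds_alt = [(-12, 12), (-12, 12), (-12, 12),
                  (math.log(1e-6), math.log(50))] + kappa_bounds
    xa, lla, oka = _fit(lik, build_alt, starts_alt, bounds_alt, maxiter)
    lla = max(lla, lln)  # nesting: alt contains the null at omega_2 = 1
    alt_fit = ModelFit(build_alt(xa), lla, oka)
    return BranchSiteFits(null_fit, alt_fit)


def branch_site_lrt(fits: BranchSiteFits) -> LrtResult:
    """Branch-site model A vs its omega_2 = 1 null, chi-square with 1 df."""
    return likelihood_ratio_test(fits.null.ll, fits.alt.ll, df=1)


# --------------------------------------------------------------------------- scan
@dataclass
class SelectionScanRow:
    family_id: str
    n_codons: int
    ll_m1a: float
    ll_m2a: float
    site: LrtResult
    ll_bs_null: float
    ll_bs_alt: float
    branch_site: LrtResult
    omega2_site: float
    omega2_branch: float
    selected_site: bool
    selected_branch: bool
    note: str = ""


@dataclass
class SelectionScanSummary:
    n_tested: int
    n_selected_site: int
    n_selected_branch: int
    pct_selected_site: float
    pct_selected_branch: float
    n_branch_only: int
    n_shared: int
    skipped: dict[str, str] = field(default_factory=dict)


def _is_single_copy_core(family: GeneFamily, genome_ids: list[str]) -> bool:
    genomes = [split_qualified(m)[0] for m in family.members]
    return sorted(genomes) == sorted(genome_ids)


def scan_core_genes(families: list[GeneFamily], alignments: dict[str, CodonAlignment],
                    tree: PhyloTree, foreground: set[str] | str, alpha: float = 0.05,
                    *, foreground_clade: bool = True, n_starts: int = 1, seed: int = 0,
                    fix_kappa: bool = True
                    ) -> tuple[list[SelectionScanRow], SelectionScanSummary]:
    """Site and branch-site selection tests on every single-copy core family.

    ``alignments`` maps family_id to a codon alignment whose labels are
    genome ids.  Families that are not single-copy core are skipped with a
    reason; a failed fit flags the row rather than aborting the scan.

    Per gene, branch lengths and (by default) kappa are estimated once under
    a single-omega M0 model and held fixed across the four model fits.
    """
    genome_ids = tree.leaf_labels()
    marked = tree.copy()
    marked.mark_foreground(foreground, clade=foreground_clade)
    rows: list[SelectionScanRow] = []
    skipped: dict[str, str] = {}
    for family in families:
        fid = family.family_id
        if fid not in alignments:
            skipped[fid] = "no alignment"
            continue
        if not _is_single_copy_core(family, genome_ids):
            skipped[fid] = "not single-copy core"
            continue
        aln = alignments[fid]
        try:
            work = marked.copy()
            for n in work.postorder():
                if n is not work.root and (n.length is None or n.length <= 0):
                    n.length = 0.02
            lik = CodonLikelihood(aln, work)
            fitted_tree, kappa0, _ = estimate_branch_lengths_m0(aln, work, _lik=lik)
            kf = kappa0 if fix_kappa else None
            site_fits = fit_site_models(aln, fitted_tree, n_starts=n_starts,
                                        seed=seed, fixed_kappa=kf, _lik=lik)
            s_lrt = site_lrt(site_fits)
            bs_fits = fit_branch_site(aln, fitted_tree, n_starts=n_starts,
                                      seed=seed, fixed_kappa=kf, _lik=lik)
            b_lrt = branch_site_lrt(bs_fits)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"selection fit failed for {fid}: {exc}")
            skipped[fid] = f"fit failed: {exc}"
            continue
        note = "" if (site_fits.m2a.converged and bs_fits.alt.converged) else "non-converged"
        rows.append(SelectionScanRow(
            fid, aln.n_codons, site_fits.m1a.ll, site_fits.m2a.ll, s_lrt,
            bs_fits.null.ll, bs_fits.alt.ll, b_lrt,
            site_fits.m2a.params.site_classes[2][1],
            bs_fits.alt.params.site_classes[2][2],
            s_lrt.p_value < alpha, b_lrt.p_value < alpha, note))
    n = len(rows)
    n_site = sum(r.selected_site for r in rows)
    n_branch = sum(r.selected_branch for r in rows)
    n_shared = sum(r.selected_site and r.selected_branch for r in rows)
    summary = SelectionScanSummary(
        n, n_site, n_branch,
        100.0 * n_site / n if n else 0.0,
        100.0 * n_branch / n if n else 0.0,
        n_branch - n_shared, n_shared, skipped)
    return rows, summary


def write_scan_tsv(rows: list[SelectionScanRow], path) -> None:
    cols = ["family_id", "n_codons", "ll_m1a", "ll_m2a", "site_stat", "site_df",
            "site_p", "ll_bs_null", "ll_bs_alt", "bs_stat", "bs_df", "bs_p",
            "omega2_site", "omega2_branch", "selected_site", "selected_branch", "note"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(map(str, [
                r.family_id, r.n_codons, f"{r.ll_m1a:.6f}", f"{r.ll_m2a:.6f}",
                f"{r.site.statistic:.6f}", r.site.df, f"{r.site.p_value:.6g}",
                f"{r.ll_bs_null:.6f}", f"{r.ll_bs_alt:.6f}",
                f"{r.branch_site.statistic:.6f}", r.branch_site.df,
                f"{r.branch_site.p_value:.6g}",
                f"{r.omega2_site:.4f}", f"{r.omega2_branch:.4f}",
                int(r.selected_site), int(r.selected_branch), r.note])) + "\n")
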