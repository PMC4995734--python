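"""Alignment chain, supermatrix filtering, NJ, and GTR+Gamma4 likelihood."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from pansel.core_phylogeny import (CodonAlignment, FilterPolicy, Msa,
                                   NucModelParams, backtranslate,
                                   bootstrap_support, concatenate_and_filter,
                                   gtr_gamma_loglik, gtr_rate_matrix,
                                   nj_topology,
                                   optimize_branch_lengths_and_params,
                                   progressive_align, sum_of_pairs_score)
from pansel.gene_content import DistanceMatrix, upgma
from pansel._likelihood import discrete_gamma_rates
from pansel.tree import PhyloTree

from oracles import enumerate_tree_likelihood

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        msa = progressive_align([("a", "MKTAYIAK"), ("b", "MKTAYIAK"), ("c", "MKTAYIAK")])
        assert all("-" not in r for r in msa.rows)

    def test_single_deletion_gives_one_gap_column(self):
        msa = progressive_align([("a", "MKTA"), ("b", "MKA")])
        gap_cols = sum("-" in msa.column(j) for j in range(msa.n_columns))
        assert gap_cols == 1 and msa.n_columns == 4

    def test_single_sequence_warns(self):
        with pytest.warns(UserWarning, match="single sequence"):
            msa = progressive_align([("a", "MKTA")])
        assert msa.rows == ["MKTA"]

    def test_sp_score_beats_padding_baseline(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            base = "".join(rng.choice(list(AA), size=40))
            seqs = []
            for k in range(3):
                s = list(base)
                for pos in rng.choice(40, size=4, replace=False):
                    s[pos] = rng.choice(list(AA))
                if rng.random() < 0.5:
                    del s[int(rng.integers(0, len(s)))]
                seqs.append((f"s{k}", "".join(s)))
            msa = progressive_align(seqs)
            width = max(len(s) for _, s in seqs)
            padded = Msa([l for l, _ in seqs],
                         [s + "-" * (width - len(s)) for _, s in seqs])
            assert sum_of_pairs_score(msa) >= sum_of_pairs_score(padded)


class TestBacktranslate:
    def test_gap_becomes_triple_gap(self):
        msa = Msa(["x"], ["M-A"])
        out = backtranslate(msa, {"x": "ATGGCT"})
        assert out.rows == ["ATG---GCT"]

    def test_terminal_stop_stripped(self):
        msa = Msa(["x"], ["MA"])
        out = backtranslate(msa, {"x": "ATGGCTTAA"})
        assert out.rows == ["ATGGCT"]

    def test_translation_mismatch_names_gene_and_position(self):
        msa = Msa(["geneX"], ["MK"])
        with pytest.raises(ValueError, match="geneX.*residue 2"):
            backtranslate(msa, {"geneX": "ATGGCT"})  # translates MA, not MK

    def test_round_trip_on_simulated_family(self):
        from pansel.synthetic_data import regime_params, simulate_codon_alignment
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln, _ = simulate_codon_alignment(tree, regime_params("purifying"), 40, seed=3)
        from pansel._seq import translate_cds
        prots = [(lab, translate_cds(row)) for lab, row in zip(aln.labels, aln.rows)]
        msa = progressive_align(prots)
        back = backtranslate(msa, dict(zip(aln.labels, aln.rows)))
        for lab, row in zip(back.labels, back.rows):
            original = aln.rows[aln.labels.index(lab)]
            assert row.replace("-", "") == original


class TestConcatenateFilter:
    def test_gap_column_removed(self):
        msa = Msa(["a", "b"], ["AC-G", "ACTG"], "nucleotide")
        out, report = concatenate_and_filter([msa])
        assert out.rows == ["ACG", "ACG"]
        assert [r.original_column for r in report] == [1, 2, 4]

    def test_identical_alignment_fully_kept(self):
        msa = Msa(["a", "b", "c"], ["ACGT", "ACGT", "ACGT"], "nucleotide")
        out, _ = concatenate_and_filter([msa])
        assert out.n_columns == 4

    def test_hand_enumerated_mixed_filter(self):
        """3x10 alignment: 2 gap columns + 1 all-distinct column -> 7 kept."""
        rows = ["ACGTACGTAC",
                "AC-TACGTCC",
                "ACGTAC-TGC"]
        # column 3 and 7 have gaps; column 9 is A/C/G (majority 1/3 < 0.5)
        msa = Msa(["a", "b", "c"], rows, "nucleotide")
        out, report = concatenate_and_filter([msa], FilterPolicy(divergence_rule=0.5))
        assert out.n_columns == 7
        assert [r.original_column for r in report] == [1, 2, 4, 5, 6, 8, 10]

    def test_label_mismatch_lists_missing(self):
        a = Msa(["x", "y"], ["AC", "AC"], "nucleotide")
        b = Msa(["x", "z"], ["AC", "AC"], "nucleotide")
        with pytest.raises(ValueError, match="z"):
            concatenate_and_filter([a, b])

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(23)
        rows = ["".join(rng.choice(list("ACGT-"), size=30)) for _ in range(4)]
        msa = Msa([f"s{i}" for i in range(4)], rows, "nucleotide")
        once, _ = concatenate_and_filter([msa])
        twice, _ = concatenate_and_filter([once])
        assert twice.rows == once.rows

    def test_codon_units_filtered_wholesale(self):
        aln = CodonAlignment(["a", "b"], ["ATG---GGG", "ATGAAAGGG"])
        out, _ = concatenate_and_filter([aln])
        assert out.rows == ["ATGGGG", "ATGGGG"]


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); additive distances are exact
        d = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
             ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        labels = list("ABCD")
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_topology(DistanceMatrix(labels, mat))
        assert tree.bipartitions() == {frozenset("CD")} or \
            tree.bipartitions() == {frozenset("AB")}
        # path lengths reproduce the additive input
        for (x, y), v in d.items():
            assert _path_length(tree, x, y) == pytest.approx(v, abs=1e-9)

    def test_star_distances_total_length(self):
        mat = np.full((4, 4), 2.0)
        np.fill_diagonal(mat, 0.0)
        tree = nj_topology(DistanceMatrix(list("ABCD"), mat))
        # every resolution of a star with d=2 has total length 4
        assert tree.total_length() == pytest.approx(4.0)

    def test_ultrametric_matches_upgma_topology(self):
        truth = PhyloTree.from_newick("(((A:1,B:1):2,C:3):1,(D:2,E:2):2);")
        labels = sorted(truth.leaf_labels())
        depths = truth.leaf_depths()
        mat = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    mat[i, j] = mat[j, i] = _cophenetic_from_tree(truth, a, b)
        dm = DistanceMatrix(labels, mat)
        assert nj_topology(dm).robinson_foulds(upgma(dm)) == 0

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            nj_topology(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))


def _path_length(tree, a, b):
    depths = tree.leaf_depths()
    mrca = tree.mrca({a, b})
    d = 0.0
    node = mrca
    while node.parent is not None:
        d += node.length or 0.0
        node = node.parent
    return depths[a] + depths[b] - 2 * d


def _cophenetic_from_tree(tree, a, b):
    return _path_length(tree, a, b)


def _random_params(rng):
    rates = tuple(rng.uniform(0.3, 3.0, size=5)) + (1.0,)
    f = rng.dirichlet([10, 10, 10, 10])
    return NucModelParams(rates, tuple(f), alpha=float(rng.uniform(0.3, 3.0)))


class TestGtrGammaLikelihood:
    def test_identical_sequences_zero_branches(self):
        tree = PhyloTree.from_newick("(A:0,B:0,C:0);")
        msa = Msa(["A", "B", "C"], ["ACGT", "ACGT", "ACGT"], "nucleotide")
        params = NucModelParams()
        ll = gtr_gamma_loglik(msa, tree, params)
        assert ll == pytest.approx(4 * np.log(0.25), abs=1e-10)

    def test_matches_enumeration_oracle(self):
        """4-taxon, 3 sites: pruning equals summation over internal states,
        with oracle transition matrices from scipy expm (independent route)."""
        rng = np.random.default_rng(31)
        tree = PhyloTree.from_newick("((A:0.2,B:0.35):0.1,(C:0.15,D:0.4):0.2);")
        msa = Msa(list("ABCD"), ["ACG", "ATG", "GCG", "ACT"], "nucleotide")
        for _ in range(5):
            params = _random_params(rng)
            ll = gtr_gamma_loglik(msa, tree, params)
            Q = gtr_rate_matrix(params)
            pi = np.asarray(params.freqs)
            rates = discrete_gamma_rates(params.alpha, 4)
            idx = {"A": 0, "C": 1, "G": 2, "T": 3}
            ll_oracle = 0.0
            for site in range(3):
                col = {lab: idx[msa.rows[k][site]] for k, lab in enumerate(msa.labels)}
                site_lik = 0.0
                for rate in rates:
                    P = {id(n): expm(Q * rate * (n.length or 0.0))
                         for n in tree.postorder()}
                    site_lik += 0.25 * enumerate_tree_likelihood(
                        tree, col, lambda n, _P=P: _P[id(n)], pi)
                ll_oracle += np.log(site_lik)
            assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_column_pattern_likelihoods_sum_to_one(self):
        rng = np.random.default_rng(32)
        tree = PhyloTree.from_newick("(A:0.3,B:0.1,C:0.5);")
        params = _random_params(rng)
        total = 0.0
        for pattern in itertools.product("ACGT", repeat=3):
            msa = Msa(list("ABC"), [p for p in pattern], "nucleotide")
            total += np.exp(gtr_gamma_loglik(msa, tree, params))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(33)
        params = _random_params(rng)
        msa = Msa(list("ABCD"), ["ACGTT", "ACGTA", "GGGTA", "ACTTA"], "nucleotide")
        t1 = PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.2);")
        # same unrooted tree, rooted on the A branch instead
        t2 = PhyloTree.from_newick("(A:0.1,(B:0.3,((C:0.25,D:0.15):0.3)):0.1);")
        ll1 = gtr_gamma_loglik(msa, t1, params)
        ll2 = gtr_gamma_loglik(msa, t2, params)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_gaps_treated_as_missing(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.1);")
        params = NucModelParams()
        with_gap = Msa(list("ABC"), ["A-G", "ATG", "ATG"], "nucleotide")
        ll = gtr_gamma_loglik(with_gap, tree, params)
        # marginalising the gap: sum over the 4 completions
        total = 0.0
        for b in "ACGT":
            filled = Msa(list("ABC"), [f"A{b}G", "ATG", "ATG"], "nucleotide")
            total += np.exp(gtr_gamma_loglik(filled, tree, params))
        assert ll == pytest.approx(np.log(total), abs=1e-9)

    def test_empty_alignment_rejected(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.1);")
        with pytest.raises(ValueError):
            gtr_gamma_loglik(Msa(list("ABC"), ["", "", ""], "nucleotide"),
                             tree, NucModelParams())


class TestOptimisation:
    def test_ll_never_decreases_from_truth(self):
        from pansel.synthetic_data import regime_params, simulate_codon_alignment
        tree = PhyloTree.from_newick("((A:0.1,B:0.15):0.05,(C:0.1,D:0.2):0.05);")
        aln, _ = simulate_codon_alignment(tree, regime_params("neutral"), 300, seed=5)
        msa = Msa(aln.labels, aln.rows, "nucleotide")
        params = NucModelParams()
        ll_init = gtr_gamma_loglik(msa, tree, params)
        _, _, ll_fit, _ = optimize_branch_lengths_and_params(msa, tree, params,
                                                            maxiter=60)
        assert ll_fit >= ll_init - 1e-6

    def test_branch_length_recovery(self):
        """Fitted branch lengths land within 15% of truth (median over
        branches) on a 10 kb simulated alignment."""
        # trifurcating root: every branch of the unrooted tree identifiable
        truth = PhyloTree.from_newick(
            "((A:0.08,B:0.12):0.11,C:0.1,D:0.15);")
        msa = _simulate_gtr_gamma(truth, NucModelParams(alpha=1.0), 10_000,
                                  seed=77)
        start = truth.copy()
        for n in start.postorder():
            if n is not start.root:
                n.length = 0.05
        fitted, _, _, _ = optimize_branch_lengths_and_params(msa, start,
                                                             maxiter=120)
        true_lens = {frozenset(_clade(n)): n.length for n in truth.postorder()
                     if n is not truth.root}
        errors = []
        for n in fitted.postorder():
            if n is fitted.root:
                continue
            key = frozenset(_clade(n))
            if key in true_lens and true_lens[key] > 0:
                errors.append(abs(n.length - true_lens[key]) / true_lens[key])
        assert errors and float(np.median(errors)) <= 0.15

    def test_alpha_ordering_recovered(self):
        """Rate heterogeneity strength is identifiable: data at alpha=0.5
        yields a smaller fitted alpha than data at alpha=5."""
        tree = PhyloTree.from_newick("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);")
        fitted = {}
        for true_alpha, seed in ((0.5, 11), (5.0, 12)):
            msa = _simulate_gtr_gamma(tree, NucModelParams(alpha=true_alpha),
                                      3000, seed)
            _, params, _, _ = optimize_branch_lengths_and_params(msa, tree,
                                                                maxiter=80)
            fitted[true_alpha] = params.alpha
        assert fitted[0.5] < fitted[5.0]


def _clade(node):
    from pansel.tree import _leafset
    return _leafset(node)


def _simulate_gtr_gamma(tree, params, n_sites, seed):
    rng = np.random.default_rng(seed)
    Q = gtr_rate_matrix(params)
    pi = np.asarray(params.freqs)
    rates = discrete_gamma_rates(params.alpha, params.n_rate_categories)
    cats = rng.integers(0, len(rates), size=n_sites)
    states = {id(tree.root): rng.choice(4, size=n_sites, p=pi)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = states[id(node.parent)]
        child = parent.copy()
        for c, rate in enumerate(rates):
            sel = cats == c
            if sel.any():
                P = expm(Q * rate * (node.length or 0.0))
                cum = np.cumsum(P, axis=1)
                u = rng.random(sel.sum())
                child[sel] = (u[:, None] < cum[parent[sel]]).argmax(axis=1)
        states[id(node)] = child
    leaf_rows = {n.label: "".join("ACGT"[s] for s in states[id(n)])
                 for n in tree.leaves()}
    labels = sorted(leaf_rows)
    return Msa(labels, [leaf_rows[l] for l in labels], "nucleotide")


class TestBootstrap:
    def test_fixed_seed_is_deterministic(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        msa = _simulate_gtr_gamma(tree, NucModelParams(), 300, seed=41)
        t1 = bootstrap_support(msa, tree, n_replicates=30, seed=9)
        t2 = bootstrap_support(msa, tree, n_replicates=30, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_identical_sequences_vacuous_support(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        msa = Msa(list("ABCD"), ["ACGT"] * 4, "nucleotide")
        out = bootstrap_support(msa, tree, n_replicates=10, seed=1)
        assert set(out.leaf_labels()) == set("ABCD")

    def test_structured_data_high_support(self):
        tree = PhyloTree.from_newick("((A:0.15,B:0.15):0.2,(C:0.15,D:0.15):0.2);")
        msa = _simulate_gtr_gamma(tree, NucModelParams(), 2000, seed=42)
        out = bootstrap_support(msa, tree, n_replicates=50, seed=2)
        supports = [n.support for n in out.postorder()
                    if n.support is not None]
        assert supports and min(supports) >= 90.0
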