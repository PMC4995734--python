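"""Codon rate matrices, mixture likelihoods, LRTs and the selection scan."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from pansel._likelihood import pattern_likelihoods
from pansel._seq import CODON_INDEX, SENSE_CODONS
from pansel.core_phylogeny import CodonAlignment
from pansel.selection import (CodonLikelihood, branch_site_lrt,
                              branch_site_params, codon_rate_matrix,
                              codon_site_loglik, estimate_branch_lengths_m0,
                              f3x4_frequencies, fit_branch_site,
                              fit_site_models, likelihood_ratio_test,
                              m1a_params, m2a_params, scan_core_genes,
                              site_lrt, uniform_codon_frequencies)
from pansel.synthetic_data import regime_params, simulate_codon_alignment
from pansel.tree import PhyloTree

from oracles import enumerate_tree_likelihood, gy_raw_matrix

UNIFORM = uniform_codon_frequencies()


class TestCodonRateMatrix:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            f = rng.dirichlet(np.full(61, 5.0))
            Q = codon_rate_matrix(rng.uniform(0.5, 5), rng.uniform(0.05, 4), f)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet(np.full(61, 5.0))
        Q = codon_rate_matrix(2.3, 0.4, f)
        flux = f[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_neutral_rates_proportional_to_target_frequency(self):
        """At omega=1 synonymous and nonsynonymous single-step rates to j are
        both pi_j (x kappa for transitions)."""
        kappa = 3.0
        Q = codon_rate_matrix(kappa, 1.0, UNIFORM)
        scale = None
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    if i != j:
                        assert Q[i, j] == 0.0
                    continue
                a, b = diffs[0]
                is_ts = (a in "AG") == (b in "AG")
                expected = UNIFORM[j] * (kappa if is_ts else 1.0)
                if scale is None:
                    scale = Q[i, j] / expected
                assert Q[i, j] == pytest.approx(scale * expected, rel=1e-12)

    def test_multi_nucleotide_changes_forbidden(self):
        Q = codon_rate_matrix(2.0, 0.5, UNIFORM)
        i, j = CODON_INDEX["AAA"], CODON_INDEX["CCA"]
        assert Q[i, j] == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            codon_rate_matrix(-1.0, 0.5, UNIFORM)
        with pytest.raises(ValueError):
            codon_rate_matrix(2.0, -0.5, UNIFORM)


class TestCodonLikelihood:
    def test_identical_sequences_zero_branches(self):
        tree = PhyloTree.from_newick("(A:0,B:0,C:0);")
        row = "ATGAAAGGG"
        aln = CodonAlignment(list("ABC"), [row] * 3)
        params = m1a_params(0.6, 0.2, 2.0, UNIFORM)
        ll = codon_site_loglik(aln, tree, params)
        expected = sum(np.log(UNIFORM[CODON_INDEX[row[k:k + 3]]])
                       for k in range(0, 9, 3))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_ancestral_enumeration_oracle(self):
        """4-taxon, 2 codon columns: pruning equals explicit summation over
        the 61^2 internal-state assignments, P matrices via scipy expm."""
        tree = PhyloTree.from_newick("((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05);")
        aln = CodonAlignment(list("ABCD"),
                             ["ATGAAA", "ATGAAG", "ATAAAA", "CTGAAA"])
        params = m2a_params(0.5, 0.3, 0.2, 3.0, 2.0, UNIFORM)
        ll = codon_site_loglik(aln, tree, params)
        raw = {w: gy_raw_matrix(params.kappa, w, UNIFORM)
               for _, w, _ in params.site_classes}
        s = sum(p * raw[w][1] for p, w, _ in params.site_classes)
        ll_oracle = 0.0
        for site in range(2):
            col = {lab: CODON_INDEX[aln.codon(k, site)]
                   for k, lab in enumerate(aln.labels)}
            site_lik = 0.0
            for p, w, _ in params.site_classes:
                P = {id(n): expm(raw[w][0] * (n.length or 0.0) / s)
                     for n in tree.postorder()}
                site_lik += p * enumerate_tree_likelihood(
                    tree, col, lambda n, _P=P: _P[id(n)], UNIFORM)
            ll_oracle += np.log(site_lik)
        assert ll == pytest.approx(ll_oracle, abs=1e-6)

    def test_branch_site_matches_enumeration_oracle(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05);")
        tree.mark_foreground({"A", "B"}, clade=True)
        aln = CodonAlignment(list("ABCD"), ["ATG", "CTG", "ATA", "ATA"])
        params = branch_site_params(0.5, 0.3, 0.2, 4.0, 2.0, UNIFORM)
        ll = codon_site_loglik(aln, tree, params)
        col = {lab: CODON_INDEX[aln.codon(k, 0)] for k, lab in enumerate(aln.labels)}
        raw = {}
        for _, wb, wf in params.site_classes:
            for w in (wb, wf):
                raw.setdefault(w, gy_raw_matrix(params.kappa, w, UNIFORM))
        s_bg = sum(p * raw[wb][1] for p, wb, _ in params.site_classes)
        s_fg = sum(p * raw[wf][1] for p, _, wf in params.site_classes)
        site_lik = 0.0
        for p, wb, wf in params.site_classes:
            P = {id(n): expm((raw[wf][0] / s_fg if n.foreground else raw[wb][0] / s_bg)
                             * (n.length or 0.0))
                 for n in tree.postorder()}
            site_lik += p * enumerate_tree_likelihood(
                tree, col, lambda n, _P=P: _P[id(n)], UNIFORM)
        assert ll == pytest.approx(np.log(site_lik), abs=1e-6)

    def test_two_taxon_pattern_probabilities_sum_to_one(self):
        tree = PhyloTree.from_newick("(A:0.2,B:0.4);")
        params = m1a_params(0.7, 0.3, 2.5, UNIFORM)
        patterns = np.array(list(itertools.product(range(61), repeat=2)))
        aln = CodonAlignment(["A", "B"], ["ATG", "ATG"])  # placeholder rows
        lik = CodonLikelihood(aln, tree, UNIFORM)
        s = sum(p * lik._gen(params.kappa, w)[1] for p, w, _ in params.site_classes)
        total = 0.0
        for p, w, _ in params.site_classes:
            gen, mu = lik._gen(params.kappa, w)
            liks, scale = pattern_likelihoods(
                tree, patterns, 61, lik.taxon_order,
                lambda n, _g=gen, _r=mu / s: _g.transition_matrix(
                    (n.length or 0.0) * _r), UNIFORM)
            total += p * float(np.sum(liks * np.exp(scale)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rerooting_invariance(self):
        params = m1a_params(0.8, 0.1, 2.0, UNIFORM)
        aln = CodonAlignment(list("ABCD"), ["ATGAAA", "ATGAAG", "ATAAAA", "CTGAAA"])
        t1 = PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.1):0.2);")
        t2 = PhyloTree.from_newick("(A:0.1,(B:0.3,((C:0.25,D:0.1):0.3)):0.1);")
        assert codon_site_loglik(aln, t1, params) == \
            pytest.approx(codon_site_loglik(aln, t2, params), abs=1e-8)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(["A"], ["ATGTAAGGG"])

    def test_branch_site_requires_foreground(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        aln = CodonAlignment(list("ABC"), ["ATG"] * 3)
        params = branch_site_params(0.5, 0.3, 0.2, 2.0, 2.0, UNIFORM)
        with pytest.raises(ValueError, match="foreground"):
            codon_site_loglik(aln, tree, params)


class TestLrtMechanics:
    @pytest.mark.parametrize("stat,df,expected", [
        (0.0, 2, 1.0), (5.991, 2, 0.05), (3.841, 1, 0.05)])
    def test_chi_square_reference_points(self, stat, df, expected):
        res = likelihood_ratio_test(-100.0, -100.0 + stat / 2, df)
        assert res.p_value == pytest.approx(expected, abs=2e-4)
        assert res.p_value == pytest.approx(chi2.sf(stat, df), abs=1e-12)

    def test_tiny_negative_statistic_clamped(self):
        res = likelihood_ratio_test(-100.0, -100.0 - 1e-8, 2)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_negative_statistic_signals_refit(self):
        with pytest.raises(ValueError, match="refit"):
            likelihood_ratio_test(-100.0, -101.0, 2)


TREE8 = PhyloTree.from_newick(
    "(((t1:0.1,t2:0.1):0.15,(t3:0.15,t4:0.15):0.1):0.25,"
    "((t5:0.12,t6:0.12):0.18,(t7:0.2,t8:0.2):0.1):0.2);")


class TestModelFitting:
    def test_m1a_parameter_recovery(self):
        params = regime_params("M1a", p0=0.8, omega0=0.2)
        aln, _ = simulate_codon_alignment(TREE8, params, 300, seed=101)
        fits = fit_site_models(aln, TREE8, n_starts=1, freqs=UNIFORM)
        omega0_hat = fits.m1a.params.site_classes[0][1]
        assert omega0_hat == pytest.approx(0.2, abs=0.1)

    def test_m2a_detects_planted_selection(self):
        params = regime_params("M2a", omega2=4.0, p2=0.2)
        aln, _ = simulate_codon_alignment(TREE8, params, 300, seed=102)
        fits = fit_site_models(aln, TREE8, n_starts=1, freqs=UNIFORM)
        assert fits.m2a.params.site_classes[2][1] > 1.0
        assert site_lrt(fits).statistic > 0.0

    def test_nesting_on_fixtures(self):
        for seed, regime in ((7, "M1a"), (8, "M2a"), (9, "neutral")):
            params = regime_params(regime)
            aln, _ = simulate_codon_alignment(TREE8, params, 120, seed=seed)
            fits = fit_site_models(aln, TREE8, n_starts=1, freqs=UNIFORM)
            assert fits.m2a.ll >= fits.m1a.ll - 1e-6

    def test_branch_site_recovery_and_ordering(self):
        tree = TREE8.copy()
        tree.mark_foreground({"t5", "t6"}, clade=True)
        params = regime_params("branch_site", omega2=5.0, p2=0.15)
        aln, _ = simulate_codon_alignment(tree, params, 300, seed=103)
        fits = fit_branch_site(aln, tree, n_starts=1, freqs=UNIFORM)
        assert fits.alt.ll >= fits.null.ll - 1e-6
        assert fits.alt.params.site_classes[2][2] > 1.0
        assert branch_site_lrt(fits).statistic >= 0.0

    def test_branch_site_requires_mark(self):
        aln, _ = simulate_codon_alignment(TREE8, regime_params("M1a"), 50, seed=1)
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_site(aln, TREE8)

    def test_estimator_consistency_with_length(self):
        """|omega0_hat - truth| shrinks from 50 to 500 codons (median of 3)."""
        errs = {}
        for n in (50, 500):
            e = []
            for seed in (201, 202, 203):
                aln, _ = simulate_codon_alignment(
                    TREE8, regime_params("M1a", p0=0.8, omega0=0.2), n, seed=seed)
                fits = fit_site_models(aln, TREE8, n_starts=1, freqs=UNIFORM)
                e.append(abs(fits.m1a.params.site_classes[0][1] - 0.2))
            errs[n] = float(np.median(e))
        assert errs[500] <= errs[50]


class TestScan:
    def _mini_scan_inputs(self, n_genes=8, n_selected=2, seed=301):
        from pansel.pangenome import GeneFamily, qualify
        tree = PhyloTree.from_newick(
            "((G1:0.15,G2:0.15):0.1,((G3:0.1,G4:0.1):0.08,G5:0.18):0.07);")
        marked = tree.copy()
        marked.mark_foreground({"G3", "G4"}, clade=True)
        genomes = sorted(tree.leaf_labels())
        families, alignments, planted = [], {}, []
        rng = np.random.default_rng(seed)
        for g in range(n_genes):
            fid = f"F{g:03d}"
            selected = g < n_selected
            params = regime_params("branch_site", omega2=8.0, p2=0.3) if selected \
                else regime_params("purifying", omega0=0.2)
            aln, _ = simulate_codon_alignment(marked, params, 60,
                                              seed=int(rng.integers(2 ** 31)),
                                              labels=genomes)
            alignments[fid] = aln
            families.append(GeneFamily(fid, [qualify(g_, f"{fid}_{g_}")
                                             for g_ in genomes]))
            if selected:
                planted.append(fid)
        return families, alignments, tree, planted

    def test_planted_genes_top_ranked_and_summary_consistent(self):
        families, alignments, tree, planted = self._mini_scan_inputs()
        rows, summary = scan_core_genes(families, alignments, tree,
                                        {"G3", "G4"}, alpha=0.05, seed=0)
        assert summary.n_tested == len(rows) == 8
        ranked = sorted(rows, key=lambda r: -r.branch_site.statistic)
        assert {r.family_id for r in ranked[:2]} == set(planted)
        # summary equals a recount
        assert summary.n_selected_branch == sum(r.selected_branch for r in rows)
        assert summary.pct_selected_site == pytest.approx(
            100.0 * sum(r.selected_site for r in rows) / len(rows))
        assert summary.n_branch_only + summary.n_shared == summary.n_selected_branch

    def test_alpha_zero_selects_nothing(self):
        families, alignments, tree, _ = self._mini_scan_inputs(n_genes=3,
                                                               n_selected=1)
        rows, summary = scan_core_genes(families, alignments, tree,
                                        {"G3", "G4"}, alpha=0.0, seed=0)
        assert summary.n_selected_site == summary.n_selected_branch == 0

    def test_non_single_copy_families_skipped(self):
        from pansel.pangenome import GeneFamily, qualify
        families, alignments, tree, _ = self._mini_scan_inputs(n_genes=2,
                                                               n_selected=0)
        families.append(GeneFamily("PARA", [qualify("G1", "a"), qualify("G1", "b"),
                                            qualify("G2", "c")]))
        rows, summary = scan_core_genes(families, alignments, tree,
                                        {"G3", "G4"}, seed=0)
        assert "PARA" in summary.skipped
        assert all(r.family_id != "PARA" for r in rows)


class TestFrequencies:
    def test_f3x4_uniform_alignment(self):
        aln = CodonAlignment(["A", "B"], ["ATGAAA", "ATGAAA"])
        f = f3x4_frequencies(aln)
        assert f.shape == (61,) and f.sum() == pytest.approx(1.0)
        assert (f > 0).all()

    def test_m0_branch_length_estimation_scales_tree(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln, _ = simulate_codon_alignment(tree, regime_params("purifying"), 200,
                                          seed=77)
        fitted, kappa, omega = estimate_branch_lengths_m0(aln, tree, freqs=UNIFORM)
        assert kappa > 0 and 0 < omega < 1.5
        ratio = fitted.total_length() / tree.total_length()
        assert 0.3 < ratio < 3.0
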