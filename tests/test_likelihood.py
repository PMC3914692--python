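"""Pruning likelihood, its invariances, and ML fitting."""

import numpy as np
import pytest

import stemloop as sl

from helpers import brute_force_loglik, random_model, random_structured_alignment


class TestTransitionMatrix:
    def test_identity_at_zero(self, loop_hky_g):
        assert np.allclose(sl.transition_matrix(loop_hky_g, 0.0), np.eye(4), atol=1e-12)

    def test_negative_branch_rejected(self, loop_hky_g):
        with pytest.raises(ValueError):
            sl.transition_matrix(loop_hky_g, -0.1)

    def test_rows_sum_and_stationarity(self, rng):
        for name in ("GTR", "7D", "16C"):
            m = random_model(name, rng)
            for t in (0.01, 0.3, 2.5):
                P = m.transition(t)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
                assert np.allclose(m.pi @ P, m.pi, atol=1e-10)

    def test_jc_closed_form(self):
        m = sl.build_model("HKY", {"pi": np.full(4, 0.25), "kappa": 1.0})
        for t in (0.05, 0.4, 1.7):
            P = m.transition(t)
            expected = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            assert np.allclose(np.diag(P), expected, atol=1e-10)


class TestPruning:
    def test_two_taxon_closed_form(self, rng):
        m = random_model("HKY", rng)
        tree = sl.PhyloTree.from_newick("(t1:0.0,t2:0.35);")
        aln = random_structured_alignment(rng, n_taxa=2, n_pairs=0, n_loop=30, gap_prob=0.0)
        enc = sl.encode(aln)
        mix = sl.MixtureModel(m, None, partitioned=False)
        lnL = sl.partition_loglik(tree, mix, enc)
        P = m.transition(0.35)
        direct = sum(
            np.log(m.pi[a] * P[a, b])
            for a, b in zip(enc.loop_obs[0], enc.loop_obs[1])
        )
        assert abs(lnL - direct) < 1e-10

    @pytest.mark.parametrize("name,gamma", [("HKY", True), ("7G", False), ("16C", False)])
    def test_brute_force_four_taxa(self, name, gamma, rng, four_taxon_tree):
        m = random_model(name, rng, gamma=gamma)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=5, n_loop=6)
        enc = sl.encode(aln)
        which = {4: "loop", 7: "stem7", 16: "stem16"}[m.n_states]
        pats, w = enc.compressed(which)
        arr = four_taxon_tree.arrays(enc.taxa)
        fast = sl.prune_loglik(arr, m, pats, w, branch_scale=1.2)
        slow = brute_force_loglik(four_taxon_tree, m, pats, w, enc.taxa, branch_scale=1.2)
        assert abs(fast - slow) < 1e-8

    def test_root_invariance(self, rng, small_alignment, four_taxon_tree, loop_hky_g):
        stem = random_model("16D", rng)
        mix = sl.MixtureModel(loop_hky_g, stem, rho=1.4)
        enc = sl.encode(small_alignment)
        ref = sl.partition_loglik(four_taxon_tree, mix, enc)
        for e in (0, 2, 4):
            rerooted = four_taxon_tree.rerooted_at_edge(e)
            assert abs(sl.partition_loglik(rerooted, mix, enc) - ref) < 1e-8

    def test_compression_lossless(self, rng, four_taxon_tree):
        m = random_model("16E", rng)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=25, n_loop=0)
        enc = sl.encode(aln)
        pats, w = enc.compressed("stem16")
        arr = four_taxon_tree.arrays(enc.taxa)
        compressed = sl.prune_loglik(arr, m, pats, w)
        raw = sl.prune_loglik(arr, m, enc.stem16, np.ones(25))
        assert abs(compressed - raw) < 1e-10

    def test_rho_equals_scaled_branches(self, rng, four_taxon_tree):
        m = random_model("7F", rng)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=12, n_loop=3)
        enc = sl.encode(aln)
        pats, w = enc.compressed("stem7")
        arr1 = four_taxon_tree.arrays(enc.taxa)
        arr2 = four_taxon_tree.scaled(2.0).arrays(enc.taxa)
        assert abs(
            sl.prune_loglik(arr1, m, pats, w, branch_scale=2.0)
            - sl.prune_loglik(arr2, m, pats, w, branch_scale=1.0)
        ) < 1e-9

    def test_taxa_mismatch_raises(self, small_alignment):
        tree = sl.PhyloTree.from_newick("((x1:0.1,x2:0.2):0.1,x3:0.3,x4:0.1);")
        enc = sl.encode(small_alignment)
        mix = sl.MixtureModel(
            sl.build_model("HKY", {"pi": np.full(4, 0.25), "kappa": 2.0}),
            None,
            partitioned=False,
        )
        with pytest.raises(ValueError, match="mismatch"):
            sl.partition_loglik(tree, mix, enc)

    def test_empty_partition_raises(self, four_taxon_tree, rng, loop_hky_g):
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=0, n_loop=20)
        enc = sl.encode(aln)
        mix = sl.MixtureModel(loop_hky_g, random_model("16F", rng), rho=1.0)
        with pytest.raises(ValueError, match="partition"):
            sl.partition_loglik(four_taxon_tree, mix, enc)


class TestFit:
    def test_refit_from_truth_never_decreases(self, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        spec = sl.MixtureSpec("HKY+G", "16D", partitioned=True)
        fit = sl.fit_ml(four_taxon_tree, spec, enc, seed=1)
        # likelihood at the generating parameter point
        truth_mix = sl.MixtureModel(
            sl.build_model(
                "HKY",
                {"pi": fit.params["loop_pi"], "kappa": 3.0, "gamma_shape": 0.7},
            ),
            sl.build_model(
                "16D",
                {
                    "nuc_pi": fit.params["stem_nuc_pi"],
                    "alpha": 5.0,
                    "beta": 2.0,
                    "rates": {"ts": 3.0, "double": 0.4},
                },
            ),
            rho=1.3,
        )
        lnL_truth = sl.partition_loglik(four_taxon_tree, truth_mix, enc)
        assert fit.lnL >= lnL_truth - 1e-6

    def test_frequencies_are_empirical_counts(self, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fit = sl.fit_ml(
            four_taxon_tree, sl.MixtureSpec("HKY+G", "16I", partitioned=True), enc,
            n_starts=1, seed=0,
        )
        np.testing.assert_array_equal(
            fit.params["loop_pi"], sl.empirical_frequencies(enc, 4, "loop")
        )
        np.testing.assert_array_equal(
            fit.params["stem_pi"], sl.empirical_frequencies(enc, 16)
        )

    @pytest.mark.parametrize("restricted,general", [("HKY+G", "GTR+G")])
    def test_nested_loop_models_monotone(self, restricted, general, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fits = [
            sl.fit_ml(
                four_taxon_tree,
                sl.MixtureSpec(name, None, partitioned=False),
                enc,
                seed=0,
            )
            for name in (restricted, general)
        ]
        assert fits[1].lnL >= fits[0].lnL - 1e-4

    @pytest.mark.parametrize("restricted,general", [("7G", "7F"), ("16F", "16E")])
    def test_nested_stem_models_monotone(self, restricted, general, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fits = [
            sl.fit_ml(
                four_taxon_tree,
                sl.MixtureSpec("HKY+G", name, partitioned=True),
                enc,
                seed=0,
            )
            for name in (restricted, general)
        ]
        assert fits[1].lnL >= fits[0].lnL - 1e-4

    def test_branch_length_optimization_improves(self, small_alignment):
        enc = sl.encode(small_alignment)
        wrong = sl.PhyloTree.from_newick("((t1:0.5,t2:0.5):0.5,t3:0.5,t4:0.5);")
        spec = sl.MixtureSpec("HKY+G", None, partitioned=False)
        fixed = sl.fit_ml(wrong, spec, enc, n_starts=1, seed=0)
        opt = sl.fit_ml(wrong, spec, enc, optimize_branch_lengths=True, n_starts=1, seed=0)
        assert opt.lnL > fixed.lnL
        assert opt.k == fixed.k + 5  # 2n-3 branches join the parameter count


class TestGeneRate:
    def test_no_stems(self, loop_hky_g, rng):
        mix = sl.MixtureModel(loop_hky_g, random_model("16D", rng), rho=3.0)
        assert sl.gene_rate(mix, 0.0) == 1.0

    def test_dinucleotide_scaling_identity(self, loop_hky_g, rng):
        mix = sl.MixtureModel(loop_hky_g, random_model("16D", rng), rho=1.0)
        # all-stem gene under rho=1: per-nucleotide rate is half the
        # per-dinucleotide unit
        assert abs(sl.gene_rate(mix, 1.0) - 0.5) < 1e-12

    def test_monotone_in_rho(self, loop_hky_g, rng):
        stem = random_model("16D", rng)
        rates = [
            sl.gene_rate(sl.MixtureModel(loop_hky_g, stem, rho=r), 0.5)
            for r in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_invalid_fraction(self, loop_hky_g, rng):
        mix = sl.MixtureModel(loop_hky_g, random_model("16D", rng), rho=1.0)
        with pytest.raises(ValueError):
            sl.gene_rate(mix, 1.5)
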