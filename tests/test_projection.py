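"""State-space projections and the cross-space likelihood correction."""

import numpy as np
import pytest

import stemloop as sl
from stemloop._states import MM7, MISMATCH16_INDICES
from stemloop.projection import LARGE_SIGMA

from helpers import (
    alignment_with_mismatches,
    random_model,
    random_structured_alignment,
)


def equal_mismatch_shares(m7):
    return np.full(10, m7.pi[MM7] / 10.0)


class TestProject4To16:
    def test_transition_is_kronecker_product(self, rng):
        m4 = random_model("GTR", rng)
        p16 = sl.project_4_to_16(m4)
        for t in (0.07, 0.4, 1.3):
            assert np.abs(p16.transition(t) - np.kron(m4.transition(t), m4.transition(t))).max() < 1e-8

    def test_stationary_is_outer_product(self, rng):
        m4 = random_model("HKY", rng)
        p16 = sl.project_4_to_16(m4)
        assert np.allclose(p16.pi, np.outer(m4.pi, m4.pi).ravel())
        assert np.allclose(p16.pi @ p16.Q, 0.0, atol=1e-10)

    def test_likelihood_equivalence(self, rng, four_taxon_tree):
        m4 = random_model("HKY", rng)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=15, n_loop=0)
        enc = sl.encode(aln)
        arr = four_taxon_tree.arrays(enc.taxa)
        lnL4 = sl.prune_loglik(arr, m4, *enc.compressed("stem_nuc"))
        lnL16 = sl.prune_loglik(arr, sl.project_4_to_16(m4), *enc.compressed("stem16"))
        assert abs(lnL4 - lnL16) < 1e-8

    def test_gamma_equivalence_with_pair_level_mixing(self, rng, four_taxon_tree):
        # with Gamma the category is shared by both positions of a pair, so
        # the 4-state side must mix the two per-column likelihoods at the
        # pair level before averaging categories
        m4 = random_model("HKY", rng, gamma=True)
        p16 = sl.project_4_to_16(m4)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=10, n_loop=0, gap_prob=0.0)
        enc = sl.encode(aln)
        arr = four_taxon_tree.arrays(enc.taxa)
        lnL16 = sl.prune_loglik(arr, p16, enc.stem16, np.ones(enc.n_pairs))
        m4_plain = m4.with_gamma(None)
        gr = m4.gamma_rates()
        total = 0.0
        for k in range(enc.n_pairs):
            per_cat = []
            for rate in gr.rates:
                scaled_arr = four_taxon_tree.scaled(rate).arrays(enc.taxa)
                l1 = sl.prune_loglik(scaled_arr, m4_plain, enc.stem_nuc[:, [2 * k]], np.ones(1))
                l2 = sl.prune_loglik(scaled_arr, m4_plain, enc.stem_nuc[:, [2 * k + 1]], np.ones(1))
                per_cat.append(l1 + l2)
            total += np.log(np.mean(np.exp(per_cat)))
        assert abs(lnL16 - total) < 1e-8


class TestProject7To16:
    def test_collapsed_stationary_matches(self, rng):
        m7 = random_model("7B", rng)
        p16 = sl.project_7_to_16(m7, equal_mismatch_shares(m7))
        assert np.allclose(p16.pi[MISMATCH16_INDICES].sum(), m7.pi[MM7])
        assert np.allclose(p16.pi @ p16.Q, 0.0, atol=1e-8)

    def test_flux_preservation(self, rng):
        m7 = random_model("7E", rng)
        p16 = sl.project_7_to_16(m7, equal_mismatch_shares(m7), sigma=LARGE_SIGMA)
        # stationary flux canonical -> mismatch set, both spaces
        flux7 = sum(m7.pi[c] * m7.Q[c, MM7] for c in range(6))
        mm = set(MISMATCH16_INDICES.tolist())
        flux16 = sum(
            p16.pi[i] * p16.Q[i, j]
            for i in range(16)
            if i not in mm
            for j in mm
        )
        assert abs(flux7 - flux16) < 1e-6

    def test_inconsistent_mismatch_freqs_rejected(self, rng):
        m7 = random_model("7G", rng)
        with pytest.raises(ValueError, match="mismatch"):
            sl.project_7_to_16(m7, np.full(10, 0.05))

    @pytest.mark.parametrize("name", ["7A", "7D", "7G"])
    def test_oracle_equivalence_tightens_with_sigma(self, name, rng, four_taxon_tree):
        m7 = random_model(name, rng)
        aln = random_structured_alignment(rng, n_taxa=4, n_pairs=20, n_loop=0)
        enc = sl.encode(aln)
        arr = four_taxon_tree.arrays(enc.taxa)
        lnL7 = sl.prune_loglik(arr, m7, *enc.compressed("stem7"))
        corr = sl.correction_7_to_16(enc, "equal")
        errs = []
        for sigma in (1e3, 1e5, 1e7):
            p16 = sl.project_7_to_16(m7, equal_mismatch_shares(m7), sigma=sigma)
            lnL16 = sl.prune_loglik(arr, p16, *enc.compressed("stem16"))
            errs.append(abs(lnL7 + corr.delta_lnL - lnL16))
        assert errs[-1] < 1e-4
        assert errs[0] < 1e-1 and errs[1] <= errs[0] + 1e-9


class TestCorrection:
    def test_match_only_data_zero(self):
        enc = sl.encode(alignment_with_mismatches(0))
        for mode in ("equal",):
            corr = sl.correction_7_to_16(enc, mode)
            assert corr.delta_lnL == 0.0

    @pytest.mark.parametrize("m", [1, 3, 17])
    def test_equal_mode_counts_mismatches(self, m):
        enc = sl.encode(alignment_with_mismatches(m))
        corr = sl.correction_7_to_16(enc, "equal")
        assert abs(corr.delta_lnL - m * np.log(0.1)) < 1e-12
        assert corr.extra_k == 0

    def test_empirical_all_identical_mismatches(self):
        enc = sl.encode(alignment_with_mismatches(5))  # all AA
        corr = sl.correction_7_to_16(enc, "empirical")
        assert corr.delta_lnL == 0.0
        assert corr.extra_k == 9

    def test_empirical_fallback_warns(self):
        enc = sl.encode(alignment_with_mismatches(0))
        with pytest.warns(UserWarning, match="falls back"):
            corr = sl.correction_7_to_16(enc, "empirical")
        assert corr.mode == "equal" and corr.extra_k == 0

    def test_row_permutation_invariance(self, rng):
        aln = random_structured_alignment(rng, n_taxa=5, n_pairs=15, n_loop=4)
        perm = sl.StructuredAlignment(
            list(reversed(aln.taxa)), list(reversed(aln.rows)), aln.mask
        )
        for mode in ("equal", "empirical"):
            a = sl.correction_7_to_16(sl.encode(aln), mode).delta_lnL
            b = sl.correction_7_to_16(sl.encode(perm), mode).delta_lnL
            assert abs(a - b) < 1e-12

    def test_breakdown_table(self):
        enc = sl.encode(alignment_with_mismatches(3))
        corr = sl.correction_7_to_16(enc, "equal", breakdown=True)
        assert len(corr.per_taxon_site_terms) == 3
        assert abs(corr.per_taxon_site_terms["term"].sum() - corr.delta_lnL) < 1e-12


class TestComparableAicc:
    def _fit(self, stem, tree, enc):
        return sl.fit_ml(
            tree, sl.MixtureSpec("HKY+G", stem, partitioned=True), enc,
            n_starts=1, seed=0,
        )

    def test_seven_state_requires_correction(self, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fit = self._fit("7G", four_taxon_tree, enc)
        with pytest.raises(ValueError, match="correction"):
            sl.comparable_aicc(fit, None)

    def test_identity_without_adjustment(self, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fit = self._fit("16F", four_taxon_tree, enc)
        assert sl.comparable_aicc(fit, None) == fit.aicc
        zero = sl.CorrectionResult(0.0, 0, "equal")
        assert abs(sl.comparable_aicc(fit, zero) - fit.aicc) < 1e-12

    def test_best_correction_is_min_of_modes(self, small_alignment, four_taxon_tree):
        enc = sl.encode(small_alignment)
        fit = self._fit("7G", four_taxon_tree, enc)
        value, mode = sl.best_corrected_aicc(fit, enc)
        both = [
            sl.comparable_aicc(fit, sl.correction_7_to_16(enc, m))
            for m in ("equal", "empirical")
        ]
        assert abs(value - min(both)) < 1e-12
        assert mode in ("equal", "empirical")
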