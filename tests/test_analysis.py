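"""Reconstruction metrics, screening, clustering, enrichment, divergence."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from embed.analysis import (
    cluster_otus_by_loadings,
    daily_change_error_profile,
    ecn_taxon_correlation_screen,
    hypergeometric_enrichment,
    kl_reconstruction_error,
    model_agreement_divergence,
    otu_trajectory_errors,
    reconstruction_report,
    subject_variability_ranking,
)


def _random_compositions(seed, O=5, S=1, T=8):
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(np.ones(O), size=(S, T)).transpose(2, 0, 1)
    return x


class TestKL:
    def test_zero_for_perfect_reconstruction(self):
        x = _random_compositions(0)
        assert np.allclose(kl_reconstruction_error(x, x), 0.0)

    def test_hand_value_for_disjoint_mass(self):
        x = np.array([[[1.0]], [[0.0]]])
        q = np.array([[[0.5]], [[0.5]]])
        assert kl_reconstruction_error(x, q)[0] == pytest.approx(np.log(2))

    def test_time_normalization_invariant_to_duplication(self):
        x = _random_compositions(1, T=6)
        q = _random_compositions(2, T=6) * 0.5 + x * 0.5
        q /= q.sum(axis=0, keepdims=True)
        once = kl_reconstruction_error(x, q)
        twice = kl_reconstruction_error(
            np.concatenate([x, x], axis=2), np.concatenate([q, q], axis=2)
        )
        assert np.allclose(once, twice)

    def test_negative_inputs_rejected(self):
        x = _random_compositions(0)
        with pytest.raises(ValueError):
            kl_reconstruction_error(-x, x + 0.1)


class TestTrajectoryErrors:
    def test_perfect_reconstruction(self):
        x = _random_compositions(3, T=6)
        per_otu, per_subj = otu_trajectory_errors(x, x)
        assert np.allclose(per_otu["mse"], 0.0)
        assert np.allclose(per_otu["pearson"].dropna(), 1.0)

    def test_constant_trajectory_excluded_and_counted(self):
        x = _random_compositions(4, T=6)
        x[0] = 0.2  # constant OTU
        x /= x.sum(axis=0, keepdims=True)
        x[0] = 0.25  # re-pin to an exactly constant value
        q = _random_compositions(5, T=6)
        _, per_subj = otu_trajectory_errors(x, q)
        assert per_subj.loc[0, "n_constant_excluded"] >= 1

    def test_hand_computed_two_otu_table(self):
        x = np.array([[0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2]])[:, None, :]
        q = np.array([[0.3, 0.3, 0.7, 0.7], [0.7, 0.7, 0.3, 0.3]])[:, None, :]
        per_otu, per_subj = otu_trajectory_errors(x, q)
        mse0 = np.mean((x[0, 0] - q[0, 0]) ** 2)
        assert per_otu.loc[0, "mse"] == pytest.approx(mse0)
        r0 = np.corrcoef(x[0, 0], q[0, 0])[0, 1]
        assert per_otu.loc[0, "pearson"] == pytest.approx(r0)
        assert per_subj.loc[0, "mean_mse"] == pytest.approx(
            per_otu["mse"].mean()
        )

    def test_report_summaries_recompute(self):
        x = _random_compositions(6, S=2, T=7)
        q = _random_compositions(7, S=2, T=7)
        rep = reconstruction_report(x, q)
        assert rep.mean_kl == pytest.approx(rep.kl_per_subject.mean())


class TestDailyChangeProfile:
    def test_zero_error_when_model_equals_data(self):
        x = _random_compositions(8, T=10)
        prof = daily_change_error_profile(x, x)
        assert np.allclose(prof.bin_mean[np.isfinite(prof.bin_mean)], 0.0)

    def test_hundred_points_make_twenty_even_bins(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.01, 1.0, size=(10, 1, 11))  # 10 OTUs x 10 transitions
        q = x * rng.uniform(0.9, 1.1, size=x.shape)
        prof = daily_change_error_profile(x, q)
        counts = np.histogram(prof.abundance, bins=prof.bin_edges)[0]
        assert prof.abundance.size == 100
        assert np.all(counts == 5)

    def test_error_inflated_at_high_abundance_detected(self):
        # high-abundance OTUs get an alternating ±0.5-decade reconstruction
        # error; low-abundance OTUs are reconstructed perfectly
        rng = np.random.default_rng(10)
        T = 15
        x_hi = rng.uniform(0.5, 1.0, size=(10, 1, T))
        x_lo = rng.uniform(0.001, 0.01, size=(10, 1, T))
        x = np.concatenate([x_hi, x_lo], axis=0)
        q = x.copy()
        wobble = 10.0 ** (0.5 * (-1.0) ** np.arange(T))
        q[:10] *= wobble[None, None, :]
        prof = daily_change_error_profile(x, q)
        assert np.nanmean(prof.bin_mean[-5:]) > 10 * np.nanmean(prof.bin_mean[:5])

    def test_gaps_skipped(self):
        x = _random_compositions(11, T=6)
        mask = np.array([[True, True, False, True, True, True]])
        prof = daily_change_error_profile(x, x, mask=mask)
        # transitions 0-1, 3-4, 4-5 only
        assert prof.abundance.size == x.shape[0] * 3


class TestCorrelationScreen:
    def test_constructed_single_mode_taxa_all_specific(self):
        rng = np.random.default_rng(12)
        T, K, O = 50, 3, 30
        y, _ = np.linalg.qr(rng.normal(size=(T, K)))
        x = np.empty((O, 1, T))
        owner = np.arange(O) % K
        for o in range(O):
            x[o, 0] = y[:, owner[o]] + rng.normal(0, 0.02, T)
        scr = ecn_taxon_correlation_screen(y, x)
        assert scr.frac_one == 1.0
        sig = scr.table[scr.table["significant"]]
        assert np.array_equal(np.sort(sig["otu"].to_numpy()), np.arange(O))
        assert np.array_equal(sig.sort_values("otu")["mode"].to_numpy() - 1,
                              owner)

    def test_null_screen_controls_fdr(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, _ = np.linalg.qr(rng.normal(size=(40, 5)))
            x = rng.uniform(0.1, 1.0, size=(100, 1, 40))
            scr = ecn_taxon_correlation_screen(y, x)
            fracs.append(scr.table["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_bh_step_up_rule_by_hand(self):
        # statsmodels BH on a worked p-value list: first four significant
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
        rej = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert rej.tolist() == [True, True, True, True, False]


class TestClustering:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(13)
        O = 30
        phi = np.zeros((3, O, 1))
        group = np.arange(O) % 2
        phi[1, group == 0, 0] = rng.choice([-1, 1], (group == 0).sum())
        phi[2, group == 1, 0] = rng.choice([-1, 1], (group == 1).sum())
        phi[1:] += rng.normal(0, 0.05, size=(2, O, 1))
        cl = cluster_otus_by_loadings(np.abs(phi), [2, 3], n_clusters=2)
        labels = cl.labels
        same = labels[group == 0]
        assert len(set(same)) == 1 and len(set(labels[group == 1])) == 1
        assert set(labels) == {1, 2}

    def test_identical_loadings_collapse(self):
        phi = np.ones((2, 8, 1))
        cl = cluster_otus_by_loadings(phi, [1, 2])
        assert np.allclose(cl.linkage_matrix[:, 2], 0.0)

    def test_component_selection_contract(self):
        rng = np.random.default_rng(14)
        phi = rng.normal(size=(4, 6, 2))
        cl = cluster_otus_by_loadings(phi, [2, 3, 4])
        assert cl.features.shape == (6, 3 * 2)
        expected = phi[1:].transpose(1, 0, 2).reshape(6, -1)
        assert np.array_equal(cl.features, expected)

    def test_newick_serialization_parses(self):
        rng = np.random.default_rng(15)
        cl = cluster_otus_by_loadings(rng.normal(size=(2, 5, 1)), [1, 2],
                                      otu_ids=list("abcde"))
        nwk = cl.to_newick()
        assert nwk.endswith(";") and nwk.count(",") == 4
        for name in "abcde":
            assert name in nwk

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_otus_by_loadings(np.zeros((2, 3, 1)), [1], n_clusters=5)


class TestSubjectVariability:
    def test_identical_subjects_give_zero(self):
        phi = np.tile(np.random.default_rng(16).normal(size=(3, 5, 1)), (1, 1, 4))
        rank = subject_variability_ranking(phi)
        assert np.allclose(rank.to_numpy(), 0.0)

    def test_three_four_five_triangle(self):
        phi = np.zeros((2, 1, 2))
        phi[:, 0, 1] = [3.0, 4.0]
        rank = subject_variability_ranking(phi)
        assert rank.iloc[0] == pytest.approx(5.0)

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(17)
        phi = rng.normal(size=(3, 6, 4))
        r1 = subject_variability_ranking(phi)
        r2 = subject_variability_ranking(phi[:, :, [2, 0, 3, 1]])
        assert np.allclose(np.sort(r1.to_numpy()), np.sort(r2.to_numpy()))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            subject_variability_ranking(np.zeros((2, 3, 1)))


class TestEnrichment:
    def test_zero_successes_is_certain(self):
        assert hypergeometric_enrichment(0, 5, 3, 50).p_value == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 10, 50)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(2, 5, 3, 4)

    def test_matches_exact_summation(self):
        # independent oracle: direct sum of hypergeometric pmf terms
        from math import comb

        k, n, K_pop, N_pop = 3, 8, 6, 30
        p_exact = sum(
            comb(K_pop, i) * comb(N_pop - K_pop, n - i) for i in range(k, min(n, K_pop) + 1)
        ) / comb(N_pop, n)
        res = hypergeometric_enrichment(k, n, K_pop, N_pop)
        assert res.p_value == pytest.approx(p_exact, rel=1e-12)


class TestModelAgreement:
    def test_identical_models_agree_perfectly(self):
        q = _random_compositions(18)
        assert model_agreement_divergence(q, q) == 0.0

    def test_symmetry(self):
        q1, q2 = _random_compositions(19), _random_compositions(20)
        assert model_agreement_divergence(q1, q2) == pytest.approx(
            model_agreement_divergence(q2, q1)
        )

    def test_disjoint_supports_reach_one_bit(self):
        p = np.array([[[1.0]], [[0.0]]])
        q = np.array([[[0.0]], [[1.0]]])
        assert model_agreement_divergence(p, q) == pytest.approx(1.0)

    def test_unnormalized_inputs_rejected(self):
        q = _random_compositions(21)
        with pytest.raises(ValueError):
            model_agreement_divergence(q, q * 2)


class TestPermutationEquivariance:
    def test_metrics_follow_otu_relabeling(self):
        rng = np.random.default_rng(22)
        x = _random_compositions(23, O=7, T=9)
        q = _random_compositions(24, O=7, T=9)
        perm = rng.permutation(7)
        per_otu, _ = otu_trajectory_errors(x, q)
        per_otu_p, _ = otu_trajectory_errors(x[perm], q[perm])
        assert np.allclose(
            per_otu.set_index("otu").loc[perm, "mse"].to_numpy(),
            per_otu_p["mse"].to_numpy(),
        )
        assert kl_reconstruction_error(x, q)[0] == pytest.approx(
            kl_reconstruction_error(x[perm], q[perm])[0]
        )
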