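"""Architecture statistics: CV, interactions, multimodality, pleiotropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import funnelqtl as fq
from funnelqtl.archstats import kmeans_1d_two

from conftest import plant


class TestCrossValidation:
    def test_null_phenotype_explains_nothing(self, haps2000):
        rng = np.random.default_rng(80)
        cv = fq.cv_variance(haps2000, rng.normal(size=2000), seed=1)
        assert abs(cv.mean) <= 0.02

    def test_single_qtl_curve_jumps_then_plateaus(self, haps2000,
                                                  scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.3, seed=81)
        cv = fq.cv_variance(haps2000, y, seed=2)
        assert abs(cv.mean - 0.3) < 0.05
        assert abs(cv.per_k_curve[0] - 0.3) < 0.05

    def test_training_variance_nondecreasing_in_k(self, haps2000,
                                                  scaffold_idx):
        from funnelqtl.qtlmodel import fit_additive_model

        j1, j2 = scaffold_idx[20], scaffold_idx[130]
        mk = lambda j: (haps2000.markers.chrom[j],
                        int(haps2000.markers.pos[j]))
        arch = fq.TraitArchitecture(
            [fq.CausalLocus(*mk(j1), [0, 0, 0, 0, 1, 1, 1, 1], [0.0, 1.0]),
             fq.CausalLocus(*mk(j2), [0, 1, 0, 1, 0, 1, 0, 1], [0.0, 0.8])],
            target_h2=0.35, strain_noise_sd=0.0)
        y, _ = fq.phenotype_from_architecture(haps2000, arch, seed=82)
        model = fq.forward_select(haps2000, y)
        r2 = []
        for k in range(1, len(model) + 1):
            fit = fit_additive_model(haps2000, y, model.marker_indices[:k])
            yv = y[fit.used]
            r2.append(1 - fit.rss / ((yv - yv.mean()) ** 2).sum())
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_additive_architecture_gains_nothing_from_interactions(
            self, haps2000, scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 1, 1, 2, 2, 3, 3],
                     [0.0, 0.5, 1.0, 1.5], target_h2=0.3, seed=83)
        cv = fq.cv_variance(haps2000, y, seed=3, per_k=False)
        ext = fq.extend_with_interactions(cv, haps2000, y)
        assert abs(ext.interaction_extended_mean - cv.mean) < 0.02

    def test_masking_epistasis_improves_extension(self, haps2000,
                                                  scaffold_idx):
        ja, jb = scaffold_idx[15], scaffold_idx[120]
        mk = lambda j: (haps2000.markers.chrom[j],
                        int(haps2000.markers.pos[j]))
        pat_q = [0, 0, 0, 0, 1, 1, 1, 1]
        pat_m = [1, 1, 1, 1, 0, 0, 0, 0]
        # synergistic interaction: strong non-additive variance while both
        # loci keep clear marginal effects so forward selection finds them
        arch = fq.TraitArchitecture(
            [fq.CausalLocus(*mk(ja), pat_q, [0.0, 1.0]),
             fq.CausalLocus(*mk(jb), pat_m, [0.0, 0.6])],
            epistatic_terms=[fq.EpistaticTerm(
                [mk(ja), mk(jb)], [pat_q, pat_m], {(1, 1): 1.2})],
            strain_noise_sd=0.3,
        )
        y, _ = fq.phenotype_from_architecture(haps2000, arch, seed=84)
        cv = fq.cv_variance(haps2000, y, seed=4, per_k=False,
                            lod_threshold=6.0)
        ext = fq.extend_with_interactions(cv, haps2000, y)
        assert ext.interaction_extended_mean > cv.mean + 0.02

    def test_no_significant_pairs_leaves_result_unchanged(self, haps2000,
                                                          scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.3, seed=85)
        cv = fq.cv_variance(haps2000, y, seed=5, per_k=False)
        ext = fq.extend_with_interactions(cv, haps2000, y, stop_p=1e-30)
        assert np.allclose(ext.fold_variance, cv.fold_variance)


class TestKMeans:
    def test_sign_partition_recovered(self):
        assign = kmeans_1d_two(np.array([-1., -1, -1, -1, 1, 1, 1, 1]))
        assert len(set(assign[:4])) == 1 and len(set(assign[4:])) == 1
        assert assign[0] != assign[4]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_split_is_globally_optimal(self, seed):
        """The sorted-split search equals brute force over all two-set
        partitions (an optimal 2-means partition is always an interval)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(2, 8)))
        assign = kmeans_1d_two(x)

        def wss(mask):
            a, b = x[mask], x[~mask]
            if len(a) == 0 or len(b) == 0:
                return np.inf
            return ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()

        best = min(
            wss(np.array([(m >> i) & 1 == 1 for i in range(len(x))]))
            for m in range(1, 2 ** len(x) - 1)
        )
        assert np.isclose(wss(assign == 0), best)


class TestMultimodality:
    def test_biallelic_qtl_not_called_polymodal(self, haps2000,
                                                scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.1, seed=86)
        model = fq.forward_select(haps2000, y)
        res = fq.multimodality_test(model, haps2000, y, min_n=15,
                                    n_splits=60, seed=87)
        assert res[0].polymodal is False

    def test_trimodal_qtl_called_polymodal(self, haps2000, scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 0, 1, 1, 1, 2, 2],
                     [0.0, 1.0, 2.0], target_h2=0.1, seed=88)
        model = fq.forward_select(haps2000, y)
        res = fq.multimodality_test(model, haps2000, y, min_n=15,
                                    n_splits=60, seed=89)
        assert res[0].polymodal is True
        assert res[0].mean_ve_full > res[0].mean_ve_binary

    def test_rare_haplotypes_masked_and_flagged(self, haps2000,
                                                scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[30], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.1, seed=90)
        model = fq.forward_select(haps2000, y)
        res = fq.multimodality_test(model, haps2000, y, min_n=10**6,
                                    n_splits=5, seed=91)
        assert res[0].polymodal is None
        assert res[0].flags

    def test_holm_adjustment_monotone_and_conservative(self):
        from funnelqtl.archstats import ModalityResult, apply_holm

        raws = [0.001, 0.04, 0.2, 0.5]
        results = [
            ModalityResult(f"m{i}", np.zeros(8), np.zeros(8), 0, 0, p)
            for i, p in enumerate(raws)
        ]
        out = apply_holm(results)
        adj = [r.p_holm for r in out]
        assert all(a >= r for a, r in zip(adj, raws))
        assert all(b >= a for a, b in zip(adj, adj[1:]))


class TestPleiotropy:
    def test_three_condition_toy_matches_exact_enumeration(self):
        res = fq.pleiotropy_permutation(
            {"c1": ["g1"], "c2": ["g1"], "c3": ["g2"]}, gene_universe=3,
            n_perm=10_000, seed=92,
        )
        null = res.null_distribution
        # exact: P(1)=6/27, P(2)=18/27, P(3)=3/27
        assert abs(np.mean(null == 1) - 6 / 27) < 0.02
        assert abs(np.mean(null == 2) - 18 / 27) < 0.02
        assert abs(np.mean(null == 3) - 1 / 9) < 0.02
        assert res.quantile95 == 3

    def test_single_condition_quantile_is_one(self):
        res = fq.pleiotropy_permutation({"c1": ["g1", "g2"]},
                                        gene_universe=100, n_perm=200,
                                        seed=93)
        assert res.quantile95 == 1
        assert res.significant_genes == []

    def test_empty_sets_give_zero_statistic(self):
        res = fq.pleiotropy_permutation({"c1": []}, gene_universe=10,
                                        n_perm=50, seed=94)
        assert (res.null_distribution == 0).all()

    def test_universe_smaller_than_list_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fq.pleiotropy_permutation({"c1": ["a", "b"]}, gene_universe=1)


class TestEffectPCA:
    def test_proportional_rows_collapse_to_one_component(self):
        E = np.vstack([np.arange(8.0), 3 * np.arange(8.0) + 2])
        frac = fq.effect_profile_pca(E)
        assert np.isclose(frac[0], 1.0)

    def test_orthogonal_patterns_split_evenly(self):
        E = np.array([[1., -1, 1, -1, 1, -1, 1, -1],
                      [1., 1, -1, -1, 1, 1, -1, -1]])
        frac = fq.effect_profile_pca(E)
        assert np.allclose(frac[:2], [0.5, 0.5])

    def test_random_rows_spread_over_components(self):
        rng = np.random.default_rng(95)
        frac = fq.effect_profile_pca(rng.normal(size=(200, 8)))
        assert frac[0] < 0.3  # nothing dominates for unstructured effects

    def test_constant_row_names_the_condition(self):
        E = np.vstack([np.arange(8.0), np.full(8, 2.0)])
        with pytest.raises(ValueError, match="GAL"):
            fq.effect_profile_pca(E, condition_names=["YPD", "GAL"])
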