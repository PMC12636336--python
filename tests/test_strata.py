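"""Subgroup definition, subgroup scans, global-vs-subgroup comparison."""

import numpy as np
import pytest

import funnelqtl as fq
from funnelqtl.simcross import expected_crossover_density

from conftest import plant


@pytest.fixture(scope="module")
def master_setup(haps2000, scaffold_idx):
    """Master locus with a modifier QTL active only in one allele class."""
    scM, scQ = scaffold_idx[20], scaffold_idx[120]
    mk = lambda j: (haps2000.markers.chrom[j], int(haps2000.markers.pos[j]))
    pat = [0, 0, 0, 0, 1, 1, 1, 1]
    arch = fq.TraitArchitecture(
        [fq.CausalLocus(*mk(scM), pat, [0.0, 2.0])],
        [fq.EpistaticTerm([mk(scM), mk(scQ)], [pat, pat], {(1, 1): 1.5})],
        strain_noise_sd=1.0,
    )
    y, _ = fq.phenotype_from_architecture(haps2000, arch, seed=120)
    return {"y": y, "scM": scM, "scQ": scQ,
            "mmid": haps2000.markers.ids[scM]}


class TestDefineSubgroup:
    def test_membership_and_ambiguity_rules(self):
        mm = fq.MarkerMap.from_positions(["chr01"] * 3, [100, 200, 300])
        labels = np.array([[3, 3, 3], [3, 3, 5], [5, 5, 5], [0, 1, 1]],
                          dtype=np.int8)
        haps = fq.HaplotypeMatrix(
            np.array(list("abcd"), dtype=object), labels, mm)
        spec = fq.SubgroupSpec("g", "chr01_100", frozenset({1, 3}),
                               flank=("chr01_100", "chr01_300"))
        members, n_excluded = fq.define_subgroup(haps, spec)
        assert list(haps.strains[members]) == ["a"]
        # strain b: matching label but flanks disagree -> ambiguous
        assert n_excluded == 1
        # strain c: label 5 not required; strain d: missing label -> out
        assert "c" not in haps.strains[members]
        assert "d" not in haps.strains[members]
        # explicit exclusion removes otherwise-qualifying strains
        spec2 = fq.SubgroupSpec("g", "chr01_100", frozenset({1, 3}),
                                flank=("chr01_100", "chr01_300"),
                                exclude_strains=frozenset({"a"}))
        members2, _ = fq.define_subgroup(haps, spec2)
        assert len(members2) == 0

    def test_idempotent(self, haps2000, master_setup):
        spec = fq.SubgroupSpec("B", master_setup["mmid"],
                               frozenset({5, 6, 7, 8}))
        g1, _ = fq.define_subgroup(haps2000, spec)
        sub = haps2000.subset_strains(g1)
        g2, _ = fq.define_subgroup(sub, spec)
        assert len(g2) == len(g1)

    def test_exclusion_fraction_matches_crossover_expectation(self,
                                                              haps2000):
        """The ambiguous fraction between two flanking markers matches the
        visible crossover density of the meiosis model."""
        idx = haps2000.markers.chrom_indices("chr01")
        pos = haps2000.markers.pos[idx]
        j1 = idx[0]
        j2 = idx[int(np.argmin(np.abs(pos - (pos[0] + 40_000))))]
        d = abs(haps2000.markers.pos[j2] - haps2000.markers.pos[j1])
        spec = fq.SubgroupSpec(
            "g", haps2000.markers.ids[j1], frozenset(range(1, 9)),
            flank=(haps2000.markers.ids[j1], haps2000.markers.ids[j2]),
        )
        members, _ = fq.define_subgroup(haps2000, spec)
        frac_ambiguous = 1 - len(members) / haps2000.n_strains
        rate = expected_crossover_density(
            fq.simcross.DEFAULT_CROSSOVER_RATE, visible=True)
        expect = 1 - np.exp(-rate * d)
        se = np.sqrt(expect * (1 - expect) / haps2000.n_strains)
        assert abs(frac_ambiguous - expect) < 4 * se + 0.01

    def test_empty_subgroup_warns(self, haps2000, master_setup):
        spec = fq.SubgroupSpec("none", master_setup["mmid"], frozenset())
        with pytest.warns(UserWarning, match="empty"):
            members, _ = fq.define_subgroup(haps2000, spec)
        assert len(members) == 0


class TestSubgroupScan:
    def test_full_population_matches_plain_scan(self, haps2000,
                                                master_setup):
        y = master_setup["y"]
        prof_all = fq.single_marker_scan(haps2000, y)
        prof_sub, _ = fq.subgroup_scan(
            haps2000, y, np.arange(haps2000.n_strains), n_perm=20, seed=1)
        assert np.allclose(prof_all.lod, prof_sub.lod)

    def test_small_subgroup_rejected(self, haps2000, master_setup):
        with pytest.raises(ValueError, match="minimum"):
            fq.subgroup_scan(haps2000, master_setup["y"], np.arange(10))

    def test_modifier_found_only_in_active_class(self, haps2000,
                                                 master_setup):
        y, mmid, scQ = (master_setup["y"], master_setup["mmid"],
                        master_setup["scQ"])
        gB, _ = fq.define_subgroup(
            haps2000, fq.SubgroupSpec("B", mmid, frozenset({5, 6, 7, 8})))
        gA, _ = fq.define_subgroup(
            haps2000, fq.SubgroupSpec("A", mmid, frozenset({1, 2, 3, 4})))
        profB, thrB = fq.subgroup_scan(haps2000, y, gB, n_perm=100, seed=2)
        profA, thrA = fq.subgroup_scan(haps2000, y, gA, n_perm=100, seed=2)
        iq = np.flatnonzero(profB.marker_indices == scQ)[0]
        assert profB.lod[iq] > thrB.threshold
        assert profA.lod[iq] < thrA.threshold


class TestLocusVariance:
    def test_null_marker_explains_nothing(self, haps2000, master_setup,
                                          scaffold_idx):
        rng = np.random.default_rng(121)
        mean, se = fq.locus_variance_in_subgroup(
            haps2000, rng.normal(size=2000), np.arange(2000),
            haps2000.markers.ids[scaffold_idx[50]], n_splits=30, seed=3)
        assert abs(mean) < 0.03

    def test_planted_variance_recovered(self, haps2000, scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[50], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.2, seed=122)
        mean, se = fq.locus_variance_in_subgroup(
            haps2000, y, np.arange(2000),
            haps2000.markers.ids[scaffold_idx[50]], n_splits=50, seed=4)
        assert abs(mean - 0.2) < 0.05

    def test_se_shrinks_with_more_splits(self, haps2000, scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[50], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.2, seed=123)
        _, se_few = fq.locus_variance_in_subgroup(
            haps2000, y, np.arange(2000),
            haps2000.markers.ids[scaffold_idx[50]], n_splits=10, seed=5)
        _, se_many = fq.locus_variance_in_subgroup(
            haps2000, y, np.arange(2000),
            haps2000.markers.ids[scaffold_idx[50]], n_splits=80, seed=5)
        assert se_many < se_few


class TestGlobalVsSubgroup:
    def test_homogeneous_architecture_shows_no_stratification(
            self, haps2000, scaffold_idx, master_setup):
        y, _ = plant(haps2000, scaffold_idx[60], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.3, seed=124)
        mmid = master_setup["mmid"]
        gA, _ = fq.define_subgroup(
            haps2000, fq.SubgroupSpec("A", mmid, frozenset({1, 2, 3, 4})))
        gB, _ = fq.define_subgroup(
            haps2000, fq.SubgroupSpec("B", mmid, frozenset({5, 6, 7, 8})))
        res = fq.compare_global_vs_subgroup(
            haps2000, y, {"A": gA, "B": gB}, n_splits=8, seed=6,
            lod_threshold=6.0)
        for name in ("A", "B"):
            assert res.pct_change_global[name] < 0  # both models help
            assert abs(res.pct_change_global[name]
                       - res.pct_change_subgroup[name]) < 10

    def test_overlapping_subgroups_rejected(self, haps2000, master_setup):
        with pytest.raises(ValueError, match="disjoint"):
            fq.compare_global_vs_subgroup(
                haps2000, master_setup["y"],
                {"a": np.arange(100), "b": np.arange(50, 150)}, n_splits=2)


class TestFourWay:
    def test_single_class_locus_rejected(self, haps2000, scaffold_idx,
                                         master_setup):
        mmid = master_setup["mmid"]
        loci = [mmid] + [haps2000.markers.ids[scaffold_idx[i]]
                         for i in (40, 90, 140)]
        with pytest.raises(ValueError, match="single class"):
            fq.four_way_interaction_test(
                haps2000, master_setup["y"], loci, mmid,
                {h: 0 for h in range(1, 9)})

    def test_planted_four_way_masking_detected(self, haps2000,
                                               scaffold_idx):
        js = [scaffold_idx[i] for i in (10, 60, 100, 145)]
        mk = lambda j: (haps2000.markers.chrom[j],
                        int(haps2000.markers.pos[j]))
        pat = [0, 0, 0, 0, 1, 1, 1, 1]
        arch = fq.TraitArchitecture(
            epistatic_terms=[fq.EpistaticTerm(
                [mk(j) for j in js], [pat] * 4, {(1, 1, 1, 1): 3.0})],
            strain_noise_sd=0.5,
        )
        y, _ = fq.phenotype_from_architecture(haps2000, arch, seed=125)
        loci = [haps2000.markers.ids[j] for j in js]
        p = fq.four_way_interaction_test(
            haps2000, y, loci, loci[0],
            {1: 0, 2: 0, 3: 0, 4: 0, 5: 1, 6: 1, 7: 1, 8: 1})
        assert p < 1e-6


class TestResidualize:
    def test_fully_determined_phenotype_residuals_zero(self, haps2000,
                                                       scaffold_idx):
        j = scaffold_idx[70]
        lab = haps2000.labels[:, j].astype(float)
        r = fq.residualize_on_locus(lab, haps2000, haps2000.markers.ids[j])
        assert np.allclose(r, 0.0)

    def test_independent_marker_leaves_centered_phenotype(self, haps2000,
                                                          scaffold_idx):
        rng = np.random.default_rng(126)
        y = rng.normal(size=2000)
        r = fq.residualize_on_locus(y, haps2000,
                                    haps2000.markers.ids[scaffold_idx[70]])
        assert np.corrcoef(r, y - y.mean())[0, 1] > 0.99

    def test_scan_after_residualizing_shows_no_peak_at_locus(
            self, haps2000, scaffold_idx):
        y, _ = plant(haps2000, scaffold_idx[70], [0, 0, 0, 0, 1, 1, 1, 1],
                     [0.0, 1.0], target_h2=0.3, seed=127)
        mid = haps2000.markers.ids[scaffold_idx[70]]
        r = fq.residualize_on_locus(y, haps2000, mid)
        prof = fq.single_marker_scan(haps2000, r)
        i = np.flatnonzero(prof.marker_indices == scaffold_idx[70])[0]
        assert prof.lod[i] < 1e-6
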