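"""Normalization: masking, plate/batch/edge factors, aggregation."""

import numpy as np
import pandas as pd
import pytest

import funnelqtl as fq

from conftest import plant


def _table(rows, cols=("strain", "condition", "timepoint", "replicate",
                       "value")):
    return fq.PhenotypeTable(pd.DataFrame(rows, columns=list(cols)))


class TestMasking:
    def test_boundary_is_inclusive(self):
        t = _table([("a", "C", 72, 1, 2000.0), ("a", "C", 72, 2, 2001.0)])
        out, model = fq.mask_small_patches(t)
        assert np.isnan(out.frame.loc[0, "value"])
        assert out.frame.loc[1, "value"] == 2001.0
        assert model.n_masked == 1

    def test_all_missing_passes_through(self):
        t = _table([("a", "C", 72, 1, np.nan)])
        out, model = fq.mask_small_patches(t)
        assert np.isnan(out.frame["value"]).all()
        assert model.n_masked == 0


class TestPlateNormalization:
    def test_doubled_controls_give_factor_two(self):
        rows = []
        for plate, mult in (("p1", 1.0), ("p2", 2.0)):
            for f in range(1, 9):
                rows.append((f"F{f}", "C", 72, plate, plate,
                             100.0 * f * mult, True))
            rows.append((f"s_{plate}", "C", 72, "r1", plate, 500.0 * mult,
                         False))
        t = fq.PhenotypeTable(pd.DataFrame(
            rows, columns=["strain", "condition", "timepoint", "replicate",
                           "plate", "value", "control"]))
        out, model = fq.normalize_plates(t)
        gm = np.exp(np.mean(np.log([model.plate_factors["p1"],
                                    model.plate_factors["p2"]])))
        assert np.isclose(model.plate_factors["p2"]
                          / model.plate_factors["p1"], 2.0)
        assert np.isclose(gm, 1.0)  # identifiability: factors centre on 1
        s1 = out.frame.loc[out.frame["strain"] == "s_p1", "value"].iloc[0]
        s2 = out.frame.loc[out.frame["strain"] == "s_p2", "value"].iloc[0]
        assert np.isclose(s1, s2)

    def test_single_plate_factor_is_one(self):
        rows = [(f"F{f}", "C", 72, "p1", "p1", 100.0 * f, True)
                for f in range(1, 9)]
        t = fq.PhenotypeTable(pd.DataFrame(
            rows, columns=["strain", "condition", "timepoint", "replicate",
                           "plate", "value", "control"]))
        _, model = fq.normalize_plates(t)
        assert np.isclose(model.plate_factors["p1"], 1.0)

    def test_simulated_plate_factors_recovered(self, haps2000):
        """Planted plate factors recovered within ~5% from 8 controls per
        plate at ~10% replicate CV (batch factors off so the plate step
        sees only plate-level structure)."""
        sub = haps2000.subset_strains(np.arange(400))
        design = fq.make_plate_design(list(sub.strains), seed=31,
                                      plate_factor_sd=0.15,
                                      batch_factor_sd=0.0)
        arch = fq.TraitArchitecture([], strain_noise_sd=150.0,
                                    replicate_noise_sd=500.0)
        raw, truth = fq.plant_and_phenotype(sub, arch, design, seed=31)
        _, model = fq.normalize_plates(raw)
        est, tru = model.plate_factors, truth["plate_factors"]
        ratios = np.array([est[p] / tru[p] for p in tru])
        rel = ratios / np.exp(np.mean(np.log(ratios)))
        assert np.sqrt(np.mean((rel - 1) ** 2)) < 0.05


class TestBatchNormalization:
    def test_median_equalization_arithmetic(self):
        rows = [("a", "C", 72, 1, "b1", 90.0), ("b", "C", 72, 1, "b1", 100.0),
                ("c", "C", 72, 1, "b1", 110.0),
                ("d", "C", 72, 1, "b2", 190.0), ("e", "C", 72, 1, "b2", 200.0),
                ("f", "C", 72, 1, "b2", 210.0)]
        t = fq.PhenotypeTable(pd.DataFrame(
            rows, columns=["strain", "condition", "timepoint", "replicate",
                           "batch", "value"]))
        out, model = fq.normalize_batches(t)
        assert np.isclose(model.batch_factors[("b1", "C", 72)], 1.5)
        assert np.isclose(model.batch_factors[("b2", "C", 72)], 0.75)
        meds = out.frame.groupby("batch")["value"].median()
        assert np.isclose(meds["b1"], meds["b2"])

    def test_single_batch_is_identity_and_missing_ignored(self):
        rows = [("a", "C", 72, 1, "b1", 100.0), ("b", "C", 72, 1, "b1",
                                                 np.nan)]
        t = fq.PhenotypeTable(pd.DataFrame(
            rows, columns=["strain", "condition", "timepoint", "replicate",
                           "batch", "value"]))
        out, model = fq.normalize_batches(t)
        assert model.batch_factors[("b1", "C", 72)] == 1.0
        assert out.frame.loc[0, "value"] == 100.0
        assert np.isnan(out.frame.loc[1, "value"])


class TestEdgeNormalization:
    @staticmethod
    def _plate_rows(edge_mult=1.0, base=1000.0):
        rows = []
        for r in range(1, 9):
            for c in range(1, 13):
                v = base * (edge_mult if fq.simcross.well_edge(r, c) else 1.0)
                rows.append((f"s{r}_{c}", "C", 72, 1, "p1", r, c, v))
        return pd.DataFrame(rows, columns=["strain", "condition",
                                           "timepoint", "replicate", "plate",
                                           "well_row", "well_col", "value"])

    def test_uniform_edge_deficit_recovered(self):
        t = fq.PhenotypeTable(self._plate_rows(edge_mult=0.8))
        out, model = fq.normalize_edges(t)
        for e in ("top", "bottom", "left", "right"):
            prod = model.edge_factors[(e, 72)] * \
                model.condition_edge_factors[("C", 72)]
            assert np.isclose(prod, 0.8, atol=1e-6)
        assert np.allclose(out.frame["value"], 1000.0)

    def test_null_edge_effect_fits_unity(self):
        t = fq.PhenotypeTable(self._plate_rows(edge_mult=1.0))
        _, model = fq.normalize_edges(t)
        for e in ("top", "bottom", "left", "right"):
            assert np.isclose(model.edge_factors[(e, 72)], 1.0, atol=1e-6)

    def test_no_interior_wells_is_an_error(self):
        df = self._plate_rows()
        df = df[[fq.simcross.well_edge(r, c) is not None
                 for r, c in zip(df["well_row"], df["well_col"])]]
        with pytest.raises(ValueError, match="interior"):
            fq.normalize_edges(fq.PhenotypeTable(df))


class TestAggregation:
    def test_replicate_means_with_missing(self):
        t = _table([("a", "C", 72, 1, 1.0), ("a", "C", 72, 2, 3.0),
                    ("b", "C", 72, 1, 1.0), ("b", "C", 72, 2, np.nan),
                    ("c", "C", 72, 1, np.nan), ("c", "C", 72, 2, np.nan)])
        out = fq.aggregate_replicates(t)
        vals = out.frame.set_index("strain")["value"]
        assert vals["a"] == 2.0
        assert vals["b"] == 1.0
        assert np.isnan(vals["c"])


class TestPipeline:
    def test_rank_order_preserved_by_scaling_steps(self, haps2000):
        sub = haps2000.subset_strains(np.arange(200))
        design = fq.make_plate_design(list(sub.strains), seed=41)
        arch = fq.TraitArchitecture([], strain_noise_sd=200.0,
                                    replicate_noise_sd=50.0)
        raw, _ = fq.plant_and_phenotype(sub, arch, design, seed=41)
        plated, _ = fq.normalize_plates(raw)
        batched, _ = fq.normalize_batches(plated)
        for plate in raw.frame["plate"].unique()[:3]:
            sel = raw.frame["plate"] == plate
            before = raw.frame.loc[sel, "value"].rank()
            after = batched.frame.loc[sel, "value"].rank()
            assert (before == after).all()

    def test_pipeline_removes_most_artifact_variance(self, haps2000,
                                                     scaffold_idx):
        sub = haps2000.subset_strains(np.arange(500))
        design = fq.make_plate_design(list(sub.strains), seed=42)
        j = scaffold_idx[8]
        arch = fq.TraitArchitecture(
            [fq.CausalLocus(sub.markers.chrom[j], int(sub.markers.pos[j]),
                            [0, 0, 0, 0, 1, 1, 1, 1], [0.0, 400.0])],
            strain_noise_sd=150.0, replicate_noise_sd=100.0)
        raw, _ = fq.plant_and_phenotype(sub, arch, design, seed=42)
        masked, _ = fq.mask_small_patches(raw, min_area=0.0)
        plated, _ = fq.normalize_plates(masked)
        batched, _ = fq.normalize_batches(plated)
        edged, _ = fq.normalize_edges(batched)
        sel = ~raw.frame["control"]
        before = np.log(raw.frame.loc[sel, "value"]
                        / raw.frame.loc[sel, "true_value"]).var()
        after = np.log(edged.frame.loc[sel, "value"]
                       / edged.frame.loc[sel, "true_value"]).var()
        assert after < 0.1 * before

    def test_full_pipeline_records_order(self, haps2000):
        sub = haps2000.subset_strains(np.arange(150))
        design = fq.make_plate_design(list(sub.strains), seed=43)
        arch = fq.TraitArchitecture([], strain_noise_sd=100.0,
                                    replicate_noise_sd=50.0)
        raw, _ = fq.plant_and_phenotype(sub, arch, design, seed=43)
        final, model = fq.normalize_pipeline(raw, min_area=0.0)
        assert model.steps == ["mask", "plate", "batch", "edge", "aggregate"]
        assert final.meta["normalization_order"] == model.steps
        assert len(final.frame) == 150
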