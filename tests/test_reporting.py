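"""Master-table assembly, summaries, validation, KDE and EMD similarity."""

import numpy as np
import pandas as pd
import pytest

from rootphen.config import PipelineConfig
from rootphen.datasets import example_validation_counts
from rootphen.reporting import (
    assemble_master,
    emd_distance_matrix,
    emd_dendrogram,
    image_feature_vectors,
    size_kde,
    summaries_to_frame,
    summarize_genotypes,
    validate_counts,
)
from rootphen.schema import MASTER_COLUMNS


def fake_image_table(name, diams, cluster=None, nmdeep=3, wall=5000, inner=40000):
    n = len(diams)
    rng = np.random.default_rng(abs(hash(name)) % 2**31)
    t = pd.DataFrame({c: np.nan for c in MASTER_COLUMNS}, index=range(n))
    t["order"] = np.arange(1, n + 1)
    t["s.area"] = np.pi * (np.asarray(diams) / 2) ** 2
    t["s.perimeter"] = np.pi * np.asarray(diams)
    for c in ("s.radius.mean", "s.radius.sd", "s.radius.max", "s.radius.min"):
        t[c] = np.asarray(diams) / 2
    t["m.cx"] = rng.uniform(0, 1000, n)
    t["m.cy"] = rng.uniform(0, 300, n)
    t["m.majoraxis"] = diams
    t["m.eccentricity"] = 0.3
    t["m.theta"] = 0.0
    t["Meandiameterµm"] = diams
    t["Diameter_log"] = np.log10(diams)
    t["Q1"] = t["Q3"] = t["IQR"] = 0.0
    t["nmbpeak"] = nmdeep + 1
    t["nmdeep"] = nmdeep
    t["Cluster_drei"] = 2
    t["Cluster_zw"] = cluster if cluster is not None else ["VT"] * (n // 2) + ["SP"] * (n - n // 2)
    t["Imagetotalpix"] = 50000
    t["Innerpixarea"] = inner
    t["Cellwallcount"] = wall
    t["Intercellcount"] = 100
    t["Dataname"] = name
    return t


class TestAssembleMaster:
    def test_single_image_passthrough(self):
        t = fake_image_table("a.tif", [10.0, 20.0])
        m = assemble_master([t])
        assert list(m.columns) == MASTER_COLUMNS
        assert len(m) == 2

    def test_two_images_concatenate(self):
        m = assemble_master(
            [fake_image_table("a.tif", np.full(10, 15.0)), fake_image_table("b.tif", np.full(20, 25.0))]
        )
        assert len(m) == 30
        assert set(m["Dataname"]) == {"a.tif", "b.tif"}

    def test_missing_column_is_an_error(self):
        t = fake_image_table("a.tif", [10.0]).drop(columns=["Cellwallcount"])
        with pytest.raises(ValueError, match="Cellwallcount"):
            assemble_master([t])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            assemble_master([])


class TestSummaries:
    def test_single_image_arithmetic(self):
        m = assemble_master([fake_image_table("a.tif", [10.0, 10.0, 20.0, 40.0])])
        (s,) = summarize_genotypes(m, {"a.tif": "G1"})
        assert s.n_cells_mean == 4
        assert s.mean_diam_mean == pytest.approx(20.0)
        assert s.max_diam_mean == pytest.approx(40.0)
        assert s.wall_fraction_mean == pytest.approx(5000 / 40000)

    def test_identical_images_have_zero_sd(self):
        a = fake_image_table("a.tif", np.full(12, 18.0))
        b = fake_image_table("b.tif", np.full(12, 18.0))
        (s,) = summarize_genotypes(assemble_master([a, b]), {"a.tif": "G", "b.tif": "G"})
        assert s.n_images == 2
        assert s.n_cells_sd == 0 and s.mean_diam_sd == 0

    def test_planted_ordering_preserved(self):
        g1 = [fake_image_table(f"g1_{i}.tif", np.random.default_rng(i).normal(17, 1, 50)) for i in range(2)]
        g2 = [fake_image_table(f"g2_{i}.tif", np.random.default_rng(i).normal(22, 1, 50)) for i in range(2)]
        mapping = {t["Dataname"].iloc[0]: ("A" if "g1" in t["Dataname"].iloc[0] else "B") for t in g1 + g2}
        s = {x.genotype: x for x in summarize_genotypes(assemble_master(g1 + g2), mapping)}
        assert s["A"].mean_diam_mean < s["B"].mean_diam_mean

    def test_unmapped_image_errors(self):
        m = assemble_master([fake_image_table("a.tif", [10.0])])
        with pytest.raises(ValueError, match="a.tif"):
            summarize_genotypes(m, {})

    def test_cluster_shares_sum_to_hundred(self):
        m = assemble_master([fake_image_table("a.tif", np.linspace(8, 40, 30))])
        (s,) = summarize_genotypes(m, {"a.tif": "G"})
        assert 0 <= s.vt_cell_share_pct <= 100
        sp_share = 100 - s.vt_cell_share_pct
        assert s.vt_cell_share_pct + sp_share == pytest.approx(100)
        frame = summaries_to_frame([s])
        assert "Mean cell diameter [µm]" in frame.columns


class TestValidateCounts:
    def test_perfect_agreement(self):
        assert validate_counts([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_scale_free(self):
        assert validate_counts([2, 4, 6, 8], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_published_validation_counts(self):
        df = example_validation_counts()
        r2_w = validate_counts(df["watershed_count"], df["ground_truth"])
        r2_f = validate_counts(df["final_count"], df["ground_truth"])
        assert r2_w == pytest.approx(0.9798, abs=5e-4)
        assert r2_f == pytest.approx(0.9815, abs=5e-4)

    def test_length_mismatch_and_short_vectors(self):
        with pytest.raises(ValueError):
            validate_counts([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            validate_counts([1, 2], [1, 2])


class TestSizeKde:
    def test_mode_near_sample_mean(self, cfg):
        rng = np.random.default_rng(0)
        grid, dens = size_kde(rng.normal(12, 2, 4000), cfg)
        assert grid[np.argmax(dens)] == pytest.approx(12.0, abs=0.5)

    def test_integrates_to_one(self, cfg):
        rng = np.random.default_rng(1)
        grid, dens = size_kde(rng.normal(20, 5, 500), cfg)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_two_points_give_symmetric_bimodal_curve(self, cfg):
        grid, dens = size_kde(np.array([0.0, 10.0]), cfg)
        assert dens[np.argmin(np.abs(grid - 0))] == pytest.approx(
            dens[np.argmin(np.abs(grid - 10))], rel=0.05
        )
        assert dens[np.argmin(np.abs(grid - 5))] < dens[np.argmin(np.abs(grid - 0))]

    def test_too_few_values(self, cfg):
        with pytest.raises(ValueError):
            size_kde(np.array([5.0]), cfg)


def _three_genotype_master(shift_c=20.0):
    tables, groups = [], {}
    for g, base in (("A", 15.0), ("B", 15.5), ("C", 15.0 + shift_c)):
        for i in range(3):
            name = f"{g}{i}.tif"
            rng = np.random.default_rng(hash((g, i)) % 2**31)
            tables.append(fake_image_table(name, rng.normal(base, 1.0, 60)))
            groups[name] = g
    return assemble_master(tables), groups


class TestEmdSimilarity:
    def test_identical_groups_have_zero_distance(self, cfg):
        tables, groups = [], {}
        for g in ("A", "B"):
            for i in range(2):
                name = f"{g}{i}.tif"
                tables.append(fake_image_table(f"img{i}.tif", np.linspace(10, 30, 40)).assign(Dataname=name))
                groups[name] = g
        m = assemble_master(tables)
        dmat, labels = emd_distance_matrix(image_feature_vectors(m), groups, cfg)
        assert dmat[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_distance_matrix_symmetric_zero_diagonal(self, cfg):
        m, groups = _three_genotype_master()
        dmat, labels = emd_distance_matrix(image_feature_vectors(m), groups, cfg)
        assert np.allclose(dmat, dmat.T)
        assert np.allclose(np.diag(dmat), 0)

    def test_shifted_genotype_forms_outgroup(self, cfg):
        m, groups = _three_genotype_master(shift_c=20.0)
        newick, dmat, labels = emd_dendrogram(m, groups, cfg)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        # the two similar genotypes (A, B) merge before C joins
        mrca = tree.mrca(taxon_labels=["A", "B"])
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"A", "B"}

    def test_banned_columns_excluded_from_vectors(self):
        m, _ = _three_genotype_master()
        vec = image_feature_vectors(m)
        banned = ("m.cx", "m.cy", "Q1", "Q3", "IQR", "order")
        assert not [c for c in vec.columns if any(c.startswith(f"{b}.") for b in banned)]

    def test_single_group_is_an_error(self, cfg):
        m = assemble_master([fake_image_table("a.tif", np.full(10, 15.0))])
        with pytest.raises(ValueError):
            emd_distance_matrix(image_feature_vectors(m), {"a.tif": "G"}, cfg)
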