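"""Region classification, GO enrichment, allele direction, karyogram."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastgwas import annotate, popgen, scans, simdata
from plastgwas.simdata import QTLSpec, SimConfig

GFF = """##gff-version 3
1H\ttest\tgene\t100\t1000\t.\t+\t.\tID=gene1
1H\ttest\tmRNA\t100\t1000\t.\t+\t.\tID=mrna1;Parent=gene1
1H\ttest\tCDS\t100\t200\t.\t+\t0\tID=cds1a;Parent=mrna1
1H\ttest\tCDS\t400\t600\t.\t+\t0\tID=cds1b;Parent=mrna1
2H\ttest\tgene\t5000\t6000\t.\t-\t.\tID=gene2
2H\ttest\tmRNA\t5000\t6000\t.\t-\t.\tID=mrna2;Parent=gene2
2H\ttest\tCDS\t5000\t6000\t.\t-\t0\tID=cds2;Parent=mrna2
"""


@pytest.fixture()
def gff_path(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF)
    return path


def _markers(rows):
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])


class TestClassifyRegion:
    def test_three_way_classification(self, gff_path):
        markers = _markers([
            ("in_cds", "1H", 150),
            ("between_cds", "1H", 300),
            ("far_away", "1H", 11_000),
            ("other_gene", "2H", 5500),
        ])
        out = annotate.classify_region(markers, gff_path).set_index("marker_id")
        assert out.loc["in_cds", "region"] == "coding"
        assert out.loc["in_cds", "gene_id"] == "gene1"
        assert out.loc["between_cds", "region"] == "intronic"
        assert out.loc["far_away", "region"] == "intergenic"
        assert out.loc["far_away", "distance"] == 10_000
        assert out.loc["other_gene", "region"] == "coding"

    def test_partition_property(self, gff_path):
        rng = np.random.default_rng(0)
        markers = _markers(
            [(f"m{i}", "1H", int(p)) for i, p in enumerate(rng.integers(1, 20_000, 50))]
        )
        out = annotate.classify_region(markers, gff_path)
        assert len(out) == len(markers)
        assert set(out["region"]) <= {"coding", "intronic", "intergenic"}
        coding = out[out["region"] == "coding"]
        assert coding["gene_id"].notna().all()

    def test_malformed_gff_reports_line(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("##gff-version 3\n1H\ttest\tgene\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            annotate.classify_region(_markers([("m", "1H", 1)]), bad)

    def test_bad_coordinates_report_line(self, tmp_path):
        bad = tmp_path / "bad2.gff3"
        bad.write_text(
            "##gff-version 3\n"
            "1H\tt\tgene\t100\t1000\t.\t+\t.\tID=g\n"
            "1H\tt\tgene\t500\t100\t.\t+\t.\tID=h\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            annotate.classify_region(_markers([("m", "1H", 1)]), bad)


def hypergeom_tail_oracle(k, N, K, n):
    """Exact-rational upper tail P(X >= k) by direct enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return float(total)


class TestGoEnrichment:
    def _g2g(self, mapping):
        rows = [(g, t, "biological_process") for t, gs in mapping.items() for g in gs]
        return pd.DataFrame(rows, columns=["gene_id", "go_id", "namespace"])

    def test_fisher_matches_hypergeometric_oracle(self):
        population = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(10)}
        term_genes = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(20, 25)}
        out = annotate.go_enrichment(study, population, self._g2g({"GO:1": term_genes}))
        assert out.loc[0, "study_count"] == 5
        expected = hypergeom_tail_oracle(5, 100, 10, 10)
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)

    def test_study_equals_population_gives_p_one(self):
        population = {f"g{i}" for i in range(20)}
        out = annotate.go_enrichment(
            population, population, self._g2g({"GO:1": {f"g{i}" for i in range(7)}})
        )
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_single_term_fdr_equals_p(self):
        population = {f"g{i}" for i in range(30)}
        study = {f"g{i}" for i in range(6)}
        out = annotate.go_enrichment(
            study, population, self._g2g({"GO:1": {f"g{i}" for i in range(3)}})
        )
        assert len(out) == 1
        assert out.loc[0, "fdr"] == out.loc[0, "p_value"]

    def test_study_outside_population_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            annotate.go_enrichment({"x"}, {"a", "b"}, self._g2g({"GO:1": {"a"}}))

    def test_bh_fdr_monotone_after_step_up(self):
        rng = np.random.default_rng(1)
        population = {f"g{i}" for i in range(60)}
        study = set(rng.choice(sorted(population), size=15, replace=False))
        mapping = {
            f"GO:{t}": set(rng.choice(sorted(population), size=rng.integers(3, 20),
                                      replace=False))
            for t in range(8)
        }
        out = annotate.go_enrichment(study, population, self._g2g(mapping))
        if len(out) > 1:
            assert (np.diff(out["fdr"].to_numpy()) >= -1e-12).all()
            assert (out["fdr"] >= out["p_value"] - 1e-12).all()


class TestAlleleDirection:
    def _case(self, kind, seed):
        cfg = SimConfig(
            n_families=4, lines_per_family=50, markers_per_chromosome=10,
            missing_rate=0.0, n_replicates=2, sigma2_poly=0.3,
            sigma2_resid=1.0, seed=seed,
        )
        panel = simdata.simulate_genotypes(cfg)
        reg = simdata.plant_qtls(
            panel, [QTLSpec(kind, var_frac=0.15)], seed=seed + 1,
            sigma2_poly=cfg.sigma2_poly, sigma2_resid=cfg.sigma2_resid,
        )
        phen = simdata.simulate_phenotypes(panel, reg, cfg)
        from plastgwas import plasticity

        means = plasticity.env_means(phen)
        plast = plasticity.plasticity_table(means)
        K = popgen.kinship(panel)
        ww = plast.xs("GY", level="trait")["WW"]
        wl = plast.xs("GY", level="trait")["WL"]
        eff_ww = scans.mlm_scan(panel, ww, K).table
        eff_wl = scans.mlm_scan(panel, wl, K).table
        marker = reg.entries["marker_id"].iloc[0]
        out = annotate.allele_direction(panel, plast, eff_ww, eff_wl, [marker], "GY")
        return out

    def test_antagonistic_qtl_flagged(self):
        out = self._case("antagonistic", seed=31)
        assert out["antagonistic"].all()

    def test_main_effect_qtl_not_flagged(self):
        out = self._case("main", seed=32)
        assert not out["antagonistic"].any()

    def test_allele_means_present_per_estimator(self):
        out = self._case("antagonistic", seed=33)
        assert set(out["estimator"]) == {"WW", "WL", "Ratio", "RDPI", "Linear"}
        assert (out.groupby("estimator")["allele"].nunique() == 2).all()

    def test_monomorphic_marker_skipped(self, small_panel):
        from plastgwas import plasticity

        plast = pd.DataFrame(
            {"WW": 1.0, "WL": 1.0, "Ratio": 1.0, "RDPI": 0.0, "Linear": 1.0},
            index=pd.MultiIndex.from_product(
                [small_panel.line_ids, ["GY"]], names=["genotype", "trait"]
            ),
        )
        panel = small_panel
        panel.genotypes[:, 0] = 0.0
        eff = pd.DataFrame(
            {"marker_id": panel.markers["marker_id"], "score": 1.0, "se": 0.1}
        )
        mk = panel.markers["marker_id"].iloc[0]
        with pytest.warns(UserWarning, match="monomorphic"):
            out = annotate.allele_direction(panel, plast, eff, eff, [mk], "GY")
        assert out.empty


class TestKaryogram:
    def test_coordinate_conversion_and_round_trip(self, tmp_path):
        markers = pd.DataFrame(
            {"marker_id": ["m1", "m2"], "chrom": ["1H", "2H"],
             "pos": [100, 5000], "trait": ["GY", "HI"]}
        )
        lengths = {"1H": 10_000, "2H": 10_000}
        path = tmp_path / "karyo.bed"
        bed = annotate.karyogram_export(markers, lengths, path=path)
        assert bed.loc[0, "start"] == 99 and bed.loc[0, "end"] == 100
        back = annotate.read_bed_track(path)
        assert list(back["pos"]) == [100, 5000]
        assert list(back["name"]) == ["GY", "HI"]

    def test_position_beyond_length_rejected(self):
        markers = pd.DataFrame(
            {"marker_id": ["m1"], "chrom": ["1H"], "pos": [200], "trait": ["GY"]}
        )
        with pytest.raises(ValueError, match="beyond"):
            annotate.karyogram_export(markers, {"1H": 100})

    def test_empty_track(self):
        markers = pd.DataFrame(columns=["marker_id", "chrom", "pos", "trait"])
        bed = annotate.karyogram_export(markers, {"1H": 100})
        assert bed.empty


class TestSyntheticAnnotation:
    def test_fixture_is_classifiable(self, small_panel, tmp_path):
        gff_text, gene2go = annotate.synthetic_annotation(
            small_panel, seed=3, out_dir=tmp_path
        )
        out = annotate.classify_region(small_panel.markers, tmp_path / "annotation.gff3")
        counts = out["region"].value_counts()
        assert counts.get("coding", 0) > 0
        assert counts.get("intergenic", 0) > 0
        assert set(gene2go.columns) == {"gene_id", "go_id", "namespace"}
        assert gene2go["gene_id"].str.startswith("GENE").all()
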