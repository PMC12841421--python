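"""Association scans: OLS oracle equivalence, recovery, calls, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastgwas import popgen, scans, simdata
from plastgwas.simdata import QTLSpec, SimConfig


def _panel_response(seed, var_frac=0.20, n_families=5, lines_per_family=60,
                    markers_per_chromosome=30, kind="main"):
    cfg = SimConfig(
        n_families=n_families, lines_per_family=lines_per_family,
        markers_per_chromosome=markers_per_chromosome, missing_rate=0.0,
        n_replicates=1, sigma2_poly=0.3, sigma2_resid=1.0, seed=seed,
    )
    panel = simdata.simulate_genotypes(cfg)
    reg = simdata.plant_qtls(
        panel, [QTLSpec(kind, var_frac=var_frac)], seed=seed + 1,
        sigma2_poly=cfg.sigma2_poly, sigma2_resid=cfg.sigma2_resid,
    )
    phen = simdata.simulate_phenotypes(panel, reg, cfg)
    y = (
        phen[phen["env"] == "WW"].set_index("genotype")["value"]
        .reindex(panel.line_ids)
    )
    return panel, reg, y


def _ols_pvalues(y, geno):
    n = len(y)
    out = np.empty(geno.shape[1])
    for j in range(geno.shape[1]):
        x = np.column_stack([np.ones(n), geno[:, j]])
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        out[j] = 2 * stats.t.sf(abs(coef[1] / se), n - 2)
    return out


class TestMlmScan:
    def test_identity_kinship_equals_ols_oracle(self):
        panel, _, y = _panel_response(seed=1, markers_per_chromosome=10)
        k = np.eye(panel.n_lines)
        res = scans.mlm_scan(panel, y, k)
        oracle = _ols_pvalues(y.to_numpy(), panel.imputed())
        ok = np.isfinite(res.table["p_value"].to_numpy())
        np.testing.assert_allclose(
            res.table["p_value"].to_numpy()[ok], oracle[ok], atol=1e-8
        )

    def test_planted_qtl_is_top_hit(self):
        panel, reg, y = _panel_response(seed=2, var_frac=0.20)
        K = popgen.kinship(panel)
        res = scans.mlm_scan(panel, y, K)
        top = res.table.loc[res.table["p_value"].idxmin(), "marker_id"]
        causal = reg.entries["marker_id"].iloc[0]
        j_top = panel.marker_index([top])[0]
        j_cau = panel.marker_index([causal])[0]
        r2 = np.corrcoef(panel.genotypes[:, j_top], panel.genotypes[:, j_cau])[0, 1] ** 2
        assert top == causal or r2 >= 0.8

    def test_length_mismatch_rejected(self, small_panel):
        with pytest.raises(ValueError, match="length"):
            scans.mlm_scan(small_panel, np.ones(3), np.eye(small_panel.n_lines))

    def test_monomorphic_marker_flagged_absent(self):
        panel, _, y = _panel_response(seed=3, markers_per_chromosome=5)
        panel.genotypes[:, 0] = 0.0
        res = scans.mlm_scan(panel, y, popgen.kinship(panel))
        assert np.isnan(res.table["p_value"].iloc[0])

    def test_marker_order_invariance(self):
        panel, _, y = _panel_response(seed=4, markers_per_chromosome=8)
        K = popgen.kinship(panel)
        p1 = scans.mlm_scan(panel, y, K).table.set_index("marker_id")["p_value"]
        perm = np.random.default_rng(0).permutation(panel.n_markers)
        markers = panel.markers.iloc[perm].reset_index(drop=True)
        markers = markers.sort_values(["chrom", "pos"]).reset_index(drop=True)
        order = panel.marker_index(markers["marker_id"])
        shuffled = simdata.GenotypePanel(
            genotypes=panel.genotypes[:, order],
            markers=markers,
            line_ids=panel.line_ids,
            families=panel.families,
        )
        p2 = scans.mlm_scan(shuffled, y, K).table.set_index("marker_id")["p_value"]
        pd.testing.assert_series_equal(p1.sort_index(), p2.sort_index(), atol=1e-12)


class TestMultilocusScan:
    def test_no_entry_reduces_to_single_marker_scan(self):
        rng = np.random.default_rng(5)
        panel, _, y = _panel_response(seed=5, markers_per_chromosome=8)
        noise = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
        res = scans.multilocus_scan(panel, noise, entry_p=1e-12)
        assert res.meta["pseudo_qtns"] == []
        plain = _ols_pvalues(noise.to_numpy(), panel.imputed())
        ok = np.isfinite(res.table["p_value"].to_numpy())
        np.testing.assert_allclose(res.table["p_value"].to_numpy()[ok], plain[ok], atol=1e-10)

    def test_two_unlinked_qtls_recovered(self):
        hits = 0
        for seed in range(5):
            cfg = SimConfig(
                n_families=4, lines_per_family=60, markers_per_chromosome=15,
                missing_rate=0.0, n_replicates=1, sigma2_poly=0.2,
                sigma2_resid=1.0, seed=600 + seed,
            )
            panel = simdata.simulate_genotypes(cfg)
            reg = simdata.plant_qtls(
                panel, [QTLSpec("main", var_frac=0.15), QTLSpec("main", var_frac=0.15)],
                seed=seed, sigma2_poly=cfg.sigma2_poly, sigma2_resid=cfg.sigma2_resid,
            )
            phen = simdata.simulate_phenotypes(panel, reg, cfg)
            y = phen[phen["env"] == "WW"].set_index("genotype")["value"].reindex(panel.line_ids)
            res = scans.multilocus_scan(panel, y)
            res = scans.call_significant(res, "bonferroni", 0.05)
            called = res.significant_markers()
            geno = panel.imputed()
            found = 0
            for mk in reg.entries["marker_id"]:
                j = panel.marker_index([mk])[0]
                for c in called:
                    jc = panel.marker_index([c])[0]
                    if np.corrcoef(geno[:, j], geno[:, jc])[0, 1] ** 2 >= 0.8:
                        found += 1
                        break
            if found == 2:
                hits += 1
        assert hits >= 4

    def test_null_family_wise_error_controlled(self):
        fp = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(900 + seed)
            cfg = SimConfig(
                n_families=3, lines_per_family=30, markers_per_chromosome=10,
                missing_rate=0.0, seed=seed,
            )
            panel = simdata.simulate_genotypes(cfg)
            y = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
            res = scans.multilocus_scan(panel, y)
            res = scans.call_significant(res, "bonferroni", 0.05)
            if res.significant_markers():
                fp += 1
        assert fp / n_seeds <= 0.15


class TestMlImportanceScan:
    @pytest.mark.parametrize("learner", ["RF", "GB"])
    def test_planted_qtl_top_importance_and_deterministic(self, learner):
        panel, reg, y = _panel_response(
            seed=6, var_frac=0.25, n_families=3, lines_per_family=40,
            markers_per_chromosome=8,
        )
        res1 = scans.ml_importance_scan(
            panel, y, learner, n_permutations=100, seed=5, n_estimators=60
        )
        res2 = scans.ml_importance_scan(
            panel, y, learner, n_permutations=100, seed=5, n_estimators=60
        )
        np.testing.assert_array_equal(
            res1.table["score"].to_numpy(), res2.table["score"].to_numpy()
        )
        np.testing.assert_array_equal(
            res1.table["p_value"].to_numpy(), res2.table["p_value"].to_numpy()
        )
        top = res1.table.loc[res1.table["score"].idxmax(), "marker_id"]
        causal = reg.entries["marker_id"].iloc[0]
        j_top, j_cau = panel.marker_index([top, causal])
        r2 = np.corrcoef(panel.genotypes[:, j_top], panel.genotypes[:, j_cau])[0, 1] ** 2
        assert top == causal or r2 >= 0.8

    def test_constant_response_rejected(self, small_panel):
        y = pd.Series(1.0, index=small_panel.line_ids)
        with pytest.raises(ValueError, match="constant"):
            scans.ml_importance_scan(small_panel, y, "RF", n_permutations=100, seed=0)

    def test_too_few_permutations_rejected(self, small_panel):
        y = pd.Series(np.arange(small_panel.n_lines, dtype=float),
                      index=small_panel.line_ids)
        with pytest.raises(ValueError, match="n_permutations"):
            scans.ml_importance_scan(small_panel, y, "RF", n_permutations=10, seed=0)


class TestCallSignificant:
    def _result(self, pvals):
        table = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(pvals))],
                "chrom": "1H",
                "pos": np.arange(len(pvals)) + 1,
                "score": 0.0,
                "se": np.nan,
                "p_value": pvals,
                "significant": False,
            }
        )
        return scans.ScanResult("MLM", "GY", "WW", table)

    def test_all_p_one_yields_no_calls(self):
        res = scans.call_significant(self._result([1.0] * 10), "bh_fdr", 0.05)
        assert res.significant_markers() == set()

    def test_bonferroni_cutoff(self):
        pvals = [4e-4] + [0.5] * 99
        res = scans.call_significant(self._result(pvals), "bonferroni", 0.05)
        assert res.significant_markers() == {"m0"}
        res2 = scans.call_significant(self._result([6e-4] + [0.5] * 99), "bonferroni", 0.05)
        assert res2.significant_markers() == set()

    def test_bh_matches_step_up_oracle(self):
        def bh_oracle(pvals, alpha):
            m = len(pvals)
            order = np.argsort(pvals)
            k = 0
            for rank, idx in enumerate(order, start=1):
                if pvals[idx] <= alpha * rank / m:
                    k = rank
            return {idx for idx in order[:k]}

        rng = np.random.default_rng(11)
        for _ in range(20):
            pvals = np.round(rng.uniform(0, 1, size=12) ** 2, 4)
            res = scans.call_significant(self._result(pvals), "bh_fdr", 0.05)
            got = {int(m[1:]) for m in res.significant_markers()}
            assert got == bh_oracle(pvals, 0.05)
        toy = [0.001, 0.01, 0.02, 0.8]
        res = scans.call_significant(self._result(toy), "bh_fdr", 0.05)
        assert {int(m[1:]) for m in res.significant_markers()} == bh_oracle(np.array(toy), 0.05)

    def test_unknown_procedure_rejected(self):
        with pytest.raises(ValueError, match="unknown procedure"):
            scans.call_significant(self._result([0.5]), "holm", 0.05)
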