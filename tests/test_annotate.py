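"""Catalog gene-assignment, burden convergence, and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cispqtl.annotate import (
    bonferroni_threshold,
    catalog_overlap,
    classify_assignment,
    exwas_convergence,
    feature_enrichment,
    filter_catalog,
    ld_proxies,
)
from cispqtl.simulate import simulate_catalog_and_burden


class TestLdProxies:
    def test_variant_is_its_own_proxy(self):
        R = np.eye(4)
        assert list(ld_proxies(2, R)) == [2]

    def test_inclusive_boundary_at_r2_0_8(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.894  # r^2 = 0.7992 -> excluded
        R[0, 2] = R[2, 0] = 0.895  # r^2 = 0.8010 -> included
        idx = ld_proxies(0, R, r2_min=0.8)
        assert 1 not in idx and 2 in idx

    def test_negative_correlation_counts_by_r2(self):
        R = np.eye(2)
        R[0, 1] = R[1, 0] = -0.95
        assert 1 in ld_proxies(0, R)

    def test_asymmetric_matrix_rejected(self):
        R = np.eye(2)
        R[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ld_proxies(0, R)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 12))
        A = rng.uniform(-1, 1, (m, m))
        R = (A + A.T) / 2
        np.fill_diagonal(R, 1.0)
        j = int(rng.integers(0, m))
        expected = [k for k in range(m) if R[j, k] ** 2 >= 0.8]
        assert list(ld_proxies(j, R)) == expected


class TestClassification:
    def test_unique_report_confirmed(self):
        assert classify_assignment("GENE1", ["GENE1"], "GENE1") == "confirmed"

    def test_longer_list_refined(self):
        assert classify_assignment("GENE1", ["GENE1", "OTHER"], "GENE1") == "refined"

    def test_absent_everywhere_novel(self):
        assert classify_assignment("GENE1", ["DECOY"], "DECOY2") == "novel_reassignment"

    def test_mapped_only_refined(self):
        assert classify_assignment("GENE1", ["DECOY"], "GENE1") == "refined"


class TestCatalogOverlap:
    def _setup(self):
        truth_leads = pd.DataFrame(
            {
                "set_id": ["cs0", "cs1", "cs2"],
                "lead_id": ["rs1", "rs2", "rs3"],
                "chrom": "1",
                "pos": [100, 200, 300],
                "protein_gene": ["GENE1", "GENE2", "GENE3"],
            }
        )
        genes = pd.DataFrame(
            {
                "protein_gene": ["GENE1", "GENE2", "GENE3"],
                "nearest_gene": ["NB1", "NB2", "NB3"],
                "decoy_gene": ["DEC1", "DEC2", "DEC3"],
            }
        )
        ids = ["rs1", "rs1_p", "rs2", "rs2_p", "rs3", "rs3_p"]
        R = np.eye(6)
        for k in (0, 2, 4):  # each lead has one r=0.95 proxy
            R[k, k + 1] = R[k + 1, k] = 0.95
        ld = pd.DataFrame(R, index=ids, columns=ids)
        return truth_leads, genes, ld

    def test_expected_classifications_recovered(self):
        truth_leads, genes, ld = self._setup()
        catalog, _, labels = simulate_catalog_and_burden(
            truth_leads, genes, ld=ld, seed=2
        )
        filtered, counts = filter_catalog(catalog)
        assert counts["rows_dropped"] >= 2  # unrelated rows fail invariants
        matches = catalog_overlap(truth_leads, filtered, R=ld)
        by_set = {m.set_id: m for m in matches}
        assert by_set["cs0"].classification == "confirmed"
        assert by_set["cs0"].match_type == "direct"
        assert by_set["cs1"].classification == "novel_reassignment"
        assert by_set["cs1"].match_type == "proxy"
        assert by_set["cs1"].nearest_gene_differs
        assert by_set["cs2"].classification == "refined"

    def test_every_match_classified(self):
        truth_leads, genes, ld = self._setup()
        catalog, _, _ = simulate_catalog_and_burden(truth_leads, genes, ld=ld, seed=3)
        filtered, _ = filter_catalog(catalog)
        matches = catalog_overlap(truth_leads, filtered, R=ld)
        valid = {"confirmed", "refined", "novel_reassignment"}
        assert matches and all(m.classification in valid for m in matches)

    def test_trait_denylist_excludes_proteomic_assays(self):
        truth_leads, genes, ld = self._setup()
        catalog, _, _ = simulate_catalog_and_burden(truth_leads, genes, ld=ld, seed=4)
        catalog.loc[0, "DISEASE/TRAIT"] = "Olink proteomics panel"
        filtered, _ = filter_catalog(
            catalog, trait_denylist=["Olink proteomics panel"]
        )
        assert "Olink proteomics panel" not in set(filtered["DISEASE/TRAIT"])


class TestExwasConvergence:
    def _coloc(self):
        return pd.DataFrame(
            {
                "gene": ["B", "C"],
                "trait": ["lipids", "lipids"],
                "pp": [0.95, 0.9],
            }
        )

    def _burden(self):
        return pd.DataFrame(
            {
                "gene": ["A", "C", "C"],
                "trait": ["lipids", "lipids", "lipids"],
                "mask": ["pLoF", "pLoF", "pLoF+missense"],
                "beta": [0.2, 0.25, 0.18],
                "p": [1e-9, 1e-8, 1e-7],
            }
        )

    def test_counts_partition_genes(self):
        summary = exwas_convergence(self._coloc(), self._burden(), ["A", "B", "C"])
        assert summary.counts == {"exwas_only": 1, "pqtl_only": 1, "both": 1}

    def test_most_significant_mask_kept(self):
        summary = exwas_convergence(self._coloc(), self._burden(), ["A", "B", "C"])
        pairs = summary.overlapping_pairs
        assert len(pairs) == 1
        assert pairs.iloc[0]["mask"] == "pLoF"
        assert pairs.iloc[0]["burden_p"] == 1e-8

    def test_empty_burden_table(self):
        empty = self._burden().iloc[0:0]
        summary = exwas_convergence(self._coloc(), empty, ["A", "B", "C"])
        assert summary.counts == {"exwas_only": 0, "pqtl_only": 2, "both": 0}

    def test_row_order_and_duplicates_irrelevant(self):
        b = self._burden()
        shuffled = pd.concat([b.iloc[::-1], b.iloc[[0]]], ignore_index=True)
        a = exwas_convergence(self._coloc(), b, ["A", "B", "C"])
        c = exwas_convergence(self._coloc(), shuffled, ["A", "B", "C"])
        assert a.counts == c.counts
        assert a.overlapping_pairs["burden_p"].tolist() == \
            c.overlapping_pairs["burden_p"].tolist()

    def test_uncovered_genes_excluded_and_logged(self):
        summary = exwas_convergence(self._coloc(), self._burden(), ["A", "C"])
        assert summary.excluded_genes["coloc"] == ["B"]

    def test_trait_map_bridges_naming(self):
        coloc = pd.DataFrame({"gene": ["C"], "trait": ["LDL cholesterol"], "pp": [0.9]})
        summary = exwas_convergence(
            coloc, self._burden(), ["C"], trait_map={"LDL cholesterol": "lipids"}
        )
        assert len(summary.overlapping_pairs) == 1


class TestFeatureEnrichment:
    def test_exact_p_on_diagonal_table(self):
        # [[2,0],[0,2]]: enumeration over a in {0,1,2} gives masses 1/6, 4/6, 1/6
        has = np.array([1, 1, 0, 0], dtype=bool)
        feat = np.array([1, 1, 0, 0], dtype=bool)
        _, _, p = feature_enrichment(has, feat)
        assert abs(p - 1 / 3) < 1e-12

    def test_swapping_flags_inverts_or_keeps_p(self, rng):
        has = rng.random(60) < 0.4
        feat = rng.random(60) < 0.5
        or1, _, p1 = feature_enrichment(has, feat)
        or2, _, p2 = feature_enrichment(~has, feat)
        assert abs(p1 - p2) < 1e-12
        assert abs(or1 * or2 - 1) < 1e-9

    def test_matches_permutation_estimate(self):
        rng = np.random.default_rng(5)
        has = rng.random(40) < 0.5
        feat = np.where(has, rng.random(40) < 0.7, rng.random(40) < 0.3)
        odds, _, p = feature_enrichment(has, feat)
        a_obs = int(np.sum(has & feat))
        from scipy.stats import hypergeom

        M, n, N = 40, int(feat.sum()), int(has.sum())
        probs = hypergeom.pmf(np.arange(0, n + 1), M, n, N)
        p_enum = probs[probs <= probs[a_obs] * (1 + 1e-7)].sum()
        assert abs(p - p_enum) < 1e-9
        # Monte-Carlo permutation agreement
        perm_hits = 0
        reps = 20000
        for _ in range(reps):
            a_perm = int(np.sum(has & rng.permutation(feat)))
            if probs[a_perm] <= probs[a_obs] * (1 + 1e-7):
                perm_hits += 1
        assert abs(perm_hits / reps - p) < 0.02

    def test_null_flags_give_uniformish_p(self, rng):
        ps = []
        for _ in range(200):
            has = rng.random(100) < 0.3
            feat = rng.random(100) < 0.4
            ps.append(feature_enrichment(has, feat)[2])
        # conservative discrete p-values: at most nominal rejections
        assert np.mean(np.array(ps) < 0.05) < 0.08

    def test_zero_cell_uses_continuity_correction(self):
        has = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        feat = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        odds, (lo, hi), p = feature_enrichment(has, feat)
        assert np.isfinite(odds) and np.isfinite(lo) and np.isfinite(hi)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            feature_enrichment(np.ones(3, bool), np.ones(4, bool))


class TestBonferroni:
    def test_printed_study_threshold(self):
        thr = bonferroni_threshold(0.05, 1553)
        assert abs(thr - 3.21e-5) < 1e-7  # agrees at printed precision

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_simple_cases(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == expected

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
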