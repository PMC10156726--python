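"""Intersection logic, enrichment tests and the TFBS-loss filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cavepopgen import candidates as cand
from cavepopgen.panel import GeneModel, Population


def _sweep_table(assignments, window_bp=5_000, n_win=10, pops_meta=None):
    """assignments: pop -> {window_index: class}; everything else neutral."""
    rows = []
    for pop, classes in assignments.items():
        for w in range(n_win):
            rows.append({"chrom": "chr1", "start": w * window_bp,
                         "end": (w + 1) * window_bp, "pop": pop,
                         "class": classes.get(w, "neutral")})
    return cand.SweepCallTable(pd.DataFrame(rows), pops_meta)


GENE = GeneModel("g1", "chr1", 12_000, 18_000, "+")  # windows 2 and 3
META = {
    "cave1": Population("cave1", "cave", 1),
    "cave2": Population("cave2", "cave", 2),
    "cave3": Population("cave3", "cave", 2),
    "surf1": Population("surf1", "surface", 1),
    "surf2": Population("surf2", "surface", 2),
}


class TestCaveAdaptiveGenes:
    def test_soft_sweep_in_cave_neutral_surface_included(self):
        table = _sweep_table({"cave1": {2: "soft"}, "surf1": {}}, pops_meta=META)
        assert cand.cave_adaptive_genes(table, [GENE], "cave1", "surf1") == {"g1"}

    def test_linked_call_is_not_a_sweep(self):
        table = _sweep_table({"cave1": {2: "hardLinked"}, "surf1": {}},
                             pops_meta=META)
        assert cand.cave_adaptive_genes(table, [GENE], "cave1", "surf1") == set()

    def test_surface_sweep_vetoes_gene(self):
        table = _sweep_table({"cave1": {2: "hard"}, "surf1": {3: "soft"}},
                             pops_meta=META)
        assert cand.cave_adaptive_genes(table, [GENE], "cave1", "surf1") == set()

    def test_skipped_surface_windows_are_evidence_neutral(self):
        table = _sweep_table({"cave1": {2: "hard"},
                              "surf1": {2: "skipped", 3: "skipped"}},
                             pops_meta=META)
        assert cand.cave_adaptive_genes(table, [GENE], "cave1", "surf1") == {"g1"}

    def test_cross_lineage_pairing_rejected(self):
        table = _sweep_table({"cave1": {2: "hard"}, "surf2": {}}, pops_meta=META)
        with pytest.raises(ValueError, match="lineage"):
            cand.cave_adaptive_genes(table, [GENE], "cave1", "surf2")


class TestOverlappingSweeps:
    caves = ["cave1", "cave2", "cave3"]
    surfs = ["surf1", "surf2"]

    def _table(self, cave_classes, surf_classes=None):
        surf_classes = surf_classes or {}
        assignments = {c: dict(cave_classes.get(c, {})) for c in self.caves}
        assignments.update({s: dict(surf_classes.get(s, {}))
                            for s in self.surfs})
        return _sweep_table(assignments, pops_meta=META)

    def test_sweeps_in_all_caves_clean_surfaces_included(self):
        table = self._table({c: {2: "hard"} for c in self.caves})
        out = cand.overlapping_sweeps(table, [GENE], self.caves, self.surfs)
        assert out == {"g1"}

    def test_missing_sweep_in_one_cave_excluded(self):
        table = self._table({"cave1": {2: "hard"}, "cave2": {2: "hard"}})
        out = cand.overlapping_sweeps(table, [GENE], self.caves, self.surfs)
        assert out == set()

    def test_linked_surface_calls_allowed(self):
        table = self._table({c: {2: "hard"} for c in self.caves},
                            {"surf1": {2: "softLinked"}})
        out = cand.overlapping_sweeps(table, [GENE], self.caves, self.surfs)
        assert out == {"g1"}

    def test_contained_in_every_pairwise_cave_adaptive_set(self):
        rng = np.random.default_rng(0)
        classes = np.array(["neutral", "hard", "soft", "softLinked", "skipped"])
        genes = [GeneModel(f"g{i}", "chr1", i * 10_000 + 2_000,
                           i * 10_000 + 8_000, "+") for i in range(5)]
        assignments = {p: {w: rng.choice(classes) for w in range(10)}
                       for p in self.caves + self.surfs}
        table = _sweep_table(assignments, pops_meta=META)
        overlap = cand.overlapping_sweeps(table, genes, self.caves, self.surfs)
        for c in self.caves:
            for s in self.surfs:
                pair = cand._cave_adaptive_no_lineage_check(table, genes, c, s)
                assert overlap <= pair


def test_sweep_fraction_ignores_skipped_windows():
    table = _sweep_table({"cave1": {0: "hard", 1: "soft", 2: "skipped"}},
                         n_win=4)
    # 2 sweeps over 3 classified windows
    assert cand.sweep_fraction(table, "cave1") == pytest.approx(2 / 3)


class TestPhenotypeCategories:
    keywords = {"pigmentation": ["pigment", "melanosome"],
                "vision": ["eye", "retina"]}

    def _gene(self, terms, gid="g"):
        return GeneModel(gid, "chr1", 0, 1000, "+", go_terms=list(terms))

    def test_substring_match_is_case_insensitive(self):
        gene = self._gene(["Melanosome Transport"])
        out = cand.assign_phenotype_categories([gene], self.keywords)
        assert out == {"g": {"pigmentation"}}

    def test_gene_without_go_terms_unassigned(self):
        out = cand.assign_phenotype_categories([self._gene([])], self.keywords)
        assert out == {}

    def test_multi_category_assignment(self):
        gene = self._gene(["eye pigment granule"])
        out = cand.assign_phenotype_categories([gene], self.keywords)
        assert out["g"] == {"pigmentation", "vision"}

    def test_empty_keyword_table_rejected(self):
        with pytest.raises(ValueError):
            cand.assign_phenotype_categories([self._gene(["x"])], {})


class TestQtlPermutation:
    def _genes(self, n=60):
        return [GeneModel(f"g{i}", "chr1", i * 10_000, i * 10_000 + 5_000, "+")
                for i in range(n)]

    def test_genome_wide_qtl_degenerate_null(self):
        genes = self._genes(20)
        qtl = [("chr1", 0, 10**9)]
        out = cand.qtl_overlap_permutation({"g1", "g2"}, genes, qtl,
                                           n_perm=200, seed=1)
        assert out["observed"] == 2
        assert out["null_sd"] == 0.0
        assert np.isnan(out["z"])
        assert out["p"] == pytest.approx(1 / 201)

    def test_empty_qtl_observed_zero(self):
        genes = self._genes(10)
        out = cand.qtl_overlap_permutation({"g1"}, genes, [], n_perm=100, seed=1)
        assert out["observed"] == 0 and out["p"] == 1.0

    def test_set_larger_than_universe_rejected(self):
        genes = self._genes(3)
        with pytest.raises(ValueError):
            cand.qtl_overlap_permutation({"g0", "g1", "g2", "zz"}, genes,
                                         [("chr1", 0, 10)], n_perm=10, seed=0)

    def test_null_sets_give_moderate_z(self):
        genes = self._genes(60)
        qtl = [("chr1", 100_000, 300_000)]
        rng = np.random.default_rng(3)
        for trial in range(20):
            chosen = set(rng.choice([g.gene_id for g in genes], size=15,
                                    replace=False))
            out = cand.qtl_overlap_permutation(chosen, genes, qtl,
                                               n_perm=300, seed=trial)
            assert np.isnan(out["z"]) or abs(out["z"]) < 4

    def test_enriched_set_detected(self):
        genes = self._genes(60)
        qtl = [("chr1", 0, 200_000)]  # first 20 genes overlap
        hit_set = {f"g{i}" for i in range(15)}
        out = cand.qtl_overlap_permutation(hit_set, genes, qtl,
                                           n_perm=2000, seed=5)
        assert out["z"] > 3
        assert out["p"] < 0.01


class TestFisherEnrichment:
    def test_proportional_rows_null(self):
        odds, p = cand.fisher_enrichment(2, 10, 22, 110)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_complete_association_exact_p(self):
        odds, p = cand.fisher_enrichment(10, 10, 10, 20)
        assert np.isinf(odds)
        # the only tables as extreme are the two corners of the support
        expected = 2.0 / sps.binom(20, 10) if False else 2.0 / 184_756
        assert p == pytest.approx(expected)

    def test_doubling_cells_keeps_odds_ratio(self):
        odds1, _ = cand.fisher_enrichment(6, 20, 30, 120)
        odds2, _ = cand.fisher_enrichment(12, 40, 60, 240)
        assert odds1 == pytest.approx(odds2)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            cand.fisher_enrichment(10, 10, 5, 100)


class TestLengthComparison:
    def test_identical_groups_null(self):
        t, df, p = cand.length_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_sign_convention_candidate_minus_genome(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5000, 1000, 300)
        t, _, _ = cand.length_comparison(base + 1000, base)
        assert t > 0

    def test_welch_df_matches_satterthwaite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2000, 100)
        y = rng.normal(0, 1500, 1000)
        _, df, _ = cand.length_comparison(x, y)
        v1, v2 = np.var(x, ddof=1) / 100, np.var(y, ddof=1) / 1000
        expected = (v1 + v2) ** 2 / (v1 ** 2 / 99 + v2 ** 2 / 999)
        assert df == pytest.approx(expected, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            cand.length_comparison([5.0, 5.0], [5.0, 5.0])


class TestSweepAgeByCategory:
    def test_fully_separated_ranks_hand_value(self):
        # two categories of 3, completely separated: H = 3.857
        h, df, p = cand.sweep_age_by_category(
            {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([10.0, 11.0, 12.0])})
        assert df == 1
        assert h == pytest.approx(12 / 42 * (3 * 2.25 + 3 * 2.25), abs=1e-9)
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_label_permutation_destroys_signal(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        h_sep, _, p_sep = cand.sweep_age_by_category({"a": a, "b": b})
        pooled = np.concatenate([a, b])
        perm = rng.permutation(pooled)
        h_perm, _, _ = cand.sweep_age_by_category(
            {"a": perm[:30], "b": perm[30:]})
        assert p_sep < 0.001
        assert h_perm < h_sep

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            cand.sweep_age_by_category({"a": np.array([1.0, 2.0])})


class TestTfbsLossFilter:
    def _table(self, surf_frac, cave_fracs, n=10):
        rows = []
        pops = {"surf1": surf_frac, "cave1": cave_fracs[0],
                "cave2": cave_fracs[1]}
        for pop, frac in pops.items():
            k = int(round(frac * n))
            for g in range(n):
                rows.append({"motif": "M1", "gene": "g1", "flank": "upstream",
                             "pop": pop, "genome": f"{pop}_{g}",
                             "present": int(g < k)})
        return pd.DataFrame(rows)

    def test_full_loss_detected(self):
        losses = cand.tfbs_loss_filter(self._table(1.0, (0.0, 0.0)),
                                       ["surf1"], ["cave1", "cave2"])
        assert len(losses) == 1
        assert tuple(losses.iloc[0]) == ("g1", "upstream", "M1")

    def test_exact_boundaries(self):
        # exactly 80% surface passes; exactly 20% in one cave fails
        losses = cand.tfbs_loss_filter(self._table(0.8, (0.2, 0.0)),
                                       ["surf1"], ["cave1", "cave2"])
        assert losses.empty
        losses = cand.tfbs_loss_filter(self._table(0.8, (0.1, 0.0)),
                                       ["surf1"], ["cave1", "cave2"])
        assert len(losses) == 1

    def test_insufficient_surface_presence_not_a_loss(self):
        losses = cand.tfbs_loss_filter(self._table(0.7, (0.0, 0.0)),
                                       ["surf1"], ["cave1", "cave2"])
        assert losses.empty

    def test_monotone_in_surface_presence(self):
        base = cand.tfbs_loss_filter(self._table(0.9, (0.1, 0.0)),
                                     ["surf1"], ["cave1", "cave2"])
        more = cand.tfbs_loss_filter(self._table(1.0, (0.1, 0.0)),
                                     ["surf1"], ["cave1", "cave2"])
        assert set(map(tuple, base.values)) <= set(map(tuple, more.values))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            cand.tfbs_loss_filter(self._table(1.0, (0.0, 0.0)),
                                  ["missing_pop"], ["cave1"])


class TestCategoryCounts:
    def test_surface_population_mean(self):
        out = cand.summarize_category_counts({"Rascon": 739, "Mante": 1101})
        assert out["mean"] == 920

    def test_single_population_mean_is_count(self):
        out = cand.summarize_category_counts({"only": 42})
        assert out["mean"] == 42

    def test_annotation_fraction_rounds_to_whole_percent(self):
        out = cand.summarize_category_counts({"set": 6223},
                                             annotation_total=26_698)
        assert out["percent_of_annotation"]["set"] == 23
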