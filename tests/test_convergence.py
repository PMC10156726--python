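"""Composite-likelihood machinery: kernels, covariances, oracle, fits."""

import numpy as np
import pytest
from scipy import stats as sps

from cavepopgen import convergence as conv
from cavepopgen import synthdata as sd
from cavepopgen.panel import GeneModel

from conftest import make_panel

CAVES = ("L1_cave1", "L2_cave1", "L2_cave2")


@pytest.fixture(scope="module")
def neutral_background():
    """Shared neutral panel and its coancestry estimate."""
    config = sd.DemographyConfig(snp_count=8000, chrom_length=4_000_000,
                                 seed=999)
    panel, _ = sd.simulate_neutral_panel(config, draw_haplotypes=False)
    F = conv.estimate_neutral_F(panel, thin_bp=500)
    return panel, F


@pytest.fixture(scope="module")
def model_specs():
    return conv.default_model_specs(CAVES, ne=10_000)


# ---------------------------------------------------------------------------
# sweep retention kernel
# ---------------------------------------------------------------------------

class TestSweepRetention:
    def test_zero_distance_full_retention(self):
        assert conv.sweep_retention(0.0, s=0.01) == 1.0

    def test_hand_computed_value(self):
        # Ne=1e5, s=0.01, rec=1.16e-8, r_bp=1e4:
        # y = exp(-1.16e-4 * log(4000)/0.01) = exp(-0.0962) ~ 0.908
        y = conv.sweep_retention(10_000, s=0.01, ne=100_000, rec_rate=1.16e-8)
        assert y == pytest.approx(np.exp(-1.16e-4 * np.log(4000.0) / 0.01))
        assert y == pytest.approx(0.908, abs=2e-3)

    def test_monotone_in_distance_and_selection(self):
        r = np.array([0, 1e3, 1e4, 1e5, 1e6])
        y = conv.sweep_retention(r, s=0.01)
        assert np.all(np.diff(y) < 0)
        # stronger selection sweeps faster, keeping more linked variation
        assert conv.sweep_retention(5e4, s=0.1) > conv.sweep_retention(5e4, s=0.01)

    def test_nonpositive_s_rejected(self):
        with pytest.raises(ValueError):
            conv.sweep_retention(100.0, s=0.0)


# ---------------------------------------------------------------------------
# neutral coancestry
# ---------------------------------------------------------------------------

class TestNeutralF:
    def test_identical_populations_give_epsilon_matrix(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 500)
        panel = make_panel(np.tile(p, (4, 1)), pos=np.arange(1, 501) * 10)
        F = conv.estimate_neutral_F(panel, thin_bp=10)
        assert np.allclose(F.F, F.epsilon * np.eye(4), atol=1e-12)

    def test_symmetric_psd_on_any_input(self, neutral_background):
        _, F = neutral_background
        assert np.allclose(F.F, F.F.T)
        assert np.min(np.linalg.eigvalsh(F.F)) >= 0

    def test_within_lineage_coancestry_exceeds_between(self, neutral_background):
        panel, F = neutral_background
        lineages = [p.lineage for p in panel.populations]
        within, between = [], []
        for i in range(len(lineages)):
            for j in range(i + 1, len(lineages)):
                (within if lineages[i] == lineages[j] else between).append(F.F[i, j])
        assert np.mean(within) > np.mean(between)

    def test_too_few_sites_rejected(self):
        panel = make_panel(np.full((3, 10), 0.4), pos=np.arange(1, 11) * 10)
        with pytest.raises(ValueError, match="neutral sites"):
            conv.estimate_neutral_F(panel)


# ---------------------------------------------------------------------------
# model covariance
# ---------------------------------------------------------------------------

class TestModelCovariance:
    def test_no_sweep_limit_reduces_to_F_for_all_models(self, neutral_background,
                                                        model_specs):
        _, F = neutral_background
        far = 5e8  # y ~ 0
        for spec in model_specs:
            params = next(iter(spec.param_combinations()))
            C = conv.model_covariance(spec, params, far, F)
            assert np.allclose(C, F.F, atol=1e-8), spec.model

    def test_independent_model_never_increases_between_coancestry(
            self, neutral_background, model_specs):
        _, F = neutral_background
        spec = next(s for s in model_specs if s.model == "independent")
        sel = [F.populations.index(p) for p in CAVES]
        for params in spec.param_combinations():
            for r in (0.0, 1e3, 1e5):
                C = conv.model_covariance(spec, params, r, F)
                for a in range(len(sel)):
                    for b in range(a + 1, len(sel)):
                        i, j = sel[a], sel[b]
                        # coancestry attenuates toward zero, never inflates
                        assert abs(C[i, j]) <= abs(F.F[i, j]) + 1e-12
                        assert C[i, j] * F.F[i, j] >= 0

    def test_standing_long_time_reduces_to_independent(self, neutral_background,
                                                       model_specs):
        _, F = neutral_background
        standing = next(s for s in model_specs if s.model == "standing")
        indep = next(s for s in model_specs if s.model == "independent")
        params_st = {"s": 0.1, "t_st": 1000.0, "g": 1e-3}
        params_in = {"s": 0.1, "t_st": 1000.0}
        r = 1e6  # exp(-2 r_M t) ~ 0 at this distance
        C_st = conv.model_covariance(standing, params_st, r, F)
        C_in = conv.model_covariance(indep, params_in, r, F)
        assert np.allclose(C_st, C_in, atol=1e-6)

    def test_positive_semidefinite_across_grid(self, neutral_background,
                                               model_specs):
        _, F = neutral_background
        for spec in model_specs:
            for params in spec.param_combinations():
                for r in (0.0, 1e3, 3e4, 1e6):
                    C = conv.model_covariance(spec, params, r, F)
                    assert np.min(np.linalg.eigvalsh(C)) >= -1e-10

    def test_off_grid_parameters_rejected(self, neutral_background, model_specs):
        _, F = neutral_background
        spec = next(s for s in model_specs if s.model == "migration")
        with pytest.raises(ValueError, match="off-grid"):
            conv.model_covariance(spec, {"s": 0.123, "m": 1e-3}, 0.0, F)


# ---------------------------------------------------------------------------
# composite likelihood vs brute-force MVN oracle
# ---------------------------------------------------------------------------

class TestCompositeLikelihood:
    def _window(self, neutral_background, n=10):
        panel, F = neutral_background
        idx = np.arange(200, 200 + n)
        freqs = panel.freq[:, idx]
        pos = (panel.pos[idx] - 1).astype(float)
        return freqs, pos, F

    def test_matches_brute_force_mvn(self, neutral_background, model_specs):
        """Independently coded oracle: per-site scipy MVN densities."""
        freqs, pos, F = self._window(neutral_background)
        site = float(pos[4]) + 37.0
        for spec in model_specs:
            params = {"s": 0.1, "t_st": 25.0, "g": 1e-2, "m": 1e-3}
            params = {k: params[k] for k in spec.live_params()}
            ll = conv.composite_loglik(freqs, pos, site, spec, params, F)
            X, keep = conv.standardize_freqs(freqs)
            expected = 0.0
            for j, p in enumerate(pos[keep]):
                C = conv.model_covariance(spec, params, abs(p - site), F)
                expected += sps.multivariate_normal(
                    mean=np.zeros(X.shape[0] - 1),
                    cov=C[:-1, :-1]).logpdf(X[:-1, j])
            assert ll == pytest.approx(expected, abs=1e-8), spec.model

    def test_duplicated_site_adds_its_own_term(self, neutral_background,
                                               model_specs):
        freqs, pos, F = self._window(neutral_background, n=6)
        spec = model_specs[0]
        site = float(pos[2])
        base = conv.composite_loglik(freqs, pos, site, spec, {}, F)
        one = conv.composite_loglik(freqs[:, -1:], pos[-1:], site, spec, {}, F)
        dup = conv.composite_loglik(
            np.hstack([freqs, freqs[:, -1:]]), np.append(pos, pos[-1]),
            site, spec, {}, F)
        assert dup == pytest.approx(base + one, abs=1e-9)

    def test_neutral_model_preferred_on_neutral_data(self, neutral_background,
                                                     model_specs):
        """Expectation over replicate neutral windows: no selection model
        outranks the neutral composite likelihood."""
        panel, F = neutral_background
        neutral = model_specs[0]
        standing = next(s for s in model_specs if s.model == "standing")
        params = {"s": 0.1, "t_st": 25.0, "g": 1e-2}
        diffs = []
        for rep in range(100):
            idx = np.arange(rep * 20, rep * 20 + 15)
            freqs = panel.freq[:, idx]
            pos = (panel.pos[idx] - 1).astype(float)
            site = float(pos[7])
            diffs.append(
                conv.composite_loglik(freqs, pos, site, neutral, {}, F)
                - conv.composite_loglik(freqs, pos, site, standing, params, F))
        assert np.mean(diffs) > 0

    def test_empty_window_rejected(self, neutral_background, model_specs):
        _, F = neutral_background
        with pytest.raises(ValueError):
            conv.composite_loglik(np.empty((6, 0)), np.array([]), 0.0,
                                  model_specs[0], {}, F)


# ---------------------------------------------------------------------------
# per-gene fits
# ---------------------------------------------------------------------------

class TestFitGene:
    def test_proposed_sites_evenly_spaced(self):
        sites = conv.proposed_sites(0.0, 980.0, 50)
        assert sites.size == 50
        assert sites[0] == 0.0 and sites[-1] == 980.0
        assert np.allclose(np.diff(sites), sites[1] - sites[0])

    def test_best_model_attains_maximum(self, neutral_background, model_specs):
        panel, F = neutral_background
        gene = GeneModel("g", "chr1", 1_000_000, 1_030_000, "+")
        res = conv.fit_gene(panel, gene, model_specs, F)
        assert res.model_logliks[res.best_model] == max(res.model_logliks.values())
        assert res.n_snps > 0

    def test_binned_path_tracks_exact_path(self, neutral_background,
                                           model_specs):
        panel, F = neutral_background
        gene = GeneModel("g", "chr1", 2_000_000, 2_010_000, "+")
        specs = [s for s in model_specs
                 if s.model in ("neutral", "migration", "standing")]
        fast = conv.fit_gene(panel, gene, specs, F, r_bins=24)
        exact = conv.fit_gene(panel, gene, specs, F, r_bins=None)
        for m in fast.model_logliks:
            assert fast.model_logliks[m] == pytest.approx(
                exact.model_logliks[m], abs=1.0)

    def test_oversized_gene_skipped(self, neutral_background, model_specs):
        panel, F = neutral_background
        gene = GeneModel("big", "chr1", 0, 500_000, "+")
        assert conv.fit_gene(panel, gene, model_specs, F) is None

    def test_gene_without_snps_skipped(self, model_specs, neutral_background):
        _, F = neutral_background
        panel = make_panel(np.full((6, 150), 0.4),
                           pos=np.arange(1, 151) * 10,
                           pops=None)
        # reuse the background F's population labels for index lookup
        panel.populations = [type(p)(name, p.ecotype, p.lineage)
                             for p, name in zip(panel.populations,
                                                F.populations)]
        gene = GeneModel("far", "chr1", 900_000, 910_000, "+")
        assert conv.fit_gene(panel, gene, model_specs, F) is None


class TestSiteClassification:
    gene = GeneModel(
        "g", "chr1", 10_000, 20_000, "+",
        cds=[(10_500, 13_500), (15_500, 19_500)],
        utr5=[(10_000, 10_500)], utr3=[(19_500, 20_000)])

    @pytest.mark.parametrize("pos,expected", [
        (11_000, "CDS"),
        (10_200, "UTR5"),
        (19_700, "UTR3"),
        (14_000, "intron"),
        (5_000, "upstream10k"),
        (25_000, "downstream10k"),
    ])
    def test_plus_strand_classes(self, pos, expected):
        assert conv.classify_selected_site(pos, self.gene) == expected

    def test_minus_strand_flanks_flip(self):
        gene = GeneModel("g", "chr1", 10_000, 20_000, "-")
        assert conv.classify_selected_site(5_000, gene) == "downstream10k"
        assert conv.classify_selected_site(25_000, gene) == "upstream10k"

    def test_position_outside_flanks_rejected(self):
        with pytest.raises(ValueError):
            conv.classify_selected_site(50_000, self.gene)


class TestModeSummary:
    def test_cave_candidate_percentages(self):
        table = conv.summarize_mode_assignments(
            {"independent": 304, "standing": 404, "migration": 52})
        pct = dict(zip(table["model"], table["percent"]))
        assert pct == {"independent": 40, "standing": 53, "migration": 7}

    def test_surface_control_percentages(self):
        table = conv.summarize_mode_assignments(
            {"standing": 163, "independent": 3, "migration": 6})
        pct = dict(zip(table["model"], table["percent"]))
        assert pct == {"standing": 95, "independent": 2, "migration": 3}

    def test_single_gene_is_hundred_percent(self):
        table = conv.summarize_mode_assignments({"migration": 1})
        assert table["percent"].tolist() == [100]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            conv.summarize_mode_assignments({})
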