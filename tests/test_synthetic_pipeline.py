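import json

import numpy as np
import pytest

from msatbot.abc import model_posterior, param_posterior, point_estimates
from msatbot.coalsim import (BOTTLENECK, NON_BOTTLENECK, DemographicParams,
                             simulate_dataset)
from msatbot.genotype_io import read_genepop
from msatbot.pipeline import AnalysisConfig, analyze_species, panel_report
from msatbot.sumstats import mean_sumstats
from msatbot.synthetic_data import (PanelConfig, TruthManifest,
                                    generate_fixture, generate_panel)


@pytest.fixture(scope="module")
def small_panel(tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    cfg = PanelConfig(n_species=6, n_ind_range=(16, 200),
                      n_ind_median=50, n_loci_range=(5, 20),
                      n_loci_median=10, missing_rate=0.05)
    datasets, manifest = generate_panel(
        cfg, np.random.default_rng(31), out)
    return cfg, datasets, manifest, out


class TestGeneratePanel:
    def test_dims_within_ranges(self, small_panel):
        cfg, datasets, _, _ = small_panel
        assert len(datasets) == cfg.n_species
        for ds in datasets:
            assert cfg.n_ind_range[0] <= ds.n_individuals <= cfg.n_ind_range[1]
            assert cfg.n_loci_range[0] <= ds.n_loci <= cfg.n_loci_range[1]

    def test_manifest_file_bijection_and_readback(self, small_panel):
        _, datasets, manifest, out = small_panel
        assert len(manifest.entries) == len(datasets)
        for entry, ds in zip(manifest.entries, datasets):
            back = read_genepop(entry["path"])
            assert back == ds
        loaded = TruthManifest.from_json(out / "manifest.json")
        assert loaded.entries == manifest.entries

    def test_same_master_seed_byte_identical(self, tmp_path):
        cfg = PanelConfig(n_species=3, n_ind_range=(16, 60), n_ind_median=30,
                          n_loci_range=(5, 10), n_loci_median=7)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        _, m1 = generate_panel(cfg, np.random.default_rng(8), d1)
        _, m2 = generate_panel(cfg, np.random.default_rng(8), d2)
        for f in sorted(d1.glob("*.gen")):
            assert f.read_bytes() == (d2 / f.name).read_bytes()
        for e1, e2 in zip(m1.entries, m2.entries):
            assert {k: v for k, v in e1.items() if k != "path"} == \
                   {k: v for k, v in e2.items() if k != "path"}

    def test_bottleneck_fraction(self, small_panel):
        _, _, manifest, _ = small_panel
        n_bot = sum(e["model"] == BOTTLENECK for e in manifest.entries)
        assert n_bot == round(6 * 11 / 30)

    def test_dim_medians_hit_targets(self):
        cfg = PanelConfig(n_species=400)
        _, manifest = generate_panel(cfg, np.random.default_rng(12))
        n_ind = np.array([e["n_ind"] for e in manifest.entries])
        n_loci = np.array([e["n_loci"] for e in manifest.entries])
        assert abs(np.median(n_ind) - 253) < 60
        assert abs(np.median(n_loci) - 14) < 3


class TestFixtures:
    def test_known_kinds_only(self):
        with pytest.raises(ValueError):
            generate_fixture("everything_missing")

    def test_fixture_invariants_clean(self, fixture_dataset):
        # constructing GenotypeDataset re-checks all invariants
        assert fixture_dataset.n_loci >= 1
        assert fixture_dataset.n_individuals >= 1


class TestNeBotOrderingRecovery:
    def test_weak_vs_strong_bottleneck_posterior_ordering(self, small_table):
        # species simulated at N_e_bot = 30 should receive smaller
        # posterior N_e_bot modes than species simulated at 400
        rng = np.random.default_rng(55)
        correct = 0
        n_pairs = 8
        for _ in range(n_pairs):
            modes = []
            for ne_bot in (30, 400):
                p = DemographicParams(
                    BOTTLENECK, ne=20_000, ne_hist=20_000, mu=5e-5,
                    gsm_par=0.15, ne_bot=ne_bot, t_bot_start=55,
                    t_bot_end=10)
                ds = simulate_dataset(p, 40, 10, rng)
                post = param_posterior(mean_sumstats(ds), small_table,
                                       BOTTLENECK, tolerance=0.05)
                modes.append(point_estimates(post).loc["ne_bot", "mode"])
            correct += modes[0] < modes[1]
        assert correct >= n_pairs - 2


@pytest.fixture(scope="module")
def config():
    return AnalysisConfig(tolerance=0.05, min_accepted=100,
                          n_resamples=200, n_heq_sims=300,
                          hwe_n_mc=1000, n_ppc_draws=100, n_gof_null=100)


class TestAnalyzeSpecies:

    def test_bottlenecked_species_report(self, small_table, config):
        p = DemographicParams(BOTTLENECK, ne=30_000, ne_hist=30_000,
                              mu=5e-5, gsm_par=0.1, ne_bot=20,
                              t_bot_start=60, t_bot_end=5)
        ds = simulate_dataset(p, 60, 12, np.random.default_rng(2),
                              species_id="deep_bot")
        rep = analyze_species(ds, small_table, config,
                              np.random.default_rng(3))
        assert rep.preferred_model in (BOTTLENECK, NON_BOTTLENECK)
        assert rep.p_bot == pytest.approx(
            rep.model_probs[BOTTLENECK])
        # estimates only for the preferred model's parameters
        if rep.preferred_model == BOTTLENECK:
            assert "ne_bot" in rep.param_estimates
            assert "t_hist" not in rep.param_estimates
        else:
            assert "ne_bot" not in rep.param_estimates
        assert 0 <= rep.gof_p <= 1
        for label in ("SMM", "TPM70", "TPM80", "TPM90"):
            assert 0 <= rep.prop_het_exc[label] <= 1

    def test_report_reproducible_and_json_round_trip(self, small_table,
                                                     config, tmp_path):
        p = DemographicParams(NON_BOTTLENECK, ne=10_000, ne_hist=10_000,
                              mu=5e-5, gsm_par=0.1, t_hist=30)
        ds = simulate_dataset(p, 40, 8, np.random.default_rng(4))
        r1 = analyze_species(ds, small_table, config,
                             np.random.default_rng(6))
        r2 = analyze_species(ds, small_table, config,
                             np.random.default_rng(6))
        assert r1 == r2
        path = tmp_path / "rep.json"
        r1.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["species_id"] == ds.species_id
        assert payload["p_bot"] == r1.p_bot

    def test_stage_tagged_diagnostics(self, small_table, config):
        ds = generate_fixture("monomorphic")  # breaks the het-excess stage
        with pytest.raises(RuntimeError, match="stage"):
            analyze_species(ds, small_table, config,
                            np.random.default_rng(0))


@pytest.fixture(scope="module")
def reports(small_table):
    cfg = AnalysisConfig(tolerance=0.05, min_accepted=100,
                         n_resamples=100, n_heq_sims=200,
                         hwe_n_mc=1000, n_ppc_draws=50, n_gof_null=100)
    panel_cfg = PanelConfig(n_species=4, n_ind_range=(20, 60),
                            n_ind_median=40, n_loci_range=(5, 12),
                            n_loci_median=8)
    datasets, _ = generate_panel(panel_cfg, np.random.default_rng(19))
    return [analyze_species(ds, small_table, cfg,
                            np.random.default_rng(100 + i))
            for i, ds in enumerate(datasets)]


class TestPanelReport:

    def test_schema_and_counts(self, reports):
        tab, summary = panel_report(reports)
        assert len(tab) == len(reports)
        for col in ("species_id", "ho_10", "ar_10", "p_bot",
                    "preferred_model", "prop_het_exc_TPM80", "gof_p"):
            assert col in tab.columns
        assert summary["n_p_bot_gt_0.5"] == int((tab["p_bot"] > 0.5).sum())
        assert -1 <= summary["r_ho_ar"] <= 1

    def test_single_report_rejected(self, reports):
        with pytest.raises(ValueError):
            panel_report(reports[:1])

    def test_identical_reports_correlation_na(self, reports):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab, summary = panel_report([reports[0], reports[0]])
        assert np.isnan(summary["r_ho_ar"])
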