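"""Synthetic cohort generator: priors, determinism, event-level oracles."""

import numpy as np
import pytest
from scipy.stats import binom

from lnaspire.cohort import (CohortConfig, default_cohort_config,
                             draw_patient_truth, prior_median_truth,
                             simulate_cohort, simulate_fmo, simulate_sample)
from lnaspire.panels import identification_panel, characterization_panel
from lnaspire.templates import VIABLE_POPULATIONS
from lnaspire.transforms import DEFAULT_TRANSFORM

from conftest import make_truth


class TestDefaultConfig:
    def test_group_priors_centered_on_printed_medians(self):
        cfg_n = default_cohort_config("NSCLC")
        cfg_s = default_cohort_config("SCLC")
        assert cfg_n.population_fraction_priors["tumor"].median == pytest.approx(0.625)
        assert cfg_s.population_fraction_priors["tumor"].median == pytest.approx(0.885)
        assert cfg_s.antigen_positivity_priors["CD56"].median == pytest.approx(0.885)
        assert cfg_n.antigen_positivity_priors["EpCAM"].median == pytest.approx(0.701)

    def test_all_populations_and_antigens_present(self):
        cfg = default_cohort_config("NSCLC")
        assert set(cfg.population_fraction_priors) == set(VIABLE_POPULATIONS)
        assert len(cfg.antigen_positivity_priors) == 16

    def test_viability_cap(self):
        assert default_cohort_config("NSCLC").dead_fraction_max <= 0.05
        with pytest.raises(ValueError):
            CohortConfig("NSCLC", 5, dead_fraction_max=0.2)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            default_cohort_config("mesothelioma")


class TestDrawPatientTruth:
    def test_deterministic(self):
        cfg = default_cohort_config("SCLC", master_seed=99, n_patients=5)
        a = draw_patient_truth(cfg, 3)
        b = draw_patient_truth(cfg, 3)
        assert a == b

    def test_index_out_of_range(self):
        cfg = default_cohort_config("NSCLC", n_patients=4)
        with pytest.raises(IndexError):
            draw_patient_truth(cfg, 4)

    def test_fractions_sum_to_one(self):
        cfg = default_cohort_config("NSCLC", master_seed=5, n_patients=8)
        for i in range(8):
            t = draw_patient_truth(cfg, i)
            assert sum(t.population_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_dispersion_returns_medians(self):
        truth = prior_median_truth(default_cohort_config("NSCLC", master_seed=1))
        comp = truth.viable_composition()
        assert comp["tumor"] == pytest.approx(0.625, abs=1e-9)
        # others share the remaining mass proportionally to their medians
        priors = default_cohort_config("NSCLC").population_fraction_priors
        w = sum(p.median for n, p in priors.items() if n != "tumor")
        expect_neut = (1 - 0.625) * priors["neutrophil"].median / w
        assert comp["neutrophil"] == pytest.approx(expect_neut, rel=1e-9)
        assert truth.antigen_positive_fractions["EpCAM"] == pytest.approx(0.701)

    def test_median_recovery_monte_carlo(self):
        # stratified quantile slots reproduce the configured prior median
        cfg = default_cohort_config("NSCLC", master_seed=11, n_patients=10_000)
        tumors = np.array([draw_patient_truth(cfg, i).viable_composition()["tumor"]
                           for i in range(cfg.n_patients)])
        assert abs(np.median(tumors) - 0.625) < 0.02
        q1, q3 = np.percentile(tumors, [25, 75])
        assert abs(q1 - 0.323) < 0.03 and abs(q3 - 0.784) < 0.03


class TestSimulateSample:
    def test_multinomial_conservation_and_determinism(self, id_panel):
        truth = make_truth(tumor=0.5, T_CD4=0.2, debris=0.05, dead=0.02)
        t1, l1 = simulate_sample(id_panel, truth, 5000)
        t2, l2 = simulate_sample(id_panel, truth, 5000)
        assert t1.n_events == 5000
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(l1.population, l2.population)

    def test_tumor_count_binomial_oracle(self, id_panel):
        truth = make_truth(tumor=0.7)
        _, labels = simulate_sample(id_panel, truth, 50_000)
        n_tumor = int((labels.population == "tumor").sum())
        lo, hi = binom.ppf([0.0005, 0.9995], 50_000, 0.7)
        assert lo <= n_tumor <= hi

    def test_pure_tumor_forced_components(self, id_panel):
        truth = make_truth(tumor=1.0, antigens=None)
        table, labels = simulate_sample(id_panel, truth, 4000)
        tr = DEFAULT_TRANSFORM.forward
        assert np.all(labels.population == "tumor")
        # CD45 from the negative component, EpCAM from the positive one
        assert np.quantile(tr(table.column("CD45")), 0.999) < 3.0
        assert np.quantile(tr(table.column("EpCAM")), 0.001) > 3.0

    def test_doublets_reduce_event_count(self, id_panel):
        truth = make_truth(tumor=0.6)
        table, labels = simulate_sample(id_panel, truth, 10_000,
                                        doublet_fraction=0.05)
        n_dbl = int((labels.population == "doublet").sum())
        assert n_dbl == 500
        assert table.n_events == 10_000 - 500

    def test_char_panel_antigen_positivity_zero(self, char_panel):
        # positivity fraction 0: only FMO-level leakage above the negative
        # component's 99.5th percentile
        truth = make_truth(tumor=1.0, antigens={"PD-L1": 0.0})
        table, labels = simulate_sample(char_panel, truth, 20_000)
        tr = DEFAULT_TRANSFORM.forward(table.column("PD-L1"))
        neg995 = 0.9 + 2.576 * 0.35
        frac = np.mean(tr > neg995)
        assert frac == pytest.approx(0.005, abs=0.003)

    def test_viability_floor(self, id_panel):
        truth = make_truth(tumor=0.6, dead=0.03)
        table, labels = simulate_sample(id_panel, truth, 20_000)
        tr = DEFAULT_TRANSFORM.forward(table.column("7-AAD"))
        assert np.mean(tr <= 2.5) >= 1 - 0.03 - 0.005


class TestSimulateFmo:
    def test_fmo_channel_is_background(self, char_panel):
        truth = make_truth(tumor=0.9, antigens={"EpCAM": 1.0})
        fmo = simulate_fmo(char_panel, truth, "EpCAM", 20_000)
        tr = DEFAULT_TRANSFORM.forward(fmo.column("EpCAM"))
        # 99.5th percentile matches the negative component's quantile
        assert np.quantile(tr, 0.995) == pytest.approx(0.9 + 2.576 * 0.35,
                                                       abs=0.06)
        assert fmo.panel.channel_ids == char_panel.channel_ids

    def test_fmo_containment(self, char_panel):
        # full stain stochastically dominates the FMO whenever positivity > 0
        truth = make_truth(tumor=0.9, antigens={"CD56": 0.6})
        full, _ = simulate_sample(char_panel, truth, 15_000)
        fmo = simulate_fmo(char_panel, truth, "CD56", 15_000)
        for q in (0.5, 0.75, 0.9, 0.99):
            assert np.quantile(fmo.column("CD56"), q) <= \
                np.quantile(full.column("CD56"), q) + 1e-9

    def test_rejects_scatter_and_unknown(self, id_panel):
        truth = make_truth(tumor=0.5)
        with pytest.raises(ValueError):
            simulate_fmo(id_panel, truth, "FSC-A", 100)
        with pytest.raises(ValueError):
            simulate_fmo(id_panel, truth, "CD99", 100)


class TestSimulateCohort:
    def test_sizes_manifest_and_determinism(self):
        cfg_n = default_cohort_config("NSCLC", 3000, master_seed=21,
                                      n_patients=2)
        cfg_s = default_cohort_config("SCLC", 3000, master_seed=22,
                                      n_patients=3)
        a = simulate_cohort(cfg_n, cfg_s, fmo_events=2000)
        b = simulate_cohort(cfg_n, cfg_s, fmo_events=2000)
        assert len(a.group_samples("NSCLC")) == 2
        assert len(a.group_samples("SCLC")) == 3
        assert a.manifest.equals(b.manifest)
        assert a.truth_table.equals(b.truth_table)
        assert np.array_equal(a.samples[0].id_table.values,
                              b.samples[0].id_table.values)
        # one FMO tube per thresholded marker per panel per group
        assert len(a.fmo[("NSCLC", "identification")]) == 11
        assert len(a.fmo[("SCLC", "characterization")]) == 17

    def test_default_sizes_match_study(self):
        assert default_cohort_config("NSCLC").n_patients == 20
        assert default_cohort_config("SCLC").n_patients == 27
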