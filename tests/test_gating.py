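"""Pre-gates, FMO thresholds and the population classifier."""

import numpy as np
import pytest
import yaml

from lnaspire.cohort import simulate_fmo, simulate_sample
from lnaspire.fcs import EventTable
from lnaspire.gating import (GatingError, ScatterCutpoints, ThresholdSet,
                             build_ln_gating_tree, classify_events,
                             characterization_tumor_gate, debris_gate,
                             derive_thresholds, singlet_gate,
                             transform_events, viability_gate, GatingTree)
from lnaspire.panels import identification_panel
from lnaspire.transforms import DEFAULT_TRANSFORM, TransformSpec

from conftest import make_truth


def default_thresholds():
    """Fixed thresholds at the negative component's 99.5th percentile."""
    cut = 0.9 + 2.576 * 0.35
    chans = ("CD45", "CD3", "CD4", "CD8", "CD19", "CD16", "CD64",
             "HLA-DR", "CD146", "FMA", "EpCAM")
    return ThresholdSet({c: cut for c in chans},
                        {c: "fixed" for c in chans})


class TestTransform:
    def test_zero_maps_to_zero_and_monotone(self):
        spec = TransformSpec()
        assert spec.forward(0.0) == 0.0
        x = np.sort(np.random.default_rng(0).uniform(-1e4, 1e6, 100))
        assert np.all(np.diff(spec.forward(x)) > 0)

    def test_inverse_round_trip(self):
        spec = TransformSpec(cofactor=150)
        x = np.geomspace(1e-3, 1e6, 50)
        assert np.allclose(spec.inverse(spec.forward(x)), x, rtol=1e-9)

    def test_nonpositive_cofactor_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec(cofactor=0)

    def test_scatter_left_linear(self, id_panel):
        truth = make_truth(tumor=0.5)
        table, _ = simulate_sample(id_panel, truth, 300)
        out = transform_events(table)
        j = table.panel.index_of("FSC-A")
        assert np.array_equal(out[:, j], table.values[:, j])
        k = table.panel.index_of("CD45")
        assert np.allclose(out[:, k],
                           DEFAULT_TRANSFORM.forward(table.values[:, k]))


class TestPreGates:
    def test_doublets_excluded_singlets_kept(self, id_panel):
        truth = make_truth(tumor=0.7)
        table, labels = simulate_sample(id_panel, truth, 10_000,
                                        doublet_fraction=0.04)
        mask = singlet_gate(table)
        dbl = labels.population == "doublet"
        assert mask[dbl].mean() < 0.01
        assert mask[~dbl].mean() >= 0.99

    def test_empty_table_empty_mask(self, id_panel):
        table = EventTable("e", id_panel,
                           np.empty((0, len(id_panel.channels))))
        assert singlet_gate(table).shape == (0,)

    def test_debris_gate_excludes_debris_keeps_cells(self, id_panel):
        truth = make_truth(tumor=0.5, debris=0.3)
        table, labels = simulate_sample(id_panel, truth, 20_000)
        mask = debris_gate(table)
        deb = labels.population == "debris"
        assert (~mask[deb]).mean() >= 0.95
        assert (~mask[~deb]).mean() <= 0.01

    def test_all_debris_near_empty(self, id_panel):
        truth = make_truth(debris=1.0)
        table, _ = simulate_sample(id_panel, truth, 2_000)
        assert debris_gate(table).mean() < 0.05

    def test_viability_gate_tracks_dead_fraction(self, id_panel):
        truth = make_truth(tumor=0.5, dead=0.03)
        table, labels = simulate_sample(id_panel, truth, 20_000)
        mask = viability_gate(table)
        assert mask.mean() == pytest.approx(0.97, abs=0.01)
        dead = labels.population == "dead"
        assert mask[dead].mean() < 0.01
        assert mask[~dead].mean() > 0.995


class TestDeriveThresholds:
    def test_constant_channel(self, id_panel):
        n = len(id_panel.channels)
        vals = np.full((100, n), 500.0)
        fmo = {"CD45": EventTable("f", id_panel, vals)}
        ts = derive_thresholds(fmo, q=0.995)
        assert ts["CD45"] == pytest.approx(DEFAULT_TRANSFORM.forward(500.0))
        assert ts.provenance["CD45"] == "fmo_quantile 0.995"

    def test_standard_normal_quantile_oracle(self, id_panel):
        # transformed values ~ N(0,1): the 99.5% cutoff is z_0.995 = 2.576
        rng = np.random.default_rng(7)
        n = len(id_panel.channels)
        vals = np.ones((200_000, n))
        j = id_panel.index_of("EpCAM")
        vals[:, j] = DEFAULT_TRANSFORM.inverse(rng.standard_normal(200_000))
        fmo = {"EpCAM": EventTable("f", id_panel, vals)}
        ts = derive_thresholds(fmo, q=0.995)
        assert ts["EpCAM"] == pytest.approx(2.5758, abs=0.03)

    def test_invalid_quantile_and_empty_rejected(self, id_panel):
        n = len(id_panel.channels)
        fmo = {"CD45": EventTable("f", id_panel, np.ones((10, n)))}
        with pytest.raises(GatingError):
            derive_thresholds(fmo, q=0.5)
        with pytest.raises(GatingError):
            derive_thresholds(
                {"CD45": EventTable("f", id_panel, np.empty((0, n)))})

    def test_missing_threshold_named(self):
        ts = ThresholdSet({"CD45": 1.8})
        with pytest.raises(GatingError, match="CD3"):
            build_ln_gating_tree(ts)


def _event(panel, **values):
    """One transformed-scale event row; scatter in linear units."""
    row = np.full(len(panel.channels), 0.9)  # background everywhere
    defaults = {"FSC-A": 100_000.0, "FSC-H": 100_000.0, "SSC-A": 30_000.0,
                "SFL": 10_000.0}
    for ch, v in {**defaults, **values}.items():
        row[panel.index_of(ch)] = v
    return row


class TestGatingTree:
    def test_phenotype_assignments(self, id_panel):
        ts = default_thresholds()
        tree = build_ln_gating_tree(ts)
        colmap = {c.channel_id: j for j, c in enumerate(id_panel.channels)}
        hi, lo = 5.0, 0.9
        cases = [
            # tumor: CD45- EpCAM+ SSC-bright CD146- FMA-
            (_event(id_panel, EpCAM=hi, **{"SSC-A": 120_000.0}), "tumor"),
            # CD45 low + CD146 high -> endothelium even if EpCAM high
            (_event(id_panel, EpCAM=hi, CD146=hi,
                    **{"SSC-A": 120_000.0}), "endothelium"),
            (_event(id_panel, CD45=3.0, FMA=hi,
                    **{"SSC-A": 60_000.0}), "fibroblast"),
            (_event(id_panel, CD45=hi, CD3=hi, CD4=hi), "T_CD4"),
            (_event(id_panel, CD45=hi, CD3=hi, CD8=hi), "T_CD8"),
            (_event(id_panel, CD45=hi, CD3=hi), "T_other"),
            (_event(id_panel, CD45=hi, CD19=hi, **{"HLA-DR": hi}), "B"),
            (_event(id_panel, CD45=hi, CD16=hi), "NK"),
            (_event(id_panel, CD45=hi, CD16=hi,
                    **{"SSC-A": 60_000.0}), "neutrophil"),
            (_event(id_panel, CD45=hi, **{"SSC-A": 70_000.0}), "eosinophil"),
            (_event(id_panel, CD45=hi, CD64=hi, **{"HLA-DR": hi,
                    "SSC-A": 52_000.0}), "monocyte"),
            (_event(id_panel, CD45=hi, **{"HLA-DR": hi}), "dendritic"),
            (_event(id_panel), "unclassified"),
        ]
        matrix = np.vstack([c[0] for c in cases])
        labels = tree.classify(matrix, colmap)
        assert list(labels) == [c[1] for c in cases]

    def test_oracle_equivalence_brute_force(self, id_panel):
        """First-match tree output equals independent brute-force evaluation
        of every leaf's full conjunction in documented precedence order."""
        ts = default_thresholds()
        tree = build_ln_gating_tree(ts)
        colmap = {c.channel_id: j for j, c in enumerate(id_panel.channels)}
        rng = np.random.default_rng(3)
        n = 10_000
        matrix = np.empty((n, len(id_panel.channels)))
        for j, ch in enumerate(id_panel.channels):
            if ch.role == "scatter":
                matrix[:, j] = rng.uniform(0, 200_000, n)
            else:
                matrix[:, j] = rng.uniform(-1, 7, n)  # transformed scale

        def brute(row):
            for node in tree.nodes:
                ok = True
                for chan, op, bound in node.conditions:
                    v = row[colmap[chan]]
                    ok &= (v > bound) if op == ">" else (v <= bound)
                if ok:
                    return node.name
            return "unclassified"

        expect = np.array([brute(matrix[i]) for i in range(n)], dtype=object)
        assert np.array_equal(tree.classify(matrix, colmap), expect)

    def test_yaml_round_trip(self):
        tree = build_ln_gating_tree(default_thresholds())
        back = GatingTree.from_yaml(tree.to_yaml())
        assert back == tree
        doc = yaml.safe_load(tree.to_yaml())
        assert doc[0]["name"] == "endothelium"


class TestClassifyEvents:
    def test_partition_and_permutation_invariance(self, id_panel):
        truth = make_truth(tumor=0.6, T_CD4=0.1, B=0.05, debris=0.04,
                           dead=0.02)
        table, _ = simulate_sample(id_panel, truth, 20_000)
        tree = build_ln_gating_tree(default_thresholds())
        res = classify_events(table, tree)
        pct = res.population.percentages
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)
        # shuffling event order changes no reported statistic
        rng = np.random.default_rng(0)
        shuffled = EventTable(table.sample_id, table.panel,
                              table.values[rng.permutation(table.n_events)],
                              table.keywords)
        res2 = classify_events(shuffled, tree)
        assert res2.population.counts == res.population.counts
        assert res2.population.viability_percent == pytest.approx(
            res.population.viability_percent)

    def test_all_tumor_sample(self, id_panel):
        truth = make_truth(tumor=1.0)
        table, _ = simulate_sample(id_panel, truth, 10_000)
        tree = build_ln_gating_tree(default_thresholds())
        res = classify_events(table, tree)
        pct = res.population.percentages
        assert pct["tumor"] > 97.5
        assert pct["unclassified"] <= 1.5

    def test_gated_tumor_tracks_truth(self, id_panel):
        truth = make_truth(tumor=0.62, T_CD4=0.05, T_CD8=0.04, B=0.02,
                           NK=0.01, neutrophil=0.15, fibroblast=0.02,
                           endothelium=0.01, debris=0.04, dead=0.02)
        table, _ = simulate_sample(id_panel, truth, 50_000,
                                   doublet_fraction=0.03)
        tree = build_ln_gating_tree(default_thresholds())
        res = classify_events(table, tree)
        true_viable = truth.viable_composition()["tumor"] * 100
        assert res.population.percentages["tumor"] == pytest.approx(
            true_viable, abs=2.0)

    def test_threshold_monotonicity(self, char_panel, nsclc_median_truth):
        # raising the FMO quantile never increases any downstream %positive
        from lnaspire.profiles import percent_positive
        truth = nsclc_median_truth
        fmo = {m: simulate_fmo(char_panel, truth, m, 10_000)
               for m in ("CD56", "PD-L2")}
        table, labels = simulate_sample(char_panel, truth, 10_000)
        tumor = labels.population == "tumor"
        for marker in ("CD56", "PD-L2"):
            vals = table.column(marker)[tumor]
            fracs = [percent_positive(vals, derive_thresholds(fmo, q=q)[marker])
                     for q in (0.99, 0.995, 0.999)]
            assert fracs[0] >= fracs[1] >= fracs[2]

    def test_min_events_refusal(self, id_panel):
        truth = make_truth(tumor=1.0)
        table, _ = simulate_sample(id_panel, truth, 300)
        tree = build_ln_gating_tree(default_thresholds())
        with pytest.raises(GatingError, match="viable singlet"):
            classify_events(table, tree, min_events=500)
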