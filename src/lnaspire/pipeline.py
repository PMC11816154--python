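"""End-to-end orchestration: simulate -> gate -> profile -> analyze -> compare.

This is the programmatic equivalent of running the full study once: build
both cohorts, derive FMO thresholds per cohort and tube, gate every sample,
profile the tumor gate of the characterization tube, compute the virtual
analyzer parameters, and emit the per-sample table plus the group
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analyzer import AnalyzerResult, positional_parameters
from .cohort import (CohortConfig, SampleSet, default_cohort_config,
                     simulate_cohort)
from .gating import (ClassificationResult, ScatterCutpoints, ThresholdSet,
                     build_ln_gating_tree, characterization_tumor_gate,
                     classify_events, derive_thresholds)
from .profiles import AntigenProfile, profile_tumor_cells
from .stats import compare_groups

log = logging.getLogger("lnaspire")


def group_seed(master_seed: int, group: str) -> int:
    """Stable per-group sub-seed below 2**31."""
    key = {"NSCLC": 0, "SCLC": 1}[group]
    ss = np.random.SeedSequence(entropy=master_seed & 0x7FFFFFFF,
                                spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SampleOutput:
    patient_id: str
    group: str
    classification: ClassificationResult
    char_classification: ClassificationResult
    profile: AntigenProfile
    analyzer: AnalyzerResult


@dataclass
class CohortRun:
    sample_set: SampleSet
    outputs: list[SampleOutput]
    thresholds: dict[tuple[str, str], ThresholdSet]
    per_sample: pd.DataFrame
    comparison: pd.DataFrame

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.per_sample[self.per_sample["group"] == group]


def default_configs(master_seed: int, n_events: int = 50_000,
                    n_nsclc: int | None = None, n_sclc: int | None = None,
                    ) -> tuple[CohortConfig, CohortConfig]:
    cfg_n = default_cohort_config("NSCLC", n_events,
                                  group_seed(master_seed, "NSCLC"), n_nsclc)
    cfg_s = default_cohort_config("SCLC", n_events,
                                  group_seed(master_seed, "SCLC"), n_sclc)
    return cfg_n, cfg_s


def run_cohort(master_seed: int = 20250127, n_events: int = 50_000,
               n_nsclc: int | None = None, n_sclc: int | None = None,
               fmo_quantile: float = 0.995,
               cutpoints: ScatterCutpoints = ScatterCutpoints(),
               min_events: int = 500,
               sample_set: SampleSet | None = None) -> CohortRun:
    """Run the whole two-cohort study once and return every artifact."""
    if sample_set is None:
        cfg_n, cfg_s = default_configs(master_seed, n_events, n_nsclc, n_sclc)
        log.info("simulating cohorts: %d NSCLC + %d SCLC patients, "
                 "%d events/sample", cfg_n.n_patients, cfg_s.n_patients,
                 n_events)
        sample_set = simulate_cohort(cfg_n, cfg_s)

    thresholds: dict[tuple[str, str], ThresholdSet] = {}
    for key, tubes in sample_set.fmo.items():
        thresholds[key] = derive_thresholds(tubes, q=fmo_quantile)
    log.info("derived %d FMO threshold sets", len(thresholds))

    outputs: list[SampleOutput] = []
    rows = []
    for rec in sample_set.samples:
        id_thr = thresholds[(rec.group, "identification")]
        char_thr = thresholds[(rec.group, "characterization")]
        tree = build_ln_gating_tree(id_thr, cutpoints)
        cls = classify_events(rec.id_table, tree, min_events=min_events)
        char_tree = characterization_tumor_gate(char_thr, cutpoints)
        char_cls = classify_events(rec.char_table, char_tree,
                                   min_events=min_events)
        profile = profile_tumor_cells(rec.char_table, char_cls.labels,
                                      char_thr)
        ana = positional_parameters(rec.id_table, cls.labels)

        outputs.append(SampleOutput(rec.patient_id, rec.group, cls, char_cls,
                                    profile, ana))
        row = {"patient_id": rec.patient_id, "group": rec.group}
        row.update(cls.population.to_row())
        row.update(profile.to_row() if profile.evaluable
                   else {"tumor_events_char": 0})
        row["tumor_events"] = cls.population.tumor_event_count
        row.update(ana.to_row())
        row["true_tumor_fraction"] = rec.truth.viable_composition()["tumor"]
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    comparison = compare_groups(per_sample[per_sample["group"] == "NSCLC"],
                                per_sample[per_sample["group"] == "SCLC"])
    return CohortRun(sample_set, outputs, thresholds, per_sample, comparison)


def write_run(run: CohortRun, out_dir) -> None:
    import os

    from .stats import format_comparison_markdown
    os.makedirs(out_dir, exist_ok=True)
    run.per_sample.to_csv(os.path.join(out_dir, "per_sample.csv"), index=False,
                          float_format="%.6g")
    run.comparison.to_csv(os.path.join(out_dir, "comparison.csv"), index=False,
                          float_format="%.6g")
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(format_comparison_markdown(run.comparison,
                                            "NSCLC vs SCLC comparison"))
    summary = {
        "n_nsclc": int((run.per_sample["group"] == "NSCLC").sum()),
        "n_sclc": int((run.per_sample["group"] == "SCLC").sum()),
        "tumor_pct_median_nsclc": float(
            run.group_frame("NSCLC")["tumor_pct"].median()),
        "tumor_pct_median_sclc": float(
            run.group_frame("SCLC")["tumor_pct"].median()),
        "tumor_pct_mean_all": float(run.per_sample["tumor_pct"].mean()),
        "min_viability_pct": float(run.per_sample["viability_pct"].min()),
    }
    import json
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
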