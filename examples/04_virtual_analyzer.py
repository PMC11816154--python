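"""Virtual hematology-analyzer readouts for one NSCLC and one SCLC sample.

Events are mapped to 0-255 WDF channel axes; NE-SSC/NE-SFL/NE-FSC are
medians of the neutrophil cluster, LY-X/LY-Y of the lymphocyte cluster, and
the high-fluorescence (HF) cloud fraction counts events high on the SFL
axis — in tumor-rich aspirates that cloud is the tumor population itself.
"""

from lnaspire import (default_cohort_config, detect_hf_cloud,
                      draw_patient_truth, identification_panel,
                      positional_parameters, simulate_sample)

panel = identification_panel()
for group in ("NSCLC", "SCLC"):
    config = default_cohort_config(group, master_seed=5)
    truth = draw_patient_truth(config, index=1)
    table, labels = simulate_sample(panel, truth, 50_000)

    res = positional_parameters(table, labels.population)
    blind = positional_parameters(table, labels=None)
    frac, flag = detect_hf_cloud(table)

    print(f"{group}: tumor truth "
          f"{100 * truth.viable_composition()['tumor']:.0f}%")
    print(f"  NE-SSC {res.ne_ssc:.1f} ch | NE-SFL {res.ne_sfl:.1f} | "
          f"NE-FSC {res.ne_fsc:.1f} | LY-X {res.ly_x:.1f} | "
          f"LY-Y {res.ly_y:.1f}")
    print(f"  blind-mode NE-SSC {blind.ne_ssc:.1f} ch (rectangle clusters)")
    print(f"  HF cloud: {100 * frac:.1f}% of intact events, "
          f"flag={'ON' if flag else 'off'}")
    print(f"  WBC {res.wbc_per_ul:.0f} cells/uL "
          f"(truth {truth.wbc_per_ul:.0f})")
# NSCLC neutrophils sit near channel 150 on the SSC axis and SCLC ones near
# 119; lymphocyte complexity (LY-X) runs the other way (84 vs 95).
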