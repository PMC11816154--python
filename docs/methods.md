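# Methods

## The measurement problem

A metastatic mediastinal lymph node sampled by EBUS/TBNA yields a liquid
aspirate in which tumor cells usually dominate. Two instruments read it:

1. a fluorescence hematology analyzer whose WDF differential channel
   places each nucleated cell on FSC (volume), SSC (granularity) and SFL
   (nucleic-acid dye fluorescence) axes, and
2. a multicolor flow cytometer with a two-tube antibody panel: an
   *identification* tube (CD64, FMA, CD146, CD19, CD3, CD8, EpCAM, CD16,
   HLA-DR, CD45, CD4, 7-AAD) that assigns every event to a population, and
   a *characterization* tube carrying 16 tumor-relevant antigens.

The package reproduces both readouts and the NSCLC-vs-SCLC group
comparison. Because no event-level data are deposited, a synthetic cohort
generator is a first-class component: it defines the study conditions and
supplies ground truth for every downstream stage.

## Synthetic cohort model

### Per-patient truth

Each patient owns a truth record: the population mixture of their
aspirate, the positive fraction of each of the 16 antigens on their tumor
cells, and a WBC concentration. Every truth variable follows a **split
normal on the logit scale** (log scale for WBC): location at the group
median, with separate lower and upper scales chosen so the prior's
quartiles equal the group's Q1/median/Q3 exactly. A single symmetric
dispersion cannot do this — the published group IQRs are strongly
asymmetric — and the split parameterization reproduces all three printed
quartiles rather than a compromise between them.

Patients receive **stratified quantile slots**: for each variable, a
seed-derived permutation deals the cohort grid `(rank + 0.5 ± jitter)/n`
out to patients. The cohort-level quartiles of every truth variable
therefore match the configured priors by construction, while the joint
profile of any one patient remains random (independent permutations per
variable). This is deliberate: the generator's job is to *reproduce the
cohort tables*, and with n = 20–27 patients, independent draws would leave
the sample median with a standard error near ten percentage points.
A consequence is that changing `n_patients` re-deals all truth slots;
event-level streams, in contrast, are splittable per patient
(`SeedSequence(master, spawn_key=(index,))`), so event noise for patient
*i* never depends on the cohort size.

The tumor fraction is drawn first from its own prior; the other ten viable
populations split the remaining mass proportionally to their drawn
weights. Tumor quartile recovery is exact; the minor populations are
inflated by a common factor (the printed non-tumor medians sum to ~22%,
not to 100 − 62.5), which no headline statistic reads. Populations whose
group median prints as zero (eosinophils, monocytes, dendritic cells) are
generated as trace populations (medians 0.1–0.2%) so their heuristic gates
have something to find. Debris is fixed at 4% of events; the dead fraction
varies in [0.5%, 3%], keeping every sample above the 95% viability floor
by construction.

### Per-event emission

Events are drawn per population with multinomial counts. Fluorescence
channels use a two-component normal on the arcsinh scale
(`t(x) = asinh(x/150)`): background N(0.9, 0.35), positive N(5.0, 0.5),
plus a CD45-dim component N(3.0, 0.35) for fibroblasts; values are
inverse-transformed to linear before storage. The analytic location of
every component makes quantiles checkable in closed form — e.g. an FMO
cutoff at q = 0.995 must land at 0.9 + 2.576·0.35 ≈ 1.80.

Scatter and SFL are linear normals per population. Neutrophil and
lymphocyte locations are group-conditional and were fixed once by
inverting the analyzer's frozen affine calibration at the group positional
medians (see below); a per-patient 2% multiplicative jitter (shared by
both tubes) provides biological location noise. Dying cells and stromal
cells are emitted with elevated SFL — dying cells bind the nucleic-acid
dye strongly, and stromal cells carry more RNA than resting granulocytes —
which is also what keeps them out of the analyzer's blind neutrophil box.

Doublets (default 3%) merge random event pairs: areas add, FSC-H stays at
the first member's level, so the area-to-height ratio gate removes them.

**Gate markers vs readout antigens.** In the identification tube, tumor
events are always EpCAM-positive: EpCAM is the gate marker there. The
per-patient antigen-positive fractions apply to the characterization tube,
where EpCAM is a readout. This mirrors the assay's own logic — a tumor
gate defined on EpCAM coexisting with an EpCAM percent-positive below
100% — and is why the characterization tube's reduced tumor gate (below)
must not condition on EpCAM.

### What the generator does not model

No spillover/compensation (events are "post-compensation"), no
acquisition-time drift, no permeabilization effects for the intracellular
markers (TTF-1, Ki67, cytokeratin, CTLA-4 are treated like surface
stains), no analyzer reagent chemistry, and no correlation between
antigens within a patient beyond what the per-patient fractions induce.
Passing recovery tests therefore demonstrates that the *pipeline* is
correct and well calibrated, not that it would meet the same tolerances on
real aspirates with instrument-specific artifacts.

## Gating

Pre-gates run in fixed order: singlets (FSC-A/FSC-H ∈ [0.75, 1.35]),
debris (FSC-A ≥ 25,000), viability (arcsinh 7-AAD ≤ 2.5). The composition
denominator ("% of all cells") is always viable singlet non-debris events;
classification refuses samples with fewer than 500 of them (configurable).

The classifier is a flat first-match-wins conjunction list — equivalent
to, and property-tested against, brute-force evaluation of every leaf.
Precedence encodes the elimination logic: endothelium (CD45− CD146+) and
fibroblast (CD45-dim FMA+) are tested *before* tumor, so the tumor leaf
keeps only events that are neither; monocytes (CD64+ HLA-DR+,
marker-anchored) precede the lymphoid branches; CD3+ branches precede
CD19/CD16 branches; neutrophils precede NK so granulocytes straddling the
SSC dim cut are not absorbed into NK. Eosinophil (CD16− granulocyte) and
dendritic (lineage− HLA-DR+ CD64−) leaves are heuristic extrapolations and
are flagged as such in results.

Scatter cutpoints are named config values: `ssc_dim` = 41,000 (lymphocyte
SSC 99th percentile under the default generator), `ssc_bright` = 39,000
(neutrophil SSC 5th percentile), a monocyte intermediate band up to
75,000, and the fibroblast CD45-dim band (FMO cutoff, lymphocyte CD45 5th
percentile ≈ 4.18 transformed). Ties at a cutoff count as negative:
"positive" is strictly greater.

Known behavior at the defaults: SCLC neutrophils (lower granularity,
NE-SSC ≈ 119 ch) overlap the bright cut, costing ~5% neutrophil recall,
with a small spill into NK; all populations at ≥ 1% abundance retain
≥ 90% recall against truth labels.

**Characterization tube.** The second tube carries CD45 and 7-AAD
alongside the 16 antigens so it can be pre-gated and tumor-gated on its
own. Its reduced tumor gate is `CD45− ∧ SSC > 75,000`: EpCAM is excluded
from the gate so the EpCAM readout is unbiased, and the high SSC cut keeps
endothelium (the other CD45− population) out.

## Thresholds and profile readouts

FMO controls are simulated once per cohort (population mixture at the
prior medians), one tube per thresholded marker per panel — representative
controls, as labs run them, rather than per-patient tubes. The cutoff is
the q = 0.995 quantile of the omitted channel; the quantile is a config
value since the assay description does not pin it. Raising q can only
lower every percent-positive readout (monotonicity is property-tested);
note the tumor *gate* percentage is not monotone in q, because CD45, CD146
and FMA enter it negated.

Percent positive is a strict count above the cutoff; an empty tumor gate
is a structured "not evaluable" result, never a silent zero. GMF floors
values at 1 linear unit before the log (configurable) so near-zero
baseline-restored values cannot dominate; GMF is scale-equivariant above
the floor.

## Virtual analyzer

Linear values map to 0–255 channel axes by frozen affine constants —
SSC/400 + 9, SFL/250 + 5, FSC/2000 + 17, clipped — chosen once so that the
default cohorts land at the published positional medians (NE-SSC
150.6/119.1 ch, LY-X 83.9/95.0, NE-SFL 45.9/48.1, NE-FSC 72.4/66.0, LY-Y
53.8/48.7 for NSCLC/SCLC). Absolute channel calibration of the real
instrument is unpublished, so these recoveries are calibration-anchored
checks of the pipeline, not predictions.

Positional parameters are medians of the neutrophil and lymphocyte
clusters (so they are permutation-invariant and robust); clusters with
fewer than 50 events report a reason code instead of a number. Cluster
membership comes from gating labels when available; blind mode uses fixed
rectangles on the SSC×SFL plane (lymphocytes: SSC ≤ 105, SFL ≤ 70;
neutrophils: 105 < SSC ≤ 200, SFL ≤ 53 — the lower SFL ceiling keeps
monocytes and stromal cells out at the cost of a ≤ 2-channel downward bias
on blind NE-SFL). The HF cloud is the fraction of intact events above
SFL channel 70 (the 99th percentile of normal leukocyte SFL), flagged at
≥ 5%. WBC concentration is events divided by aspirated volume.

## Statistics

Mean ± SD (n−1), median and type-7 quartiles per group and variable;
two-sided Mann–Whitney U with the min-U convention — exact enumeration for
tie-free samples with n₁·n₂ ≤ 400, otherwise the normal approximation with
tie and continuity corrections (at group sizes 20×27 the comparison is
always asymptotic). Exact and asymptotic p agree within 0.02 for tie-free
samples at n = 5–10. No multiplicity adjustment drives the significance
flag (matching the assay's reporting convention); a Benjamini–Hochberg
column is emitted alongside.

## Problem sizes and tolerances

The default study is 20 + 27 patients at 50,000 events per sample — a
desk-scale stand-in for the instrument's ≥ 300,000-event acquisitions
(configurable upward); the full pipeline runs in about half a minute.
Recovery tolerances in the test suite: group medians of tumor % and
antigen percent-positives within ±3 percentage points; positional medians
within ±4 channel units; per-population recall ≥ 90% at ≥ 1% abundance.

One recovery sits knowingly outside its band: the whole-cohort mean gated
tumor percentage. Priors faithful to the published group quartiles imply a
mixture mean of 67.7%, and the elimination gate loses ~1.5% of true tumor
events to FMO-quantile leakage on its three negated channels (0.5% per
channel at q = 0.995), so the pipeline recovers ≈ 66.8% against the
published 70.4% — the published quartiles and the published mean are not
jointly consistent with any model that matches all three quartiles. We
report the number the faithful model produces rather than inflating the
priors to chase the mean.
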