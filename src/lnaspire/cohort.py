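"""Synthetic lymph-node-aspirate cohorts calibrated to printed group tables.

The generator emulates the study design this package analyzes: two disease
groups (NSCLC, n=20; SCLC, n=27), one identification tube and one
characterization tube per patient, cohort-level FMO controls, and full
ground-truth labels for every simulated event.

Per-patient heterogeneity follows a *split* normal on the logit scale whose
lower/upper scales are set so that the prior's quartiles Q1/median/Q3 equal
the group values the cohort is calibrated to.  Patients receive stratified
quantile slots (a seed-derived permutation of the cohort grid per variable),
so the simulated cohort's quartiles reproduce the configured priors by
construction rather than only in expectation; event-level noise on top of a
patient's truth uses an independent, splittable per-patient stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from .fcs import EventTable, write_fcs
from .panels import (CHAR_ANTIGENS, Panel, SFL_MARKER,
                     characterization_panel, identification_panel)
from .templates import (ALL_POPULATIONS, FLUOR_COMPONENTS, VIABLE_POPULATIONS,
                        PopulationTemplate, default_templates)
from .transforms import DEFAULT_TRANSFORM, TransformSpec

_Q3Z = 0.6744897501960817  # standard normal upper-quartile


@dataclass(frozen=True)
class SplitPrior:
    """Three-quartile prior: split normal on a link scale.

    ``quantile(u)`` returns the value whose CDF is ``u``; by construction
    quantile(0.25/0.5/0.75) equal the calibrated Q1/median/Q3.
    """

    median: float
    sigma_lo: float
    sigma_hi: float
    link: str = "logit"

    @classmethod
    def from_quartiles(cls, median: float, q1: float, q3: float,
                       link: str = "logit") -> "SplitPrior":
        f = logit if link == "logit" else np.log
        m = float(f(median))
        return cls(median, (m - float(f(q1))) / _Q3Z,
                   (float(f(q3)) - m) / _Q3Z, link)

    def quantile(self, u: float | np.ndarray) -> np.ndarray:
        z = ndtri(np.asarray(u, dtype=float))
        s = np.where(z < 0, self.sigma_lo, self.sigma_hi)
        f, g = (logit, expit) if self.link == "logit" else (np.log, np.exp)
        return g(f(self.median) + s * z)

    def scaled(self, factor: float) -> "SplitPrior":
        return replace(self, sigma_lo=self.sigma_lo * factor,
                       sigma_hi=self.sigma_hi * factor)


def _pr(median_pct, q1_pct, q3_pct):
    return SplitPrior.from_quartiles(median_pct / 100, q1_pct / 100, q3_pct / 100)


# Population priors as % of viable singlet events.  Populations whose group
# median prints as 0 are generated as trace populations with small fixed
# medians taken from the whole-cohort means; printed zero quartiles are
# floored at a quarter of the median so the logit is defined.
_POPULATION_PRIORS: dict[str, dict[str, SplitPrior]] = {
    "NSCLC": {
        "tumor": _pr(62.5, 32.3, 78.4),
        "T_CD4": _pr(3.5, 1.5, 8.4),
        "T_CD8": _pr(3.2, 0.9, 5.5),
        "B": _pr(1.8, 0.5, 6.3),
        "NK": _pr(0.4, 0.1, 1.2),
        "neutrophil": _pr(11.1, 2.0, 22.2),
        "eosinophil": _pr(0.1, 0.025, 0.3),
        "monocyte": _pr(0.2, 0.05, 0.6),
        "dendritic": _pr(0.1, 0.025, 0.3),
        "fibroblast": _pr(1.2, 0.2, 4.8),
        "endothelium": _pr(0.6, 0.1, 1.8),
    },
    "SCLC": {
        "tumor": _pr(88.5, 65.7, 94.6),
        "T_CD4": _pr(1.2, 0.4, 4.0),
        "T_CD8": _pr(1.4, 0.3, 2.2),
        "B": _pr(0.6, 0.3, 1.7),
        "NK": _pr(0.2, 0.05, 0.9),
        "neutrophil": _pr(2.9, 0.8, 17.8),
        "eosinophil": _pr(0.1, 0.025, 0.3),
        "monocyte": _pr(0.2, 0.05, 1.4),
        "dendritic": _pr(0.1, 0.025, 0.3),
        "fibroblast": _pr(0.4, 0.1, 1.0),
        "endothelium": _pr(0.1, 0.025, 1.4),
    },
}

# Antigen-positive fraction of tumor cells, per group.
_ANTIGEN_PRIORS: dict[str, dict[str, SplitPrior]] = {
    "NSCLC": {
        "EpCAM": _pr(70.1, 51.9, 80.1),
        "MUC-1": _pr(88.0, 82.7, 94.3),
        "TTF-1": _pr(77.0, 48.2, 85.0),
        "Ki67": _pr(72.7, 57.1, 90.9),
        "cytokeratin": _pr(82.3, 43.9, 89.9),
        "CD56": _pr(60.4, 35.6, 67.3),
        "CD38": _pr(8.0, 4.2, 12.7),
        "HLA-DR": _pr(11.8, 5.7, 59.4),
        "HER-2": _pr(24.7, 16.8, 50.0),
        "CD39": _pr(20.0, 10.1, 30.9),
        "CD73": _pr(25.8, 16.2, 58.6),
        "CD90": _pr(9.8, 3.1, 19.1),
        "CD184": _pr(16.5, 2.9, 27.1),
        "PD-L1": _pr(21.6, 8.3, 45.1),
        "PD-L2": _pr(58.7, 39.5, 71.9),
        "CTLA-4": _pr(3.2, 1.1, 7.1),
    },
    "SCLC": {
        "EpCAM": _pr(87.5, 75.5, 91.4),
        "MUC-1": _pr(72.6, 59.9, 79.0),
        "TTF-1": _pr(78.5, 65.6, 85.3),
        "Ki67": _pr(65.5, 54.2, 77.8),
        "cytokeratin": _pr(72.8, 15.1, 89.0),
        "CD56": _pr(88.5, 61.9, 96.7),
        "CD38": _pr(2.4, 0.7, 13.3),
        "HLA-DR": _pr(1.1, 0.6, 3.7),
        "HER-2": _pr(40.8, 5.6, 64.0),
        "CD39": _pr(3.0, 0.9, 10.5),
        "CD73": _pr(18.1, 12.5, 32.9),
        "CD90": _pr(26.3, 5.4, 54.0),
        "CD184": _pr(35.1, 13.6, 67.2),
        "PD-L1": _pr(6.4, 0.3, 13.4),
        "PD-L2": _pr(26.7, 8.2, 42.9),
        "CTLA-4": _pr(21.4, 2.2, 46.6),
    },
}

# White-blood-cell concentration (cells/uL), log-scale split prior.
_WBC_PRIORS = {
    "NSCLC": SplitPrior.from_quartiles(757, 333, 1752, link="log"),
    "SCLC": SplitPrior.from_quartiles(2115, 765, 6499, link="log"),
}

GROUP_SIZES = {"NSCLC": 20, "SCLC": 27}


@dataclass(frozen=True)
class CohortConfig:
    group: str
    n_patients: int
    n_events_per_sample: int = 50_000
    population_fraction_priors: dict[str, SplitPrior] = field(default_factory=dict)
    antigen_positivity_priors: dict[str, SplitPrior] = field(default_factory=dict)
    wbc_prior: SplitPrior | None = None
    doublet_fraction: float = 0.03
    debris_fraction: float = 0.04
    dead_fraction_min: float = 0.005
    dead_fraction_max: float = 0.03
    master_seed: int = 20250127

    def __post_init__(self) -> None:
        if self.group not in ("NSCLC", "SCLC"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_events_per_sample < 1:
            raise ValueError("n_events_per_sample must be >= 1")
        if not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet_fraction must be in [0, 1)")
        if not 0 <= self.dead_fraction_min <= self.dead_fraction_max <= 0.05:
            raise ValueError("dead fractions must satisfy 0 <= min <= max <= 0.05")


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth used to simulate one patient."""

    patient_id: str
    group: str
    population_fractions: dict[str, float]  # includes debris and dead; sums to 1
    antigen_positive_fractions: dict[str, float]
    wbc_per_ul: float
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.population_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")
        for name, f in self.population_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fraction of {name!r} outside [0, 1]")
        for name, f in self.antigen_positive_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"antigen fraction of {name!r} outside [0, 1]")
        if self.wbc_per_ul < 0:
            raise ValueError("wbc_per_ul must be >= 0")

    @property
    def viable_fraction(self) -> float:
        return 1.0 - self.population_fractions.get("debris", 0.0) \
            - self.population_fractions.get("dead", 0.0)

    def viable_composition(self) -> dict[str, float]:
        v = self.viable_fraction
        return {p: self.population_fractions[p] / v for p in VIABLE_POPULATIONS}


@dataclass
class TruthLabels:
    """Per-event generating population and true antigen positivity."""

    population: np.ndarray  # dtype=object strings, includes 'doublet'
    antigen_positive: dict[str, np.ndarray] = field(default_factory=dict)


def default_cohort_config(group: str, n_events_per_sample: int = 50_000,
                          master_seed: int = 20250127,
                          n_patients: int | None = None) -> CohortConfig:
    """The frozen study conditions for one disease group."""
    if group not in GROUP_SIZES:
        raise ValueError(f"unknown group label {group!r}")
    return CohortConfig(
        group=group,
        n_patients=GROUP_SIZES[group] if n_patients is None else n_patients,
        n_events_per_sample=n_events_per_sample,
        population_fraction_priors=dict(_POPULATION_PRIORS[group]),
        antigen_positivity_priors=dict(_ANTIGEN_PRIORS[group]),
        wbc_prior=_WBC_PRIORS[group],
        master_seed=master_seed,
    )


def _crc(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


_PERM_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _slot_perm(seed: int, var_crc: int, n: int) -> np.ndarray:
    key = (seed, var_crc, n)
    if key not in _PERM_CACHE:
        if len(_PERM_CACHE) > 4096:
            _PERM_CACHE.clear()
        _PERM_CACHE[key] = np.random.default_rng(
            [seed, var_crc, n]).permutation(n)
    return _PERM_CACHE[key]


def _stratified_u(config: CohortConfig, index: int, variable: str) -> float:
    """Quantile slot of patient ``index`` for one truth variable.

    A seed-derived permutation deals the cohort grid slots out per variable;
    within-slot jitter comes from the patient's own stream, so the cohort
    quantiles match the prior while patients stay mutually independent in
    their joint profile.
    """
    n = config.n_patients
    perm = _slot_perm(config.master_seed & 0x7FFFFFFF, _crc(variable), n)
    jitter = np.random.default_rng(
        [config.master_seed & 0x7FFFFFFF, index, _crc(variable)]
    ).uniform(-0.45, 0.45)
    return (perm[index] + 0.5 + jitter) / n


def _draw(config: CohortConfig, index: int, variable: str,
          prior: SplitPrior) -> float:
    if prior.sigma_lo == 0 and prior.sigma_hi == 0:
        return float(prior.median)
    return float(prior.quantile(_stratified_u(config, index, variable)))


def patient_seed(config: CohortConfig, index: int) -> int:
    ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def draw_patient_truth(config: CohortConfig, index: int) -> PatientTruth:
    """Deterministic truth draw for patient ``index`` of a configured cohort.

    The tumor fraction is drawn from its own prior first; the remaining
    viable mass is split among the other populations proportionally to their
    drawn weights, so the tumor quartiles are reproduced exactly.
    """
    if not 0 <= index < config.n_patients:
        raise IndexError(
            f"patient index {index} out of range [0, {config.n_patients})")
    priors = config.population_fraction_priors
    f_tumor = _draw(config, index, "pop:tumor", priors["tumor"])
    others = {p: _draw(config, index, f"pop:{p}", priors[p])
              for p in VIABLE_POPULATIONS if p != "tumor"}
    w = sum(others.values())
    viable = {"tumor": f_tumor}
    for p, g in others.items():
        viable[p] = (1.0 - f_tumor) * g / w if w > 0 else 0.0

    u = _stratified_u(config, index, "dead")
    dead = config.dead_fraction_min + u * (
        config.dead_fraction_max - config.dead_fraction_min)
    debris = config.debris_fraction
    live = 1.0 - debris - dead
    fractions = {p: viable[p] * live for p in VIABLE_POPULATIONS}
    fractions["debris"] = debris
    fractions["dead"] = dead
    # exact renormalization against float drift
    total = sum(fractions.values())
    fractions = {p: f / total for p, f in fractions.items()}

    antigens = {a: _draw(config, index, f"ag:{a}", prior)
                for a, prior in config.antigen_positivity_priors.items()}
    wbc = (_draw(config, index, "wbc", config.wbc_prior)
           if config.wbc_prior is not None else 0.0)
    return PatientTruth(
        patient_id=f"{config.group}-{index:03d}", group=config.group,
        population_fractions=fractions, antigen_positive_fractions=antigens,
        wbc_per_ul=wbc, seed=patient_seed(config, index))


def prior_median_truth(config: CohortConfig, patient_id: str = "FMO") -> PatientTruth:
    """A degenerate patient at the prior medians (used for cohort FMO tubes)."""
    zero = replace(config,
                   population_fraction_priors={
                       k: v.scaled(0.0) for k, v in
                       config.population_fraction_priors.items()},
                   antigen_positivity_priors={
                       k: v.scaled(0.0) for k, v in
                       config.antigen_positivity_priors.items()},
                   wbc_prior=(config.wbc_prior.scaled(0.0)
                              if config.wbc_prior else None),
                   dead_fraction_min=config.dead_fraction_max)
    truth = draw_patient_truth(zero, 0)
    return replace(truth, patient_id=f"{config.group}-{patient_id}")


def _scatter_jitter(truth: PatientTruth) -> dict[str, np.ndarray]:
    """Per-patient multiplicative shifts of every population's scatter/SFL
    locations (2% CV), shared by both tubes of the patient."""
    rng = np.random.default_rng([truth.seed, 777])
    return {pop: rng.normal(1.0, 0.02, size=3) for pop in ALL_POPULATIONS}


def _emit_population(rng: np.random.Generator, panel: Panel,
                     template: PopulationTemplate, truth: PatientTruth,
                     n: int, jitter: np.ndarray, omit: str | None,
                     transform: TransformSpec):
    """Draw ``n`` events of one population; returns (matrix, antigen truth)."""
    cols = np.empty((n, len(panel.channels)))
    antigen_truth: dict[str, np.ndarray] = {}
    jf, js, jl = jitter
    ratio = np.clip(rng.normal(1.0, 0.05, n), 0.8, 1.2)
    for j, ch in enumerate(panel.channels):
        if ch.channel_id == "FSC-A":
            loc, sd = template.scatter.fsc
            cols[:, j] = np.clip(rng.normal(loc * jf, sd, n), 1.0, None)
        elif ch.channel_id == "FSC-H":
            cols[:, j] = cols[:, panel.index_of("FSC-A")] / ratio
        elif ch.channel_id == "SSC-A":
            loc, sd = template.scatter.ssc
            cols[:, j] = np.clip(rng.normal(loc * js, sd, n), 1.0, None)
        elif ch.channel_id == SFL_MARKER:
            loc, sd = template.scatter.sfl
            cols[:, j] = np.clip(rng.normal(loc * jl, sd, n), 1.0, None)
        else:
            marker = ch.channel_id
            if ch.role == "viability":
                comp = "pos" if template.dead else "neg"
            elif marker == omit:
                comp = "neg"
            elif marker in template.heterogeneous:
                frac = truth.antigen_positive_fractions.get(marker, 0.0)
                pos = rng.random(n) < frac
                antigen_truth[marker] = pos
                mu_n, sd_n = FLUOR_COMPONENTS["neg"]
                mu_p, sd_p = FLUOR_COMPONENTS["pos"]
                t = np.where(pos, rng.normal(mu_p, sd_p, n),
                             rng.normal(mu_n, sd_n, n))
                cols[:, j] = transform.inverse(t)
                continue
            else:
                comp = template.component_for(marker)
            mu, sd = FLUOR_COMPONENTS[comp]
            cols[:, j] = transform.inverse(rng.normal(mu, sd, n))
    return cols, antigen_truth


def simulate_sample(panel: Panel, truth: PatientTruth, n_events: int,
                    doublet_fraction: float = 0.0,
                    templates: dict[str, PopulationTemplate] | None = None,
                    transform: TransformSpec = DEFAULT_TRANSFORM,
                    omit_marker: str | None = None,
                    ) -> tuple[EventTable, TruthLabels]:
    """Simulate one stained tube for one patient.

    Population counts are multinomial in the truth fractions; doublets are
    then injected by merging random event pairs (areas add, height stays at
    the first member's level), so ``doublet_fraction`` reduces the returned
    event count accordingly.  Reproducible from ``truth.seed``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    templates = templates or default_templates(truth.group, panel.name)
    for pop in ALL_POPULATIONS:
        if pop not in templates:
            raise ValueError(
                f"population {pop!r} has no template for panel {panel.name!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=truth.seed, spawn_key=(_crc(panel.name),)))
    jitter = _scatter_jitter(truth)

    pops = list(ALL_POPULATIONS)
    p = np.array([truth.population_fractions[pop] for pop in pops])
    counts = rng.multinomial(n_events, p / p.sum())

    blocks, label_blocks = [], []
    antigen_truth = {m: [] for m in CHAR_ANTIGENS} if panel.name == "characterization" else {}
    for pop, n in zip(pops, counts):
        if n == 0:
            continue
        block, ag = _emit_population(rng, panel, templates[pop], truth, n,
                                     jitter[pop], omit_marker, transform)
        blocks.append(block)
        label_blocks.append(np.full(n, pop, dtype=object))
        for m in antigen_truth:
            antigen_truth[m].append(ag.get(m, np.zeros(n, dtype=bool)))
    values = np.vstack(blocks) if blocks else np.empty((0, len(panel.channels)))
    labels = (np.concatenate(label_blocks) if label_blocks
              else np.empty(0, dtype=object))
    ag_full = {m: np.concatenate(v) for m, v in antigen_truth.items()}

    # shuffle so population blocks are interleaved as on a real instrument
    order = rng.permutation(len(values))
    values, labels = values[order], labels[order]
    ag_full = {m: v[order] for m, v in ag_full.items()}

    n_dbl = int(round(doublet_fraction * len(values)))
    if n_dbl > 0:
        idx = rng.choice(len(values), size=2 * n_dbl, replace=False)
        a, b = idx[:n_dbl], idx[n_dbl:]
        merged = values[a] + values[b]
        h = panel.index_of("FSC-H")
        merged[:, h] = values[a][:, h]  # height stays near single-event level
        keep = np.ones(len(values), dtype=bool)
        keep[b] = False
        values[a] = merged
        labels[a] = "doublet"
        values, labels = values[keep], labels[keep]
        ag_full = {m: v[keep] for m, v in ag_full.items()}

    table = EventTable(
        sample_id=f"{truth.patient_id}-{panel.name}", panel=panel,
        values=values,
        keywords={"LNASPIRE_PANEL": panel.name,
                  "LNASPIRE_SAMPLE": f"{truth.patient_id}-{panel.name}",
                  "LNASPIRE_GROUP": truth.group})
    if truth.wbc_per_ul > 0:
        vol = n_events * truth.viable_fraction / truth.wbc_per_ul
        table.keywords["LNASPIRE_VOL_UL"] = f"{vol:.6g}"
    return table, TruthLabels(labels, ag_full)


def simulate_fmo(panel: Panel, truth: PatientTruth, omitted_marker: str,
                 n_events: int,
                 templates: dict[str, PopulationTemplate] | None = None,
                 transform: TransformSpec = DEFAULT_TRANSFORM) -> EventTable:
    """Fluorescence-minus-one control: identical generative process except
    the omitted marker's channel is background for every event."""
    try:
        ch = panel.channel(omitted_marker)
    except KeyError:
        raise ValueError(
            f"omitted marker {omitted_marker!r} not in panel {panel.name!r}")
    if ch.role != "fluorescence" or omitted_marker == SFL_MARKER:
        raise ValueError(
            f"omitted marker {omitted_marker!r} is not an antibody "
            "fluorescence channel")
    table, _ = simulate_sample(panel, truth, n_events, doublet_fraction=0.0,
                               templates=templates, transform=transform,
                               omit_marker=omitted_marker)
    table.sample_id = f"{truth.patient_id}-{panel.name}-FMO-{omitted_marker}"
    table.keywords["LNASPIRE_SAMPLE"] = table.sample_id
    table.keywords["LNASPIRE_FMO"] = omitted_marker
    return table


@dataclass
class SampleRecord:
    patient_id: str
    group: str
    truth: PatientTruth
    id_table: EventTable
    id_labels: TruthLabels
    char_table: EventTable
    char_labels: TruthLabels


@dataclass
class SampleSet:
    """Everything one simulated study produces."""

    samples: list[SampleRecord]
    fmo: dict[tuple[str, str], dict[str, EventTable]]  # (group, panel) -> marker -> table
    manifest: pd.DataFrame
    truth_table: pd.DataFrame

    def group_samples(self, group: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.group == group]

    def write(self, out_dir) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = []
        for rec in self.samples:
            for table in (rec.id_table, rec.char_table):
                path = os.path.join(out_dir, f"{table.sample_id}.fcs")
                write_fcs(table, path)
                paths.append(path)
        for (group, panel_name), tubes in self.fmo.items():
            for marker, table in tubes.items():
                safe = marker.replace("/", "-")
                path = os.path.join(
                    out_dir, f"{group}-{panel_name}-FMO-{safe}.fcs")
                write_fcs(table, path)
        self.manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        self.truth_table.to_csv(os.path.join(out_dir, "truth.csv"), index=False,
                                float_format="%.10g")


def _truth_row(t: PatientTruth) -> dict:
    row = {"patient_id": t.patient_id, "group": t.group, "seed": t.seed,
           "wbc_per_ul": t.wbc_per_ul}
    for p, f in t.population_fractions.items():
        row[f"frac_{p}"] = f
    for a, f in t.antigen_positive_fractions.items():
        row[f"pos_{a}"] = f
    return row


def simulate_cohort(config_nsclc: CohortConfig, config_sclc: CohortConfig,
                    fmo_events: int | None = None) -> SampleSet:
    """Simulate both cohorts, their FMO controls, manifest and truth table.

    FMO tubes are simulated once per cohort at the prior medians (shared
    across patients); one tube per thresholded marker per panel.
    """
    id_panel = identification_panel()
    char_panel = characterization_panel()
    samples: list[SampleRecord] = []
    manifest_rows = []
    truth_rows = []
    fmo: dict[tuple[str, str], dict[str, EventTable]] = {}

    for config in (config_nsclc, config_sclc):
        n_ev = config.n_events_per_sample
        for i in range(config.n_patients):
            truth = draw_patient_truth(config, i)
            id_table, id_labels = simulate_sample(
                id_panel, truth, n_ev, config.doublet_fraction)
            char_table, char_labels = simulate_sample(
                char_panel, truth, n_ev, config.doublet_fraction)
            samples.append(SampleRecord(truth.patient_id, truth.group, truth,
                                        id_table, id_labels,
                                        char_table, char_labels))
            truth_rows.append(_truth_row(truth))
            for table in (id_table, char_table):
                manifest_rows.append({
                    "sample_id": table.sample_id, "patient_id": truth.patient_id,
                    "group": truth.group,
                    "panel": table.keywords["LNASPIRE_PANEL"],
                    "kind": "sample", "marker": "",
                    "n_events": table.n_events, "seed": truth.seed})
        fmo_truth = prior_median_truth(config)
        n_fmo = fmo_events or n_ev
        for panel in (id_panel, char_panel):
            tubes: dict[str, EventTable] = {}
            markers = [c.channel_id for c in panel.channels
                       if c.role == "fluorescence" and c.channel_id != SFL_MARKER]
            for m in markers:
                tubes[m] = simulate_fmo(panel, fmo_truth, m, n_fmo)
                manifest_rows.append({
                    "sample_id": tubes[m].sample_id,
                    "patient_id": fmo_truth.patient_id, "group": config.group,
                    "panel": panel.name, "kind": "fmo", "marker": m,
                    "n_events": tubes[m].n_events, "seed": fmo_truth.seed})
            fmo[(config.group, panel.name)] = tubes

    return SampleSet(samples=samples, fmo=fmo,
                     manifest=pd.DataFrame(manifest_rows),
                     truth_table=pd.DataFrame(truth_rows))
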