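"""Hierarchical gating of lymph-node aspirate samples.

Pre-gates (singlets by FSC-A/FSC-H ratio, debris by an FSC-A floor,
viability by 7-AAD) are followed by a flat first-match-wins classifier over
FMO-anchored fluorescence thresholds and two named side-scatter cutpoints
("dim" and "bright").  The putative tumor leaf is reached by elimination:
non-hematopoietic (CD45-), epithelial (EpCAM+), high-granularity
(SSC bright), and explicitly not endothelium (CD146-) nor fibroblast (FMA-);
endothelium and fibroblast are tested *before* tumor, mirroring the
elimination logic of the assay.

"Positive" always means strictly greater than the channel's cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .fcs import EventTable
from .panels import VIABILITY_MARKER
from .transforms import DEFAULT_TRANSFORM, TransformSpec


class GatingError(ValueError):
    pass


#: classifier leaves, in precedence order (catch-all excluded)
LEAF_ORDER = (
    "endothelium", "fibroblast", "tumor", "monocyte",
    "T_CD4", "T_CD8", "T_other", "B", "neutrophil", "NK",
    "eosinophil", "dendritic",
)

#: leaves whose phenotype is an extrapolation beyond the assay's core panel
HEURISTIC_LEAVES = ("eosinophil", "dendritic")

#: the ten populations reported in the composition table
REPORTED_POPULATIONS = (
    "tumor", "T_CD4", "T_CD8", "B", "NK", "neutrophil",
    "monocyte", "dendritic", "fibroblast", "endothelium",
)

GATED_CHANNELS = ("CD45", "CD3", "CD4", "CD8", "CD19", "CD16", "CD64",
                  "HLA-DR", "CD146", "FMA", "EpCAM")


def transform_events(table: EventTable,
                     spec: TransformSpec = DEFAULT_TRANSFORM) -> np.ndarray:
    """Apply the fluorescence transform; scatter channels stay linear."""
    out = table.values.copy()
    for j, ch in enumerate(table.panel.channels):
        if ch.role != "scatter":
            out[:, j] = spec.forward(out[:, j])
    return out


def singlet_gate(table: EventTable, r_lo: float = 0.75,
                 r_hi: float = 1.35) -> np.ndarray:
    """Keep events whose FSC-A/FSC-H ratio is single-cell-like."""
    try:
        a = table.column("FSC-A")
        h = table.column("FSC-H")
    except KeyError as exc:
        raise GatingError(f"singlet gate needs FSC-A and FSC-H: {exc}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(h > 0, a / np.where(h > 0, h, 1.0), np.inf)
    return (ratio >= r_lo) & (ratio <= r_hi)


def debris_gate(table: EventTable, fsc_floor: float = 25_000.0) -> np.ndarray:
    """Exclude very-low-forward-scatter events (debris)."""
    try:
        a = table.column("FSC-A")
    except KeyError as exc:
        raise GatingError(f"debris gate needs FSC-A: {exc}")
    return a >= fsc_floor


def viability_gate(table: EventTable, threshold_7aad: float = 2.5,
                   spec: TransformSpec = DEFAULT_TRANSFORM) -> np.ndarray:
    """Keep 7-AAD-low (live) events; threshold on the transformed scale."""
    try:
        v = table.column(VIABILITY_MARKER)
    except KeyError as exc:
        raise GatingError(f"viability gate needs a 7-AAD channel: {exc}")
    return spec.forward(v) <= threshold_7aad


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel positivity cutoffs on the transformed scale."""

    cutoffs: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)
    transform: TransformSpec = DEFAULT_TRANSFORM

    def __getitem__(self, channel: str) -> float:
        try:
            return self.cutoffs[channel]
        except KeyError:
            raise GatingError(f"no positivity threshold for channel {channel!r}")

    def __contains__(self, channel: str) -> bool:
        return channel in self.cutoffs


def derive_thresholds(fmo_tables: dict[str, EventTable], q: float = 0.995,
                      spec: TransformSpec = DEFAULT_TRANSFORM,
                      fixed: dict[str, float] | None = None) -> ThresholdSet:
    """Positivity cutoffs from FMO controls.

    The cutoff of a channel is the ``q``-quantile of that channel's
    transformed values in the tube where its antibody was omitted, i.e. the
    upper envelope of background plus autofluorescence.
    """
    if not 0.5 < q < 1.0:
        raise GatingError(f"FMO quantile q={q} outside the allowed (0.5, 1)")
    cutoffs: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for marker, table in fmo_tables.items():
        if table.n_events == 0:
            raise GatingError(f"FMO table for {marker!r} is empty")
        vals = spec.forward(table.column(marker))
        cutoffs[marker] = float(np.quantile(vals, q))
        provenance[marker] = f"fmo_quantile {q}"
    for marker, cut in (fixed or {}).items():
        cutoffs.setdefault(marker, float(cut))
        provenance.setdefault(marker, "fixed")
    return ThresholdSet(cutoffs, provenance, spec)


@dataclass(frozen=True)
class ScatterCutpoints:
    """Named linear side-scatter cutpoints.

    Defaults follow the documented rule: ``ssc_dim`` at the lymphocyte SSC
    99th percentile and ``ssc_bright`` at the neutrophil SSC 5th percentile
    of the default generator; ``ssc_mono_hi`` bounds the monocyte
    intermediate band, ``ssc_tumor_hi`` is the high cut used by the reduced
    characterization-tube tumor gate, ``cd45_dim_hi`` (transformed scale)
    closes the fibroblast CD45-dim band.
    """

    ssc_dim: float = 41_000.0
    ssc_bright: float = 39_000.0
    ssc_mono_hi: float = 75_000.0
    ssc_tumor_hi: float = 75_000.0
    cd45_dim_hi: float = 4.18


@dataclass(frozen=True)
class GateNode:
    """One leaf: a conjunction of atomic (channel, relation, bound) tests."""

    name: str
    conditions: tuple[tuple[str, str, float], ...]
    parent: str = "root"
    heuristic: bool = False

    def evaluate(self, matrix: np.ndarray, colmap: dict[str, int]) -> np.ndarray:
        mask = np.ones(len(matrix), dtype=bool)
        for channel, op, bound in self.conditions:
            if channel not in colmap:
                raise GatingError(
                    f"gate {self.name!r} references channel {channel!r} "
                    "absent from the panel")
            col = matrix[:, colmap[channel]]
            mask &= (col > bound) if op == ">" else (col <= bound)
        return mask


@dataclass(frozen=True)
class GatingTree:
    """Ordered first-match-wins classifier; precedence is the node order."""

    nodes: tuple[GateNode, ...]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def classify(self, matrix: np.ndarray,
                 colmap: dict[str, int]) -> np.ndarray:
        labels = np.full(len(matrix), "unclassified", dtype=object)
        unassigned = np.ones(len(matrix), dtype=bool)
        for node in self.nodes:
            hit = unassigned & node.evaluate(matrix, colmap)
            labels[hit] = node.name
            unassigned &= ~hit
        return labels

    def to_yaml(self) -> str:
        doc = [{"name": n.name, "parent": n.parent, "heuristic": n.heuristic,
                "conditions": [
                    {"channel": c, "relation": op, "bound": float(b)}
                    for c, op, b in n.conditions]}
               for n in self.nodes]
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GatingTree":
        doc = yaml.safe_load(text)
        nodes = tuple(
            GateNode(d["name"],
                     tuple((c["channel"], c["relation"], float(c["bound"]))
                           for c in d["conditions"]),
                     d.get("parent", "root"), d.get("heuristic", False))
            for d in doc)
        return cls(nodes)


def build_ln_gating_tree(thresholds: ThresholdSet,
                         cutpoints: ScatterCutpoints = ScatterCutpoints(),
                         ) -> GatingTree:
    """The lymph-node population classifier.

    Precedence (first match wins): endothelium and fibroblast are tested
    before the tumor leaf (tumor is defined by elimination); monocytes
    (marker-anchored) precede the lymphoid branches; CD3+ branches precede
    CD19/CD16 branches; neutrophils precede NK so granulocytes straddling
    the dim cut are not absorbed by the NK leaf.
    """
    for ch in GATED_CHANNELS:
        if ch not in thresholds:
            raise GatingError(f"missing threshold for channel {ch!r}")
    t = thresholds
    cp = cutpoints
    nodes = (
        GateNode("endothelium", (("CD45", "<=", t["CD45"]),
                                 ("CD146", ">", t["CD146"]))),
        GateNode("fibroblast", (("CD45", ">", t["CD45"]),
                                ("CD45", "<=", cp.cd45_dim_hi),
                                ("FMA", ">", t["FMA"]))),
        GateNode("tumor", (("CD45", "<=", t["CD45"]),
                           ("EpCAM", ">", t["EpCAM"]),
                           ("SSC-A", ">", cp.ssc_bright),
                           ("CD146", "<=", t["CD146"]),
                           ("FMA", "<=", t["FMA"]))),
        GateNode("monocyte", (("CD45", ">", t["CD45"]),
                              ("CD64", ">", t["CD64"]),
                              ("HLA-DR", ">", t["HLA-DR"]),
                              ("SSC-A", ">", cp.ssc_dim),
                              ("SSC-A", "<=", cp.ssc_mono_hi))),
        GateNode("T_CD4", (("CD45", ">", t["CD45"]), ("CD3", ">", t["CD3"]),
                           ("SSC-A", "<=", cp.ssc_dim),
                           ("CD4", ">", t["CD4"]))),
        GateNode("T_CD8", (("CD45", ">", t["CD45"]), ("CD3", ">", t["CD3"]),
                           ("SSC-A", "<=", cp.ssc_dim),
                           ("CD8", ">", t["CD8"]))),
        GateNode("T_other", (("CD45", ">", t["CD45"]), ("CD3", ">", t["CD3"]),
                             ("SSC-A", "<=", cp.ssc_dim))),
        GateNode("B", (("CD45", ">", t["CD45"]), ("CD3", "<=", t["CD3"]),
                       ("CD19", ">", t["CD19"]),
                       ("SSC-A", "<=", cp.ssc_dim))),
        GateNode("neutrophil", (("CD45", ">", t["CD45"]),
                                ("CD3", "<=", t["CD3"]),
                                ("SSC-A", ">", cp.ssc_bright),
                                ("CD16", ">", t["CD16"]))),
        GateNode("NK", (("CD45", ">", t["CD45"]), ("CD3", "<=", t["CD3"]),
                        ("SSC-A", "<=", cp.ssc_dim),
                        ("CD16", ">", t["CD16"]))),
        GateNode("eosinophil", (("CD45", ">", t["CD45"]),
                                ("CD3", "<=", t["CD3"]),
                                ("SSC-A", ">", cp.ssc_bright),
                                ("CD16", "<=", t["CD16"])), heuristic=True),
        GateNode("dendritic", (("CD45", ">", t["CD45"]),
                               ("HLA-DR", ">", t["HLA-DR"]),
                               ("CD64", "<=", t["CD64"]),
                               ("CD3", "<=", t["CD3"]),
                               ("CD19", "<=", t["CD19"]),
                               ("CD16", "<=", t["CD16"])), heuristic=True),
    )
    return GatingTree(nodes)


def characterization_tumor_gate(thresholds: ThresholdSet,
                                cutpoints: ScatterCutpoints = ScatterCutpoints(),
                                ) -> GatingTree:
    """Reduced tumor gate for the characterization tube.

    CD45- and very high side scatter; EpCAM is deliberately *not* part of
    this gate because it is a profiled readout in this tube.
    """
    return GatingTree((
        GateNode("tumor", (("CD45", "<=", thresholds["CD45"]),
                           ("SSC-A", ">", cutpoints.ssc_tumor_hi))),
    ))


@dataclass
class PopulationResult:
    """Percent composition of one sample over viable singlet events."""

    sample_id: str
    counts: dict[str, int]
    denominator: int
    viability_percent: float
    heuristic_leaves: tuple[str, ...] = HEURISTIC_LEAVES

    @property
    def percentages(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * c / self.denominator for k, c in self.counts.items()}

    @property
    def tumor_event_count(self) -> int:
        return self.counts.get("tumor", 0)

    def to_row(self) -> dict[str, float]:
        row = {"sample_id": self.sample_id,
               "all_cells_events": self.denominator,
               "tumor_events": self.tumor_event_count,
               "viability_pct": self.viability_percent}
        for k, v in self.percentages.items():
            row[f"{k}_pct"] = v
        return row


@dataclass
class ClassificationResult:
    labels: np.ndarray          # full event length; "" for pre-gated-out events
    viable_singlet_mask: np.ndarray
    population: PopulationResult


def classify_events(table: EventTable, tree: GatingTree,
                    spec: TransformSpec = DEFAULT_TRANSFORM,
                    viability_threshold: float = 2.5,
                    fsc_floor: float = 25_000.0,
                    min_events: int = 500) -> ClassificationResult:
    """Run pre-gates then the population classifier on one sample.

    The composition denominator ("% of all cells") is always the viable
    singlet non-debris event count.  Samples with fewer than ``min_events``
    viable singlets are refused.
    """
    singlets = singlet_gate(table)
    intact = singlets & debris_gate(table, fsc_floor)
    live = viability_gate(table, viability_threshold, spec)
    viable = intact & live
    viability_pct = (100.0 * (intact & live).sum() / intact.sum()
                     if intact.sum() else 0.0)
    n_viable = int(viable.sum())
    if n_viable < min_events:
        raise GatingError(
            f"sample {table.sample_id!r} has only {n_viable} viable singlet "
            f"events (minimum {min_events})")

    matrix = transform_events(table, spec)
    colmap = {c.channel_id: j for j, c in enumerate(table.panel.channels)}
    leaf = tree.classify(matrix[viable], colmap)

    labels = np.full(table.n_events, "", dtype=object)
    labels[viable] = leaf
    counts = {name: int((leaf == name).sum())
              for name in tree.leaf_names + ["unclassified"]}
    result = PopulationResult(table.sample_id, counts, n_viable, viability_pct)
    return ClassificationResult(labels, viable, result)
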