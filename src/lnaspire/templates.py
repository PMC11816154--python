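"""Per-population emission models for the synthetic event generator.

Every population emits, per channel, either a scatter normal (linear scale)
or one of three fluorescence components defined on the arcsinh scale and
inverse-transformed to linear channel values:

* ``neg`` — unstained/autofluorescence background,
* ``pos`` — stained, well separated from background,
* ``dim`` — intermediate (used for the fibroblast CD45-dim phenotype).

Scatter and SFL locations of neutrophils and lymphocytes are
group-conditional (NSCLC vs SCLC): the templates encode the biological
differences the assay is meant to resolve, with locations chosen by
inverting the virtual analyzer's frozen channel calibration at the group
medians the instrument reports (see docs/methods.md).  All other constants
are desk-scale choices of a plausible DxFLEX-like channel range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panels import CHAR_ANTIGENS

#: fluorescence components on the transformed (arcsinh, cofactor 150) scale
FLUOR_COMPONENTS: dict[str, tuple[float, float]] = {
    "neg": (0.9, 0.35),
    "pos": (5.0, 0.5),
    "dim": (3.0, 0.35),
}

#: populations that survive the viability/debris pre-gates
VIABLE_POPULATIONS = (
    "tumor", "T_CD4", "T_CD8", "B", "NK", "neutrophil",
    "eosinophil", "monocyte", "dendritic", "fibroblast", "endothelium",
)

ALL_POPULATIONS = VIABLE_POPULATIONS + ("debris", "dead")

LYMPHOCYTE_POPULATIONS = ("T_CD4", "T_CD8", "T_other", "B", "NK")


@dataclass(frozen=True)
class ScatterModel:
    """Normal location/spread (linear units) for FSC-A, SSC-A and SFL."""

    fsc: tuple[float, float]
    ssc: tuple[float, float]
    sfl: tuple[float, float]

    def __post_init__(self) -> None:
        for loc, sd in (self.fsc, self.ssc, self.sfl):
            if sd <= 0:
                raise ValueError("scatter spreads must be strictly positive")


@dataclass(frozen=True)
class PopulationTemplate:
    """Emission model of one population for one group.

    ``markers`` maps marker name -> component name; markers absent from the
    map are emitted from the negative component.  ``heterogeneous`` marks
    markers whose positivity is Bernoulli per event with the patient's true
    antigen-positive fraction (characterization-tube antigens on tumor
    cells).
    """

    name: str
    scatter: ScatterModel
    markers: dict[str, str] = field(default_factory=dict)
    heterogeneous: tuple[str, ...] = ()
    dead: bool = False

    def component_for(self, marker: str) -> str:
        comp = self.markers.get(marker, "neg")
        if comp not in FLUOR_COMPONENTS:
            raise ValueError(f"unknown component {comp!r} for marker {marker!r}")
        return comp


# lymphocyte / neutrophil scatter locations, inverted from the analyzer
# calibration at the group positional medians (NE-SSC, NE-SFL, NE-FSC on
# neutrophils; LY-X, LY-Y on lymphocytes)
_LYMPH_SSC = {"NSCLC": 29960.0, "SCLC": 34400.0}
_LYMPH_SFL = {"NSCLC": 12200.0, "SCLC": 10925.0}
_NEUT_SSC = {"NSCLC": 56640.0, "SCLC": 44040.0}
_NEUT_SFL = {"NSCLC": 10225.0, "SCLC": 10775.0}
_NEUT_FSC = {"NSCLC": 110800.0, "SCLC": 98000.0}


def _scatter_table(group: str) -> dict[str, ScatterModel]:
    ly_ssc = (_LYMPH_SSC[group], 2500.0)
    ly_sfl = (_LYMPH_SFL[group], 1500.0)
    return {
        "T_CD4": ScatterModel((70000, 8000), ly_ssc, ly_sfl),
        "T_CD8": ScatterModel((70000, 8000), ly_ssc, ly_sfl),
        "B": ScatterModel((70000, 8000), ly_ssc, ly_sfl),
        "NK": ScatterModel((75000, 8000), ly_ssc, ly_sfl),
        "dendritic": ScatterModel((85000, 9000), (34000, 2500), (14000, 2000)),
        "monocyte": ScatterModel((120000, 12000), (52000, 3000), (15000, 2000)),
        "neutrophil": ScatterModel(
            (_NEUT_FSC[group], 10000.0), (_NEUT_SSC[group], 3000.0),
            (_NEUT_SFL[group], 1500.0)),
        "eosinophil": ScatterModel((105000, 10000), (70000, 4000), (11000, 1500)),
        # stromal cells carry more RNA than resting granulocytes: higher SFL
        "fibroblast": ScatterModel((130000, 15000), (60000, 5000), (17000, 2000)),
        "endothelium": ScatterModel((125000, 15000), (45000, 4000), (17000, 2000)),
        "tumor": ScatterModel((170000, 20000), (120000, 12000), (45000, 8000)),
        "debris": ScatterModel((8000, 3000), (5000, 2000), (1000, 500)),
        # dying cells bind the nucleic-acid dye strongly: high SFL
        "dead": ScatterModel((60000, 10000), (28000, 4000), (20000, 2500)),
    }


# identification-tube marker components; everything unlisted is negative.
# Tumor events are emitted EpCAM-positive in this tube: EpCAM is the gate
# marker here, while its per-patient positive fraction applies to the
# characterization tube where it is a profiled readout.
_ID_MARKER_MAP: dict[str, dict[str, str]] = {
    "T_CD4": {"CD45": "pos", "CD3": "pos", "CD4": "pos"},
    "T_CD8": {"CD45": "pos", "CD3": "pos", "CD8": "pos"},
    "B": {"CD45": "pos", "CD19": "pos", "HLA-DR": "pos"},
    "NK": {"CD45": "pos", "CD16": "pos"},
    "neutrophil": {"CD45": "pos", "CD16": "pos"},
    "eosinophil": {"CD45": "pos"},
    "monocyte": {"CD45": "pos", "CD64": "pos", "HLA-DR": "pos"},
    "dendritic": {"CD45": "pos", "HLA-DR": "pos"},
    "fibroblast": {"CD45": "dim", "FMA": "pos"},
    "endothelium": {"CD146": "pos"},
    "tumor": {"EpCAM": "pos"},
    "debris": {},
    "dead": {"CD45": "pos"},
}

# characterization-tube components for non-tumor populations (antigen
# program of tumor cells is heterogeneous, driven by PatientTruth)
_CHAR_MARKER_MAP: dict[str, dict[str, str]] = {
    "B": {"CD45": "pos", "HLA-DR": "pos"},
    "monocyte": {"CD45": "pos", "HLA-DR": "pos"},
    "dendritic": {"CD45": "pos", "HLA-DR": "pos"},
    "T_CD4": {"CD45": "pos"},
    "T_CD8": {"CD45": "pos"},
    "NK": {"CD45": "pos"},
    "neutrophil": {"CD45": "pos"},
    "eosinophil": {"CD45": "pos"},
    "fibroblast": {"CD45": "dim", "CD90": "pos"},
    "endothelium": {},
    "tumor": {},
    "debris": {},
    "dead": {"CD45": "pos"},
}


def default_templates(group: str, panel_name: str) -> dict[str, PopulationTemplate]:
    """The frozen per-population emission models for one group and tube."""
    if group not in ("NSCLC", "SCLC"):
        raise ValueError(f"unknown group {group!r}")
    scatter = _scatter_table(group)
    out: dict[str, PopulationTemplate] = {}
    for pop in ALL_POPULATIONS:
        if panel_name == "identification":
            markers = dict(_ID_MARKER_MAP[pop])
            het: tuple[str, ...] = ()
        elif panel_name == "characterization":
            markers = dict(_CHAR_MARKER_MAP[pop])
            het = CHAR_ANTIGENS if pop == "tumor" else ()
        else:
            raise ValueError(f"unknown panel {panel_name!r}")
        out[pop] = PopulationTemplate(
            name=pop, scatter=scatter[pop], markers=markers,
            heterogeneous=het, dead=(pop == "dead"))
    return out
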