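"""Antibody panel definitions for the two-tube lymph-node aspirate assay.

The identification tube establishes the hierarchical gate (hematopoietic
lineages, endothelium, fibroblasts and the CD45- EpCAM+ tumor gate); the
characterization tube carries the 16-antigen tumor profile.  Both tubes
share the three scatter channels.  A synthetic nucleic-acid-dye channel
(``SFL``) rides on the identification tube so that the same event stream can
feed the virtual hematology analyzer.
"""

from __future__ import annotations

from dataclasses import dataclass, field


SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

#: markers gated in the identification tube (all have FMO controls)
ID_MARKERS = (
    "CD64", "FMA", "CD146", "CD19", "CD3", "CD8",
    "EpCAM", "CD16", "HLA-DR", "CD45", "CD4",
)

#: the 16 antigens profiled on the tumor gate
CHAR_ANTIGENS = (
    "EpCAM", "MUC-1", "TTF-1", "Ki67", "cytokeratin", "CD56",
    "CD38", "HLA-DR", "HER-2", "CD39", "CD73", "CD90",
    "CD184", "PD-L1", "PD-L2", "CTLA-4",
)

VIABILITY_MARKER = "7-AAD"
SFL_MARKER = "SFL"


@dataclass(frozen=True)
class ChannelDef:
    """One detector of a panel.

    ``detector_name`` maps to the FCS $PnN keyword, ``marker_name`` to $PnS
    (empty for unstained detectors).  ``role`` is one of ``scatter``,
    ``fluorescence`` or ``viability``.
    """

    channel_id: str
    detector_name: str
    marker_name: str = ""
    role: str = "fluorescence"

    def __post_init__(self) -> None:
        if self.role not in ("scatter", "fluorescence", "viability"):
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass(frozen=True)
class Panel:
    """Ordered channel list for one staining tube."""

    name: str
    channels: tuple[ChannelDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate channel_id in panel {self.name!r}")
        markers = [c.marker_name for c in self.channels if c.marker_name]
        if len(markers) != len(set(markers)):
            raise ValueError(f"duplicate marker names in panel {self.name!r}")
        for sc in SCATTER_CHANNELS:
            if sc not in ids:
                raise ValueError(f"panel {self.name!r} missing scatter channel {sc}")

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def markers(self) -> list[str]:
        return [c.marker_name for c in self.channels if c.marker_name]

    def index_of(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(f"channel {channel_id!r} not in panel {self.name!r}")

    def channel(self, channel_id: str) -> ChannelDef:
        return self.channels[self.index_of(channel_id)]

    def fluorescence_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels if c.role != "scatter"]


def _scatter_defs() -> list[ChannelDef]:
    return [ChannelDef(sc, sc, "", "scatter") for sc in SCATTER_CHANNELS]


def identification_panel(include_sfl: bool = True) -> Panel:
    """The 13-color identification tube (plus viability dye and, optionally,
    the synthetic analyzer SFL channel)."""
    chans = _scatter_defs()
    for i, m in enumerate(ID_MARKERS, start=1):
        chans.append(ChannelDef(m, f"FL{i}-A", m, "fluorescence"))
    chans.append(ChannelDef(VIABILITY_MARKER, "FL12-A", VIABILITY_MARKER, "viability"))
    if include_sfl:
        chans.append(ChannelDef(SFL_MARKER, "SFL-A", SFL_MARKER, "fluorescence"))
    return Panel("identification", tuple(chans))


def characterization_panel() -> Panel:
    """The 16-antigen characterization tube.

    CD45 and 7-AAD are carried alongside the 16 antigens so the tube can be
    pre-gated and tumor-gated on its own (the reduced tumor gate of this tube
    deliberately omits EpCAM, which is a profiled readout here).
    """
    chans = _scatter_defs()
    for i, m in enumerate(CHAR_ANTIGENS, start=1):
        chans.append(ChannelDef(m, f"FL{i}-A", m, "fluorescence"))
    chans.append(ChannelDef("CD45", "FL17-A", "CD45", "fluorescence"))
    chans.append(ChannelDef(VIABILITY_MARKER, "FL18-A", VIABILITY_MARKER, "viability"))
    return Panel("characterization", tuple(chans))


def get_panel(name: str) -> Panel:
    if name == "identification":
        return identification_panel()
    if name == "characterization":
        return characterization_panel()
    raise ValueError(f"unknown panel {name!r}")
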