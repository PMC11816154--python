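"""Antigen expression profile of the gated tumor population.

Two readouts per antigen over tumor-gated events of the characterization
tube: percent positive against the FMO-anchored cutoff, and geometric mean
fluorescence (GMF) of the linear channel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcs import EventTable
from .gating import ThresholdSet
from .panels import CHAR_ANTIGENS
from .transforms import DEFAULT_TRANSFORM, TransformSpec


class ProfileError(ValueError):
    pass


def percent_positive(values, cutoff: float,
                     spec: TransformSpec = DEFAULT_TRANSFORM) -> float:
    """Percent of linear ``values`` whose transformed value strictly exceeds
    ``cutoff`` (a transformed-scale threshold)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ProfileError("percent_positive of an empty gate is undefined "
                           "(no tumor cells gated is not the same as 0%)")
    return float(100.0 * np.mean(spec.forward(values) > cutoff))


def gmf(values, floor: float = 1.0) -> float:
    """Geometric mean fluorescence: exp(mean(ln(max(v, floor)))).

    The floor (default one linear unit) keeps logs defined for near-zero or
    negative baseline-restored values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ProfileError("GMF of an empty gate is undefined")
    return float(np.exp(np.mean(np.log(np.maximum(values, floor)))))


@dataclass
class AntigenProfile:
    """16-antigen profile of one sample's tumor gate.

    ``evaluable`` is False when no tumor events were gated; the per-antigen
    maps are then empty rather than silently zero.
    """

    sample_id: str
    tumor_event_count: int
    percent: dict[str, float] = field(default_factory=dict)
    gmf: dict[str, float] = field(default_factory=dict)
    evaluable: bool = True

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"sample_id": self.sample_id,
                                 "tumor_events": self.tumor_event_count}
        for a in self.percent:
            row[f"{a}_pct"] = self.percent[a]
            row[f"{a}_gmf"] = self.gmf[a]
        return row


def profile_tumor_cells(table: EventTable, labels: np.ndarray,
                        thresholds: ThresholdSet,
                        antigens: tuple[str, ...] = CHAR_ANTIGENS,
                        gmf_floor: float = 1.0,
                        spec: TransformSpec = DEFAULT_TRANSFORM,
                        ) -> AntigenProfile:
    """Profile every antigen over tumor-labeled events of one sample.

    ``labels`` is the per-event label vector aligned with ``table`` (from
    the gating stage or from generator truth).
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != table.n_events:
        raise ProfileError("labels are not aligned with the event table")
    tumor = labels == "tumor"
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        return AntigenProfile(table.sample_id, 0, {}, {}, evaluable=False)
    profile = AntigenProfile(table.sample_id, n_tumor)
    for a in antigens:
        vals = table.column(a)[tumor]
        profile.percent[a] = percent_positive(vals, thresholds[a], spec)
        profile.gmf[a] = gmf(vals, gmf_floor)
    return profile
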