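"""Virtual hematology-analyzer readouts (WDF-style research parameters).

A fluorescence hematology analyzer classifies nucleated cells on three axes:
forward scatter (volume), side scatter (granularity/complexity) and side
fluorescence (SFL, nucleic-acid dye binding, i.e. metabolic activity).  The
module maps event data onto 0-255 "channel" axes with frozen affine
constants and reports the positional research parameters:

* NE-SSC / NE-SFL / NE-FSC (aliases NEUT-GI / NEUT-RI for the first two) —
  medians of the neutrophil cluster on the SSC / SFL / FSC axes,
* LY-X / LY-Y — medians of the lymphocyte cluster on the SSC / SFL axes,
* the high-fluorescence (HF) cell cloud: events high on the SFL axis,
  flagged as metabolically hyperactive (putative malignant) cells,
* the white-blood-cell concentration of the aspirate.

Cluster membership comes from gating labels when available ("simulation
mode"); a deterministic rectangular partition of the SSC x SFL plane serves
as the blind fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcs import EventTable
from .panels import SFL_MARKER
from .templates import LYMPHOCYTE_POPULATIONS


class AnalyzerError(ValueError):
    pass


@dataclass(frozen=True)
class WdfCalibration:
    """Frozen affine maps (slope, intercept) from linear channel values to
    the 0-255 WDF axes; values are clipped to the axis range."""

    ssc: tuple[float, float] = (1.0 / 400.0, 9.0)
    sfl: tuple[float, float] = (1.0 / 250.0, 5.0)
    fsc: tuple[float, float] = (1.0 / 2000.0, 17.0)
    ch_max: float = 255.0


DEFAULT_CALIBRATION = WdfCalibration()

#: blind-mode rectangles on the (SSC, SFL) channel plane; the neutrophil
#: box has a tighter SFL ceiling so monocytes and stromal cells (which sit
#: a little higher on the fluorescence axis) stay out of it
_BLIND_LYMPH = {"ssc": (0.0, 105.0), "sfl": (0.0, 70.0)}
_BLIND_NEUT = {"ssc": (105.0, 200.0), "sfl": (0.0, 53.0)}


def map_wdf_channels(table: EventTable,
                     calib: WdfCalibration = DEFAULT_CALIBRATION,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-event (SSC, SFL, FSC) on the 0-255 channel axes."""
    try:
        ssc = table.column("SSC-A")
        sfl = table.column(SFL_MARKER)
        fsc = table.column("FSC-A")
    except KeyError as exc:
        raise AnalyzerError(f"analyzer mode needs SSC-A, SFL and FSC-A: {exc}")

    def apply(x, ab):
        a, b = ab
        return np.clip(a * x + b, 0.0, calib.ch_max)

    return apply(ssc, calib.ssc), apply(sfl, calib.sfl), apply(fsc, calib.fsc)


@dataclass
class AnalyzerResult:
    """Positional parameters and HF-cloud statistics of one sample."""

    sample_id: str
    ne_ssc: float | None = None
    ne_sfl: float | None = None
    ne_fsc: float | None = None
    ly_x: float | None = None
    ly_y: float | None = None
    wbc_per_ul: float | None = None
    hf_fraction: float = 0.0
    hf_flag: bool = False
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def neut_gi(self) -> float | None:  # Sysmex alias for NE-SSC
        return self.ne_ssc

    @property
    def neut_ri(self) -> float | None:  # Sysmex alias for NE-SFL
        return self.ne_sfl

    def to_row(self) -> dict:
        return {"sample_id": self.sample_id, "NE-SSC": self.ne_ssc,
                "NE-SFL": self.ne_sfl, "NE-FSC": self.ne_fsc,
                "LY-X": self.ly_x, "LY-Y": self.ly_y,
                "WBC_per_ul": self.wbc_per_ul,
                "HF_fraction": self.hf_fraction, "HF_flag": self.hf_flag}


def _blind_clusters(ssc_ch: np.ndarray, sfl_ch: np.ndarray,
                    intact: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    def rect(r):
        return (intact
                & (ssc_ch > r["ssc"][0]) & (ssc_ch <= r["ssc"][1])
                & (sfl_ch > r["sfl"][0]) & (sfl_ch <= r["sfl"][1]))
    return rect(_BLIND_NEUT), rect(_BLIND_LYMPH)


def positional_parameters(table: EventTable, labels: np.ndarray | None = None,
                          calib: WdfCalibration = DEFAULT_CALIBRATION,
                          min_cluster: int = 50,
                          fsc_floor: float = 25_000.0,
                          sampled_volume_ul: float | None = None,
                          ) -> AnalyzerResult:
    """Compute the positional medians of one sample.

    With ``labels`` (simulation mode) the neutrophil/lymphocyte clusters are
    the correspondingly labeled events; blind mode uses the fixed
    rectangular partition.  Clusters with fewer than ``min_cluster`` events
    report their parameters as missing with a reason code.
    """
    ssc_ch, sfl_ch, fsc_ch = map_wdf_channels(table, calib)
    result = AnalyzerResult(table.sample_id)
    intact = table.column("FSC-A") >= fsc_floor

    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        neut = labels == "neutrophil"
        lymph = np.isin(labels, LYMPHOCYTE_POPULATIONS)
    else:
        neut, lymph = _blind_clusters(ssc_ch, sfl_ch, intact)

    if neut.sum() >= min_cluster:
        result.ne_ssc = float(np.median(ssc_ch[neut]))
        result.ne_sfl = float(np.median(sfl_ch[neut]))
        result.ne_fsc = float(np.median(fsc_ch[neut]))
    else:
        result.reasons["neutrophil"] = (
            f"only {int(neut.sum())} neutrophil events (< {min_cluster})")
    if lymph.sum() >= min_cluster:
        result.ly_x = float(np.median(ssc_ch[lymph]))
        result.ly_y = float(np.median(sfl_ch[lymph]))
    else:
        result.reasons["lymphocyte"] = (
            f"only {int(lymph.sum())} lymphocyte events (< {min_cluster})")

    result.hf_fraction, result.hf_flag = detect_hf_cloud(table, calib=calib,
                                                         fsc_floor=fsc_floor)
    vol = sampled_volume_ul
    if vol is None and "LNASPIRE_VOL_UL" in table.keywords:
        vol = float(table.keywords["LNASPIRE_VOL_UL"])
    if vol is not None:
        result.wbc_per_ul = wbc_concentration(int(intact.sum()), vol)
    return result


def detect_hf_cloud(table: EventTable, sfl_cut: float = 70.0,
                    flag_threshold: float = 0.05,
                    calib: WdfCalibration = DEFAULT_CALIBRATION,
                    fsc_floor: float = 25_000.0) -> tuple[float, bool]:
    """Fraction of non-debris events in the high-SFL cloud, and its flag.

    ``sfl_cut`` defaults to the 99th percentile of normal leukocyte SFL on
    the channel axis; fraction is monotone non-increasing in the cut.
    """
    _, sfl_ch, _ = map_wdf_channels(table, calib)
    intact = table.column("FSC-A") >= fsc_floor
    if intact.sum() == 0:
        return 0.0, False
    frac = float(np.mean(sfl_ch[intact] > sfl_cut))
    return frac, frac >= flag_threshold


def wbc_concentration(n_viable_events: int, sampled_volume_ul: float) -> float:
    """Cell concentration (cells/uL) from an event count and aspirate volume."""
    if sampled_volume_ul <= 0:
        raise AnalyzerError("sampled volume must be positive")
    return n_viable_events / sampled_volume_ul


def plot_scattergram(table: EventTable, path,
                     calib: WdfCalibration = DEFAULT_CALIBRATION,
                     sfl_cut: float = 70.0) -> str:
    """SSC x SFL scattergram with the HF cut line (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ssc_ch, sfl_ch, _ = map_wdf_channels(table, calib)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ssc_ch, sfl_ch, s=1, alpha=0.2, rasterized=True)
    ax.axhline(sfl_cut, color="red", lw=0.8, ls="--", label="HF cut")
    ax.set_xlim(0, calib.ch_max)
    ax.set_ylim(0, calib.ch_max)
    ax.set_xlabel("SSC [ch]")
    ax.set_ylabel("SFL [ch]")
    ax.set_title(table.sample_id)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
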