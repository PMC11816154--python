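"""Minimal FCS 3.1 list-mode reading/writing and CSV export.

Scope is deliberately small: single-dataset files, $MODE=L, little-endian,
$DATATYPE F (what this package writes) plus D and uniform-width I on read.
Values are stored linear; $PnE is always ``0,0`` and transforms are applied
downstream, never baked into files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .panels import ChannelDef, Panel, VIABILITY_MARKER


class FcsError(ValueError):
    """Malformed or unsupported FCS content."""


@dataclass
class EventTable:
    """Per-sample event matrix (events x channels, linear float)."""

    sample_id: str
    panel: Panel
    values: np.ndarray
    keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.panel.channels):
            raise ValueError(
                f"value matrix has {self.values.shape[1]} columns but panel "
                f"{self.panel.name!r} defines {len(self.panel.channels)} channels")

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    def column(self, channel_id: str) -> np.ndarray:
        return self.values[:, self.panel.index_of(channel_id)]


_REQUIRED_KEYWORDS = (
    "$BEGINDATA", "$ENDDATA", "$PAR", "$TOT", "$BYTEORD", "$DATATYPE", "$MODE")


def _text_segment(pairs: list[tuple[str, str]], delim: str = "/") -> bytes:
    parts = [delim]
    for k, v in pairs:
        parts.append(k)
        parts.append(delim)
        parts.append(str(v))
        parts.append(delim)
    return "".join(parts).encode("utf-8")


def write_fcs(table: EventTable, path: str | os.PathLike) -> str:
    """Write ``table`` as a single-dataset FCS 3.1 file (float32, LE)."""
    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()
    n_events, n_par = table.values.shape

    def build_text(begin_data: int, end_data: int) -> bytes:
        pairs: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data)),
            ("$NEXTDATA", "0"),
            ("$MODE", "L"), ("$DATATYPE", "F"), ("$BYTEORD", "1,2,3,4"),
            ("$PAR", str(n_par)), ("$TOT", str(n_events)),
        ]
        for i, ch in enumerate(table.panel.channels, start=1):
            pairs.append((f"$P{i}N", ch.detector_name))
            if ch.marker_name:
                pairs.append((f"$P{i}S", ch.marker_name))
            pairs.append((f"$P{i}B", "32"))
            pairs.append((f"$P{i}E", "0,0"))
            pairs.append((f"$P{i}R", "262144"))
        for k, v in table.keywords.items():
            if not k.startswith("$"):
                pairs.append((k, v))
        return _text_segment(pairs)

    # two passes: offsets depend on TEXT length, which depends on offsets
    begin_text = 58
    begin_data = end_data = 0
    for _ in range(3):
        text = build_text(begin_data, end_data)
        end_text = begin_text + len(text) - 1
        new_begin = end_text + 1
        new_end = new_begin + len(data) - 1 if data else 0
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = build_text(begin_data, end_data)
    end_text = begin_text + len(text) - 1

    def hdr_off(v: int) -> bytes:
        s = str(v) if v <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + hdr_off(begin_text) + hdr_off(end_text)
    header += hdr_off(begin_data if end_data <= 99999999 else 0)
    header += hdr_off(end_data if end_data <= 99999999 else 0)
    header += hdr_off(0) + hdr_off(0)  # analysis
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return str(path)


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FcsError("TEXT segment has an odd number of delimited tokens")
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def _infer_role(name: str, marker: str) -> str:
    label = marker or name
    if any(label.upper().startswith(p) for p in ("FSC", "SSC")):
        return "scatter"
    if label == VIABILITY_MARKER:
        return "viability"
    return "fluorescence"


def read_fcs(path: str | os.PathLike, sample_id: str | None = None) -> EventTable:
    """Read a single-dataset FCS 3.0/3.1 list-mode file."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FcsError("file shorter than an FCS header")
    version = blob[:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsError(f"unsupported FCS version {version!r}")
    try:
        bt, et = int(blob[10:18]), int(blob[18:26])
        bd, ed = int(blob[26:34]), int(blob[34:42])
    except ValueError as exc:
        raise FcsError("malformed HEADER byte offsets") from exc
    if not (0 < bt < et < len(blob)):
        raise FcsError("TEXT segment offsets out of range")
    kw = _parse_text(blob[bt:et + 1])

    for req in _REQUIRED_KEYWORDS:
        if req not in kw:
            raise FcsError(f"missing required keyword {req}")
    if kw.get("$NEXTDATA", "0").strip() not in ("0", ""):
        raise FcsError("multi-dataset FCS files are not supported")
    if kw["$MODE"].strip() != "L":
        raise FcsError(f"unsupported $MODE {kw['$MODE']!r} (list mode only)")

    if bd == 0 or ed == 0:  # large files put offsets in TEXT only
        bd, ed = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])

    dtype_code = kw["$DATATYPE"].strip().upper()
    byteord = kw["$BYTEORD"].strip()
    endian = "<" if byteord in ("1,2,3,4", "1,2") else ">"
    if dtype_code == "F":
        dt = np.dtype(endian + "f4")
    elif dtype_code == "D":
        dt = np.dtype(endian + "f8")
    elif dtype_code == "I":
        widths = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(widths) != 1 or widths.pop() not in (16, 32):
            raise FcsError("integer data requires a uniform $PnB of 16 or 32")
        dt = np.dtype(endian + ("u2" if int(kw["$P1B"]) == 16 else "u4"))
    else:
        raise FcsError(f"unsupported $DATATYPE {dtype_code!r}")

    expected = n_tot * n_par * dt.itemsize
    raw = blob[bd:ed + 1]
    if len(raw) < expected:
        raise FcsError(
            f"truncated DATA segment: expected {expected} bytes, found {len(raw)}")
    values = np.frombuffer(raw[:expected], dtype=dt).reshape(n_tot, n_par)

    chans = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", f"P{i}")
        marker = kw.get(f"$P{i}S", "")
        cid = marker or name
        chans.append(ChannelDef(cid, name, marker, _infer_role(name, marker)))
    panel_name = kw.get("LNASPIRE_PANEL", "unknown")
    try:
        panel = Panel(panel_name, tuple(chans))
    except ValueError:
        # files from other instruments may lack our scatter trio; keep a
        # permissive container with the same channel order
        panel = Panel.__new__(Panel)
        object.__setattr__(panel, "name", panel_name)
        object.__setattr__(panel, "channels", tuple(chans))
    sid = sample_id or kw.get("LNASPIRE_SAMPLE", os.path.basename(str(path)))
    return EventTable(sid, panel, values.astype(np.float64), dict(kw))


def write_csv(table: EventTable, path: str | os.PathLike) -> str:
    """CSV export with header ``event_index,<detector>:<marker>,...``."""
    cols = [f"{c.detector_name}:{c.marker_name}" for c in table.panel.channels]
    header = "event_index," + ",".join(cols)
    idx = np.arange(table.n_events)[:, None]
    mat = np.hstack([idx, table.values])
    np.savetxt(path, mat, delimiter=",", header=header, comments="",
               fmt=["%d"] + ["%.6g"] * len(cols))
    return str(path)
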