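"""Listmode (FCS) input/output and fluorescence-scale transforms.

Reads FCS 3.0/3.1 files (float, double, and fixed-width integer DATA
segments, either byte order), writes FCS 3.1 (float32, little-endian),
and applies the per-channel monotone transforms (arcsinh, logicle) under
which all clustering and phenotyping in this package operates.  Scatter
and time channels are never transformed.

FCS 2.0 files are rejected explicitly rather than parsed by guesswork.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import ConfigurationError, FcsFormatError

__all__ = [
    "ChannelMeta",
    "EventTable",
    "PanelConfig",
    "read_fcs",
    "write_fcs",
    "transform_fluorescence",
]

_SCATTER_PREFIXES = ("FSC", "SSC")


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one acquisition channel."""

    short_name: str          # detector label, e.g. "FL1-A" or "FSC-A"
    marker: str = ""         # antibody name ($PnS) or empty
    is_scatter: bool = False
    is_time: bool = False

    @staticmethod
    def infer(short_name: str, marker: str = "") -> "ChannelMeta":
        up = short_name.upper()
        return ChannelMeta(
            short_name=short_name,
            marker=marker,
            is_scatter=up.startswith(_SCATTER_PREFIXES),
            is_time=up == "TIME",
        )


@dataclass
class EventTable:
    """Events x channels matrix with channel metadata.

    ``values`` column order matches ``channels``.  ``transform_state`` is
    "raw" for unconverted fluorescence units and "transformed" after
    :func:`transform_fluorescence`.
    """

    values: np.ndarray
    channels: list[ChannelMeta]
    tube_id: str = ""
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("column count does not match channel list")
        if self.values.shape[0] < 1:
            raise ValueError("EventTable requires at least one event")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EventTable contains missing/non-finite values")
        markers = [c.marker for c in self.channels if c.marker]
        if len(markers) != len(set(markers)):
            raise ValueError("marker names must be unique within a tube")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels if c.marker and not c.is_scatter and not c.is_time]

    def channel_index(self, name: str) -> int:
        """Index of a channel by marker name first, then detector name."""
        for i, c in enumerate(self.channels):
            if c.marker == name:
                return i
        for i, c in enumerate(self.channels):
            if c.short_name == name:
                return i
        raise KeyError(f"channel {name!r} not found in tube {self.tube_id!r}")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def has_channel(self, name: str) -> bool:
        try:
            self.channel_index(name)
            return True
        except KeyError:
            return False

    def time_index(self) -> int:
        idx = [i for i, c in enumerate(self.channels) if c.is_time]
        if len(idx) != 1:
            raise ConfigurationError(
                f"tube {self.tube_id!r}: exactly one time channel required, found {len(idx)}"
            )
        return idx[0]

    def subset(self, mask_or_indices: np.ndarray) -> "EventTable":
        return replace(self, values=self.values[mask_or_indices])

    def fluorescence_indices(self) -> list[int]:
        return [
            i for i, c in enumerate(self.channels) if not c.is_scatter and not c.is_time
        ]

    def to_dataframe(self):
        import pandas as pd

        cols = [c.marker or c.short_name for c in self.channels]
        return pd.DataFrame(self.values, columns=cols)


@dataclass
class PanelConfig:
    """Tube -> marker mapping with the backbone present in every tube."""

    tubes: dict[str, list[str]] = field(default_factory=dict)
    backbone_markers: list[str] = field(default_factory=lambda: ["CD45"])

    def __post_init__(self) -> None:
        for tube, markers in self.tubes.items():
            missing = [m for m in self.backbone_markers if m not in markers]
            if missing:
                raise ConfigurationError(
                    f"tube {tube!r} lacks backbone markers {missing}"
                )
            if len(markers) != len(set(markers)):
                raise ConfigurationError(f"tube {tube!r} lists duplicate markers")

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            tubes={str(k): list(v) for k, v in doc["tubes"].items()},
            backbone_markers=list(doc.get("backbone_markers", ["CD45"])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"tubes": self.tubes, "backbone_markers": self.backbone_markers}, fh
            )


# ---------------------------------------------------------------------------
# FCS binary format
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FcsFormatError("TEXT segment too short")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        # trailing empty value is tolerated
        if parts and parts[-1] == b"":
            parts = parts[:-1]
        else:
            raise FcsFormatError("TEXT segment has an odd number of tokens")
    kv: dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        kv[k.decode("utf-8", "replace").strip().upper()] = v.decode("utf-8", "replace").strip()
    return kv


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable` (raw values)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 58:
        raise FcsFormatError(f"{path}: HEADER segment truncated ({len(data)} bytes)")
    version = data[:10].decode("ascii", "replace").strip()
    if version.startswith("FCS2"):
        raise FcsFormatError(
            f"{path}: FCS 2.0 is not supported (byte order and amplification "
            "are ambiguous); please convert to FCS 3.0/3.1"
        )
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unrecognized FCS version {version!r} in HEADER")

    def _hdr_int(lo: int, hi: int, what: str) -> int:
        tok = data[lo:hi].decode("ascii", "replace").strip()
        try:
            return int(tok) if tok else 0
        except ValueError as exc:
            raise FcsFormatError(f"{path}: bad {what} offset in HEADER: {tok!r}") from exc

    t0 = _hdr_int(10, 18, "TEXT start")
    t1 = _hdr_int(18, 26, "TEXT end")
    d0 = _hdr_int(26, 34, "DATA start")
    d1 = _hdr_int(34, 42, "DATA end")
    if t1 <= t0 or t1 >= len(data):
        raise FcsFormatError(f"{path}: TEXT segment offsets out of range")
    text = _parse_text_segment(data[t0 : t1 + 1])

    def _kw(name: str, required: bool = True, default: str = "") -> str:
        if name in text:
            return text[name]
        if required:
            raise FcsFormatError(f"{path}: TEXT segment missing required keyword {name}")
        return default

    tot = int(_kw("$TOT"))
    par = int(_kw("$PAR"))
    if tot == 0:
        raise FcsFormatError(f"{path}: DATA segment is empty ($TOT=0)")
    if par == 0:
        raise FcsFormatError(f"{path}: no parameters declared ($PAR=0)")
    if d0 == 0 and d1 == 0:
        d0 = int(_kw("$BEGINDATA"))
        d1 = int(_kw("$ENDDATA"))
    if d1 <= d0 or d1 >= len(data):
        raise FcsFormatError(f"{path}: DATA segment offsets out of range")
    datatype = _kw("$DATATYPE").upper()
    byteord = _kw("$BYTEORD")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FcsFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")
    mode = _kw("$MODE", required=False, default="L").upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE=L) is supported, got {mode!r}")

    bits = [int(_kw(f"$P{i}B")) for i in range(1, par + 1)]
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE=F requires $PnB=32")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
        if any(b != 64 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE=D requires $PnB=64")
    elif datatype == "I":
        width = bits[0]
        if any(b != width for b in bits) or width not in (8, 16, 32):
            raise FcsFormatError(
                f"{path}: integer DATA requires uniform $PnB in (8,16,32), got {bits}"
            )
        dtype = np.dtype(endian + f"u{width // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = data[d0 : d1 + 1]
    need = tot * par * dtype.itemsize
    if len(raw) < need:
        raise FcsFormatError(
            f"{path}: DATA segment truncated ({len(raw)} bytes, expected {need})"
        )
    values = np.frombuffer(raw[:need], dtype=dtype).reshape(tot, par).astype(float)

    channels = []
    for i in range(1, par + 1):
        name = _kw(f"$P{i}N")
        marker = _kw(f"$P{i}S", required=False)
        channels.append(ChannelMeta.infer(name, marker))
    tube_id = _kw("TUBE NAME", required=False) or _kw("$FIL", required=False)
    return EventTable(values=values, channels=channels, tube_id=tube_id, transform_state="raw")


def write_fcs(table: EventTable, path) -> None:
    """Write an :class:`EventTable` as FCS 3.1 (float32, little-endian)."""
    if table.n_events < 1:
        raise ValueError("cannot write an empty EventTable")
    n, p = table.values.shape
    payload = table.values.astype("<f4").tobytes()

    d = "/"
    kv: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%010d"),
        ("$ENDDATA", "%010d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(p)),
        ("$TOT", str(n)),
    ]
    if table.tube_id:
        kv.append(("TUBE NAME", table.tube_id))
    col_max = table.values.max(axis=0)
    for i, ch in enumerate(table.channels, start=1):
        kv.append((f"$P{i}N", ch.short_name))
        if ch.marker:
            kv.append((f"$P{i}S", ch.marker))
        kv.append((f"$P{i}B", "32"))
        kv.append((f"$P{i}E", "0,0"))
        rng = int(np.ceil(max(col_max[i - 1], 1.0))) + 1
        kv.append((f"$P{i}R", str(rng)))

    def render(begin_data: int, end_data: int) -> bytes:
        parts = []
        for k, v in kv:
            if v == "%010d":
                v = "%010d" % (begin_data if k == "$BEGINDATA" else end_data)
            parts.append(k + d + v)
        return (d + d.join(parts) + d).encode("ascii")

    text_start = 58
    text_len = len(render(0, 0))  # fixed-width placeholders -> length is stable
    data_start = text_start + text_len
    data_end = data_start + len(payload) - 1
    text = render(data_start, data_end)
    assert len(text) == text_len
    text_end = text_start + text_len - 1

    header = b"FCS3.1    " + b"".join(
        b"%8d" % v for v in (text_start, text_end, 0, 0, 0, 0)
    )
    assert len(header) == 58
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(text)
            fh.write(payload)
    except OSError as exc:
        raise OSError(f"failed writing FCS file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Fluorescence transforms
# ---------------------------------------------------------------------------

def _logicle_lut(T: float, W: float = 0.5, M: float = 4.5, A: float = 0.0,
                 n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Grid of (linear value, display value) pairs for the logicle scale.

    The biexponential S(y) = a*exp(b*y) - c*exp(-d*y) - f on y in [0, 1]
    is parameterized so that the scale is linear around zero over a region
    of width W decades and asymptotically logarithmic up to T at M decades.
    The forward transform inverts S by monotone interpolation.
    """
    b = (M + A) * np.log(10.0)
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    if w > 0:
        # d solves w*(b+d) = 2*ln(b/d); root exists in (0, b)
        g = lambda dd: w * (b + dd) - 2.0 * np.log(b / dd)
        d_par = brentq(g, 1e-12 * b, b, xtol=1e-14)
    else:
        d_par = b
    c_a = np.exp(x0 * (b + d_par))
    mf_a = np.exp(b * x1) - c_a * np.exp(-d_par * x1)
    a_par = T / (np.exp(b) - mf_a - c_a * np.exp(-d_par))
    f_a = -mf_a * a_par
    y = np.linspace(0.0, 1.0, n_grid)
    x = a_par * np.exp(b * y) - a_par * c_a * np.exp(-d_par * y) + f_a
    return x, y * M


def transform_fluorescence(
    table: EventTable,
    method: str = "arcsinh",
    cofactor: float = 150.0,
) -> EventTable:
    """Apply a monotone scale transform to fluorescence channels only.

    method "arcsinh": y = asinh(x / cofactor); "logicle": the biexponential
    display scale (cofactor ignored); "none": identity.  Scatter and time
    channels pass through unchanged.  Returns a new table with
    transform_state = "transformed".
    """
    if table.transform_state != "raw":
        raise ConfigurationError("table is already transformed")
    if cofactor <= 0:
        raise ConfigurationError("cofactor must be positive")
    values = table.values.copy()
    idx = table.fluorescence_indices()
    if method == "arcsinh":
        values[:, idx] = np.arcsinh(values[:, idx] / cofactor)
    elif method == "logicle":
        sub = values[:, idx]
        top = max(262144.0, float(sub.max()) if sub.size else 262144.0)
        lut_x, lut_y = _logicle_lut(T=top)
        values[:, idx] = np.interp(sub, lut_x, lut_y)
    elif method == "none":
        pass
    else:
        raise ConfigurationError(
            f"unknown transform method {method!r}; expected arcsinh, logicle or none"
        )
    return replace(table, values=values, transform_state="transformed")
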