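"""Event-level cytometry data containers and serialization.

The universal currency of the pipeline is the :class:`EventTable`: a
rectangular event x channel matrix of non-negative ion-count intensities,
with per-channel metadata (:class:`ChannelInfo`) and per-event annotation
columns added by the processing stages (barcode assignment, gate flags,
cluster ids, ...).

Two on-disk dialects are supported:

* a minimal FCS 3.1 float32 single-dataset file, for interoperability with
  cytometry software, and
* a delimited tabular dialect (CSV matrix plus a ``<path>.channels.csv``
  sidecar carrying marker/metal/role metadata), which is the fixture format
  used throughout the test-suite because plain text survives version control.

On write, numeric annotation columns are persisted as extra channels with
role ``other`` — the same convention the debarcoding stage uses to carry
``bc_neg`` inside the FCS file itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "EventTable",
    "FormatError",
    "read_events",
    "write_events",
]

#: valid channel roles; every channel has exactly one
ROLES = frozenset(
    {"identity", "signaling", "barcode", "bead", "intercalator", "instrument", "other"}
)


class FormatError(ValueError):
    """Raised when a file does not conform to the declared dialect."""


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one acquisition channel.

    Parameters
    ----------
    name
        Short unique channel label (e.g. ``"pERK"``, ``"Pd104"``).
    marker
        Human-readable marker name, empty for non-antibody channels.
    metal
        Isotope tag label (e.g. ``"167Er"``), empty if not applicable.
    role
        One of ``identity``, ``signaling``, ``barcode``, ``bead``,
        ``intercalator``, ``instrument`` or ``other``.
    """

    name: str
    marker: str = ""
    metal: str = ""
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {sorted(ROLES)}")


@dataclass
class EventTable:
    """Event x channel intensity matrix with channel metadata and annotations.

    ``values`` holds non-negative float32 intensities, one row per event in
    acquisition order.  ``annotations`` is a DataFrame aligned row-for-row
    with ``values``; stages append columns to it rather than mutating the
    intensity matrix.  ``provenance`` records the ordered stage descriptors
    applied so far.
    """

    values: np.ndarray
    channels: list[ChannelInfo]
    annotations: pd.DataFrame = None  # type: ignore[assignment]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D event x channel matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but {len(self.channels)} channels declared"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=pd.RangeIndex(self.values.shape[0]))
        if len(self.annotations) != self.values.shape[0]:
            raise ValueError("annotation length does not match event count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def data(self, name: str) -> np.ndarray:
        """Intensity column for one channel (view, not a copy)."""
        return self.values[:, self.channel_index(name)]

    def channels_by_role(self, *roles: str) -> list[str]:
        """Names of all channels whose role is in ``roles``, in panel order."""
        return [c.name for c in self.channels if c.role in roles]

    def marker_names(self) -> list[str]:
        """Identity + signaling channel names, in panel order."""
        return self.channels_by_role("identity", "signaling")

    # -- construction helpers ---------------------------------------------

    def copy(self) -> "EventTable":
        return EventTable(
            self.values.copy(),
            list(self.channels),
            self.annotations.copy(),
            list(self.provenance),
        )

    def subset(self, index) -> "EventTable":
        """New table restricted to the given event rows (bool mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EventTable(
            self.values[index],
            list(self.channels),
            self.annotations.iloc[index].reset_index(drop=True),
            list(self.provenance),
        )

    def with_annotation(self, name: str, values) -> "EventTable":
        """New table with an added/replaced annotation column."""
        ann = self.annotations.copy()
        ann[name] = np.asarray(values) if not isinstance(values, pd.Series) else values.to_numpy()
        return EventTable(self.values, list(self.channels), ann, list(self.provenance))

    def log_stage(self, descriptor: str) -> None:
        self.provenance.append(descriptor)


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".channels.csv")


def _write_tabular(table: EventTable, path: Path) -> None:
    extra = [c for c in table.annotations.columns
             if pd.api.types.is_numeric_dtype(table.annotations[c])]
    channels = list(table.channels) + [ChannelInfo(name=c, role="other") for c in extra]
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise FormatError("annotation column collides with a channel name")
    mat = table.values
    if extra:
        mat = np.column_stack([mat, table.annotations[extra].to_numpy(dtype=np.float32)])
    pd.DataFrame(mat.astype(np.float32), columns=names).to_csv(path, index=False)
    meta = pd.DataFrame(
        {
            "name": names,
            "marker": [c.marker for c in channels],
            "metal": [c.metal for c in channels],
            "role": [c.role for c in channels],
        }
    )
    meta.to_csv(_sidecar_path(path), index=False)


def _read_tabular(path: Path) -> EventTable:
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = pd.read_csv(sidecar, keep_default_na=False)
        roles = dict(zip(meta["name"], meta["role"]))
        markers = dict(zip(meta["name"], meta["marker"]))
        metals = dict(zip(meta["name"], meta["metal"]))
        unmatched = [c for c in df.columns if c not in roles]
        if unmatched:
            raise FormatError(f"channels missing from sidecar metadata: {unmatched}")
        channels = [
            ChannelInfo(c, marker=str(markers[c]), metal=str(metals[c]), role=str(roles[c]))
            for c in df.columns
        ]
    else:
        channels = [ChannelInfo(c) for c in df.columns]
    return EventTable(df.to_numpy(dtype=np.float32), channels)


# ---------------------------------------------------------------------------
# minimal FCS 3.1 (float32, single dataset)
# ---------------------------------------------------------------------------

_DELIM = "/"


def _write_fcs(table: EventTable, path: Path) -> None:
    extra = [c for c in table.annotations.columns
             if pd.api.types.is_numeric_dtype(table.annotations[c])]
    channels = list(table.channels) + [ChannelInfo(name=c, role="other") for c in extra]
    mat = table.values
    if extra:
        mat = np.column_stack([mat, table.annotations[extra].to_numpy(dtype=np.float32)])
    mat = np.ascontiguousarray(mat, dtype="<f4")
    n_events, n_par = mat.shape if mat.size else (mat.shape[0], len(channels))

    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
        "$PAR": str(len(channels)),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, ch in enumerate(channels, start=1):
        kw[f"$P{i}N"] = ch.name
        if ch.marker:
            kw[f"$P{i}S"] = ch.marker
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(mat[:, i - 1].max()) if n_events else 1.0)) + 1)
        # non-standard keywords carry role/metal so round-trips keep the panel
        kw[f"P{i}ROLE"] = ch.role
        if ch.metal:
            kw[f"P{i}METAL"] = ch.metal

    data_nbytes = mat.nbytes

    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        parts = [_DELIM]
        for k, v in items.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("utf-8")

    # fixed-point iteration: offsets depend on TEXT length which depends on offsets
    text_start = 256
    begin_data = text_start + len(render_text(10**8, 10**8))
    for _ in range(8):
        text = render_text(begin_data, begin_data + max(data_nbytes - 1, 0))
        new_begin = text_start + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = render_text(begin_data, begin_data + max(data_nbytes - 1, 0))
    text_end = text_start + len(text) - 1
    end_data = begin_data + max(data_nbytes - 1, 0)

    header = b"FCS3.1    "
    header += f"{text_start:>8d}{text_end:>8d}".encode()
    if end_data <= 99999999:
        header += f"{begin_data:>8d}{end_data:>8d}".encode()
    else:
        header += f"{0:>8d}{0:>8d}".encode()  # offsets only in TEXT
    header += f"{0:>8d}{0:>8d}".encode()  # no ANALYSIS

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - len(header)))
        fh.write(text)
        fh.write(mat.tobytes())


def _read_fcs(path: Path) -> EventTable:
    raw = Path(path).read_bytes()
    if len(raw) < 58 or not raw[:6].startswith(b"FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file (bad magic at offset 0)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header offsets at offset 10") from exc
    if text_end <= text_start or text_end >= len(raw):
        raise FormatError(f"{path}: TEXT segment offsets out of range at offset 10")
    text = raw[text_start : text_end + 1].decode("utf-8", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FormatError(f"{path}: TEXT segment has an odd token count at offset {text_start}")
    kw = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens), 2)}

    for req in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD"):
        if req not in kw:
            raise FormatError(f"{path}: missing required keyword {req}")
    if kw["$DATATYPE"] != "F":
        raise FormatError(f"{path}: only $DATATYPE F is supported, got {kw['$DATATYPE']}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin_data = int(kw.get("$BEGINDATA", raw[26:34] or 0))
    end_data = int(kw.get("$ENDDATA", raw[34:42] or 0))
    expected = n_par * n_tot * 4
    avail = min(end_data + 1, len(raw)) - begin_data if n_tot else 0
    if n_tot and avail < expected:
        raise FormatError(
            f"{path}: declared $TOT={n_tot} x $PAR={n_par} needs {expected} bytes "
            f"but DATA segment at offset {begin_data} holds {avail}"
        )
    little = kw["$BYTEORD"].startswith("1")
    dtype = "<f4" if little else ">f4"
    if n_tot:
        mat = np.frombuffer(raw[begin_data : begin_data + expected], dtype=dtype)
        mat = mat.reshape(n_tot, n_par).astype(np.float32)
    else:
        mat = np.empty((0, n_par), dtype=np.float32)

    channels = []
    for i in range(1, n_par + 1):
        channels.append(
            ChannelInfo(
                name=kw.get(f"$P{i}N", f"P{i}"),
                marker=kw.get(f"$P{i}S", ""),
                metal=kw.get(f"P{i}METAL", ""),
                role=kw.get(f"P{i}ROLE", "other"),
            )
        )
    return EventTable(mat, channels)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".fcs":
        return "fcs"
    return "tabular"


def read_events(path, format: str = "auto", panel=None) -> EventTable:
    """Read an :class:`EventTable` from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"fcs"``, ``"tabular"``, or ``"auto"`` (by extension; ``.fcs`` is
        FCS, everything else tabular).
    panel
        Optional :class:`~cytoglia.panel.PanelDefinition` used to resolve
        channel roles/markers by channel name; channels not covered by the
        panel keep their file-declared role (or ``other``).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        On malformed files; the message names the offending offset or the
        unmatched channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _infer_format(path)
    if format == "fcs":
        table = _read_fcs(path)
    elif format == "tabular":
        table = _read_tabular(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if panel is not None:
        lookup = {c.name: c for c in panel.channels}
        unmatched = [c.name for c in table.channels
                     if c.name not in lookup and c.role != "other"]
        table.channels = [
            replace(lookup[c.name]) if c.name in lookup else c for c in table.channels
        ]
        if unmatched:
            raise FormatError(f"channels not declared in panel: {unmatched}")
    table.log_stage(f"read_events:{format}:{path.name}")
    return table


def write_events(table: EventTable, path, format: str = "auto") -> None:
    """Write ``table`` to ``path`` in the FCS or tabular dialect.

    Numeric annotation columns (e.g. ``bc_neg``) are appended as channels
    with role ``other`` so downstream tools see them as ordinary parameters.
    """
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    if format == "fcs":
        _write_fcs(table, path)
    elif format == "tabular":
        _write_tabular(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")
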