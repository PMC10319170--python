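"""Reading, writing and compensating FCS event data.

Flow cytometers store list-mode data in FCS files: a small ASCII header
with segment offsets, a TEXT segment of ``$KEYWORD/value`` pairs and a
binary DATA segment of per-event channel intensities.  Beckman Coulter
Navios instruments write ``.LMD`` files that chain two datasets through
``$NEXTDATA`` — an FCS 2.0 dataset for legacy software followed by an
FCS 3.0 dataset; by convention the FCS 3.0 dataset is the one analysed.

This module implements:

* :class:`EventTable` — the in-memory event matrix with channel names
  and acquisition metadata;
* :func:`read_events` / :func:`write_events` — FCS 3.0/3.1 reading
  (including the LMD two-dataset layout) and FCS 3.1 writing with
  float32 data;
* :class:`SpilloverMatrix` and :func:`apply_compensation` — standard
  linear spillover compensation of fluorescence channels.

All intensities are carried on a linear fluorescence-unit (FU) scale:
log-amplified integer data are converted through ``$PnE`` and gains
through ``$PnG`` at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "SpilloverMatrix",
    "PanelDefinition",
    "FCSError",
    "FCSParseError",
    "FCSIntegrityError",
    "read_events",
    "write_events",
    "apply_compensation",
    "is_scatter_channel",
]


class FCSError(Exception):
    """Base class for FCS I/O failures."""


class FCSParseError(FCSError):
    """Malformed header or TEXT segment; the message names the offending keyword."""


class FCSIntegrityError(FCSError):
    """TEXT keywords inconsistent with the DATA segment (e.g. ``$TOT`` vs data length)."""


#: Channel-name prefixes treated as scatter (never compensated, never log-scaled).
_SCATTER_PREFIXES = ("FSC", "SSC", "FS-", "SS-", "TIME")


def is_scatter_channel(name: str) -> bool:
    """True for forward/side-scatter (and time) channels such as ``FSC-INT`` or ``FS-PEAK``."""
    return name.upper().startswith(_SCATTER_PREFIXES)


@dataclass
class EventTable:
    """Per-event intensity matrix for one acquired tube.

    Parameters
    ----------
    sample_id, tube_id :
        Identity of the sample and the staining tube.
    channels :
        Ordered, unique channel names, ``"<marker>-<fluorochrome>"`` for
        antibodies (e.g. ``"CD45-KO"``) and ``FSC-INT``/``SSC-INT``/
        ``FS-PEAK`` for scatter.
    values :
        ``(n_events, n_channels)`` array of linear-FU intensities.
    metadata :
        Acquisition keywords carried through I/O round trips.
    """

    sample_id: str
    tube_id: str
    channels: list[str]
    values: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.channels))
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"values have {self.values.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("event values must be finite")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel_index(self, marker: str) -> int:
        """Index of the channel for *marker*, case-insensitive on the marker part.

        ``"cd45"`` matches ``"CD45-KO"``; an exact full-name match is
        preferred.  Raises ``KeyError`` when no channel matches.
        """
        low = marker.lower()
        for i, ch in enumerate(self.channels):
            if ch.lower() == low:
                return i
        for i, ch in enumerate(self.channels):
            if ch.lower().startswith(low + "-"):
                return i
        raise KeyError(f"no channel matching marker {marker!r}")

    def channel_name(self, marker: str) -> str:
        return self.channels[self.channel_index(marker)]

    def has_marker(self, marker: str) -> bool:
        try:
            self.channel_index(marker)
            return True
        except KeyError:
            return False

    def column(self, marker: str) -> np.ndarray:
        """Intensity column for *marker* (view, not copy)."""
        return self.values[:, self.channel_index(marker)]

    def with_values(self, values: np.ndarray, channels: list[str] | None = None) -> "EventTable":
        return EventTable(
            sample_id=self.sample_id,
            tube_id=self.tube_id,
            channels=list(self.channels if channels is None else channels),
            values=values,
            metadata=dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over fluorescence channels.

    Convention: ``observed = true @ matrix`` with rows indexed by the
    emitting fluorochrome's primary channel, so compensation multiplies
    observed intensities by the matrix inverse.
    """

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square over its channels")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal entries must equal 1")
        if np.any(self.matrix < 0):
            raise ValueError("spillover coefficients must be non-negative")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise np.linalg.LinAlgError("spillover matrix is singular")

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(list(channels), np.eye(len(channels)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, columns=self.channels).to_csv(path, index=False)


@dataclass
class PanelDefinition:
    """Tube → marker/fluorochrome mapping with backbone groups.

    ``tubes`` maps a tube id to the list of ``(marker, fluorochrome,
    channel_name)`` it measures.  ``backbone_groups`` maps a group id to
    ``(set of tube ids, set of backbone markers)``; every backbone marker
    of a group must be measured by every tube of that group, which is
    what makes cross-tube merging possible.
    """

    tubes: dict[str, list[tuple[str, str, str]]]
    backbone_groups: dict[str, tuple[set[str], set[str]]]

    def __post_init__(self) -> None:
        if len(set(self.tubes)) != len(self.tubes):
            raise ValueError("tube ids must be unique")
        for gid, (tube_ids, backbone) in self.backbone_groups.items():
            for tid in tube_ids:
                markers = {m.lower() for m, _, _ in self.tubes[tid]}
                missing = {b for b in backbone if b.lower() not in markers}
                if missing:
                    raise ValueError(
                        f"backbone markers {sorted(missing)} of group {gid!r} "
                        f"missing from tube {tid!r}"
                    )

    def tube_channels(self, tube_id: str) -> list[str]:
        return [ch for _, _, ch in self.tubes[tube_id]]

    def backbone_for_tube(self, tube_id: str) -> set[str]:
        for tube_ids, backbone in self.backbone_groups.values():
            if tube_id in tube_ids:
                return set(backbone)
        raise KeyError(f"tube {tube_id!r} belongs to no backbone group")


# ---------------------------------------------------------------------------
# FCS parsing


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    text = raw.decode("latin-1")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value: split,
    # then fold empty tokens back into their neighbours.
    parts = body.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok += delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    return {
        tokens[j].strip().upper(): tokens[j + 1]
        for j in range(0, len(tokens), 2)
    }


def _parse_header_offsets(buf: bytes, offset: int) -> tuple[str, dict[str, int]]:
    header = buf[offset : offset + 58]
    if len(header) < 58:
        raise FCSParseError("file too short for an FCS HEADER segment")
    version = header[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"bad FCS version string {version!r} in HEADER")
    fields = {}
    names = ["text_begin", "text_end", "data_begin", "data_end", "ana_begin", "ana_end"]
    for i, name in enumerate(names):
        raw = header[10 + 8 * i : 18 + 8 * i].strip() or b"0"
        try:
            fields[name] = int(raw)
        except ValueError as exc:
            raise FCSParseError(f"non-numeric HEADER offset {name}: {raw!r}") from exc
    return version, fields


def _read_one_dataset(buf: bytes, offset: int) -> tuple[EventTable, int]:
    """Parse the dataset starting at *offset*; return (table, next_offset)."""
    version, hdr = _parse_header_offsets(buf, offset)
    text = _parse_text_segment(
        buf[offset + hdr["text_begin"] : offset + hdr["text_end"] + 1]
    )

    def req(key: str) -> str:
        if key not in text:
            raise FCSParseError(f"required keyword {key} missing from TEXT segment")
        return text[key]

    n_par = int(req("$PAR"))
    n_tot = int(req("$TOT"))
    datatype = req("$DATATYPE").upper()
    byteord = req("$BYTEORD").strip()
    endian = "<" if byteord.startswith("1") else ">"
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSParseError(f"unsupported $MODE {mode!r} (only list mode)")

    data_begin = hdr["data_begin"] or int(text.get("$BEGINDATA", "0"))
    data_end = hdr["data_end"] or int(text.get("$ENDDATA", "0"))
    raw = buf[offset + data_begin : offset + data_end + 1]

    channels, widths, scales, gains = [], [], [], []
    for i in range(1, n_par + 1):
        channels.append(text.get(f"$P{i}N", f"P{i}"))
        widths.append(int(text.get(f"$P{i}B", "32")))
        e = text.get(f"$P{i}E", "0,0").split(",")
        scales.append((float(e[0]), float(e[1])))
        gains.append(float(text.get(f"$P{i}G", "1")) or 1.0)

    if datatype == "F":
        dt, itemsize = np.dtype(endian + "f4"), 4
    elif datatype == "D":
        dt, itemsize = np.dtype(endian + "f8"), 8
    elif datatype == "I":
        if len(set(widths)) != 1 or widths[0] not in (16, 32):
            raise FCSParseError("$PnB: only uniform 16/32-bit integer data supported")
        dt, itemsize = np.dtype(endian + ("u2" if widths[0] == 16 else "u4")), widths[0] // 8
    else:
        raise FCSParseError(f"unsupported $DATATYPE {datatype!r}")

    need = n_tot * n_par * itemsize
    if len(raw) < need:
        raise FCSIntegrityError(
            f"$TOT={n_tot} x $PAR={n_par} needs {need} data bytes, segment has {len(raw)}"
        )
    values = np.frombuffer(raw[:need], dtype=dt).astype(np.float64).reshape(n_tot, n_par)

    # $PnE log amplification and $PnG gain → linear FU.
    for i, ((a, b), g) in enumerate(zip(scales, gains)):
        if a > 0:
            rng = float(text.get(f"$P{i + 1}R", "1024"))
            values[:, i] = (b if b > 0 else 1.0) * 10.0 ** (a * values[:, i] / rng)
        elif g != 1.0:
            values[:, i] = values[:, i] / g

    meta = {k: v for k, v in text.items() if not k.startswith("$P") or k in ("$PROJ",)}
    table = EventTable(
        sample_id=text.get("SAMPLE_ID", text.get("$SMNO", "")),
        tube_id=text.get("TUBE_ID", text.get("$TUBE", "")),
        channels=channels,
        values=values,
        metadata=meta,
    )
    next_off = int(text.get("$NEXTDATA", "0"))
    return table, (offset + next_off if next_off else 0)


def read_events(path: str | Path, dataset: int | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 file (or LMD container) into an :class:`EventTable`.

    Parameters
    ----------
    path :
        FCS or LMD file.
    dataset :
        Force the 0-based dataset index in a multi-dataset (LMD) file.
        By default, when the first dataset is FCS 2.0 and a second
        dataset follows, the second (FCS 3.0) dataset is returned —
        the Navios LMD convention.
    """
    buf = Path(path).read_bytes()
    version, _ = _parse_header_offsets(buf, 0)
    if dataset is not None:
        offset, idx = 0, 0
        while True:
            table, nxt = _read_one_dataset(buf, offset)
            if idx == dataset:
                return table
            if not nxt:
                raise FCSParseError(f"file has no dataset index {dataset}")
            offset, idx = nxt, idx + 1
    table, nxt = _read_one_dataset(buf, 0)
    if version.startswith("FCS2") and nxt:
        table, _ = _read_one_dataset(buf, nxt)
    return table


def write_events(table: EventTable, path: str | Path) -> None:
    """Write *table* as a single-dataset FCS 3.1 file with float32 data."""
    n_tot, n_par = table.values.shape
    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("SAMPLE_ID", table.sample_id),
        ("TUBE_ID", table.tube_id),
    ]
    for i, ch in enumerate(table.channels, start=1):
        col_max = float(table.values[:, i - 1].max()) if n_tot else 1.0
        pairs += [
            (f"$P{i}N", ch),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(col_max, 1.0)) + 1)),
        ]
    reserved = {k for k, _ in pairs} | {f"$P{i}{s}" for i in range(1, n_par + 1) for s in "NBER"}
    for k, v in table.metadata.items():
        ku = k.strip().upper()
        if ku in reserved or ku in ("$BEGINDATA", "$ENDDATA"):
            continue
        pairs.append((k, str(v)))

    delim = "/"

    def render(begin_data: int, end_data: int) -> bytes:
        items = pairs + [("$BEGINDATA", f"{begin_data:010d}"), ("$ENDDATA", f"{end_data:010d}")]
        out = delim
        for k, v in items:
            v = str(v) if str(v) != "" else " "
            if delim in k or delim in v:
                raise ValueError(f"delimiter {delim!r} not allowed in keyword {k!r}")
            out += f"{k}{delim}{v}{delim}"
        return out.encode("latin-1")

    text = render(0, 0)
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1 if data else 0
    text = render(data_begin, data_end)  # fixed-width placeholders keep length stable

    header = b"FCS3.1    " + b"".join(
        f"{v:8d}".encode() for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == 58
    Path(path).write_bytes(header + text + data)


def apply_compensation(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Return a compensated copy: fluorescence columns multiplied by ``inv(spill)``.

    Scatter channels are never part of a spillover matrix and are left
    untouched.  Raises a configuration error when the spillover channels
    are not a subset of the table's channels.
    """
    try:
        idx = [table.channels.index(ch) for ch in spill.channels]
    except ValueError as exc:
        raise KeyError(f"spillover channel missing from event table: {exc}") from exc
    for ch in spill.channels:
        if is_scatter_channel(ch):
            raise ValueError(f"scatter channel {ch!r} cannot be compensated")
    inv = np.linalg.inv(spill.matrix)
    values = table.values.copy()
    values[:, idx] = values[:, idx] @ inv
    out = table.with_values(values)
    out.metadata["COMPENSATED"] = "1"
    return out
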