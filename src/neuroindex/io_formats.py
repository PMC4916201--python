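"""Reading and writing of EEG/ECG recordings and channel maps.

Recordings arrive as delimited numeric text (comma, tab, or whitespace,
auto-sniffed from the first line) with an optional single header row of
channel labels, or as a MAT-file holding a single 2-D numeric array.
Orientation is resolved automatically: channels always end up in rows.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import (
    ChannelNotFoundError,
    DataError,
    LayoutError,
    ParseError,
)

__all__ = [
    "Condition",
    "Recording",
    "ChannelMap",
    "biosemi64_map",
    "read_channel_map",
    "read_recording",
    "read_mat_recording",
    "write_recording",
    "resolve_channels",
    "write_report",
]


class Condition(enum.Enum):
    """Recording condition tag."""

    EO = "EO"
    EC = "EC"
    ECG = "ECG"
    UNKNOWN = "UNKNOWN"


@dataclass
class Recording:
    """A labeled multichannel time series.

    Parameters
    ----------
    data
        Channels x samples matrix in microvolts.
    sample_rate_hz
        Sampling frequency, strictly positive.
    labels
        One label per row of ``data``.
    condition
        Condition tag (EO/EC/ECG/UNKNOWN).
    """

    data: np.ndarray
    sample_rate_hz: float
    labels: list[str]
    condition: Condition = Condition.UNKNOWN

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise LayoutError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if not (self.sample_rate_hz > 0 and math.isfinite(self.sample_rate_hz)):
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains NaN or Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class ChannelMap:
    """Mapping from canonical channel label to zero-based row index."""

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        indices = list(self.entries.values())
        if len(set(indices)) != len(indices):
            raise LayoutError("channel map indices are not unique")
        if any(i < 0 for i in indices):
            raise LayoutError("channel map indices must be non-negative")

    def __len__(self) -> int:
        return len(self.entries)

    def labels_in_order(self) -> list[str]:
        """Labels sorted by their row index."""
        return [lab for lab, _ in sorted(self.entries.items(), key=lambda kv: kv[1])]


def biosemi64_map() -> ChannelMap:
    """The default 64-channel BioSemi 10/10 layout shipped with the package."""
    text = resources.files("neuroindex.data").joinpath("biosemi64.tsv").read_text()
    entries: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        label, idx = line.split("\t")
        entries[label] = int(idx)
    return ChannelMap(entries)


def read_channel_map(path: str | Path) -> ChannelMap:
    """Read a user channel map: two tab- or whitespace-separated columns
    (label, zero-based row index), one entry per line."""
    entries: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 'label index'")
        try:
            entries[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: bad index {parts[1]!r}") from exc
    return ChannelMap(entries)


def _sniff_delimiter(line: str) -> str | None:
    """Return ',' or '\\t' when present, else None (any whitespace)."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def _is_numeric_row(tokens: list[str]) -> bool:
    try:
        for t in tokens:
            float(t)
    except ValueError:
        return False
    return len(tokens) > 0


def _tokenize(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [t.strip() for t in line.split(delimiter)]


def _locate_bad_cell(path: Path, delimiter: str | None, skiprows: int) -> None:
    """Scan the file to name the first non-numeric cell, then raise."""
    with open(path) as fh:
        for row, line in enumerate(fh, start=1):
            if row <= skiprows or not line.strip():
                continue
            for col, tok in enumerate(_tokenize(line.strip(), delimiter), start=1):
                try:
                    float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {tok!r} at row {row}, column {col}"
                    ) from None
    raise ParseError(f"{path}: could not parse numeric matrix")


def read_recording(
    path: str | Path,
    sample_rate_hz: float,
    channel_map: ChannelMap | None = None,
    condition: Condition = Condition.UNKNOWN,
) -> Recording:
    """Read a delimited text recording.

    A single optional header row supplies channel labels. Without a header,
    labels come from ``channel_map`` (or the shipped BioSemi-64 map when the
    file has 64 channels). Orientation is auto-resolved: the longer axis is
    taken as time.

    Raises
    ------
    ParseError
        Non-numeric cell (named by row/column).
    LayoutError
        Channel count matches neither the map nor, for headerless 64-channel
        data, the default layout.
    DataError
        NaN or Inf present after loading.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ParseError(f"{path}: empty file")
    delimiter = _sniff_delimiter(first)
    header_tokens = _tokenize(first.strip(), delimiter)
    has_header = not _is_numeric_row(header_tokens)

    try:
        data = np.loadtxt(
            path,
            delimiter=delimiter,
            skiprows=1 if has_header else 0,
            ndmin=2,
            dtype=float,
        )
    except ValueError:
        _locate_bad_cell(path, delimiter, skiprows=1 if has_header else 0)
        raise  # pragma: no cover - _locate_bad_cell always raises

    if has_header:
        labels = header_tokens
        n = len(labels)
        if data.shape[0] == n and data.shape[1] != n:
            pass  # channels already in rows
        elif data.shape[1] == n:
            data = data.T
        else:
            raise LayoutError(
                f"{path}: header has {n} labels but data is {data.shape[0]}x{data.shape[1]}"
            )
        return Recording(data, sample_rate_hz, labels, condition)

    # headerless: orient so channels are in rows (rows <= columns)
    if data.shape[0] > data.shape[1]:
        data = data.T
    n_ch = data.shape[0]
    if channel_map is None:
        if n_ch == 64:
            channel_map = biosemi64_map()
        else:
            raise LayoutError(
                f"{path}: {n_ch} channels without header; supply a channel map "
                "(the default BioSemi map covers exactly 64 channels)"
            )
    if len(channel_map) != n_ch:
        raise LayoutError(
            f"{path}: {n_ch} channels but channel map has {len(channel_map)} entries"
        )
    if max(channel_map.entries.values()) >= n_ch:
        raise LayoutError(f"{path}: channel map index out of bounds for {n_ch} rows")
    return Recording(data, sample_rate_hz, channel_map.labels_in_order(), condition)


def read_mat_recording(
    path: str | Path,
    sample_rate_hz: float,
    channel_map: ChannelMap | None = None,
    condition: Condition = Condition.UNKNOWN,
) -> Recording:
    """Read a MAT-file holding exactly one 2-D numeric array.

    Any other structure (multiple arrays, cell arrays, structs) is rejected.
    """
    from scipy.io import loadmat

    contents = loadmat(str(path))
    arrays = {
        k: v
        for k, v in contents.items()
        if not k.startswith("__")
        and isinstance(v, np.ndarray)
        and v.ndim == 2
        and np.issubdtype(v.dtype, np.number)
    }
    if len(arrays) != 1:
        raise ParseError(
            f"{path}: expected a single 2-D numeric array, found "
            f"{sorted(arrays) or 'none'}"
        )
    data = np.asarray(next(iter(arrays.values())), dtype=float)
    if data.shape[0] > data.shape[1]:
        data = data.T
    n_ch = data.shape[0]
    if channel_map is None:
        if n_ch != 64:
            raise LayoutError(f"{path}: {n_ch} channels; supply a channel map")
        channel_map = biosemi64_map()
    if len(channel_map) != n_ch:
        raise LayoutError(
            f"{path}: {n_ch} channels but channel map has {len(channel_map)} entries"
        )
    return Recording(data, sample_rate_hz, channel_map.labels_in_order(), condition)


def write_recording(recording: Recording, path: str | Path, header: bool = True) -> None:
    """Write a recording as tab-separated text at full float precision.

    Round-trips bit-identically through :func:`read_recording`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(recording.labels) + "\n")
        np.savetxt(fh, recording.data, fmt="%.17g", delimiter="\t")


def resolve_channels(recording: Recording, wanted: list[str]) -> list[int]:
    """Row indices of the wanted labels, case-insensitively, in request order."""
    lookup = {lab.lower(): i for i, lab in enumerate(recording.labels)}
    indices = []
    for lab in wanted:
        key = lab.lower()
        if key not in lookup:
            raise ChannelNotFoundError(
                f"channel {lab!r} not found; available: {recording.labels}"
            )
        indices.append(lookup[key])
    return indices


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report to JSON (sorted keys, so byte-stable)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
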