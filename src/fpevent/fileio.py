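"""Reading and writing the pipeline's on-disk formats.

Raw force-plate exports are plain-text delimiter-separated files: one row
per sample, columns carrying time, force/moment channels (Fx, Fy, Fz in N;
Mx, My, Mz in N·m) and either per-pin parallel-port voltages or an already
decoded integer trigger column.  Manufacturer headers are skipped by an
explicit line count, never auto-detected.  Filenames must contain
``subj<digits>`` and may contain ``block<digits>``; that is the only place
subject/block identity lives for force-plate data.

Processed trial-level statistics round-trip through ordinary CSV.  Floats
are written at full ``repr`` precision, so write→read reproduces every
value bit-for-bit — no binary sidecar is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .triggers import decode_pin_levels

__all__ = [
    "SubjectBlockID",
    "RecordingFormatSpec",
    "RawRecording",
    "FileFormatError",
    "parse_data_filename",
    "read_raw_recording",
    "write_trial_stats",
    "read_trial_stats",
    "KEY_COLUMNS",
]

#: Key columns identifying one trial across every table in the pipeline.
KEY_COLUMNS = ("subject", "block", "trial")

_SUBJ_RE = re.compile(r"subj(\d+)")
_BLOCK_RE = re.compile(r"block(\d+)")


class FileFormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass(frozen=True)
class SubjectBlockID:
    """Identity parsed from a data filename.

    ``block`` is ``None`` when the file holds all blocks of a subject.
    """

    subject: int
    block: int | None = None

    def __post_init__(self) -> None:
        if self.subject < 1:
            raise ValueError(f"subject must be positive, got {self.subject}")
        if self.block is not None and self.block < 1:
            raise ValueError(f"block must be positive, got {self.block}")


@dataclass
class RecordingFormatSpec:
    """Column layout and dialect of a raw force-plate export.

    Columns are addressed by 0-based integer position, or by name when the
    file's first body line is a header row (``has_column_names=True``).
    Exactly one of ``pin_columns`` (LSB first) or ``trigger_column`` must be
    given.  The decimal separator is ``.``; locale exports must be converted
    before reading.

    Parameters
    ----------
    delimiter:
        Field separator; tab, comma and semicolon are the supported dialects.
    header_lines:
        Number of manufacturer-header lines to skip before the body.
    sampling_rate:
        Sampling rate in Hz.
    channel_columns:
        Ordered mapping channel name → column for the force/moment channels.
    pin_columns:
        Per-pin voltage columns, least-significant pin first.
    trigger_column:
        A single column already holding decoded integer trigger codes.
    time_column:
        Optional time column (ms).  When absent, time is synthesized as
        ``sample_index / sampling_rate * 1000`` (0-based).
    pin_high_threshold:
        Voltage above which a pin counts as high (TTL default 2.5 V).
    """

    sampling_rate: float
    channel_columns: Mapping[str, int | str]
    delimiter: str = "\t"
    header_lines: int = 0
    has_column_names: bool = False
    pin_columns: Sequence[int | str] | None = None
    trigger_column: int | str | None = None
    time_column: int | str | None = None
    pin_high_threshold: float = 2.5

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.header_lines < 0:
            raise ValueError("header_lines must be >= 0")
        if self.delimiter not in ("\t", ",", ";"):
            raise ValueError(f"unsupported delimiter {self.delimiter!r}")
        if (self.pin_columns is None) == (self.trigger_column is None):
            raise ValueError(
                "exactly one of pin_columns or trigger_column must be given"
            )
        if not self.channel_columns:
            raise ValueError("channel_columns must not be empty")
        self.channel_columns = dict(self.channel_columns)
        if self.pin_columns is not None:
            self.pin_columns = tuple(self.pin_columns)
        used: list = list(self.channel_columns.values())
        used += list(self.pin_columns or [])
        if self.trigger_column is not None:
            used.append(self.trigger_column)
        if self.time_column is not None:
            used.append(self.time_column)
        if len(set(used)) != len(used):
            raise ValueError("channel, pin/trigger and time columns must be disjoint")


@dataclass
class RawRecording:
    """One continuous block of samples with decoded trigger codes.

    All arrays share length ``n_samples``; ``time`` is in ms and
    ``trigger_codes`` holds non-negative integers.
    """

    id: SubjectBlockID
    sampling_rate: float
    time: np.ndarray
    channels: dict[str, np.ndarray]
    trigger_codes: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        for name, series in self.channels.items():
            if len(series) != n:
                raise ValueError(f"channel {name!r} has length {len(series)} != {n}")
        if len(self.trigger_codes) != n:
            raise ValueError("trigger_codes length mismatch")
        if np.any(self.trigger_codes < 0):
            raise ValueError("trigger codes must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.time)


def parse_data_filename(filename: str | Path) -> SubjectBlockID:
    """Extract subject and (optionally) block number from a filename.

    Matches the case-sensitive substring ``subj`` followed by digits
    anywhere in the basename (first match wins), and likewise ``block``.
    Leading zeros are ignored.

    Raises
    ------
    FileFormatError
        If the basename contains no ``subj<digits>`` tag.
    """
    base = Path(filename).name
    m = _SUBJ_RE.search(base)
    if m is None:
        raise FileFormatError(
            f"filename {base!r} lacks the required 'subj<digits>' tag"
        )
    b = _BLOCK_RE.search(base)
    return SubjectBlockID(subject=int(m.group(1)),
                          block=int(b.group(1)) if b else None)


def _resolve(df: pd.DataFrame, col: int | str, path: Path, what: str) -> pd.Series:
    try:
        if isinstance(col, int) and col not in df.columns:
            return df.iloc[:, col]
        return df[col]
    except (KeyError, IndexError):
        raise FileFormatError(f"{path.name}: {what} column {col!r} not found") from None


def read_raw_recording(path: str | Path, spec: RecordingFormatSpec) -> RawRecording:
    """Read one raw force-plate DSV file into a :class:`RawRecording`.

    Header lines are skipped per ``spec.header_lines``; channels are parsed
    as floats; pin voltages, when given, are decoded into integer trigger
    codes.  Subject/block identity comes from the filename.

    Raises
    ------
    FileFormatError
        On an empty body, ragged rows, or non-numeric channel cells.
    """
    path = Path(path)
    rec_id = parse_data_filename(path)
    try:
        df = pd.read_csv(
            path,
            sep=spec.delimiter,
            skiprows=spec.header_lines,
            header=0 if spec.has_column_names else None,
            dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{path.name}: empty body after skipping header") from None
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path.name}: ragged rows — {exc}") from None
    if df.empty:
        raise FileFormatError(f"{path.name}: empty body after skipping header")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        line = row + spec.header_lines + (2 if spec.has_column_names else 1)
        raise FileFormatError(f"{path.name}: ragged or incomplete row at line {line}")

    def as_float(col: int | str, what: str) -> np.ndarray:
        raw = _resolve(df, col, path, what)
        try:
            return raw.astype(float).to_numpy()
        except ValueError as exc:
            raise FileFormatError(
                f"{path.name}: non-numeric value in {what} column {col!r}: {exc}"
            ) from None

    channels = {name: as_float(col, f"channel {name}")
                for name, col in spec.channel_columns.items()}

    if spec.pin_columns is not None:
        volts = np.column_stack(
            [as_float(c, "pin") for c in spec.pin_columns]
        )
        codes = decode_pin_levels(volts, spec.pin_high_threshold)
    else:
        raw = as_float(spec.trigger_column, "trigger")
        if not np.all(raw == np.round(raw)):
            raise FileFormatError(f"{path.name}: non-integer trigger codes")
        codes = raw.astype(np.int64)

    n = len(df)
    if spec.time_column is not None:
        time = as_float(spec.time_column, "time")
    else:
        time = np.arange(n, dtype=float) / spec.sampling_rate * 1000.0

    return RawRecording(id=rec_id, sampling_rate=spec.sampling_rate,
                        time=time, channels=channels, trigger_codes=codes)


def write_trial_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write a trial-statistics table to CSV, one row per trial.

    The table must carry the ``(subject, block, trial)`` key columns with
    unique keys.  Floats are serialized at full precision so the round-trip
    through :func:`read_trial_stats` is exact; missing values (incomplete
    trials) round-trip as missing.
    """
    missing = [k for k in KEY_COLUMNS if k not in stats.columns]
    if missing:
        raise ValueError(f"stats table lacks key columns {missing}")
    if len(stats) and stats.duplicated(subset=list(KEY_COLUMNS)).any():
        dupes = stats.loc[
            stats.duplicated(subset=list(KEY_COLUMNS)), list(KEY_COLUMNS)
        ].drop_duplicates()
        raise ValueError(
            f"duplicate (subject, block, trial) keys: {dupes.values.tolist()}"
        )
    stats.to_csv(path, index=False, float_format=None)


def read_trial_stats(path: str | Path) -> pd.DataFrame:
    """Read a trial-statistics table written by :func:`write_trial_stats`."""
    df = pd.read_csv(path)
    for k in KEY_COLUMNS:
        if k in df.columns:
            df[k] = df[k].astype("Int64")
    return df
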