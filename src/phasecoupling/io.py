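"""Recording and protocol I/O plus run configuration.

Recordings are plain delimited text (CSV or TSV, autodetected from the
header line) with one comment line ``# fs=<Hz>`` carrying the sampling
rate and one named column per channel.  Stage protocols are small CSV
files with columns ``label,start_s,end_s``.  All times are seconds from
the start of the record and stage intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError, ValidationError

__all__ = [
    "SignalRecord",
    "StageProtocol",
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_protocol",
    "write_protocol",
    "segment_stages",
]

#: Longest interior NaN gap (seconds) repaired by linear interpolation.
MAX_GAP_S = 1.0


@dataclass
class SignalRecord:
    """A uniformly sampled multichannel time series.

    Parameters
    ----------
    channels : list of str
        Channel names, e.g. ``["BP", "SAS_LEFT", "SAS_RIGHT"]``.
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel samples in arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Start time in seconds (0 at record start by convention).
    """

    channels: list[str]
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channels:
            raise ValidationError("SignalRecord needs at least one channel")
        if len(self.channels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel names but "
                f"{self.samples.shape[0]} sample rows"
            )
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("non-finite samples after ingestion")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None


@dataclass
class StageProtocol:
    """Ordered protocol stages as ``(label, start_s, end_s)`` triples.

    Labels are unique (A-D in the slow-breathing protocol); intervals are
    half-open, non-overlapping and monotone in time.
    """

    stages: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        seen: set[str] = set()
        for label, start, end in self.stages:
            if end <= start:
                raise ValidationError(f"stage {label}: end {end} <= start {start}")
            if start < prev_end:
                raise ValidationError(f"stage {label} overlaps the previous stage")
            if label in seen:
                raise ValidationError(f"duplicate stage label {label!r}")
            seen.add(label)
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.stages]

    def label_at(self, t: float) -> str | None:
        """Stage label containing time ``t`` (half-open), or None."""
        for label, start, end in self.stages:
            if start <= t < end:
                return label
        return None


@dataclass
class RunConfig:
    """Analysis configuration; defaults follow the study pipeline.

    Frequency bands are Hz; windows are seconds.  ``fourier_order`` is the
    order K of the Fourier expansion of the phase model (K = 2 in the study),
    ``grid_size`` the side M of the 2π×2π coupling-function grid.
    """

    respiratory_band: tuple[float, float] = (0.1, 0.6)
    cardiac_band: tuple[float, float] = (0.6, 2.0)
    filter_order: int = 2
    detrend_window_s: float = 30.0
    edge_exclude_s: float = 10.0
    window_s: float = 50.0
    fourier_order: int = 2
    grid_size: int = 100
    n_surrogates: int = 100
    propagation: float = 0.2
    protophase_harmonics: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("filter_order", "detrend_window_s", "edge_exclude_s",
                     "window_s", "grid_size", "n_surrogates",
                     "protophase_harmonics"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.detrend_window_s <= 0 or self.window_s <= 0 or self.filter_order < 1:
            raise ValidationError("windows and filter order must be positive")
        if self.fourier_order < 1:
            raise ValidationError("fourier_order must be >= 1")
        if self.grid_size < 8:
            raise ValidationError("grid_size must be >= 8")
        for lo, hi in (self.respiratory_band, self.cardiac_band):
            if not (0 < lo < hi):
                raise ValidationError(f"bad band ({lo}, {hi})")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("respiratory_band", "cardiac_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_fs_line(line: str) -> float | None:
    line = line.lstrip("# \t")
    if line.lower().startswith("fs"):
        try:
            return float(line.split("=", 1)[1].strip())
        except (IndexError, ValueError) as exc:
            raise FormatError(f"unparseable sampling-rate line: {line!r}") from exc
    return None


def _interpolate_gaps(col: np.ndarray, fs: float, name: str) -> np.ndarray:
    """Linearly interpolate interior NaN runs no longer than MAX_GAP_S."""
    bad = ~np.isfinite(col)
    if not bad.any():
        return col
    if bad[0] or bad[-1]:
        raise FormatError(f"channel {name}: non-finite samples at record edge")
    # locate NaN runs
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    max_len = int(MAX_GAP_S * fs)
    for run in splits:
        if len(run) > max_len:
            raise FormatError(
                f"channel {name}: gap of {len(run)} samples exceeds "
                f"{MAX_GAP_S} s interpolation limit"
            )
    good = ~bad
    col = col.copy()
    col[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), col[good])
    return col


def read_recording(path: str | Path, fs: float | None = None) -> SignalRecord:
    """Read a delimited-text recording.

    The file holds one header row of channel names, optionally preceded by a
    ``# fs=<Hz>`` metadata line; ``fs`` may instead be given as an argument
    (the argument wins if both are present and disagree is an error).
    Interior NaN gaps up to 1 s are linearly interpolated.
    """
    path = Path(path)
    file_fs: float | None = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                got = _parse_fs_line(line)
                if got is not None:
                    file_fs = got
            else:
                header = line
                break
        else:
            raise FormatError(f"{path}: empty file")
    delim = "\t" if "\t" in header else ","
    if file_fs is not None and fs is not None and not math.isclose(file_fs, fs):
        raise ConfigurationError(
            f"fs argument {fs} conflicts with file metadata {file_fs}")
    fs = fs if fs is not None else file_fs
    if fs is None:
        raise ConfigurationError(
            f"{path}: no '# fs=' metadata line and no fs argument")
    try:
        df = pd.read_csv(path, sep=delim, skiprows=skip, na_values=["", "nan", "NaN"])
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        newly_bad = values.isna() & df[col].notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad)[0])
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r} at data row {row}")
        df[col] = values
    samples = np.vstack([
        _interpolate_gaps(df[c].to_numpy(float), fs, str(c)) for c in df.columns
    ])
    return SignalRecord(channels=[str(c) for c in df.columns], samples=samples, fs=fs)


def write_recording(record: SignalRecord, path: str | Path) -> None:
    """Write a recording as CSV with a ``# fs=`` metadata line.

    Values are printed with 12 significant digits so that
    ``read_recording(write_recording(r))`` reproduces the samples at that
    precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(",".join(record.channels) + "\n")
        for row in record.samples.T:
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def read_protocol(path: str | Path) -> StageProtocol:
    df = pd.read_csv(path, comment="#")
    expected = ["label", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: protocol columns must be {expected}")
    return StageProtocol([(str(r.label), float(r.start_s), float(r.end_s))
                          for r in df.itertuples()])


def write_protocol(protocol: StageProtocol, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label,start_s,end_s\n")
        for label, start, end in protocol.stages:
            fh.write(f"{label},{start:.12g},{end:.12g}\n")


def segment_stages(record: SignalRecord,
                   protocol: StageProtocol) -> dict[str, SignalRecord]:
    """Split a record into per-stage sub-records (half-open intervals).

    Each sub-record keeps the original sampling rate and gets ``t0`` equal to
    the stage start; sample counts equal ``round(fs * duration)`` for stages
    aligned to the sample grid.
    """
    out: dict[str, SignalRecord] = {}
    for label, start, end in protocol.stages:
        if end - record.t0 > record.duration + 0.5 / record.fs:
            raise ValidationError(
                f"stage {label} ends at {end} s but record lasts "
                f"{record.duration} s")
        i0 = int(round((start - record.t0) * record.fs))
        i1 = int(round((end - record.t0) * record.fs))
        out[label] = SignalRecord(
            channels=list(record.channels),
            samples=record.samples[:, i0:i1].copy(),
            fs=record.fs,
            t0=start,
        )
    return out
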