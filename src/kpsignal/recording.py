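"""Multichannel voltage recording container and CSV/WAV I/O.

The canonical on-disk form of a recording is a CSV with one header row, a
``time_s`` column (seconds, uniform sampling) and one ``ch<N>_mV`` column
per electrode channel.  A permissive (``loose``) parser accepts arbitrary
channel column names and assumes mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "VoltageRecording",
    "RecordingParseError",
    "read_recording_csv",
    "write_recording_csv",
    "read_wav",
]

_JITTER_TOL = 0.01  # relative sampling-interval jitter accepted as uniform


class RecordingParseError(ValueError):
    """Raised when a recording file violates the expected dialect."""


@dataclass
class VoltageRecording:
    """Uniformly sampled multichannel voltage series in mV.

    values is a (n_samples, n_channels) array; channels are ordered,
    uniquely labelled; fs is in samples per second (1 Hz for the
    data-logger recordings this pipeline targets).
    """

    fs: float
    channels: list[str]
    values: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.channels)} channel labels were given"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; available: {self.channels}"
            ) from None
        return self.values[:, idx]


def read_recording_csv(
    path: str | Path,
    loose: bool = False,
    resample: bool = False,
) -> VoltageRecording:
    """Read a recording CSV (``time_s, ch1_mV, ch2_mV, ...``).

    The sampling rate is inferred from the median time step; sampling with
    more than 1% interval jitter is rejected unless ``resample`` is set, in
    which case values are linearly interpolated onto a uniform grid at the
    median step.  In strict mode channel columns must carry the ``_mV``
    suffix asserting millivolt units; ``loose`` accepts any column names.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise RecordingParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise RecordingParseError(f"{path}: need a time column plus >= 1 channel")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise RecordingParseError(f"{path}: missing value at line {row}")

    time_col = df.columns[0]
    if not loose and time_col != "time_s":
        raise RecordingParseError(
            f"{path}: first column must be 'time_s', got {time_col!r}"
        )
    t = df[time_col].to_numpy(dtype=float)
    if len(t) < 2:
        raise RecordingParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise RecordingParseError(
            f"{path}: time not strictly increasing at line {bad[0] + 3}"
        )

    step = float(np.median(dt))
    channels = list(df.columns[1:])
    if not loose:
        for c in channels:
            if not c.endswith("_mV"):
                raise RecordingParseError(
                    f"{path}: channel column {c!r} must end in '_mV' "
                    "(or pass loose=True)"
                )
    values = df[channels].to_numpy(dtype=float)

    if np.max(np.abs(dt - step)) > _JITTER_TOL * step:
        if not resample:
            raise RecordingParseError(
                f"{path}: non-uniform sampling (interval jitter > 1%); "
                "pass resample=True to interpolate onto a uniform grid"
            )
        grid = np.arange(t[0], t[-1] + step / 2, step)
        values = np.column_stack([np.interp(grid, t, values[:, j])
                                  for j in range(values.shape[1])])
        t = grid

    return VoltageRecording(
        fs=1.0 / step, channels=channels, values=values, t0=float(t[0]),
        meta={"source": str(path)},
    )


def write_recording_csv(rec: VoltageRecording, path: str | Path,
                        sidecar: dict | None = None) -> None:
    """Write a recording in the canonical dialect ('.' decimals, UTF-8).

    If ``sidecar`` is given, a ``<path>.meta.json`` with the resolved run
    configuration is written next to the CSV for reproducibility.
    """
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.times})
    for j, ch in enumerate(rec.channels):
        col = ch if ch.endswith("_mV") else f"{ch}_mV"
        df[col] = rec.values[:, j]
    df.to_csv(path, index=False, float_format="%.9g")
    if sidecar is not None:
        Path(f"{path}.meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as a mono float series in [-1, 1] plus its rate.

    Integer PCM (8/16/32-bit) is scaled by its full-scale value; float data
    is passed through.  Stereo (or any multichannel) audio is averaged to
    mono.
    """
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: unsupported WAV encoding: {exc}") from exc
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        x = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        x = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        x = data.astype(float)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return x, int(rate)
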