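"""Core containers for E-nose recordings and the three-way data tensor.

A *recording* is one fish measured in the chamber: a time axis (minutes),
a matrix of baseline-normalised sensor responses (rows = time instances,
columns = the 35 MQ sensor variables), the fishing-gear label of the sample
and its biological replicate id.  The three-way tensor stacks one matrix per
gear along a third axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MQ_MODULES",
    "CHANNEL_NAMES",
    "DEFAULT_GEAR_LABELS",
    "GearRecording",
    "DataTensor",
    "RecordingFormatError",
    "channels_for_modules",
    "write_recording_csv",
    "read_recording_csv",
    "recording_filename",
    "read_recording_dir",
]

# Analyte sensitivities of each MQ sensor module; 7 modules x 5 analytes = 35
# sensor variables.  Column names are "<module>_<analyte>", e.g. "MQ4_CO".
MQ_MODULES: dict[str, tuple[str, ...]] = {
    "MQ2": ("Hydrogen", "LPG", "CO", "Alcohol", "Propane"),
    "MQ3": ("LPG", "CO", "Alcohol", "Benzene", "Hexane"),
    "MQ4": ("LPG", "CH4", "CO", "Alcohol", "Smoke"),
    "MQ5": ("Hydrogen", "LPG", "CH4", "CO", "Alcohol"),
    "MQ6": ("Hydrogen", "LPG", "CH4", "CO", "Alcohol"),
    "MQ7": ("Hydrogen", "LPG", "CH4", "CO", "Alcohol"),
    "MQ8": ("Hydrogen", "LPG", "CH4", "CO", "Alcohol"),
}

CHANNEL_NAMES: list[str] = [
    f"{mod}_{analyte}" for mod, analytes in MQ_MODULES.items() for analyte in analytes
]

# The eight acquisition methods, ordered from lowest to highest expected
# deviation from the basal volatile profile.
DEFAULT_GEAR_LABELS: list[str] = [
    "Longline",
    "Hook and line",
    "Gillnet (two panels)",
    "Gillnet (single panel)",
    "Gillnet (three panels)",
    "Trawl",
    "Purse seine",
    "Aquaculture",
]

TIME_COLUMN = "time_min"


class RecordingFormatError(ValueError):
    """Raised when a recording CSV is structurally malformed."""


def _normalize_module(name: str) -> str:
    """Accept 'MQ-4', 'mq4', 'MQ 4' ... and return the canonical 'MQ4'."""
    canon = re.sub(r"[\s\-_]", "", name).upper()
    if canon not in MQ_MODULES:
        raise KeyError(
            f"unknown sensor module {name!r}; valid modules: {sorted(MQ_MODULES)}"
        )
    return canon


def channels_for_modules(modules: list[str]) -> list[str]:
    """Channel names (5 analytes each) for the requested MQ modules."""
    if not modules:
        raise ValueError("at least one sensor module must be requested")
    out: list[str] = []
    for m in modules:
        canon = _normalize_module(m)
        out.extend(f"{canon}_{a}" for a in MQ_MODULES[canon])
    return out


@dataclass
class GearRecording:
    """One E-nose recording of a single fish.

    ``values`` may contain NaN before preprocessing; afterwards it is complete
    and ``imputed_mask`` marks every cell that was filled in (originally
    missing or treated as an outlier).
    """

    gear: str
    replicate: int
    times: np.ndarray  # [I] minutes
    values: np.ndarray  # [I x J]
    channels: list[str]
    imputed_mask: np.ndarray | None = None
    # bookkeeping from the synthetic generator: (row, col) index arrays
    injected_missing: np.ndarray | None = field(default=None, repr=False)
    injected_outliers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (time x channel)")
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"time axis length {self.times.shape[0]} does not match "
                f"{self.values.shape[0]} rows of values"
            )
        if len(self.channels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.values, dtype=np.int8)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=np.int8)
            if self.imputed_mask.shape != self.values.shape:
                raise ValueError("imputed_mask shape must equal values shape")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class DataTensor:
    """Three-way array X (time x sensor variable x gear) with axis labels."""

    values: np.ndarray  # [I x J x K]
    time_labels: np.ndarray
    channel_labels: list[str]
    gear_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be three-way (I x J x K)")
        i, j, k = self.values.shape
        self.time_labels = np.asarray(self.time_labels, dtype=float)
        if len(self.time_labels) != i:
            raise ValueError("time_labels length mismatch")
        if len(self.channel_labels) != j:
            raise ValueError("channel_labels length mismatch")
        if len(self.gear_labels) != k:
            raise ValueError("gear_labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor entries must be finite (preprocess first)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def recording_filename(gear: str, replicate: int) -> str:
    return f"{gear}__rep{replicate}.csv"


def write_recording_csv(recording: GearRecording, path: str | Path) -> None:
    """Write one recording as CSV: column 1 ``time_min``, then one column per
    channel.  Missing cells are serialized as empty fields."""
    df = pd.DataFrame(recording.values, columns=recording.channels)
    df.insert(0, TIME_COLUMN, recording.times)
    df.to_csv(path, index=False, na_rep="")


def read_recording_csv(
    path: str | Path,
    gear: str | None = None,
    replicate: int | None = None,
) -> GearRecording:
    """Read a recording CSV.

    Non-numeric cells are coerced to NaN (missing).  Gear and replicate are
    parsed from a ``<gear>__rep<k>.csv`` filename when not given explicitly.
    """
    path = Path(path)
    if gear is None or replicate is None:
        m = re.match(r"(?P<gear>.+)__rep(?P<rep>\d+)$", path.stem)
        if m:
            gear = gear if gear is not None else m.group("gear")
            replicate = replicate if replicate is not None else int(m.group("rep"))
        else:
            gear = gear if gear is not None else path.stem
            replicate = replicate if replicate is not None else 0
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise RecordingFormatError(f"{path}: empty file is not a recording") from exc
    except pd.errors.ParserError as exc:
        raise RecordingFormatError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != TIME_COLUMN:
        raise RecordingFormatError(
            f"{path}: header must start with '{TIME_COLUMN}' followed by at "
            f"least one channel column (got {list(df.columns[:3])}...)"
        )
    times = pd.to_numeric(df[TIME_COLUMN], errors="coerce").to_numpy()
    if np.isnan(times).any():
        bad = int(np.flatnonzero(np.isnan(times))[0]) + 2  # +header +1-based
        raise RecordingFormatError(f"{path}: non-numeric time value at line {bad}")
    channels = list(df.columns[1:])
    values = (
        df[channels].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    )
    return GearRecording(
        gear=gear, replicate=replicate, times=times, values=values, channels=channels
    )


def read_recording_dir(directory: str | Path) -> list[GearRecording]:
    """Read every ``*.csv`` recording in a directory (mask files excluded)."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.glob("*.csv") if not p.stem.endswith("__mask")
    )
    if not paths:
        raise RecordingFormatError(f"no recording CSVs found in {directory}")
    return [read_recording_csv(p) for p in paths]
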