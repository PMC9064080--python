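"""Force-plate recordings: file I/O and center-of-pressure computation.

A recording holds the six synchronized channels of a strain-gauge force
platform — ground-reaction forces (Fx, Fy, Fz, in N) and moments about the
plate origin (Mx, My, Mz, in N*m) — sampled at a fixed rate.  For a plate
whose origin lies in its top surface the center of pressure (COP) of a
single supporting body is

    cop_x = -My / Fz,      cop_y = Mx / Fz        (meters)

the standard flat-plate convention with the vertical moment-arm correction
omitted.  By default the plate y axis is reported as the anterior-posterior
(AP) sway direction and the x axis as medio-lateral (ML); stances that are
rotated on the plate can be remapped with ``axis_rotation_deg``.

File dialect: plain CSV with ``#``-prefixed header lines declaring the
sampling rate (``# fs=50``) and optionally the trial metadata, followed by a
named-column table ``fx,fy,fz,mx,my,mz``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParseError, UnloadedPlateError

CHANNELS = ("fx", "fy", "fz", "mx", "my", "mz")

#: Minimum |Fz| (N) below which the plate is considered unloaded.  Body
#: weight is two orders of magnitude larger, so any excursion below this is
#: a data defect, not sway.
FZ_MIN_DEFAULT = 10.0


class Group(str, Enum):
    """Experimental group: untrained controls, shooting-trained beginners,
    national-level biathletes."""

    CONTROL = "control"
    BEGINNER = "beginner"
    BIATHLETE = "biathlete"


class Task(str, Enum):
    """Balance task: quiet standing, shooting position (internal focus),
    aiming at target (external focus)."""

    QS = "QS"
    SP = "SP"
    AT = "AT"


class Direction(str, Enum):
    """Sway direction: anterior-posterior or medio-lateral."""

    AP = "AP"
    ML = "ML"


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial: who, which group, which task, which repeat."""

    subject_id: str
    group: Group
    task: Task
    repeat_index: int

    def __post_init__(self):
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "task", Task(self.task))
        if self.repeat_index not in (1, 2, 3):
            raise ValueError(f"repeat_index must be in {{1,2,3}}, got {self.repeat_index}")


def _as_channel(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"channel {name} must be one-dimensional")
    return arr


@dataclass
class ForcePlateRecording:
    """Six synchronized force/moment channels plus sampling rate and metadata.

    All channels must have identical length >= 2.  ``duration``, when given,
    must be consistent with ``len == round(fs * duration)``.
    """

    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    fs: float
    meta: TrialMeta | None = None
    duration: float | None = None

    def __post_init__(self):
        for name in CHANNELS:
            setattr(self, name, _as_channel(name, getattr(self, name)))
        lengths = {len(getattr(self, name)) for name in CHANNELS}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n < 2:
            raise ValueError(f"channels must have length >= 2, got {n}")
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.duration is not None and n != round(self.fs * self.duration):
            raise ValueError(
                f"length {n} inconsistent with fs={self.fs} Hz x duration={self.duration} s"
            )
        if self.duration is None:
            self.duration = n / self.fs

    def __len__(self) -> int:
        return len(self.fz)

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def with_channels(self, **kwargs) -> "ForcePlateRecording":
        """Copy of this recording with some channels replaced."""
        return replace(self, **kwargs)


@dataclass
class COPTrajectory:
    """Center-of-pressure position series (meters) in AP and ML directions."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float
    meta: TrialMeta | None = None

    def __post_init__(self):
        self.ap = _as_channel("ap", self.ap)
        self.ml = _as_channel("ml", self.ml)
        if len(self.ap) != len(self.ml):
            raise ValueError("ap and ml series must have equal length")
        if not (np.isfinite(self.ap).all() and np.isfinite(self.ml).all()):
            raise ValueError("COP trajectory contains non-finite values")

    def __len__(self) -> int:
        return len(self.ap)


# ---------------------------------------------------------------------------
# COP computation
# ---------------------------------------------------------------------------

def compute_cop(
    rec: ForcePlateRecording,
    fz_min: float = FZ_MIN_DEFAULT,
    axis_rotation_deg: float = 0.0,
) -> COPTrajectory:
    """Compute the COP trajectory from forces and moments.

    Parameters
    ----------
    rec
        Validated force-plate recording.
    fz_min
        Guard threshold (N): every sample must satisfy ``|fz| > fz_min``.
    axis_rotation_deg
        Rotate the plate (x, y) frame by this angle before mapping
        y -> AP, x -> ML.  Use 90 for stances turned a quarter turn on the
        plate (e.g. a shooting stance side-on to a target placed along the
        plate's y axis).

    Raises
    ------
    UnloadedPlateError
        If any sample has ``|fz| <= fz_min`` (reports the first one).
    """
    bad = np.flatnonzero(np.abs(rec.fz) <= fz_min)
    if bad.size:
        i = int(bad[0])
        raise UnloadedPlateError(i, float(rec.fz[i]), fz_min)
    cop_x = -rec.my / rec.fz
    cop_y = rec.mx / rec.fz
    if axis_rotation_deg:
        theta = math.radians(axis_rotation_deg)
        c, s = math.cos(theta), math.sin(theta)
        cop_x, cop_y = c * cop_x - s * cop_y, s * cop_x + c * cop_y
    return COPTrajectory(ap=cop_y, ml=cop_x, fs=rec.fs, meta=rec.meta)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _meta_header(meta: TrialMeta) -> str:
    return (
        f"# subject={meta.subject_id} group={meta.group.value} "
        f"task={meta.task.value} repeat={meta.repeat_index}"
    )


def write_recording(rec: ForcePlateRecording, path) -> None:
    """Write a recording in the package's CSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        if rec.meta is not None:
            fh.write(_meta_header(rec.meta) + "\n")
        pd.DataFrame(rec.channels()).to_csv(fh, index=False, float_format="%.9g")


def _parse_header(lines: list[str]) -> tuple[float | None, TrialMeta | None]:
    fs = None
    meta_kv: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        for token in body.split():
            if "=" not in token:
                continue
            key, _, value = token.partition("=")
            if key == "fs":
                try:
                    fs = float(value)
                except ValueError as exc:
                    raise ParseError(f"cannot parse sampling rate {value!r}") from exc
            else:
                meta_kv[key] = value
    meta = None
    if {"subject", "group", "task", "repeat"} <= meta_kv.keys():
        meta = TrialMeta(
            subject_id=meta_kv["subject"],
            group=meta_kv["group"],
            task=meta_kv["task"],
            repeat_index=int(meta_kv["repeat"]),
        )
    return fs, meta


def read_recording(path, meta: TrialMeta | None = None) -> ForcePlateRecording:
    """Read a recording from the CSV dialect.

    ``meta`` overrides any metadata found in the file header.  The sampling
    rate must be declared in the header (``# fs=<Hz>``).
    """
    path = Path(path)
    header_lines: list[str] = []
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            (header_lines if line.startswith("#") else data_lines).append(line)
    fs, file_meta = _parse_header(header_lines)
    if fs is None:
        raise ConfigError(f"{path}: no '# fs=<Hz>' header line found")
    table = pd.read_csv(io.StringIO("".join(data_lines)))
    table.columns = [c.strip().lower() for c in table.columns]
    for name in CHANNELS:
        if name not in table.columns:
            raise FormatError(f"{path}: channel {name} missing")
    numeric = {}
    for name in CHANNELS:
        col = pd.to_numeric(table[name], errors="coerce")
        bad = col.isna() & table[name].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2 + len(header_lines)  # 1-based file line
            raise ParseError(
                f"{path}: non-numeric value {table[name][bad.idxmax()]!r} "
                f"in channel {name} at line {row}"
            )
        if col.isna().any():
            row = int(col.isna().idxmax()) + 2 + len(header_lines)
            raise ParseError(f"{path}: empty cell in channel {name} at line {row}")
        numeric[name] = col.to_numpy()
    return ForcePlateRecording(fs=fs, meta=meta or file_meta, **numeric)


def write_cop(cop: COPTrajectory, path) -> None:
    """Write a COP trajectory as a two-column (ap, ml) CSV with metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={cop.fs:g}\n")
        if cop.meta is not None:
            fh.write(_meta_header(cop.meta) + "\n")
        pd.DataFrame({"ap": cop.ap, "ml": cop.ml}).to_csv(fh, index=False, float_format="%.9g")


def read_cop(path) -> COPTrajectory:
    """Read a COP trajectory written by :func:`write_cop`."""
    path = Path(path)
    header_lines: list[str] = []
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            (header_lines if line.startswith("#") else data_lines).append(line)
    fs, meta = _parse_header(header_lines)
    if fs is None:
        raise ConfigError(f"{path}: no '# fs=<Hz>' header line found")
    table = pd.read_csv(io.StringIO("".join(data_lines)))
    return COPTrajectory(ap=table["ap"].to_numpy(), ml=table["ml"].to_numpy(), fs=fs, meta=meta)


# ---------------------------------------------------------------------------
# XLSX adapter (long format)
# ---------------------------------------------------------------------------

def read_recordings_xlsx(path, fs: float | None = None) -> list[ForcePlateRecording]:
    """Read recordings from an XLSX workbook.

    Two layouts are auto-detected per sheet:

    * long format — columns ``subject, group, task, repeat, fx..mz`` with one
      row per sample, samples in file order;
    * single trial — just the six channel columns, metadata taken from the
      sheet name ``<subject>_<group>_<task>_<repeat>``.

    ``fs`` must be supplied because XLSX carries no sampling-rate header.
    """
    if fs is None:
        raise ConfigError("fs must be given when reading XLSX (no header line)")
    sheets = pd.read_excel(path, sheet_name=None)
    out: list[ForcePlateRecording] = []
    for sheet_name, table in sheets.items():
        table.columns = [str(c).strip().lower() for c in table.columns]
        missing = [c for c in CHANNELS if c not in table.columns]
        if missing:
            raise FormatError(f"{path}[{sheet_name}]: channel {missing[0]} missing")
        if {"subject", "group", "task", "repeat"} <= set(table.columns):
            keys = ["subject", "group", "task", "repeat"]
            for (subj, group, task, rep), block in table.groupby(keys, sort=False):
                meta = TrialMeta(str(subj), str(group), str(task), int(rep))
                out.append(
                    ForcePlateRecording(
                        fs=fs, meta=meta, **{c: block[c].to_numpy() for c in CHANNELS}
                    )
                )
        else:
            parts = sheet_name.split("_")
            meta = None
            if len(parts) == 4:
                meta = TrialMeta(parts[0], parts[1], parts[2], int(parts[3]))
            out.append(
                ForcePlateRecording(
                    fs=fs, meta=meta, **{c: table[c].to_numpy() for c in CHANNELS}
                )
            )
    return out
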