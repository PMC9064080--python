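"""Signal conditioning: low-pass filtering and the COP increment series.

The processing order mirrors standard stabilometric practice: the six raw
force/moment channels are low-pass filtered first (4th-order Butterworth,
7 Hz cutoff by default), COP is computed from the filtered channels, and the
first difference of each COP component — the displacement increment series —
is what the entropy analysis consumes.

The filter is applied forward-backward (zero phase) by default so the
increments are not phase-distorted; a single-pass option is available.  Edge
effects are controlled by odd-symmetric padding of length 3*(order+1),
which makes results deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError, LengthError
from .forceplate_io import Direction, ForcePlateRecording, compute_cop


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    order
        Filter order (per pass); default 4.
    cutoff_hz
        -3 dB cutoff frequency; must lie strictly below the Nyquist rate.
    zero_phase
        Apply forward-backward (``filtfilt``); doubles the effective
        attenuation in dB and removes phase lag.
    """

    order: int = 4
    cutoff_hz: float = 7.0
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1 or int(self.order) != self.order:
            raise ConfigError(f"filter order must be a positive integer, got {self.order}")
        if not self.cutoff_hz > 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff_hz}")

    def validate_against(self, fs: float) -> None:
        if not self.cutoff_hz < fs / 2:
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist ({fs / 2:g} Hz at fs={fs:g})"
            )


@dataclass
class IncrementSeries:
    """First-difference series of one COP component (meters per sample step)."""

    values: np.ndarray
    direction: Direction

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.direction = Direction(self.direction)

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)


def butterworth_lowpass(series, spec: FilterSpec, fs: float) -> np.ndarray:
    """Low-pass filter a series; same length out, unit DC gain."""
    spec.validate_against(fs)
    x = np.asarray(series, dtype=float)
    padlen = 3 * (spec.order + 1)
    if len(x) <= max(3 * spec.order, padlen):
        raise LengthError(
            f"series of length {len(x)} too short for order-{spec.order} filtering "
            f"(needs > {max(3 * spec.order, padlen)})"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)
    padded = np.concatenate([2 * x[0] - x[padlen:0:-1], x])  # odd extension at the start
    return signal.sosfilt(sos, padded)[padlen:]


def increments(series) -> np.ndarray:
    """First difference: out[i] = in[i+1] - in[i]; length n-1."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise LengthError(f"need at least 2 samples to difference, got {len(x)}")
    return np.diff(x)


def preprocess_trial(
    rec: ForcePlateRecording,
    spec: FilterSpec = FilterSpec(),
    filter_target: str = "channels",
    fz_min: float | None = None,
    axis_rotation_deg: float = 0.0,
) -> tuple[IncrementSeries, IncrementSeries]:
    """Run filter -> COP -> increments for one trial.

    ``filter_target`` selects whether the six raw channels are filtered
    before the COP computation (default, matching the stated processing
    order) or the COP components are filtered afterwards (``"cop"``, for
    sensitivity analysis).

    Returns the (AP, ML) increment series; for a 30 s trial at 50 Hz each
    has 1499 samples.
    """
    if filter_target not in ("channels", "cop"):
        raise ConfigError(f"filter_target must be 'channels' or 'cop', got {filter_target!r}")
    kwargs = {} if fz_min is None else {"fz_min": fz_min}
    if filter_target == "channels":
        filtered = rec.with_channels(
            **{
                name: butterworth_lowpass(chan, spec, rec.fs)
                for name, chan in rec.channels().items()
            }
        )
        cop = compute_cop(filtered, axis_rotation_deg=axis_rotation_deg, **kwargs)
        ap, ml = cop.ap, cop.ml
    else:
        cop = compute_cop(rec, axis_rotation_deg=axis_rotation_deg, **kwargs)
        ap = butterworth_lowpass(cop.ap, spec, rec.fs)
        ml = butterworth_lowpass(cop.ml, spec, rec.fs)
    return (
        IncrementSeries(increments(ap), Direction.AP),
        IncrementSeries(increments(ml), Direction.ML),
    )
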