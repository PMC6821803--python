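"""Canonical data model for multi-well MEA recordings and patch-clamp sweeps.

All times are seconds, zero-based from recording start. All rates are stored
in Hz; per-minute display conventions (e.g. network-burst rate) live in the
reporting layer. A missing electrode is represented by absence from the well;
an electrode that was recorded but silent is an explicit empty train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) for one electrode over a fixed recording duration."""

    electrode_id: str
    well_id: str
    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = _as_float_array(self.spike_times)
        object.__setattr__(self, "spike_times", times)
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if times.ndim != 1:
            raise ValidationError("spike_times must be one-dimensional")
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValidationError("spike_times must be finite")
            if np.any(np.diff(times) <= 0):
                raise ValidationError("spike_times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValidationError(
                    f"spike times must lie in [0, {self.duration}] s "
                    f"(electrode {self.electrode_id})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def firing_rate(self) -> float:
        """Spike count divided by recording duration (Hz)."""
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals (s); empty for fewer than two spikes."""
        return np.diff(self.spike_times)


@dataclass
class WellRecording:
    """All spike trains of one MEA well recorded simultaneously.

    The default layout is the 24-well system used throughout: 12 extracellular
    electrodes per well, each treated as a multi-unit channel.
    """

    well_id: str
    trains: list[SpikeTrain] = field(default_factory=list)
    group_label: str = ""
    div: int = 0
    n_electrodes: int = 12

    def __post_init__(self) -> None:
        ids = [t.electrode_id for t in self.trains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate electrode ids in well {self.well_id}")
        if len(self.trains) > self.n_electrodes:
            raise ValidationError(
                f"well {self.well_id} has {len(self.trains)} trains for "
                f"{self.n_electrodes} electrodes"
            )
        durations = {t.duration for t in self.trains}
        if len(durations) > 1:
            raise ValidationError(f"trains in well {self.well_id} differ in duration")

    @property
    def duration(self) -> float:
        if not self.trains:
            raise ValidationError(f"well {self.well_id} has no trains")
        return self.trains[0].duration

    def train(self, electrode_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.electrode_id == electrode_id:
                return t
        raise KeyError(electrode_id)


@dataclass
class PlateRecording:
    """A set of simultaneously recorded wells (one multi-well MEA plate)."""

    wells: list[WellRecording] = field(default_factory=list)
    plate_id: str = "plate"
    recorded_minutes: float = 20.0

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate well ids on plate")

    def well(self, well_id: str) -> WellRecording:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)


@dataclass(frozen=True)
class RawTrace:
    """Raw extracellular voltage samples (µV) from one electrode."""

    electrode_id: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = _as_float_array(self.samples)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("raw samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class Sweep:
    """One patch-clamp sweep: current (pA) or voltage (mV) samples vs time."""

    samples: np.ndarray
    sampling_rate: float
    stim_time: float
    holding_potential: float = float("nan")

    def __post_init__(self) -> None:
        samples = _as_float_array(self.samples)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if not 0 <= self.stim_time <= samples.size / self.sampling_rate:
            raise ValidationError("stim_time must lie within the sweep")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def window(self, start: float, stop: float) -> np.ndarray:
        """Samples with start <= t < stop (seconds from sweep start)."""
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(stop * self.sampling_rate - 1e-9))
        return self.samples[max(i0, 0):max(i1, 0)]
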