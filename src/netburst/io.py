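"""Readers and writers for the package's on-disk formats.

Spike tables are plain tab-separated text, one spike per row with columns
``well_id``, ``electrode_id``, ``spike_time_s`` (seconds, six decimals), so
fixtures stay human-diffable. Raw traces and patch-clamp sweeps live in an
HDF5 container, one dataset per electrode/sweep with the acquisition metadata
as attributes. These are repository conventions mirroring common MEA export
formats, not any vendor's binary layout.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import PlateRecording, RawTrace, SpikeTrain, Sweep, ValidationError

SPIKE_COLUMNS = ("well_id", "electrode_id", "spike_time_s")


class FormatError(ValueError):
    """Raised for malformed on-disk inputs."""


def read_spike_table(path: str | Path, duration: float, *, plate_id: str = "plate") -> PlateRecording:
    """Read a TSV spike table into a :class:`PlateRecording`.

    Every (well, electrode) pair present in the file yields one
    :class:`SpikeTrain`; wells with no rows are simply absent. Spike times are
    validated against ``[0, duration]`` and sorted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"well_id": str, "electrode_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: malformed spike table: {exc}") from exc
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna() | (df["well_id"].isna()) | (df["electrode_id"].isna())
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}: malformed row at line {line}")
    df = df.assign(spike_time_s=times)
    if ((times < 0) | (times > duration)).any():
        t = float(times[(times < 0) | (times > duration)].iloc[0])
        raise ValidationError(
            f"{path}: spike time {t} s outside [0, {duration}] s"
        )

    from .core import WellRecording  # local import to avoid cycle on type checkers

    wells = []
    for well_id, wdf in df.groupby("well_id", sort=True):
        trains = []
        for electrode_id, edf in wdf.groupby("electrode_id", sort=True):
            # µs-resolution text can collapse near-coincident spikes onto one
            # timestamp; keep a single event per timestamp
            t = np.unique(edf["spike_time_s"].to_numpy())
            trains.append(SpikeTrain(str(electrode_id), str(well_id), t, duration))
        n_electrodes = max(12, len(trains))
        wells.append(WellRecording(str(well_id), trains, n_electrodes=n_electrodes))
    return PlateRecording(wells, plate_id=plate_id, recorded_minutes=duration / 60.0)


def write_spike_table(plate: PlateRecording, path: str | Path) -> None:
    """Write a plate as a TSV spike table with deterministic row order.

    Rows are sorted by (well_id, electrode_id, spike time); times are printed
    with six decimals (µs resolution), which bounds round-trip error at 1e-6 s.
    """
    rows = []
    for well in sorted(plate.wells, key=lambda w: w.well_id):
        for train in sorted(well.trains, key=lambda t: t.electrode_id):
            for t in train.spike_times:
                rows.append((well.well_id, train.electrode_id, f"{t:.6f}"))
    df = pd.DataFrame(rows, columns=list(SPIKE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def write_raw_recording(traces: list[RawTrace], path: str | Path) -> None:
    """Write raw traces to an HDF5 container (one dataset per electrode)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for trace in traces:
            ds = grp.create_dataset(trace.electrode_id, data=trace.samples)
            ds.attrs["sampling_rate"] = trace.sampling_rate
            ds.attrs["electrode_id"] = trace.electrode_id
            ds.attrs["units"] = "uV"


def read_raw_recording(path: str | Path) -> list[RawTrace]:
    """Read raw traces back from the HDF5 container, µV units preserved."""
    traces = []
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise FormatError(f"{path}: missing 'traces' group")
        for name, ds in f["traces"].items():
            if "sampling_rate" not in ds.attrs:
                raise FormatError(f"{path}: trace {name} lacks sampling_rate attribute")
            traces.append(
                RawTrace(
                    electrode_id=str(ds.attrs.get("electrode_id", name)),
                    samples=ds[...],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                )
            )
    return sorted(traces, key=lambda t: t.electrode_id)


def write_sweeps(sweeps: list[Sweep], path: str | Path, *, group: str = "sweeps") -> None:
    """Write patch-clamp sweeps to the HDF5 container."""
    with h5py.File(path, "w") as f:
        grp = f.create_group(group)
        for i, sweep in enumerate(sweeps):
            ds = grp.create_dataset(f"sweep_{i:04d}", data=sweep.samples)
            ds.attrs["sampling_rate"] = sweep.sampling_rate
            ds.attrs["stim_time"] = sweep.stim_time
            ds.attrs["holding_potential"] = sweep.holding_potential


def read_sweeps(path: str | Path, *, group: str = "sweeps") -> list[Sweep]:
    sweeps = []
    with h5py.File(path, "r") as f:
        if group not in f:
            raise FormatError(f"{path}: missing '{group}' group")
        for name in sorted(f[group]):
            ds = f[group][name]
            for attr in ("sampling_rate", "stim_time"):
                if attr not in ds.attrs:
                    raise FormatError(f"{path}: sweep {name} lacks {attr} attribute")
            sweeps.append(
                Sweep(
                    samples=ds[...],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    stim_time=float(ds.attrs["stim_time"]),
                    holding_potential=float(ds.attrs.get("holding_potential", np.nan)),
                )
            )
    return sweeps
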