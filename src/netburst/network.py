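"""Network-burst detection and the well-level metric vector.

A network burst is a population event in which single-channel bursts occur on
strictly more than 80% of a well's *active* channels. Detection pools the
channel bursts of all active electrodes, merges bursts that overlap or fall
within a small gap of one another into candidate events (transitive closure),
and accepts a candidate iff its distinct participating channels exceed the
participation fraction.

The well-level feature vector used for phenotype discrimination is:
mean firing rate (MFR, Hz, averaged over active electrodes), network-burst
rate (per minute), mean network-burst duration (NBD, s), mean network
inter-burst interval (NIBI, s, end of one burst to start of the next), the
CV of the NIBI (SD/mean, the irregularity measure), and the percentage of
spikes outside network bursts. Undefined quantities (no active electrodes,
fewer than two network bursts) are NaN sentinels, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bursts import Burst, BurstParams, detect_bursts_logisi
from .core import SpikeTrain, ValidationError, WellRecording


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    channels: frozenset[str]
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("network burst must have end > start")
        if not self.channels:
            raise ValidationError("network burst must have participating channels")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NetworkMetrics:
    """The per-well feature vector reported by the pipeline."""

    well_id: str
    mfr: float  # Hz, mean over active electrodes
    nb_rate: float  # network bursts per minute
    mean_nbd: float  # s
    mean_nibi: float  # s
    cv_nibi: float  # dimensionless
    pct_outside: float  # percent of active-electrode spikes outside NBs
    n_active: int
    n_network_bursts: int = 0
    group_label: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "well_id": self.well_id,
            "group_label": self.group_label,
            "mfr": self.mfr,
            "nb_rate": self.nb_rate,
            "mean_nbd": self.mean_nbd,
            "mean_nibi": self.mean_nibi,
            "cv_nibi": self.cv_nibi,
            "pct_outside": self.pct_outside,
            "n_active": self.n_active,
            "n_network_bursts": self.n_network_bursts,
        }


#: feature columns entering the discriminant analysis
FEATURE_COLUMNS = ("mfr", "nb_rate", "mean_nbd", "pct_outside", "cv_nibi")


@dataclass(frozen=True)
class NetworkParams:
    """Knobs of the well-level analysis chain."""

    burst: BurstParams = field(default_factory=BurstParams)
    min_rate: float = 0.1  # Hz; active-electrode threshold, inclusive
    participation: float = 0.8  # NB needs strictly more than this fraction
    merge_gap: float = 0.1  # s; "closely spaced" channel bursts


def active_electrodes(well: WellRecording, min_rate: float = 0.1) -> set[str]:
    """Electrodes whose firing rate reaches ``min_rate`` (inclusive)."""
    if min_rate < 0:
        raise ValidationError("min_rate must be >= 0")
    return {t.electrode_id for t in well.trains if t.firing_rate >= min_rate}


def mean_firing_rate(well: WellRecording, active: set[str]) -> float:
    """Arithmetic mean firing rate (Hz) over the active electrodes.

    NaN sentinel (with a warning) when no electrode is active — a silent well
    has no defined MFR, it is not a zero-rate well.
    """
    if not active:
        warnings.warn(f"well {well.well_id}: no active electrodes, MFR undefined", stacklevel=2)
        return float("nan")
    rates = [t.firing_rate for t in well.trains if t.electrode_id in active]
    return float(np.mean(rates))


def detect_network_bursts(
    channel_bursts: dict[str, list[Burst]],
    active: set[str],
    participation: float = 0.8,
    merge_gap: float = 0.1,
) -> list[NetworkBurst]:
    """Merge closely spaced channel bursts and keep >80%-participation events.

    Bursts on active channels are pooled and sorted; bursts whose intervals
    overlap or whose gap is at most ``merge_gap`` are chained into one
    candidate event (transitive closure). A candidate becomes a network burst
    iff its distinct channels number strictly more than
    ``participation × |active|``.
    """
    if len(active) < 2:
        warnings.warn("fewer than 2 active channels: no network bursts", stacklevel=2)
        return []
    pooled = sorted(
        (b for ch, bs in channel_bursts.items() if ch in active for b in bs),
        key=lambda b: (b.start, b.end),
    )
    if not pooled:
        return []
    need = participation * len(active)
    events: list[NetworkBurst] = []
    members: list[Burst] = [pooled[0]]
    cluster_end = pooled[0].end

    def flush() -> None:
        channels = frozenset(b.electrode_id for b in members)
        if len(channels) > need:
            events.append(
                NetworkBurst(
                    start=min(b.start for b in members),
                    end=max(b.end for b in members),
                    channels=channels,
                    n_spikes=sum(b.n_spikes for b in members),
                )
            )

    for b in pooled[1:]:
        if b.start - cluster_end <= merge_gap:
            members.append(b)
            cluster_end = max(cluster_end, b.end)
        else:
            flush()
            members = [b]
            cluster_end = b.end
    flush()
    return events


def network_burst_stats(
    nbs: list[NetworkBurst],
    duration: float,
    nbd_bin: float = 0.1,
    nibi_bin: float = 1.0,
) -> dict:
    """Rate, duration, and inter-burst-interval statistics of the NB train.

    NBD is end − start per burst (histogram bin 100 ms); NIBI is the gap from
    the end of one burst to the start of the next (histogram bin 1 s). With
    fewer than two bursts the NIBI statistics are NaN.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    nbs = sorted(nbs, key=lambda nb: nb.start)
    nbds = np.array([nb.duration for nb in nbs])
    nibis = (
        np.array([nbs[i + 1].start - nbs[i].end for i in range(len(nbs) - 1)])
        if len(nbs) >= 2
        else np.empty(0)
    )
    out = {
        "nb_rate": len(nbs) * 60.0 / duration,
        "nbds": nbds,
        "nibis": nibis,
        "mean_nbd": float(np.mean(nbds)) if nbds.size else float("nan"),
        "sd_nbd": float(np.std(nbds)) if nbds.size else float("nan"),
        "mean_nibi": float(np.mean(nibis)) if nibis.size else float("nan"),
        "sd_nibi": float(np.std(nibis)) if nibis.size else float("nan"),
    }
    for key, values, width in (("nbd_hist", nbds, nbd_bin), ("nibi_hist", nibis, nibi_bin)):
        if values.size:
            edges = np.arange(0.0, values.max() + 2 * width, width)
            counts, _ = np.histogram(values, bins=edges)
        else:
            edges, counts = np.zeros(1), np.zeros(0, dtype=int)
        out[key] = (counts, edges)
    return out


def cv_nibi(nibis: np.ndarray | list[float]) -> float:
    """CV of the network inter-burst intervals: population SD over mean.

    NaN sentinel for fewer than two intervals or a non-positive mean.
    """
    nibis = np.asarray(nibis, dtype=float)
    if nibis.size < 2:
        return float("nan")
    mean = nibis.mean()
    if mean <= 0:
        return float("nan")
    return float(nibis.std() / mean)


def spikes_in_network_bursts(train: SpikeTrain, nbs: list[NetworkBurst]) -> int:
    """Count of the train's spikes inside any closed NB window [start, end]."""
    if not nbs:
        return 0
    t = train.spike_times
    inside = np.zeros(t.size, dtype=bool)
    for nb in nbs:
        inside |= (t >= nb.start) & (t <= nb.end)
    return int(inside.sum())


def pct_spikes_outside(
    well: WellRecording, active: set[str], nbs: list[NetworkBurst]
) -> float:
    """Percentage of active-electrode spikes falling outside every NB window."""
    total = 0
    inside = 0
    for train in well.trains:
        if train.electrode_id not in active:
            continue
        total += train.n_spikes
        inside += spikes_in_network_bursts(train, nbs)
    if total == 0:
        return float("nan")
    return 100.0 * (total - inside) / total


def summarize_well(well: WellRecording, params: NetworkParams = NetworkParams()) -> NetworkMetrics:
    """Run the full chain on one well and return its metric vector.

    Deterministic given the well and parameters: logISI burst detection per
    channel, active-electrode selection, network-burst detection, then the
    six discriminant features. NaN sentinels propagate from the individual
    statistics.
    """
    active = active_electrodes(well, params.min_rate)
    channel_bursts = {
        t.electrode_id: detect_bursts_logisi(t, params.burst)[0]
        for t in well.trains
        if t.electrode_id in active
    }
    if len(active) >= 2:
        nbs = detect_network_bursts(
            channel_bursts, active, params.participation, params.merge_gap
        )
    else:
        nbs = []
    duration = well.duration if well.trains else 0.0
    stats = network_burst_stats(nbs, duration) if duration > 0 else {
        "nb_rate": float("nan"), "mean_nbd": float("nan"),
        "mean_nibi": float("nan"), "nibis": np.empty(0),
    }
    return NetworkMetrics(
        well_id=well.well_id,
        mfr=mean_firing_rate(well, active) if active else float("nan"),
        nb_rate=stats["nb_rate"],
        mean_nbd=stats["mean_nbd"],
        mean_nibi=stats["mean_nibi"],
        cv_nibi=cv_nibi(stats["nibis"]),
        pct_outside=pct_spikes_outside(well, active, nbs) if active else float("nan"),
        n_active=len(active),
        n_network_bursts=len(nbs),
        group_label=well.group_label,
    )


def summarize_plate(plate, params: NetworkParams = NetworkParams()):
    """Metric vectors for every well, as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([summarize_well(w, params).as_dict() for w in plate.wells])
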