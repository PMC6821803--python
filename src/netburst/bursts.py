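"""Single-channel burst detection via the logarithmic ISI histogram.

A burst is a run of spikes whose inter-spike intervals all fall below a
channel-specific threshold. The threshold is found from the histogram of
log10(ISI): trains that burst show a fast intra-burst ISI mode (milliseconds
to tens of milliseconds) well separated from a slow inter-burst mode. The
threshold is placed at the deepest valley between the intra-burst peak and
the first subsequent peak that is sufficiently separated from it, quantified
by the void parameter

    void(p1, p2) = 1 − h(valley) / sqrt(h(p1) · h(p2)),

and is capped at 100 ms: an interval longer than that never joins two spikes
into one burst, and unimodal (non-bursting) trains fall back to the cap. A
channel counts as *bursting* when its burst rate reaches 0.4 bursts/s and
every burst has at least 5 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import SpikeTrain, ValidationError


@dataclass(frozen=True)
class Burst:
    """One single-channel burst: [start, end] spans first to last spike."""

    electrode_id: str
    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("burst end before start")
        if self.n_spikes < 2:
            raise ValidationError("a burst needs at least 2 spikes")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BurstParams:
    min_spikes: int = 5
    max_isi_cap: float = 0.100  # s; hard ceiling on the intra-burst ISI threshold
    bursting_channel_rate: float = 0.4  # bursts/s; inclusive boundary
    void_threshold: float = 0.7
    bins_per_decade: int = 10

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValidationError("min_spikes must be >= 2")
        if self.max_isi_cap <= 0:
            raise ValidationError("max_isi_cap must be > 0")
        if self.bursting_channel_rate <= 0:
            raise ValidationError("bursting_channel_rate must be > 0")
        if not 0 < self.void_threshold <= 1:
            raise ValidationError("void_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ISIHistogram:
    """Histogram of log10(ISI) with uniform log-spaced bins.

    ``smoothed`` holds the 3-bin centered moving average of the counts, on
    which peaks and valleys are located. An empty histogram (fewer than two
    spikes in the train) is the sentinel for "no ISI structure".
    """

    bin_edges: np.ndarray  # log10(seconds), len = len(counts) + 1
    counts: np.ndarray
    smoothed: np.ndarray
    bins_per_decade: int = 10

    def __post_init__(self) -> None:
        if self.counts.size and self.bin_edges.size != self.counts.size + 1:
            raise ValidationError("bin_edges must bracket counts")

    @property
    def is_empty(self) -> bool:
        return self.counts.size == 0

    def bin_centers_s(self) -> np.ndarray:
        """Bin centers in seconds (geometric centers of the log bins)."""
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return 10.0 ** mid


def log_isi_histogram(train: SpikeTrain, bins_per_decade: int = 10) -> ISIHistogram:
    """Histogram the train's ISIs on a log10 axis, with 3-bin smoothing."""
    isis = train.isis()
    if isis.size == 0:
        empty = np.empty(0)
        return ISIHistogram(empty, empty.astype(int), empty, bins_per_decade)
    log_isis = np.log10(isis)
    lo = np.floor(log_isis.min() * bins_per_decade) / bins_per_decade
    hi = np.ceil(log_isis.max() * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = lo + np.arange(n_bins + 1) / bins_per_decade
    counts, _ = np.histogram(log_isis, bins=edges)
    # edge ISIs can land on the last edge; numpy puts them in the last bin, so
    # conservation (sum == n-1) holds by construction
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    return ISIHistogram(edges, counts, smoothed, bins_per_decade)


def find_isi_threshold(hist: ISIHistogram, params: BurstParams = BurstParams()) -> tuple[float, bool]:
    """Intra-/inter-burst ISI separation threshold from the logISI histogram.

    Returns ``(threshold_s, fallback)``. The intra-burst peak is the largest
    smoothed peak at ISI < ``max_isi_cap``. Among later peaks, the first whose
    void parameter against the intra-burst peak reaches ``void_threshold``
    fixes the valley; the threshold is the ISI at the deepest minimum between
    the two peaks. If the histogram is empty, has no sub-cap peak, or no
    qualifying valley, the cap itself is returned with ``fallback=True``.
    The returned value never exceeds ``max_isi_cap``.
    """
    cap = params.max_isi_cap
    if hist.is_empty:
        return cap, True
    centers = hist.bin_centers_s()
    y = hist.smoothed
    # local maxima of the smoothed histogram; padding lets edge bins qualify
    padded = np.concatenate(([-1.0], y, [-1.0]))
    peak_idx = find_peaks(padded)[0] - 1
    peak_idx = peak_idx[y[peak_idx] > 0]
    if peak_idx.size == 0:
        return cap, True
    # the intra-burst mode must dominate the histogram: in a bursting train
    # intra-burst ISIs outnumber the gaps, so the tallest peak sits below the
    # cap; a unimodal (e.g. Poisson) train has its tallest peak above it
    intra = peak_idx[np.argmax(y[peak_idx])]
    if centers[intra] >= cap:
        return cap, True
    later = peak_idx[peak_idx > intra]
    for p2 in later:
        valley_slice = y[intra : p2 + 1]
        h_min = float(valley_slice.min())
        void = 1.0 - h_min / np.sqrt(y[intra] * y[p2])
        if void >= params.void_threshold:
            valley = intra + int(np.argmin(valley_slice))
            return min(float(centers[valley]), cap), False
    return cap, True


def detect_bursts(
    train: SpikeTrain,
    isi_threshold: float,
    params: BurstParams = BurstParams(),
) -> list[Burst]:
    """Maximal runs of spikes with ISI <= threshold and >= min_spikes spikes."""
    if isi_threshold <= 0:
        raise ValidationError("isi_threshold must be > 0")
    t = train.spike_times
    if t.size < params.min_spikes:
        return []
    close = np.diff(t) <= isi_threshold
    bursts: list[Burst] = []
    run_start = 0
    for i in range(close.size + 1):
        if i < close.size and close[i]:
            continue
        run_len = i - run_start + 1
        if run_len >= params.min_spikes:
            bursts.append(
                Burst(train.electrode_id, float(t[run_start]), float(t[i]), run_len)
            )
        run_start = i + 1
    return bursts


def detect_bursts_logisi(
    train: SpikeTrain, params: BurstParams = BurstParams()
) -> tuple[list[Burst], float, bool]:
    """Full per-channel chain: histogram → threshold → run scan.

    Returns (bursts, threshold_s, fallback_flag).
    """
    hist = log_isi_histogram(train, params.bins_per_decade)
    threshold, fallback = find_isi_threshold(hist, params)
    return detect_bursts(train, threshold, params), threshold, fallback


def channel_burst_stats(
    bursts: list[Burst], duration: float, params: BurstParams = BurstParams()
) -> tuple[float, bool]:
    """(burst rate in bursts/s, is_bursting) for one channel.

    The bursting-channel boundary is inclusive: a channel at exactly 0.4
    bursts/s counts as bursting.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rate = len(bursts) / duration
    return rate, rate >= params.bursting_channel_rate
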