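"""Synthetic MEA recordings and evoked patch-clamp sweeps with known ground truth.

The generator emulates the rhythmic network-bursting phenotype of iPSC-derived
excitatory networks on multi-well MEAs: network bursts recur quasi-periodically,
recruit (nearly) all active channels, and ride on sparse background spiking.
The inter-burst gap (NIBI: end of one network burst to the start of the next)
is drawn from a gamma renewal process with independently tunable mean and CV
(shape = 1/CV², scale = mean·CV²), because the CV of the NIBI is the
irregularity axis along which the affected (KS-like) phenotype separates from
control. Burst durations are gamma too; within a burst each participating
channel fires as a homogeneous Poisson process — intra-burst rate profiles are
not part of the phenotype model.

Two presets encode the study conditions: a control-like network (frequent,
short, regular bursts with appreciable background spiking) and a KS-like
network (rarer, longer, irregular bursts with relatively little spiking
outside bursts). The preset numbers are repository choices that reproduce the
qualitative group ordering; exact group-level values are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PlateRecording, RawTrace, SpikeTrain, Sweep, ValidationError, WellRecording


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one synthetic MEA well.

    ``mean_nibi``/``cv_nibi`` parameterize the gamma-distributed quiescent gap
    between consecutive network bursts; ``mean_nbd``/``nbd_cv`` the burst
    duration; ``participation_p`` the per-channel recruitment probability per
    burst; rates are per channel in Hz.
    """

    duration: float = 1200.0
    n_electrodes: int = 12
    active_fraction: float = 1.0
    mean_nibi: float = 15.0
    cv_nibi: float = 0.4
    mean_nbd: float = 0.5
    nbd_cv: float = 0.3
    participation_p: float = 1.0
    intra_burst_rate: float = 100.0
    background_rate: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if not 0 < self.active_fraction <= 1:
            raise ValidationError("active_fraction must be in (0, 1]")
        if not self.mean_nibi > self.mean_nbd >= 0:
            raise ValidationError("require mean_nibi > mean_nbd >= 0")
        if self.cv_nibi <= 0 or self.nbd_cv < 0:
            raise ValidationError("cv_nibi must be > 0 and nbd_cv >= 0")
        if not 0 < self.participation_p <= 1:
            raise ValidationError("participation_p must be in (0, 1]")
        if self.intra_burst_rate < 0 or self.background_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.n_electrodes < 1:
            raise ValidationError("n_electrodes must be >= 1")


@dataclass
class GroundTruth:
    """Generative truth for one simulated well."""

    nb_onsets: np.ndarray
    nb_offsets: np.ndarray
    # electrode_id -> boolean array aligned with the train's spike_times
    # (True = emitted inside a network-burst window)
    in_burst: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        on = np.asarray(self.nb_onsets, dtype=float)
        off = np.asarray(self.nb_offsets, dtype=float)
        self.nb_onsets, self.nb_offsets = on, off
        if on.size != off.size:
            raise ValidationError("onsets and offsets must pair up")
        if on.size:
            if np.any(off <= on):
                raise ValidationError("burst offsets must exceed onsets")
            if np.any(on[1:] <= off[:-1]):
                raise ValidationError("burst windows must be disjoint and increasing")

    @property
    def n_bursts(self) -> int:
        return int(self.nb_onsets.size)

    def background_fraction(self) -> float:
        """Fraction of all generated spikes emitted outside burst windows."""
        total = sum(v.size for v in self.in_burst.values())
        if total == 0:
            return float("nan")
        outside = sum(int(np.sum(~v)) for v in self.in_burst.values())
        return outside / total


def _gamma_times(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n)
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return rng.gamma(shape, scale, size=n)


def simulate_well(config: SimulationConfig, *, well_id: str = "W01", group_label: str = "") -> tuple[WellRecording, GroundTruth]:
    """Simulate one well; fully reproducible from ``config.seed``.

    Network-burst windows are laid down first (gamma NIBI gaps alternating with
    gamma durations, starting with one initial gap), then each active channel
    joins each burst with probability ``participation_p`` and fires Poisson
    spikes at ``intra_burst_rate`` inside the window, plus Poisson background
    at ``background_rate`` over the whole recording. Inactive channels are
    silent but present as explicit empty trains.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Burst windows: alternate gap, duration until the recording ends.
    onsets, offsets = [], []
    t = float(_gamma_times(rng, config.mean_nibi, config.cv_nibi, 1)[0])
    while True:
        dur = float(_gamma_times(rng, config.mean_nbd, config.nbd_cv, 1)[0])
        dur = max(dur, 1e-3)  # degenerate zero-length windows are not bursts
        if t + dur >= config.duration:
            break
        onsets.append(t)
        offsets.append(t + dur)
        t = t + dur + float(_gamma_times(rng, config.mean_nibi, config.cv_nibi, 1)[0])
    onsets_a = np.asarray(onsets)
    offsets_a = np.asarray(offsets)

    n_active = max(1, int(round(config.active_fraction * config.n_electrodes)))
    trains: list[SpikeTrain] = []
    in_burst: dict[str, np.ndarray] = {}
    for ch in range(config.n_electrodes):
        eid = f"E{ch + 1:02d}"
        if ch >= n_active:
            trains.append(SpikeTrain(eid, well_id, np.empty(0), config.duration))
            in_burst[eid] = np.empty(0, dtype=bool)
            continue
        spikes = []
        labels = []
        for on, off in zip(onsets_a, offsets_a):
            if rng.random() > config.participation_p:
                continue
            n = rng.poisson(config.intra_burst_rate * (off - on))
            s = rng.uniform(on, off, size=n)
            spikes.append(s)
            labels.append(np.ones(n, dtype=bool))
        n_bg = rng.poisson(config.background_rate * config.duration)
        bg = rng.uniform(0.0, config.duration, size=n_bg)
        bg_in = np.zeros(n_bg, dtype=bool)
        for on, off in zip(onsets_a, offsets_a):
            bg_in |= (bg >= on) & (bg <= off)
        spikes.append(bg)
        labels.append(bg_in)
        all_spikes = np.concatenate(spikes) if spikes else np.empty(0)
        all_labels = np.concatenate(labels) if labels else np.empty(0, dtype=bool)
        order = np.argsort(all_spikes)
        all_spikes, all_labels = all_spikes[order], all_labels[order]
        # collapse coincident draws (probability ~0 but invariant requires strict order)
        if all_spikes.size > 1:
            keep = np.concatenate(([True], np.diff(all_spikes) > 0))
            all_spikes, all_labels = all_spikes[keep], all_labels[keep]
        trains.append(SpikeTrain(eid, well_id, all_spikes, config.duration))
        in_burst[eid] = all_labels

    well = WellRecording(well_id, trains, group_label=group_label, n_electrodes=config.n_electrodes)
    truth = GroundTruth(onsets_a, offsets_a, in_burst)
    return well, truth


def simulate_plate(config: SimulationConfig, n_wells: int, *, group_label: str = "", plate_id: str = "plate", well_prefix: str = "W") -> tuple[PlateRecording, list[GroundTruth]]:
    """Simulate ``n_wells`` independent wells (seeds derived from config.seed)."""
    wells, truths = [], []
    for i in range(n_wells):
        cfg = replace(config, seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31))
        w, t = simulate_well(cfg, well_id=f"{well_prefix}{i + 1:02d}", group_label=group_label)
        wells.append(w)
        truths.append(t)
    return PlateRecording(wells, plate_id=plate_id, recorded_minutes=config.duration / 60.0), truths


def control_preset(seed: int = 0) -> SimulationConfig:
    """Control-like network: frequent, short, regular bursts; lively background."""
    return SimulationConfig(
        duration=1200.0,
        mean_nibi=15.0,
        cv_nibi=0.4,
        mean_nbd=0.5,
        nbd_cv=0.3,
        background_rate=1.5,
        intra_burst_rate=100.0,
        participation_p=1.0,
        seed=seed,
    )


def ks_preset(seed: int = 0) -> SimulationConfig:
    """KS-like network: rarer, longer, irregular bursts; sparse background.

    Differs from :func:`control_preset` only in (mean_nibi, cv_nibi, mean_nbd,
    background_rate), giving a lower burst rate, longer burst duration, higher
    NIBI CV, and a smaller percentage of spikes outside network bursts.
    """
    return SimulationConfig(
        duration=1200.0,
        mean_nibi=40.0,
        cv_nibi=0.8,
        mean_nbd=2.0,
        nbd_cv=0.3,
        background_rate=0.4,
        intra_burst_rate=100.0,
        participation_p=1.0,
        seed=seed,
    )


def default_spike_waveform(sampling_rate: float = 10_000.0, amplitude: float = -60.0) -> np.ndarray:
    """A biphasic extracellular spike template (~1.5 ms), peak at `amplitude` µV.

    Negative-dominant, as typical for extracellular somatic spikes.
    """
    t = np.arange(0.0, 0.0015, 1.0 / sampling_rate)
    wave = -np.exp(-((t - 3e-4) ** 2) / (2 * (1.2e-4) ** 2)) + 0.35 * np.exp(
        -((t - 7.5e-4) ** 2) / (2 * (2.5e-4) ** 2)
    )
    return amplitude * wave / np.max(np.abs(wave))


def simulate_raw_trace(
    train: SpikeTrain,
    waveform: np.ndarray,
    noise_sd: float,
    sampling_rate: float = 10_000.0,
    *,
    duration: float | None = None,
    seed: int = 0,
) -> RawTrace:
    """Additive model: Gaussian noise plus the spike template at each spike time.

    Overlapping templates sum. The waveform must be shorter than the minimum
    ISI for a clean single-spike fixture, but overlap only triggers summation,
    not an error.
    """
    if sampling_rate < 2000:
        raise ValidationError("sampling_rate too low for extracellular spikes")
    dur = duration if duration is not None else train.duration
    n = int(round(dur * sampling_rate))
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    wave = np.asarray(waveform, dtype=float)
    for t in train.spike_times:
        i0 = int(round(t * sampling_rate))
        i1 = min(i0 + wave.size, n)
        if i0 < n:
            samples[i0:i1] += wave[: i1 - i0]
    return RawTrace(train.electrode_id, samples, sampling_rate)


@dataclass(frozen=True)
class EvokedPair:
    """Baseline-aligned evoked sweeps at −70 mV (AMPAR) and +40 mV (NMDAR)."""

    sweep_minus70: Sweep
    sweep_plus40: Sweep
    baseline_window: float = 0.050

    def __post_init__(self) -> None:
        if self.sweep_minus70.sampling_rate != self.sweep_plus40.sampling_rate:
            raise ValidationError("sweeps must share a sampling rate")
        if self.sweep_minus70.stim_time != self.sweep_plus40.stim_time:
            raise ValidationError("sweeps must share stim_time alignment")


def _syn_current(t: np.ndarray, onset: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials synaptic conductance time course (unit peak)."""
    s = np.clip(t - onset, 0.0, None)
    g = np.exp(-s / tau_decay) - np.exp(-s / tau_rise)
    g[t < onset] = 0.0
    peak = np.max(g)
    return g / peak if peak > 0 else g


def simulate_evoked_pair(
    ampa_amp: float,
    nmda_amp: float,
    tau_decay: float = 0.080,
    noise_sd: float = 0.0,
    *,
    sampling_rate: float = 10_000.0,
    sweep_duration: float = 0.5,
    stim_time: float = 0.1,
    seed: int = 0,
) -> EvokedPair:
    """Synthesize an evoked AMPAR/NMDAR sweep pair with known amplitudes.

    The −70 mV sweep carries a fast inward current whose sampled peak equals
    ``ampa_amp`` (pA, negative); the +40 mV sweep a slow outward current whose
    mean over [stim+65 ms, stim+70 ms] equals ``nmda_amp`` exactly before
    noise. Baselines are zero, so the downstream ratio on the noiseless pair
    is |nmda_amp| / |ampa_amp| by construction.
    """
    if ampa_amp >= 0:
        raise ValidationError("ampa_amp must be negative (inward at −70 mV)")
    if nmda_amp < 0:
        raise ValidationError("nmda_amp must be >= 0 (outward at +40 mV)")
    if tau_decay <= 0:
        raise ValidationError("tau_decay must be > 0")
    n = int(round(sweep_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    onset = stim_time + 0.002  # 2 ms synaptic delay

    ampa_shape = _syn_current(t, onset, tau_rise=0.0005, tau_decay=0.005)
    ampa = ampa_amp * ampa_shape / np.max(ampa_shape)

    nmda_shape = _syn_current(t, onset, tau_rise=0.005, tau_decay=tau_decay)
    # same sample indexing as Sweep.window so the window mean is exact downstream
    i0 = int(np.ceil((stim_time + 0.065) * sampling_rate - 1e-9))
    i1 = int(np.ceil((stim_time + 0.070) * sampling_rate - 1e-9))
    mean_in_win = float(np.mean(nmda_shape[i0:i1]))
    if nmda_amp > 0 and mean_in_win <= 0:
        raise ValidationError("NMDA window precedes current onset")
    nmda = nmda_amp * nmda_shape / mean_in_win if nmda_amp > 0 else np.zeros(n)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        ampa = ampa + rng.normal(0.0, noise_sd, size=n)
        nmda = nmda + rng.normal(0.0, noise_sd, size=n)
    return EvokedPair(
        Sweep(ampa, sampling_rate, stim_time, holding_potential=-70.0),
        Sweep(nmda, sampling_rate, stim_time, holding_potential=40.0),
    )
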