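"""Single-cell electrophysiology quantification.

Covers the whole-cell readouts used alongside the MEA phenotype: sEPSC burst
statistics (fixed-threshold run scan over event times), the evoked NMDA/AMPA
ratio (AMPAR peak at −70 mV vs the mean NMDAR current in a 5-ms window 65 ms
post-stimulus at +40 mV, on 30-sweep averages), the NMDAR decay constant τ,
passive membrane properties from a −25 pA hyperpolarizing step, and action
potential features at rheobase. Event *detection* (mEPSC/sEPSC extraction
from raw current) is out of scope; the module consumes event-time lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .bursts import Burst, BurstParams, detect_bursts
from .core import SpikeTrain, Sweep, ValidationError

# EventTrain shares the SpikeTrain contract (increasing times within duration)
EventTrain = SpikeTrain

#: slice-protocol quality floor on the AMPA amplitude (pA)
AMPA_QC_FLOOR = 25.0


def detect_event_bursts(
    train: EventTrain,
    min_events: int = 5,
    iei_threshold: float = 0.100,
) -> tuple[list[Burst], float, float]:
    """sEPSC bursts: >= min_events events with inter-event interval <= 100 ms.

    Same run-scan semantics as the MEA single-channel burst detector, with a
    fixed threshold (no logISI step). Returns (bursts, burst frequency in
    bursts/s, mean burst duration in s — NaN when no bursts).
    """
    params = BurstParams(min_spikes=min_events, max_isi_cap=iei_threshold)
    bursts = detect_bursts(train, iei_threshold, params)
    freq = len(bursts) / train.duration
    mean_dur = float(np.mean([b.duration for b in bursts])) if bursts else float("nan")
    return bursts, freq, mean_dur


def average_sweeps(sweeps: list[Sweep], n: int | None = None) -> Sweep:
    """Pointwise mean of the first ``n`` sweeps (default: all, typically 30)."""
    if n is None:
        n = len(sweeps)
    if len(sweeps) < n or n < 1:
        raise ValidationError(f"need {n} sweeps, have {len(sweeps)}")
    head = sweeps[:n]
    ref = head[0]
    for s in head[1:]:
        if s.samples.size != ref.samples.size:
            raise ValidationError("sweeps differ in length")
        if s.sampling_rate != ref.sampling_rate or s.stim_time != ref.stim_time:
            raise ValidationError("sweeps differ in sampling rate or stim alignment")
    mean = np.mean([s.samples for s in head], axis=0)
    return Sweep(mean, ref.sampling_rate, ref.stim_time, ref.holding_potential)


def _baseline(sweep: Sweep, baseline_window: float) -> float:
    start = max(sweep.stim_time - baseline_window, 0.0)
    seg = sweep.window(start, sweep.stim_time)
    if seg.size == 0:
        raise ValidationError("baseline window precedes the sweep start")
    return float(np.mean(seg))


def nmda_ampa_ratio(
    pair,
    ampa_window: tuple[float, float] = (0.002, 0.050),
    nmda_window: tuple[float, float] = (0.065, 0.070),
    baseline_window: float = 0.050,
    qc_floor: float = AMPA_QC_FLOOR,
) -> dict:
    """Evoked NMDA/AMPA ratio from a baseline-subtracted sweep pair.

    AMPA amplitude: most negative value of the −70 mV sweep in a 2–50 ms
    post-stimulus search window (the first 2 ms are blanked as stimulus
    artifact). NMDA amplitude: mean of the +40 mV sweep over the 5-ms window
    65 ms after the stimulus. Ratio = |NMDA| / |AMPA|; NaN sentinel when the
    AMPA amplitude is zero, and a ``qc_fail`` flag (slice convention) when it
    is below 25 pA in magnitude.
    """
    m70, p40 = pair.sweep_minus70, pair.sweep_plus40
    stim = m70.stim_time
    b70 = _baseline(m70, baseline_window)
    b40 = _baseline(p40, baseline_window)

    seg = m70.window(stim + ampa_window[0], stim + ampa_window[1]) - b70
    if seg.size == 0:
        raise ValidationError("AMPA search window is empty")
    ampa_amp = float(seg.min())

    nmda_seg = p40.window(stim + nmda_window[0], stim + nmda_window[1]) - b40
    if nmda_seg.size == 0:
        raise ValidationError("NMDA window is empty")
    nmda_amp = float(np.mean(nmda_seg))

    ratio = abs(nmda_amp) / abs(ampa_amp) if ampa_amp != 0 else float("nan")
    return {
        "ampa_amp": ampa_amp,
        "nmda_amp": nmda_amp,
        "ratio": ratio,
        "qc_fail": abs(ampa_amp) < qc_floor,
    }


def fit_decay_tau(
    sweep: Sweep,
    from_fraction: float = 0.9,
    baseline_window: float = 0.050,
) -> float:
    """Single-exponential decay constant τ (s) of the evoked current.

    The fit starts where the baseline-subtracted current has fallen to
    ``from_fraction`` of its peak and runs to the end of the sweep; a trace
    with no decaying phase raises.
    """
    b = _baseline(sweep, baseline_window)
    x = sweep.samples - b
    fs = sweep.sampling_rate
    post = x[int(round(sweep.stim_time * fs)):]
    if post.size < 10:
        raise ValidationError("too few post-stimulus samples")
    sign = 1.0 if abs(post.max()) >= abs(post.min()) else -1.0
    y = sign * post
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        raise ValidationError("no identifiable peak after the stimulus")
    after = y[peak_idx:]
    below = np.flatnonzero(after <= from_fraction * peak)
    if below.size == 0:
        raise ValidationError("current never decays below the start fraction")
    start = peak_idx + int(below[0])
    yfit = y[start:]
    if yfit.size < 5 or yfit[0] <= 0:
        raise ValidationError("decay segment too short to fit")
    t = np.arange(yfit.size) / fs

    def model(tt, amp, tau):
        return amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, yfit, p0=(float(yfit[0]), max(t[-1] / 3.0, 1e-3)),
            bounds=((0.0, 1e-6), (np.inf, 10.0)), maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValidationError(f"decay fit failed: {exc}") from exc
    return float(popt[1])


def passive_properties(
    step: Sweep,
    injected_current: float = -25.0,
    step_duration: float = 0.5,
) -> tuple[float, float]:
    """Input resistance (MΩ) and membrane time constant (s) from a current step.

    The step (default −25 pA for 0.5 s) starts at ``step.stim_time``.
    Rin = steady-state ΔV / I (steady state: mean of the last 20% of the
    step); τ from a single-exponential fit to the charging transient.
    ``step`` holds voltage in mV; I in pA, so ΔV/I × 1e3 gives MΩ.
    """
    if injected_current == 0:
        raise ValidationError("injected current must be nonzero")
    fs = step.sampling_rate
    t0 = step.stim_time
    v_pre = _baseline(step, min(t0, 0.050) if t0 > 0 else 0.0) if t0 > 0 else float(step.samples[0])
    on = int(round(t0 * fs))
    off = int(round((t0 + step_duration) * fs))
    if off > step.samples.size:
        raise ValidationError("step window extends past the sweep")
    seg = step.samples[on:off]
    ss = float(np.mean(seg[int(0.8 * seg.size):]))
    delta_v = ss - v_pre  # mV
    rin_mohm = delta_v / injected_current * 1e3  # mV/pA = GΩ → ×1e3 = MΩ

    y = seg - ss  # decays to 0 as the membrane charges
    t = np.arange(y.size) / fs
    a0 = y[0] if y[0] != 0 else (v_pre - ss)

    def model(tt, amp, tau):
        return amp * np.exp(-tt / tau)

    popt, _ = curve_fit(model, t, y, p0=(a0, 0.02), maxfev=10000)
    return float(rin_mohm), float(abs(popt[1]))


@dataclass(frozen=True)
class APFeatures:
    threshold: float  # mV
    amplitude: float  # mV, threshold to peak
    half_width: float  # s, width at half amplitude
    decay_time: float  # s, peak back down to half amplitude


def ap_features(sweep: Sweep, threshold_dvdt: float = 20.0) -> APFeatures:
    """Features of the first action potential in a voltage sweep.

    Threshold: membrane potential at the first crossing of the dV/dt
    criterion (default 20 V/s); amplitude: threshold → peak; half-width:
    time above half-amplitude; decay time: peak → half-amplitude on the
    falling phase.
    """
    v = sweep.samples  # mV
    fs = sweep.sampling_rate
    dvdt = np.gradient(v) * fs / 1000.0  # mV/sample → V/s
    crossing = np.flatnonzero(dvdt >= threshold_dvdt)
    if crossing.size == 0:
        raise ValidationError("no action potential (dV/dt criterion never met)")
    i_thr = int(crossing[0])
    v_thr = float(v[i_thr])
    i_peak = i_thr + int(np.argmax(v[i_thr:]))
    v_peak = float(v[i_peak])
    amp = v_peak - v_thr
    if amp <= 0:
        raise ValidationError("no depolarizing excursion after threshold")
    half = v_thr + amp / 2.0
    above = v[i_thr:] >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValidationError("AP never reaches half amplitude")
    first = int(idx[0])
    later = np.flatnonzero(~above[first:])
    last = first + (int(later[0]) if later.size else above.size - first)
    half_width = (last - first) / fs
    decay = max(last - (i_peak - i_thr), 0) / fs
    return APFeatures(v_thr, amp, half_width, decay)


def rheobase(ladder: list[tuple[float, Sweep]], threshold_dvdt: float = 20.0) -> float:
    """Smallest ladder current (pA) eliciting at least one AP; NaN if none.

    ``ladder`` pairs injected current with the voltage response sweep and
    must be in increasing current order.
    """
    currents = [c for c, _ in ladder]
    if any(b <= a for a, b in zip(currents, currents[1:])):
        raise ValidationError("ladder currents must be strictly increasing")
    for current, sweep in ladder:
        try:
            ap_features(sweep, threshold_dvdt)
        except ValidationError:
            continue
        return float(current)
    return float("nan")
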