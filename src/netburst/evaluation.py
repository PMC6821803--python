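"""End-to-end validation benchmarks on synthetic data with known ground truth.

Each routine regenerates its inputs from a seed, runs the relevant slice of
the pipeline, and returns the measured quantities — oracle agreement for the
burst scanner, exact spike conservation, the >80% participation boundary,
generative-parameter recovery, phenotype separation by discriminant analysis,
detector recall/precision, evoked-ratio recovery, the closed-form qPCR/CV
identities, and a chance-level control for the classifier. They are consumed
by the test suite and the reproduction script; nothing here asserts — the
callers decide what counts as a pass.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import bursts as _bursts
from . import detection as _detection
from . import network as _network
from . import qpcr as _qpcr
from .core import SpikeTrain
from .discriminant import FeatureMatrix, fit_discriminant, reclassify
from .network import FEATURE_COLUMNS, NetworkParams, spikes_in_network_bursts, summarize_plate
from .patch import average_sweeps, nmda_ampa_ratio
from .simulate import (
    EvokedPair,
    SimulationConfig,
    control_preset,
    default_spike_waveform,
    ks_preset,
    simulate_evoked_pair,
    simulate_plate,
    simulate_raw_trace,
    simulate_well,
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


def _reference_burst_scan(times: np.ndarray, isi_threshold: float, min_spikes: int):
    """Independent brute-force burst scanner (plain loop, no vectorization)."""
    out = []
    run: list[float] = []
    for t in times:
        if run and t - run[-1] > isi_threshold:
            if len(run) >= min_spikes:
                out.append((run[0], run[-1], len(run)))
            run = []
        run.append(float(t))
    if len(run) >= min_spikes:
        out.append((run[0], run[-1], len(run)))
    return out


def burst_scan_oracle_agreement(seed: int, n_trains: int = 1000, duration: float = 1200.0) -> dict:
    """Fixed-threshold run scan vs the brute-force oracle on Poisson trains.

    Trains span firing rates 0.1–5 Hz over a 20-min recording; agreement is
    the fraction of trains whose burst intervals and counts are identical.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trains):
        rate = rng.uniform(0.1, 5.0)
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, n))
        if times.size > 1:
            times = times[np.concatenate(([True], np.diff(times) > 0))]
        train = SpikeTrain("E01", "W01", times, duration)
        got = [(b.start, b.end, b.n_spikes) for b in _bursts.detect_bursts(train, 0.1)]
        want = _reference_burst_scan(times, 0.1, 5)
        agree += int(got == want)
    return {"n_trains": n_trains, "agreement_fraction": agree / n_trains}


def spike_conservation(seed: int, n_wells: int = 5) -> dict:
    """Exactness of inside-NB + outside-NB = total over simulated wells."""
    max_err = 0
    total_spikes = 0
    for i, s in enumerate(_sub_seeds(seed, n_wells)):
        preset = control_preset(seed=s) if i % 2 == 0 else ks_preset(seed=s)
        well, _ = simulate_well(preset)
        active = _network.active_electrodes(well)
        cb = {
            t.electrode_id: _bursts.detect_bursts_logisi(t)[0]
            for t in well.trains if t.electrode_id in active
        }
        nbs = _network.detect_network_bursts(cb, active)
        total = sum(t.n_spikes for t in well.trains if t.electrode_id in active)
        inside = sum(
            spikes_in_network_bursts(t, nbs)
            for t in well.trains if t.electrode_id in active
        )
        # independent outside count via interval bisection, not boolean masks
        starts = np.array([e.start for e in nbs])
        ends = np.array([e.end for e in nbs])
        outside = 0
        for t in well.trains:
            if t.electrode_id not in active:
                continue
            if starts.size == 0:
                outside += t.n_spikes
                continue
            idx = np.searchsorted(starts, t.spike_times, side="right") - 1
            in_nb = (idx >= 0) & (t.spike_times <= ends[np.clip(idx, 0, None)])
            outside += int(np.sum(~in_nb))
        max_err = max(max_err, abs(inside + outside - total))
        total_spikes += total
    return {"n_wells": n_wells, "total_spikes": total_spikes, "max_abs_error": max_err}


def participation_boundary() -> dict:
    """Network-burst counts with synchronous bursts on 9 vs 8 of 10 channels."""
    active = {f"E{i:02d}" for i in range(1, 11)}
    out = {}
    for k in (9, 8):
        cb = {
            ch: [_bursts.Burst(ch, 10.0, 10.5, 10)]
            for ch in sorted(active)[:k]
        }
        out[f"events_{k}_of_10"] = len(_network.detect_network_bursts(cb, active))
    return out


def parameter_recovery(seed: int, n_wells: int = 10) -> dict:
    """Pipeline estimates vs generative values at mean NIBI 20 s, CV 0.5, NBD 2 s."""
    cfg = SimulationConfig(mean_nibi=20.0, cv_nibi=0.5, mean_nbd=2.0, seed=seed)
    plate, _ = simulate_plate(cfg, n_wells)
    df = summarize_plate(plate)
    est = {
        "mean_nibi": float(df.mean_nibi.mean()),
        "cv_nibi": float(df.cv_nibi.mean()),
        "mean_nbd": float(df.mean_nbd.mean()),
    }
    truth = {"mean_nibi": 20.0, "cv_nibi": 0.5, "mean_nbd": 2.0}
    out = {"n_wells": n_wells}
    for k in truth:
        out[f"{k}_estimate"] = est[k]
        out[f"{k}_rel_err_pct"] = 100.0 * abs(est[k] - truth[k]) / truth[k]
    return out


def phenotype_separation(seed: int, n_wells: int = 10) -> dict:
    """Control vs KS presets: discriminant resubstitution accuracy + ordering."""
    s1, s2 = _sub_seeds(seed, 2)
    pc, _ = simulate_plate(control_preset(seed=s1), n_wells, group_label="control", well_prefix="C")
    pk, _ = simulate_plate(ks_preset(seed=s2), n_wells, group_label="ks", well_prefix="K")
    df = pd.concat([summarize_plate(pc), summarize_plate(pk)], ignore_index=True)
    data = FeatureMatrix.from_frame(df, FEATURE_COLUMNS)
    model = fit_discriminant(data)
    _, pct = reclassify(model, data)
    c = df[df.group_label == "control"].mean(numeric_only=True)
    k = df[df.group_label == "ks"].mean(numeric_only=True)
    ordering = bool(
        (k.nb_rate < c.nb_rate)
        and (k.mean_nbd > c.mean_nbd)
        and (k.cv_nibi > c.cv_nibi)
        and (k.pct_outside < c.pct_outside)
    )
    return {
        "n_wells_per_group": n_wells,
        "resubstitution_accuracy_pct": pct,
        "group_ordering_correct": ordering,
    }


def spike_detection_performance(
    seed: int,
    n_seeds: int = 100,
    snr: float = 8.0,
    noise_sd: float = 7.5,
    n_spikes: int = 50,
    duration: float = 10.0,
) -> dict:
    """Detector recall/precision on synthetic raw traces at the given SNR."""
    params = _detection.DetectionParams()
    wave = default_spike_waveform(amplitude=-snr * noise_sd)
    peak_offset = np.argmax(np.abs(wave)) / 10_000.0
    tp = fp = fn = 0
    for s in _sub_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        candidates = np.sort(rng.uniform(0.01, duration - 0.01, n_spikes * 3))
        times, last = [], -np.inf
        for x in candidates:
            if x - last >= 0.005:
                times.append(x)
                last = x
            if len(times) == n_spikes:
                break
        times = np.asarray(times)
        train = SpikeTrain("E01", "W01", times, duration)
        trace = simulate_raw_trace(train, wave, noise_sd=noise_sd, seed=s)
        det = _detection.detect_spikes(_detection.highpass_filter(trace, params), params)
        truth = times + peak_offset
        used = np.zeros(det.n_spikes, dtype=bool)
        hits = 0
        for t in truth:
            d = np.abs(det.spike_times - t)
            d[used] = np.inf
            if d.size and d.min() <= 1e-3:
                used[np.argmin(d)] = True
                hits += 1
        tp += hits
        fn += times.size - hits
        fp += det.n_spikes - hits
    return {
        "n_seeds": n_seeds,
        "recall": tp / (tp + fn),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def ratio_recovery(seed: int, n_seeds: int = 100, n_sweeps: int = 30) -> dict:
    """NMDA/AMPA ratio recovery from noisy 30-sweep averages + noiseless check."""
    errs = []
    for s in _sub_seeds(seed, n_seeds):
        sweep_seeds = _sub_seeds(s, n_sweeps)
        pairs = [
            simulate_evoked_pair(-50.0, 25.0, noise_sd=2.0, seed=ss)
            for ss in sweep_seeds
        ]
        pair = EvokedPair(
            average_sweeps([p.sweep_minus70 for p in pairs]),
            average_sweeps([p.sweep_plus40 for p in pairs]),
        )
        errs.append(abs(nmda_ampa_ratio(pair)["ratio"] - 0.5) / 0.5)
    noiseless = nmda_ampa_ratio(simulate_evoked_pair(-50.0, 25.0, noise_sd=0.0))["ratio"]
    return {
        "n_seeds": n_seeds,
        "max_rel_err": float(np.max(errs)),
        "mean_rel_err": float(np.mean(errs)),
        "noiseless_ratio": noiseless,
    }


def closed_form_checks() -> dict:
    """Exact identities: % input, ddCt fold, CV of a periodic NB train."""
    return {
        "percent_input_identity": _qpcr.percent_input(23.7, 23.7, 1.0),
        "ddct_identity": _qpcr.ddct_fold_change(21.3, 17.9, 21.3, 17.9),
        "cv_nibi_periodic": _network.cv_nibi([5.0] * 10),
    }


def chance_level_accuracy(seed: int, n_seeds: int = 100, n_per_group: int = 50) -> dict:
    """Resubstitution accuracy when both groups share one distribution.

    With 5 features and 50 wells per group the Monte-Carlo mean sits at
    chance plus the resubstitution optimism of a fitted-on-itself classifier.
    """
    names = tuple(f"f{i}" for i in range(5))
    labels = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    accs = []
    for s in _sub_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        X = rng.normal(size=(2 * n_per_group, 5))
        model = fit_discriminant(FeatureMatrix(X, labels, names))
        _, pct = reclassify(model, FeatureMatrix(X, labels, names))
        accs.append(pct)
    return {
        "n_seeds": n_seeds,
        "mean_accuracy_pct": float(np.mean(accs)),
        "min_accuracy_pct": float(np.min(accs)),
        "max_accuracy_pct": float(np.max(accs)),
    }
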