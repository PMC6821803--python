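# netburst

Network-burst analysis for multi-well microelectrode-array (MEA) recordings
of cultured neuronal networks, with companion quantifications for patch-clamp
and qPCR readouts. The package targets the phenotyping workflow used for
iPSC-derived excitatory cortical networks in neurodevelopmental-disorder
models (here: Kleefstra syndrome, *EHMT1* haploinsufficiency), where the
disease signature is not the overall firing level but the *temporal
organization* of population activity: affected networks produce network
bursts that are rarer, longer, and more irregular than control networks.

## What it computes

**MEA chain** (raw trace → phenotype):

1. **Spike detection** — zero-phase Butterworth high-pass (100 Hz), robust
   noise-floor estimate, threshold at ±4.5 noise SDs, extremum timestamping,
   1.5 ms dead time.
2. **Single-channel bursts (logISI method)** — histogram of log₁₀(ISI); the
   intra-/inter-burst separation threshold sits at the deepest valley between
   the dominant fast peak and the first peak separated from it by a void
   parameter ≥ 0.7, capped at 100 ms; a burst is ≥ 5 spikes with ISIs below
   the threshold; a channel is *bursting* at ≥ 0.4 bursts/s.
3. **Network bursts** — channel bursts on *active* electrodes (rate ≥ 0.1 Hz)
   merged across channels (gap ≤ 100 ms, transitive); an event is a network
   burst iff it recruits strictly more than 80% of the active channels.
4. **Well metrics** — the feature vector
   `(MFR, NB rate, NBD, NIBI, CV of NIBI, % spikes outside NBs)`:
   mean firing rate over active electrodes (Hz), network-burst rate (min⁻¹),
   burst duration (s), inter-burst interval (end → next start, s), its
   coefficient of variation CV = σ(NIBI)/μ(NIBI), and the percentage of
   active-electrode spikes outside all network-burst windows.
5. **Phenotype discrimination** — canonical discriminant functions from the
   generalized eigenproblem `B v = λ W v` (between- vs pooled within-group
   scatter, standardized features), nearest-centroid reclassification
   (resubstitution accuracy; leave-one-out available), and chi-square
   confidence ellipses as group envelopes.
6. **Pharmacology** — per-well normalization of any metric to the
   non-treated (NT) baseline and interpolated recovery fractions for acute
   receptor-blockade time courses; group mean ± SEM tables for chronic
   treatments.

**Patch-clamp**: sEPSC burst statistics (≥ 5 events, inter-event interval
≤ 100 ms), evoked NMDA/AMPA ratio (AMPAR peak at −70 mV vs the mean NMDAR
current over 65–70 ms post-stimulus at +40 mV, on 30-sweep averages),
NMDAR decay constant τ, passive properties from a −25 pA step
(R_in = ΔV/I, membrane τ), AP features and rheobase.

**qPCR**: ChIP enrichment `% input = 100·2^−ΔCt` with
`ΔCt = Ct[ChIP] − (Ct[input] − log₂ dilution)`, and relative expression by
`2^−ΔΔCt` with technical duplicates averaged on the Ct scale.

**Synthetic data**: a generator that emulates control-like and KS-like wells
with known ground truth (gamma-renewal network bursts with tunable NIBI
mean/CV and duration, per-channel participation, Poisson intra-burst and
background spiking), plus raw-trace and evoked-sweep synthesis — so every
stage of the pipeline is testable without any recording on disk.

## Worked example

```python
import netburst as nb

well, truth = nb.simulate_well(nb.ks_preset(seed=2))
print(nb.summarize_well(well))
```

prints (one KS-like 20-min well, 12 electrodes):

```
NetworkMetrics(well_id='W01', mfr=4.729097222222223, nb_rate=1.3,
mean_nbd=2.018157880644313, mean_nibi=41.944938364696135,
cv_nibi=0.8618000526633591, pct_outside=7.932568760187374,
n_active=12, n_network_bursts=26, group_label='')
```

i.e. 1.3 network bursts per minute lasting ~2.0 s, an irregular rhythm
(CV ≈ 0.86) and only ~8% of spikes outside network bursts — against the
control preset's ~3.9 bursts/min, ~0.5 s, CV ≈ 0.38 and ~30% outside.

The numbered drivers under `analysis/` run the cohort-level story end to
end and write tables under `results/`:

```bash
python analysis/01_simulate_plates.py        # 10 control + 10 KS wells
python analysis/02_network_metrics.py        # per-well feature vectors
python analysis/03_pharmacology.py           # NT-normalized blockade time course
python analysis/04_phenotype_classification.py  # discriminant scores/envelopes
```

The same chain is scriptable from a shell via the `netburst` CLI
(`simulate`, `validate`, `convert`, `detect`, `bursts`, `metrics`,
`classify`, `qpcr`).

## Data formats

Spike tables are TSV (`well_id`, `electrode_id`, `spike_time_s`; seconds
with six decimals, sorted by well, electrode, time). Raw traces and
patch-clamp sweeps live in an HDF5 container: one dataset per
electrode/sweep under `traces/` or `sweeps/`, with `sampling_rate` (Hz) and,
for sweeps, `stim_time`/`holding_potential` attributes. These are repository
conventions, not a vendor format.

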