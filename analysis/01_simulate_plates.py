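#!/usr/bin/env python
"""Simulate the study's two MEA cohorts: control-like and KS-like wells.

Generates 10 wells per phenotype preset (20-min recordings, 12 electrodes),
writes the full spike tables to scratch/ (large, fully regenerable from the
seeds) and a compact per-well ground-truth summary to
results/simulation_truth.tsv. Downstream drivers regenerate the same plates
from the same seeds, so the scratch tables are for inspection only.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import netburst as nb

SEED_CONTROL, SEED_KS = 101, 202
N_WELLS = 10

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch"
    results = ROOT / "results"
    scratch.mkdir(exist_ok=True)
    results.mkdir(exist_ok=True)

    rows = []
    for label, preset, seed, prefix in (
        ("control", nb.control_preset, SEED_CONTROL, "C"),
        ("ks", nb.ks_preset, SEED_KS, "K"),
    ):
        plate, truths = nb.simulate_plate(
            preset(seed=seed), N_WELLS, group_label=label, well_prefix=prefix
        )
        nb.write_spike_table(plate, scratch / f"plate_{label}.tsv")
        for well, truth in zip(plate.wells, truths):
            nibis = truth.nb_onsets[1:] - truth.nb_offsets[:-1]
            rows.append(
                {
                    "well_id": well.well_id,
                    "group_label": label,
                    "true_n_bursts": truth.n_bursts,
                    "true_mean_nibi": float(np.mean(nibis)) if nibis.size else float("nan"),
                    "true_cv_nibi": float(np.std(nibis) / np.mean(nibis)) if nibis.size else float("nan"),
                    "true_mean_nbd": float(np.mean(truth.nb_offsets - truth.nb_onsets)),
                    "true_background_fraction": truth.background_fraction(),
                    "n_spikes": sum(t.n_spikes for t in well.trains),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(results / "simulation_truth.tsv", sep="\t", index=False)
    print(f"simulated {len(df)} wells ({N_WELLS} per group)")
    print(df.groupby("group_label")[["true_n_bursts", "true_mean_nbd", "true_cv_nibi"]].mean())
    print(f"spike tables -> {scratch}/plate_*.tsv; truth -> {results}/simulation_truth.tsv")


if __name__ == "__main__":
    main()
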