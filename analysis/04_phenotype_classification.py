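#!/usr/bin/env python
"""Discriminant phenotyping of the simulated cohorts.

Reads the well-level metrics of 02_network_metrics.py (regenerating them if
the table is absent), fits canonical discriminant functions on the five
network features (MFR, network-burst rate, burst duration, % spikes outside
bursts, CV of the inter-burst interval), reclassifies the wells by nearest
centroid, and writes canonical scores and 95% group envelopes to results/.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

import netburst as nb

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    metrics_path = results / "network_metrics.tsv"
    if not metrics_path.exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).parent / "02_network_metrics.py")],
            check=True,
        )
    df = pd.read_csv(metrics_path, sep="\t")
    data = nb.FeatureMatrix.from_frame(df, nb.FEATURE_COLUMNS)
    model = nb.fit_discriminant(data)
    predicted, pct = nb.reclassify(model, data)
    loo = nb.leave_one_out_accuracy(data)

    scores = model.transform(data.X)
    out = df[["well_id", "group_label"]].copy()
    out["predicted"] = predicted
    for j in range(scores.shape[1]):
        out[f"canonical_{j + 1}"] = scores[:, j]
    out.to_csv(results / "discriminant_scores.tsv", sep="\t", index=False)

    envelopes = nb.group_envelopes(model, data)
    pd.DataFrame(
        [
            {"group": e.group, "center_1": e.center[0], "center_2": e.center[1],
             "semi_major": e.semi_axes[0], "semi_minor": e.semi_axes[1],
             "angle_deg": e.angle_deg}
            for e in envelopes
        ]
    ).to_csv(results / "discriminant_envelopes.tsv", sep="\t", index=False)

    print(f"scores -> {results}/discriminant_scores.tsv")
    print(f"resubstitution accuracy: {pct:.0f}% correct classification")
    print(f"leave-one-out accuracy:  {loo:.0f}%")
    for e in envelopes:
        print(
            f"  {e.group}: centroid ({e.center[0]:+.2f}, {e.center[1]:+.2f}), "
            f"95% envelope semi-axes ({e.semi_axes[0]:.2f}, {e.semi_axes[1]:.2f})"
        )


if __name__ == "__main__":
    main()
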