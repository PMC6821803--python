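"""Treatment-condition comparisons normalized to the non-treated baseline.

Acute pharmacology on MEAs (AMPAR block with NBQX, NMDAR block with D-AP5 or
MK-801, Ca²⁺-permeable-AMPAR block with Naspm, Kv7 activation with Retigabine)
is analyzed as a series of recording segments per well: a non-treated (NT)
baseline followed by post-treatment segments at increasing time offsets.
Every metric is reported as a ratio to the well's own NT value, which removes
between-well scale differences; recovery at an arbitrary time is read off the
ratio series by linear interpolation. Chronic (7-day) treatments are ordinary
condition groups at matched DIV. Hypothesis testing is out of scope — the
module reports group means, SEMs and pairwise differences only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError
from .network import NetworkMetrics


@dataclass
class ConditionSeries:
    """Metric segments of one well across a treatment time course.

    ``t_offsets`` are minutes from treatment; the NT baseline segment carries
    offset NaN by convention and must be present before normalization.
    """

    well_id: str
    condition: str
    nt_metrics: NetworkMetrics
    t_offsets: list[float] = field(default_factory=list)
    segments: list[NetworkMetrics] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.t_offsets) != len(self.segments):
            raise ValidationError("one metric vector per time offset required")
        if any(b <= a for a, b in zip(self.t_offsets, self.t_offsets[1:])):
            raise ValidationError("t_offsets must be strictly increasing")


def normalize_to_baseline(series: ConditionSeries, field_name: str) -> list[tuple[float, float]]:
    """Per-segment ratio of ``field_name`` to the well's NT value.

    The NT value must be finite and positive; full suppression in a treated
    segment yields ratio 0.0.
    """
    baseline = getattr(series.nt_metrics, field_name)
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValidationError(
            f"well {series.well_id}: NT value of {field_name!r} is "
            f"{baseline}; cannot normalize"
        )
    out = []
    for t, seg in zip(series.t_offsets, series.segments):
        value = getattr(seg, field_name)
        out.append((t, value / baseline))
    return out


def recovery_fraction(series: ConditionSeries, field_name: str, t: float) -> float:
    """Normalized ratio at ``t`` minutes post-treatment, linearly interpolated."""
    ratios = normalize_to_baseline(series, field_name)
    ts = np.array([r[0] for r in ratios])
    vs = np.array([r[1] for r in ratios])
    if t < ts[0] or t > ts[-1]:
        raise ValidationError(
            f"t = {t} min outside recorded range [{ts[0]}, {ts[-1]}] min"
        )
    return float(np.interp(t, ts, vs))


def compare_conditions(
    groups: dict[str, list[NetworkMetrics]], field_name: str
) -> pd.DataFrame:
    """Per-condition mean ± SEM of a metric, plus pairwise mean differences.

    Descriptive only (no p-values). Conditions with fewer than two wells are
    flagged and get a NaN SEM.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two conditions to compare")
    rows = []
    means = {}
    for cond, metrics in groups.items():
        values = np.array([getattr(m, field_name) for m in metrics], dtype=float)
        mean = float(np.mean(values)) if values.size else float("nan")
        sem = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size >= 2 else float("nan")
        means[cond] = mean
        rows.append(
            {
                "condition": cond,
                "n": values.size,
                "mean": mean,
                "sem": sem,
                "flagged": values.size < 2,
            }
        )
    table = pd.DataFrame(rows).set_index("condition")
    conds = list(groups)
    diffs = [
        {"a": a, "b": b, "mean_difference": means[a] - means[b]}
        for i, a in enumerate(conds)
        for b in conds[i + 1:]
    ]
    table.attrs["pairwise"] = pd.DataFrame(diffs)
    return table
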