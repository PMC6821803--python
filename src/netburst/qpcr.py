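"""Closed-form qPCR quantifications: ChIP % input and 2^−ΔΔCt fold change.

ChIP-qPCR enrichment is expressed as percent of (dilution-corrected) input
chromatin:

    % input = 100 × 2^−ΔCt,   ΔCt = Ct[ChIP] − (Ct[input] − log2(dilution factor))

Relative expression uses the plain 2^−ΔΔCt model (no amplification-efficiency
correction), normalized to housekeeping genes and a reference sample. Cts of
technical duplicates are averaged on the Ct scale *before* exponentiation;
biological replicates are summarized (mean ± SEM) on the computed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass(frozen=True)
class CtRecord:
    target: str
    sample: str
    ct: float
    role: str  # chip | input | target_gene | housekeeping
    dilution_factor: float = 1.0
    condition: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValidationError("Ct must be finite")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")


def _check_finite(*cts: float) -> None:
    for ct in cts:
        if not math.isfinite(ct):
            raise ValidationError(f"non-finite Ct value: {ct}")


def percent_input(ct_chip: float, ct_input: float, dilution_factor: float = 1.0) -> float:
    """ChIP enrichment as % of dilution-corrected input chromatin."""
    _check_finite(ct_chip, ct_input)
    if dilution_factor < 1:
        raise ValidationError("dilution_factor must be >= 1")
    delta_ct = ct_chip - (ct_input - math.log2(dilution_factor))
    return 100.0 * 2.0 ** (-delta_ct)


def ddct_fold_change(
    ct_target_sample: float,
    ct_housekeeping_sample: float,
    ct_target_reference: float,
    ct_housekeeping_reference: float,
) -> float:
    """Relative expression by 2^−ΔΔCt against housekeeping and reference."""
    _check_finite(ct_target_sample, ct_housekeeping_sample,
                  ct_target_reference, ct_housekeeping_reference)
    ddct = (ct_target_sample - ct_housekeeping_sample) - (
        ct_target_reference - ct_housekeeping_reference
    )
    return 2.0 ** (-ddct)


def average_technical_duplicates(records: list[CtRecord]) -> list[CtRecord]:
    """Collapse technical replicas by arithmetic mean on the Ct scale."""
    df = pd.DataFrame([r.__dict__ for r in records])
    keys = ["target", "sample", "role", "dilution_factor", "condition"]
    out = []
    for key, grp in df.groupby(keys, sort=True):
        rec = dict(zip(keys, key))
        out.append(CtRecord(ct=float(grp["ct"].mean()), **rec))
    return out


def summarize_replicates(values_by_condition: dict[str, list[float]]) -> pd.DataFrame:
    """Mean ± SEM per condition on the computed (% input or fold) scale.

    Input values must already be the per-replicate computed quantities (i.e.
    technical duplicates were averaged on the Ct scale first). A single
    replicate is flagged with an undefined SEM.
    """
    rows = []
    for condition, values in values_by_condition.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValidationError(f"condition {condition!r} has no replicates")
        rows.append(
            {
                "condition": condition,
                "n": v.size,
                "mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else float("nan"),
                "flagged": v.size < 2,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
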