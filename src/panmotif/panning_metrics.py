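"""Titer arithmetic, round-wise recovery/enrichment, and ELISA classification.

Phage titers are expressed in plaque-forming units per millilitre
(pfu/ml), computed from plaque counts on serial-dilution plates.  The
recovery rate of one panning round is recovered/input titer; its rise
across rounds measures enrichment, and a plateau marks the saturation
point of the screen.  Candidate clones are called positive when their
stretched/static ELISA OD450 ratio meets a fold threshold (3.0 in the
screen this package models; the boundary is inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "TiterMeasurement",
    "RecoveryRecord",
    "ElisaRecord",
    "compute_titer",
    "recovery_rate",
    "enrichment_profile",
    "classify_positive",
    "binding_fold_change",
]

#: plaque counts above this exceed the reliably countable range of a plate
COUNTABLE_MAX = 300


class CountableRangeWarning(UserWarning):
    """Plaque count beyond the countable range (lawn-clearing)."""


class UnevaluableRecordWarning(UserWarning):
    """An ELISA record that cannot be classified (non-positive static OD)."""


@dataclass
class TiterMeasurement:
    label: str
    plaque_count: int
    dilution_factor: float
    volume_plated_ml: float

    @property
    def titer_pfu_per_ml(self) -> float:
        return compute_titer(
            self.plaque_count, self.dilution_factor, self.volume_plated_ml
        )


@dataclass
class RecoveryRecord:
    """One panning round's titers; rate and enrichment are derived."""

    round_index: int
    input_titer: float
    recovered_titer: float
    enrichment_vs_r1: Optional[float] = None

    @property
    def recovery_rate(self) -> float:
        return recovery_rate(self.recovered_titer, self.input_titer)


@dataclass
class ElisaRecord:
    clone_id: str
    od_stretched: float
    od_static: float
    ratio: Optional[float] = None
    positive: Optional[bool] = None


def compute_titer(
    plaque_count: int, dilution_factor: float, volume_plated_ml: float
) -> float:
    """pfu/ml = plaques x dilution / plated volume.

    A dilution_factor of 1e6 means a 10^-6 dilution was plated.  Counts
    above the countable range (> 300) trigger a warning, not an error.
    """
    if plaque_count < 0:
        raise ValueError("plaque_count must be >= 0")
    if dilution_factor <= 0 or volume_plated_ml <= 0:
        raise ValueError("dilution factor and plated volume must be positive")
    if plaque_count > COUNTABLE_MAX:
        warnings.warn(
            f"plaque count {plaque_count} exceeds the countable range "
            f"(> {COUNTABLE_MAX}); plate a higher dilution",
            CountableRangeWarning,
            stacklevel=2,
        )
    return plaque_count * dilution_factor / volume_plated_ml


def recovery_rate(recovered_titer: float, input_titer: float) -> float:
    """Recovered/input phage titer for one round (dimensionless)."""
    if input_titer <= 0:
        raise ValueError("input titer must be positive")
    if recovered_titer < 0:
        raise ValueError("recovered titer must be >= 0")
    return recovered_titer / input_titer


def enrichment_profile(
    rounds: Sequence[RecoveryRecord], saturation_tol: float = 0.10
) -> tuple[list[float], Optional[bool]]:
    """Enrichment of each round vs round 1, plus a saturation verdict.

    Enrichment is reported against round 1 (the screen's own convention
    for its final enrichment figure); the saturation flag is driven by
    the relative change of recovery rate between the last two rounds,
    saturated iff |r_n - r_{n-1}| / r_{n-1} <= saturation_tol.  With
    fewer than two rounds the verdict is None (unknown).
    """
    if not rounds:
        return [], None
    idx = [r.round_index for r in rounds]
    if idx != sorted(idx) or idx[0] != 1:
        raise ValueError("rounds must be sorted by round_index starting at 1")
    r1 = rounds[0].recovery_rate
    ratios = [r.recovery_rate / r1 for r in rounds]
    for rec, ratio in zip(rounds, ratios):
        rec.enrichment_vs_r1 = ratio
    if len(rounds) < 2:
        return ratios, None
    prev, last = rounds[-2].recovery_rate, rounds[-1].recovery_rate
    saturated = abs(last - prev) / prev <= saturation_tol
    return ratios, saturated


def classify_positive(
    records: Iterable[tuple[str, float, float]], fold_threshold: float = 3.0
) -> tuple[list[ElisaRecord], int]:
    """Call positive clones by the stretched/static OD450 fold rule.

    A clone is positive iff od_stretched / od_static >= fold_threshold
    (boundary inclusive: a clone exactly at the fold meets it).  Records
    with non-positive static OD are flagged unevaluable (ratio and
    positive left None) and excluded from the summary count, with a
    warning.  Returns the per-clone records and the positive count; the
    count is invariant under record order.
    """
    out: list[ElisaRecord] = []
    n_positive = 0
    for clone_id, od_stretched, od_static in records:
        if od_static <= 0:
            warnings.warn(
                f"clone {clone_id}: static OD {od_static} <= 0, unevaluable",
                UnevaluableRecordWarning,
                stacklevel=2,
            )
            out.append(ElisaRecord(clone_id, od_stretched, od_static))
            continue
        ratio = od_stretched / od_static
        positive = ratio >= fold_threshold
        n_positive += positive
        out.append(ElisaRecord(clone_id, od_stretched, od_static, ratio, positive))
    return out, n_positive


def binding_fold_change(titer_test: float, titer_reference: float) -> float:
    """Fold change of a test titer over a reference titer."""
    if titer_reference <= 0:
        raise ValueError("reference titer must be positive")
    return titer_test / titer_reference
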