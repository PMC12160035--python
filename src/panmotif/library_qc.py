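"""NNK design-rule enforcement for the 7-codon random region.

Ph.D.-style display libraries encode the random region with NNK codons
(N = any base, K = G or T), so in a correctly synthesised insert the
third nucleotide of every codon is G or T.  Reads violating that rule
point to wild-type phage contamination or sequencing error and are
excluded; the survivors are translated into the heptapeptide pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .dereplication import Heptapeptide
from .seqio import (
    InsertRecord,
    InsertStatus,
    PrematureStopError,
    translate_codons,
)

__all__ = ["ExclusionReason", "Exclusion", "QCReport", "validate_nnk", "filter_library"]

RANDOM_REGION_LEN = 21
N_CODONS = 7


class ExclusionReason(str, Enum):
    THIRD_BASE_NOT_GT = "third-base-not-GT"
    PREMATURE_STOP = "premature-stop"
    AMBIGUOUS_BASE = "ambiguous-base"
    LENGTH_MISMATCH = "length-mismatch"
    EXTRACTION_FAILED = "extraction-failed"


@dataclass
class Exclusion:
    clone_id: str
    reasons: list[ExclusionReason]
    failed_codons: list[int] = field(default_factory=list)


@dataclass
class QCReport:
    """Accounting of every input record: n_input == n_excluded + n_passed."""

    n_input: int
    n_excluded: int
    n_passed: int
    exclusions: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_excluded + self.n_passed

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "n_excluded": self.n_excluded,
                    "n_passed": self.n_passed,
                },
                indent=2,
            )
        )

    def write_exclusions(self, path: str | Path) -> None:
        rows = [
            {
                "clone_id": e.clone_id,
                "reason": ";".join(r.value for r in e.reasons),
                "failed_codons": ",".join(str(c) for c in e.failed_codons),
            }
            for e in self.exclusions
        ]
        pd.DataFrame(rows, columns=["clone_id", "reason", "failed_codons"]).to_csv(
            path, sep="\t", index=False
        )


def validate_nnk(insert_dna: str) -> tuple[bool, list[int]]:
    """Check the third base of each of the 7 codons against {G, T}.

    Returns ``(valid, failed_codons)`` with 1-based codon indices; codon i
    fails iff its third base is A or C.
    """
    if len(insert_dna) != RANDOM_REGION_LEN:
        raise ValueError(
            f"insert length {len(insert_dna)} != {RANDOM_REGION_LEN}"
        )
    if "N" in insert_dna:
        raise ValueError("insert contains ambiguous base N")
    failed = [
        i + 1 for i in range(N_CODONS) if insert_dna[3 * i + 2] not in "GT"
    ]
    return (not failed, failed)


def filter_library(
    inserts: Iterable[InsertRecord],
) -> tuple[list[Heptapeptide], QCReport]:
    """Apply the NNK rule to every insert and translate the survivors.

    A record failing for multiple reasons is excluded once, with all
    reasons listed.  Premature hard stops (TAA/TGA) are an exclusion
    reason rather than an error: the screen attributes such anomalies to
    wild-type phages or sequencing errors, so they are dropped, not fatal.
    """
    peptides: list[Heptapeptide] = []
    exclusions: list[Exclusion] = []
    n_input = 0
    for rec in inserts:
        n_input += 1
        reasons: list[ExclusionReason] = []
        failed: list[int] = []
        if rec.status is InsertStatus.ANCHORS_NOT_FOUND:
            reasons.append(ExclusionReason.EXTRACTION_FAILED)
        elif rec.status is InsertStatus.LENGTH_MISMATCH:
            reasons.append(ExclusionReason.LENGTH_MISMATCH)
        elif rec.status is InsertStatus.AMBIGUOUS_BASE:
            reasons.append(ExclusionReason.AMBIGUOUS_BASE)
        else:
            valid, failed = validate_nnk(rec.insert_dna)
            rec.valid = valid
            rec.failed_codons = failed
            if not valid:
                reasons.append(ExclusionReason.THIRD_BASE_NOT_GT)
            try:
                peptide = translate_codons(rec.insert_dna)
            except PrematureStopError:
                reasons.append(ExclusionReason.PREMATURE_STOP)
            else:
                if not reasons:
                    peptides.append(
                        Heptapeptide(
                            sequence=peptide,
                            multiplicity=1,
                            parent_clone_ids=[rec.clone_id],
                        )
                    )
        if reasons:
            exclusions.append(
                Exclusion(
                    clone_id=rec.clone_id, reasons=reasons, failed_codons=failed
                )
            )
    report = QCReport(
        n_input=n_input,
        n_excluded=len(exclusions),
        n_passed=len(peptides),
        exclusions=exclusions,
    )
    return peptides, report
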