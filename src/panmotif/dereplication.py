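"""Collapse identical heptapeptides into non-redundant representatives.

Display-library screens report a non-redundant peptide set before any
motif statistics; for 7-mers that step is exact-string grouping with
multiplicities (the sub-identity clustering offered by general-purpose
tools has no effect at this length unless explicitly relaxed, which this
module does not support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = ["Heptapeptide", "dereplicate", "as_pool", "write_peptide_table"]

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Heptapeptide:
    """A 7-mer peptide with its multiplicity and parent clone ids."""

    sequence: str
    multiplicity: int = 1
    parent_clone_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != 7:
            raise ValueError(f"{self.sequence!r}: heptapeptides have length 7")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"{self.sequence!r}: non-canonical residues {sorted(bad)}"
            )
        if not self.parent_clone_ids:
            self.parent_clone_ids = [""] * self.multiplicity
        if self.multiplicity != len(self.parent_clone_ids):
            raise ValueError(
                f"{self.sequence!r}: multiplicity {self.multiplicity} != "
                f"{len(self.parent_clone_ids)} parent clones"
            )


PoolLike = Sequence[Union[str, Heptapeptide]]


def as_pool(sequences: Iterable[Union[str, Heptapeptide]]) -> list[Heptapeptide]:
    """Normalise a mixed iterable of strings/records into Heptapeptides."""
    return [
        p if isinstance(p, Heptapeptide) else Heptapeptide(sequence=p)
        for p in sequences
    ]


def dereplicate(peptides: PoolLike, identity: float = 1.0) -> list[Heptapeptide]:
    """Group identical heptapeptides, merging multiplicities and parent ids.

    Only exact identity (1.0) is supported: at seven residues, redundancy
    removal is exact-string grouping, and approximate clustering below
    identity 1.0 is deliberately not implemented (a CD-HIT-style
    sub-identity mode would be required; requesting one raises
    ``NotImplementedError``).

    Output is sorted by multiplicity descending, then lexicographically,
    so identical inputs always yield identical output.  The sum of output
    multiplicities equals the total input multiplicity (conservation).
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    if identity < 1.0:
        raise NotImplementedError(
            "sub-identity clustering (CD-HIT style) is not implemented; "
            "only exact-identity (1.0) dereplication of 7-mers is supported"
        )
    groups: dict[str, Heptapeptide] = {}
    for pep in as_pool(peptides):
        rep = groups.get(pep.sequence)
        if rep is None:
            groups[pep.sequence] = Heptapeptide(
                sequence=pep.sequence,
                multiplicity=pep.multiplicity,
                parent_clone_ids=list(pep.parent_clone_ids),
            )
        else:
            rep.multiplicity += pep.multiplicity
            rep.parent_clone_ids.extend(pep.parent_clone_ids)
    return sorted(groups.values(), key=lambda p: (-p.multiplicity, p.sequence))


def write_peptide_table(peptides: Iterable[Heptapeptide], path) -> None:
    """TSV: sequence, multiplicity, parent_clone_ids (comma-joined)."""
    rows = [
        {
            "sequence": p.sequence,
            "multiplicity": p.multiplicity,
            "parent_clone_ids": ",".join(p.parent_clone_ids),
        }
        for p in peptides
    ]
    pd.DataFrame(
        rows, columns=["sequence", "multiplicity", "parent_clone_ids"]
    ).to_csv(path, sep="\t", index=False)
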