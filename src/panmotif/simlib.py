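"""Synthetic phage-display data with exhaustive ground truth.

Emulates the data regimes of a Ph.D.-C7C-style screen: NNK-encoded
7-mer inserts between fixed vector anchors (half the reads emitted
reverse-complemented, Phred qualities in the high-30s), optional spiked
enrichment motifs back-translated through NNK-compatible codons so the
spike is invisible at the DNA-composition level, wild-type/sequencing-
error contamination applied to an exact number of reads, per-clone ELISA
OD pairs, and round-wise panning titer tables with Poisson plaque
counts.  Every generator returns a ground-truth table alongside the data
so downstream modules can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .seqio import SequenceRead, reverse_complement, translate_codons

__all__ = [
    "SimulationSpec",
    "SpecError",
    "generate_nnk_library",
    "corrupt_library",
    "simulate_elisa",
    "simulate_panning",
    "NNK_CODONS",
    "NNK_BY_RESIDUE",
]

#: synthetic vector anchors flanking the random region; the 3' end of the
#: 5' anchor and the 5' start of the 3' anchor carry the Cys codons of the
#: disulfide-constrained Cys-X7-Cys display architecture
DEFAULT_FLANK5 = "TCTCACTCGGCCGACGGGGCTTGT"
DEFAULT_FLANK3 = "TGCGGTGGAGGTTCGGCCGAAACT"


class SpecError(ValueError):
    """An inconsistent or unsatisfiable simulation specification."""


def _nnk_codons() -> list[str]:
    return [a + b + k for a in "ACGT" for b in "ACGT" for k in "GT"]


NNK_CODONS = _nnk_codons()
#: residue -> NNK codons encoding it (TAG included under amber suppression)
NNK_BY_RESIDUE: dict[str, list[str]] = {}
for _codon in NNK_CODONS:
    NNK_BY_RESIDUE.setdefault(translate_codons(_codon), []).append(_codon)


@dataclass
class SimulationSpec:
    """Conditions for one synthetic library.

    Defaults reproduce the composition of the screen this package
    models: 723 sequenced positive clones of which 16 carry an insert
    violating the NNK third-base rule.
    """

    n_clones: int = 723
    rng_seed: int = 0
    spikes: dict[str, float] = field(default_factory=dict)
    n_invalid: int = 16
    n_wildtype: int = 0
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if self.n_clones < 0 or self.n_invalid < 0 or self.n_wildtype < 0:
            raise SpecError("counts must be >= 0")
        if self.n_invalid + self.n_wildtype > self.n_clones:
            raise SpecError("n_invalid + n_wildtype exceeds n_clones")
        if sum(self.spikes.values()) > 1.0:
            raise SpecError("spike frequencies sum above 1")
        for motif in self.spikes:
            if not 1 <= len(motif) <= 7:
                raise SpecError(f"spike motif {motif!r} longer than 7 residues")


def _random_nnk_codon(rng: np.random.Generator) -> str:
    return NNK_CODONS[rng.integers(len(NNK_CODONS))]


def _back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Sample uniformly among NNK-compatible codons for each residue."""
    codons = []
    for aa in peptide:
        options = NNK_BY_RESIDUE[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def generate_nnk_library(
    spec: SimulationSpec,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Generate amplicon reads and an exhaustive ground-truth table.

    Non-spiked inserts are 7 i.i.d. NNK codons; spiked clones embed the
    spike's residues at a uniformly chosen offset, back-translated
    through NNK-compatible codons.  Reads are flank5 + insert + flank3,
    with exactly half (rounded down) emitted reverse-complemented.
    Ground-truth columns: clone_id, insert_dna, peptide, spike, strand,
    nnk_valid, wildtype, failed_codon.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = list(spec.spikes) + [""]
    probs = list(spec.spikes.values())
    probs.append(1.0 - sum(probs))
    clone_labels = rng.choice(labels, size=spec.n_clones, p=probs)

    n_rc = spec.n_clones // 2
    rc_idx = set(rng.permutation(spec.n_clones)[:n_rc].tolist())

    width = len(str(max(spec.n_clones, 1)))
    reads: list[SequenceRead] = []
    rows = []
    for i in range(spec.n_clones):
        label = str(clone_labels[i])
        if label:
            offset = int(rng.integers(0, 7 - len(label) + 1))
            residues = [None] * 7
            for k, aa in enumerate(label):
                residues[offset + k] = aa
            codons = []
            for aa in residues:
                if aa is None:
                    codons.append(_random_nnk_codon(rng))
                else:
                    opts = NNK_BY_RESIDUE[aa]
                    codons.append(opts[rng.integers(len(opts))])
            insert = "".join(codons)
        else:
            insert = "".join(_random_nnk_codon(rng) for _ in range(7))
        clone_id = f"clone{i + 1:0{width}d}"
        amplicon = spec.flank5 + insert + spec.flank3
        if i in rc_idx:
            dna, strand = reverse_complement(amplicon), "reverse-complemented"
        else:
            dna, strand = amplicon, "as-read"
        quality = rng.integers(36, 41, size=len(dna)).tolist()
        reads.append(SequenceRead(read_id=clone_id, dna=dna, quality=quality))
        rows.append(
            {
                "clone_id": clone_id,
                "insert_dna": insert,
                "peptide": translate_codons(insert),
                "spike": label,
                "strand": strand,
                "nnk_valid": True,
                "wildtype": False,
                "failed_codon": 0,
            }
        )
    return reads, pd.DataFrame(rows)


def _splice_insert(dna: str, old_insert: str, new_insert: str, strand: str) -> str:
    """Replace the insert region of a read, respecting its orientation."""
    if strand == "reverse-complemented":
        old, new = reverse_complement(old_insert), reverse_complement(new_insert)
    else:
        old, new = old_insert, new_insert
    i = dna.find(old)
    if i < 0:
        raise SpecError("insert not found in read; truth table out of sync")
    return dna[:i] + new + dna[i + len(old) :]


def corrupt_library(
    reads: list[SequenceRead],
    truth: pd.DataFrame,
    n_invalid: int,
    n_wildtype: int,
    seed: int,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Introduce exact numbers of NNK violations and wild-type reads.

    Exactly ``n_invalid`` inserts get the third base of one codon flipped
    to A or C (guaranteeing a third-base rule violation); exactly
    ``n_wildtype`` reads have their whole sequence replaced by vector-like
    DNA lacking both anchors.  Counts are exact, not probabilistic, so
    fixture compositions are deterministic.  Returns new reads and an
    updated truth table; inputs are not modified.
    """
    if n_invalid + n_wildtype > len(reads):
        raise SpecError("corruption counts exceed the number of reads")
    rng = np.random.default_rng(seed)
    picked = rng.permutation(len(reads))[: n_invalid + n_wildtype]
    invalid_idx = set(picked[:n_invalid].tolist())
    wildtype_idx = set(picked[n_invalid:].tolist())
    truth = truth.copy()
    out: list[SequenceRead] = []
    for i, read in enumerate(reads):
        if i in invalid_idx:
            insert = truth.at[i, "insert_dna"]
            codon = int(rng.integers(0, 7))
            base = "AC"[rng.integers(2)]
            pos = 3 * codon + 2
            new_insert = insert[:pos] + base + insert[pos + 1 :]
            dna = _splice_insert(read.dna, insert, new_insert, truth.at[i, "strand"])
            out.append(SequenceRead(read.read_id, dna, read.quality))
            truth.at[i, "insert_dna"] = new_insert
            truth.at[i, "peptide"] = ""
            truth.at[i, "nnk_valid"] = False
            truth.at[i, "failed_codon"] = codon + 1
        elif i in wildtype_idx:
            dna = _vector_like(len(read.dna), rng)
            out.append(SequenceRead(read.read_id, dna, read.quality))
            truth.at[i, "insert_dna"] = ""
            truth.at[i, "peptide"] = ""
            truth.at[i, "nnk_valid"] = False
            truth.at[i, "wildtype"] = True
        else:
            out.append(read)
    return out, truth


def _vector_like(length: int, rng: np.random.Generator) -> str:
    """Random DNA of the read's length guaranteed to lack both default anchors."""
    forbidden = []
    for anchor in (DEFAULT_FLANK5, DEFAULT_FLANK3):
        forbidden.append(anchor)
        forbidden.append(reverse_complement(anchor))
    while True:
        dna = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        if not any(f in dna for f in forbidden):
            return dna


def simulate_elisa(
    n_clones: int,
    n_positive: int,
    fold_threshold: float = 3.0,
    noise_sd: float = 0.02,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-clone OD450 pairs with an exact number of positive clones.

    Exactly ``n_positive`` clones end at or above the fold threshold
    after noise; margins between the target ratios and the threshold are
    wide enough that noise cannot flip a label (boundary draws are
    rejection-resampled).  Columns: clone_id, od_stretched, od_static,
    true_positive.
    """
    if n_positive > n_clones:
        raise SpecError("n_positive exceeds n_clones")
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    # the narrowest OD gap between a label's ratio band and the threshold:
    # positives sit at >= 1.15x the fold, statics start at 0.2 OD
    margin = 0.15 * fold_threshold * 0.2
    if noise_sd > margin:
        raise SpecError(
            f"noise_sd {noise_sd} exceeds the label margin {margin:.3g}; "
            "labels could flip"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_clones, dtype=bool)
    labels[:n_positive] = True
    labels = labels[rng.permutation(n_clones)]
    width = len(str(max(n_clones, 1)))
    rows = []
    for i, positive in enumerate(labels):
        od_static = float(rng.uniform(0.2, 0.6))
        if positive:
            ratio = fold_threshold * float(rng.uniform(1.15, 3.0))
        else:
            ratio = fold_threshold * float(rng.uniform(0.25, 0.85))
        for attempt in range(1000):
            od_stretched = od_static * ratio + float(rng.normal(0.0, noise_sd))
            if od_stretched < 0:
                continue
            if (od_stretched / od_static >= fold_threshold) == positive:
                break
        else:
            raise SpecError(
                f"noise_sd {noise_sd} too large for the requested fold margins"
            )
        rows.append(
            {
                "clone_id": f"clone{i + 1:0{width}d}",
                "od_stretched": od_stretched,
                "od_static": od_static,
                "true_positive": bool(positive),
            }
        )
    return pd.DataFrame(rows)


def simulate_panning(
    n_rounds: int = 4,
    base_recovery: float = 9.2e-4,
    enrichment_factor: float = 5.0,
    plateau_round: int = 4,
    seed: Optional[int] = None,
    input_titer: float = 2.5e9,
    volume_plated_ml: float = 0.01,
) -> pd.DataFrame:
    """Round-wise titer table with geometric enrichment up to a plateau.

    The true recovery rate grows geometrically by ``enrichment_factor``
    per round until ``plateau_round``, from which it holds at the
    previous round's level within 5% jitter (so the trajectory is
    saturated at ``plateau_round``).  Recovered-phage plaque counts are
    Poisson draws at a dilution chosen to land in the countable range.
    Columns: round_index, input_titer, plaque_count, dilution_factor,
    volume_plated_ml, recovered_titer, true_recovery_rate.
    """
    if n_rounds < 1:
        raise SpecError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, n_rounds + 1):
        capped = min(r, max(plateau_round - 1, 1))
        rate = base_recovery * enrichment_factor ** (capped - 1)
        if r >= plateau_round:
            rate *= float(rng.uniform(0.97, 1.03))
        recovered_true = rate * input_titer
        # plate the 10-fold dilution whose expected count is nearest ~200
        target = 200.0
        exponent = round(math.log10(max(recovered_true * volume_plated_ml, 1.0) / target))
        dilution = 10.0 ** max(exponent, 0)
        expected = recovered_true * volume_plated_ml / dilution
        count = int(rng.poisson(expected))
        recovered_measured = count * dilution / volume_plated_ml
        rows.append(
            {
                "round_index": r,
                "input_titer": input_titer,
                "plaque_count": count,
                "dilution_factor": dilution,
                "volume_plated_ml": volume_plated_ml,
                "recovered_titer": recovered_measured,
                "true_recovery_rate": rate,
            }
        )
    return pd.DataFrame(rows)
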