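"""Tripeptide motif statistics for heptapeptide pools.

The enrichment statistic of a biopanning screen analysed here is
tripeptide *abundance*: every heptapeptide is segmented into overlapping
3-mer windows in both the forward and the reverse reading direction
(5 windows each, 10 per peptide), and the abundance of a tripeptide is
its total occurrence count across all windows of the pool.  A motif and
its reversal are distinct count keys; palindromic motifs therefore
accrue counts from both orientations.

Significance is assessed with a random permutation test: the residues of
the whole pool are shuffled jointly (preserving overall amino-acid
composition and the number and length of peptides) and the null
abundance of every observed motif is recomputed per replicate.  Raw
p-values use the add-one estimator, p = (1 + b) / (1 + n), so they are
never zero; Bonferroni correction then controls the family-wise error
over the tested motifs.  Motifs pass selection if their abundance
exceeds a count threshold or their adjusted p-value is significant.

Selected tripeptides are extended into 4-6 residue consensus motifs by
an anchor-pinned ungapped star alignment of the parent heptapeptides:
7-mers sharing an exact 3-mer admit a unique gap-free anchoring, so a
general gapped aligner would only add nondeterminism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dereplication import Heptapeptide, PoolLike

__all__ = [
    "DiscoveryConfig",
    "TripeptideStat",
    "ExtendedMotif",
    "segment_tripeptides",
    "count_abundance",
    "permutation_test",
    "bonferroni_adjust",
    "select_motifs",
    "extend_motifs",
    "write_motif_table",
    "write_extended_table",
]

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)
#: number of possible tripeptides over the canonical alphabet (20^3)
N_TRIPEPTIDES = N_AA**3
PEPTIDE_LEN = 7
WINDOWS_PER_DIRECTION = PEPTIDE_LEN - 2


@dataclass
class DiscoveryConfig:
    """Knobs of the motif-discovery stage.

    abundance_threshold
        Count above which a motif is selected regardless of significance
        (strict: abundance must *exceed* the threshold).
    alpha
        Family-wise significance level applied to adjusted p-values.
    n_permutations
        Number of shuffled replicates for the permutation test.
    rng_seed
        Seed for the permutation RNG; required for reproducible runs.
    bonferroni_m
        "observed-distinct" corrects over the motifs actually observed;
        "all-8000" corrects over every possible tripeptide (20^3).
    weight_by_multiplicity
        Count each peptide once (default, the non-redundant convention)
        or proportionally to its clone multiplicity.
    shuffle_unit
        "pooled" shuffles all residues of the pool jointly; the
        "within-peptide" variant permutes residues inside each peptide,
        preserving per-peptide composition (sensitivity analysis).
    """

    abundance_threshold: int = 20
    alpha: float = 0.05
    n_permutations: int = 10_000
    rng_seed: Optional[int] = None
    bonferroni_m: str = "observed-distinct"
    weight_by_multiplicity: bool = False
    shuffle_unit: str = "pooled"

    def __post_init__(self) -> None:
        if self.abundance_threshold < 0:
            raise ValueError("abundance_threshold must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.bonferroni_m not in ("observed-distinct", "all-8000"):
            raise ValueError(f"unknown bonferroni_m {self.bonferroni_m!r}")
        if self.shuffle_unit not in ("pooled", "within-peptide"):
            raise ValueError(f"unknown shuffle_unit {self.shuffle_unit!r}")


@dataclass
class TripeptideStat:
    """Abundance and significance of one tripeptide motif."""

    motif: str
    n_forward: int
    n_reverse: int
    p_raw: Optional[float] = None
    p_adj: Optional[float] = None
    selected: bool = False
    selection_reason: frozenset[str] = frozenset()

    @property
    def abundance(self) -> int:
        return self.n_forward + self.n_reverse


@dataclass
class ExtendedMotif:
    """A 4-6 residue consensus built around an anchor tripeptide."""

    consensus: str
    anchor: str
    supporters: list[str]
    column_support: list[float] = field(default_factory=list)
    unextended: bool = False


def _sequences(peptides: PoolLike, weight_by_multiplicity: bool = False) -> list[str]:
    seqs: list[str] = []
    for p in peptides:
        if isinstance(p, Heptapeptide):
            seqs.extend([p.sequence] * (p.multiplicity if weight_by_multiplicity else 1))
        else:
            seqs.append(p)
    return seqs


def segment_tripeptides(peptide: str) -> tuple[list[str], list[str]]:
    """Split a 7-mer into its 5 forward and 5 reverse tripeptide windows.

    The reverse direction windows the reversed string, so each reverse
    window is the reversal of a forward window; exactly 10 tripeptides
    are produced per peptide.
    """
    if len(peptide) != PEPTIDE_LEN:
        raise ValueError(f"expected a 7-mer, got {peptide!r}")
    forward = [peptide[i : i + 3] for i in range(WINDOWS_PER_DIRECTION)]
    rev = peptide[::-1]
    reverse = [rev[i : i + 3] for i in range(WINDOWS_PER_DIRECTION)]
    return forward, reverse


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode peptides as an (n, 7) int array of residue indices."""
    try:
        return np.array(
            [[AA_INDEX[aa] for aa in s] for s in seqs], dtype=np.int64
        ).reshape(len(seqs), PEPTIDE_LEN)
    except KeyError as err:
        raise ValueError(f"non-canonical residue {err}") from err


def _window_codes(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of forward and reverse tripeptide windows, (n, 5) each."""
    def codes(m: np.ndarray) -> np.ndarray:
        return (
            m[:, 0:WINDOWS_PER_DIRECTION] * (N_AA * N_AA)
            + m[:, 1 : WINDOWS_PER_DIRECTION + 1] * N_AA
            + m[:, 2 : WINDOWS_PER_DIRECTION + 2]
        )

    return codes(mat), codes(mat[:, ::-1])


def _decode_motif(code: int) -> str:
    a, rem = divmod(code, N_AA * N_AA)
    b, c = divmod(rem, N_AA)
    return AA_ALPHABET[a] + AA_ALPHABET[b] + AA_ALPHABET[c]


def count_abundance(
    peptides: PoolLike, config: Optional[DiscoveryConfig] = None
) -> list[TripeptideStat]:
    """Count forward/reverse occurrences of every observed tripeptide.

    Returns one :class:`TripeptideStat` per distinct motif (p-fields
    unset), sorted by abundance descending then lexicographically.  The
    abundances over all motifs sum to 10 x pool size.
    """
    config = config or DiscoveryConfig()
    seqs = _sequences(peptides, config.weight_by_multiplicity)
    if not seqs:
        return []
    fwd, rev = _window_codes(_encode(seqs))
    n_fwd = np.bincount(fwd.ravel(), minlength=N_TRIPEPTIDES)
    n_rev = np.bincount(rev.ravel(), minlength=N_TRIPEPTIDES)
    total = n_fwd + n_rev
    stats = [
        TripeptideStat(
            motif=_decode_motif(code),
            n_forward=int(n_fwd[code]),
            n_reverse=int(n_rev[code]),
        )
        for code in np.nonzero(total)[0]
    ]
    stats.sort(key=lambda s: (-s.abundance, s.motif))
    return stats


def permutation_test(
    observed: Sequence[TripeptideStat],
    peptides: PoolLike,
    config: DiscoveryConfig,
) -> list[TripeptideStat]:
    """Fill ``p_raw`` for each observed motif by residue shuffling.

    Each replicate shuffles the pool's residues (jointly by default),
    re-deals them into peptides of the original lengths, and recomputes
    the null abundance of every observed motif.  The add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_permutations) keeps p-values
    strictly positive.  Runs are reproducible given ``rng_seed``.
    """
    seqs = _sequences(peptides, config.weight_by_multiplicity)
    if not observed:
        return []
    if not seqs:
        raise ValueError("observed statistics but empty pool")
    rng = np.random.default_rng(config.rng_seed)
    mat = _encode(seqs)
    n_pep = mat.shape[0]
    flat = mat.ravel()
    codes = np.array(
        [
            AA_INDEX[s.motif[0]] * N_AA * N_AA
            + AA_INDEX[s.motif[1]] * N_AA
            + AA_INDEX[s.motif[2]]
            for s in observed
        ],
        dtype=np.int64,
    )
    obs_ab = np.array([s.abundance for s in observed], dtype=np.int64)
    exceed = np.zeros(len(observed), dtype=np.int64)
    for _ in range(config.n_permutations):
        if config.shuffle_unit == "pooled":
            null_mat = rng.permutation(flat).reshape(n_pep, PEPTIDE_LEN)
        else:
            # independent permutation of each row via random-key argsort
            keys = rng.random(mat.shape)
            null_mat = np.take_along_axis(mat, np.argsort(keys, axis=1), axis=1)
        fwd, rev = _window_codes(null_mat)
        null_counts = np.bincount(fwd.ravel(), minlength=N_TRIPEPTIDES)
        null_counts += np.bincount(rev.ravel(), minlength=N_TRIPEPTIDES)
        exceed += null_counts[codes] >= obs_ab
    p_raw = (1.0 + exceed) / (1.0 + config.n_permutations)
    return [replace(s, p_raw=float(p)) for s, p in zip(observed, p_raw)]


def bonferroni_adjust(
    stats: Sequence[TripeptideStat], config: DiscoveryConfig
) -> list[TripeptideStat]:
    """p_adj = min(1, m * p_raw) with m per ``config.bonferroni_m``."""
    m = len(stats) if config.bonferroni_m == "observed-distinct" else N_TRIPEPTIDES
    out = []
    for s in stats:
        if s.p_raw is None:
            raise ValueError(f"motif {s.motif}: p_raw not computed")
        out.append(replace(s, p_adj=min(1.0, m * s.p_raw)))
    return out


def select_motifs(
    stats: Sequence[TripeptideStat], config: DiscoveryConfig
) -> list[TripeptideStat]:
    """Select motifs that are abundant (> threshold) or significant (< alpha).

    Returns only the selected motifs, each annotated with the criteria
    that fired, sorted by abundance descending, then adjusted p ascending,
    then lexicographically.
    """
    selected = []
    for s in stats:
        reasons = set()
        if s.abundance > config.abundance_threshold:
            reasons.add("abundant")
        if s.p_adj is not None and s.p_adj < config.alpha:
            reasons.add("significant")
        if reasons:
            selected.append(
                replace(s, selected=True, selection_reason=frozenset(reasons))
            )
    selected.sort(
        key=lambda s: (-s.abundance, s.p_adj if s.p_adj is not None else 1.0, s.motif)
    )
    return selected


def _orient_supporters(anchor: str, seqs: Iterable[str]) -> list[tuple[str, str, int]]:
    """(original, oriented, anchor_offset) for peptides containing the anchor.

    A peptide supports the anchor if the anchor occurs in its forward
    windows, or in its reverse windows — i.e. the reversed anchor occurs
    forward — in which case the peptide is reversed so the anchor reads
    forward.  The leftmost occurrence anchors the alignment.
    """
    out = []
    rev_anchor = anchor[::-1]
    for seq in seqs:
        i = seq.find(anchor)
        if i >= 0:
            out.append((seq, seq, i))
            continue
        flipped = seq[::-1]
        j = flipped.find(anchor)
        if j >= 0 and rev_anchor in seq:
            out.append((seq, flipped, j))
    return out


def extend_motifs(
    selected: Sequence[Union[str, TripeptideStat]],
    peptides: PoolLike,
    min_len: int = 4,
    max_len: int = 6,
    column_support_min: float = 0.5,
) -> list[ExtendedMotif]:
    """Grow each selected tripeptide into a 4-6 residue consensus.

    All parent heptapeptides containing the anchor (forward, or reversed
    and then flipped into forward orientation) are stacked in an ungapped
    star alignment pinned on the anchor.  A column is called consensus
    when it has a unique modal residue whose agreement fraction among the
    supporters covering that column is at least ``column_support_min``
    (an exact tie between residues is never consensus).  The reported
    motif is the longest contiguous consensus run containing the anchor,
    trimmed to ``max_len`` by dropping columns farthest from the anchor;
    runs shorter than ``min_len`` yield an anchor-only result flagged
    ``unextended``.  Anchors with fewer than two supporters are skipped.
    """
    seqs = _sequences(peptides)
    results: list[ExtendedMotif] = []
    for item in selected:
        anchor = item.motif if isinstance(item, TripeptideStat) else item
        supporters = _orient_supporters(anchor, seqs)
        if len(supporters) < 2:
            logger.info(
                "anchor %s skipped: %d supporter(s), need >= 2",
                anchor,
                len(supporters),
            )
            continue
        # columns indexed relative to the anchor start (anchor = 0, 1, 2)
        columns: dict[int, list[str]] = {}
        for _, oriented, off in supporters:
            for pos, aa in enumerate(oriented):
                columns.setdefault(pos - off, []).append(aa)
        consensus_cols: dict[int, tuple[str, float]] = {}
        for col, residues in columns.items():
            counts = pd.Series(residues).value_counts()
            if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
                continue  # tied mode: no consensus
            support = counts.iloc[0] / len(residues)
            if support >= column_support_min:
                consensus_cols[col] = (counts.index[0], float(support))
        lo, hi = 0, 2  # the anchor is always consensus among its supporters
        while lo - 1 in consensus_cols:
            lo -= 1
        while hi + 1 in consensus_cols:
            hi += 1
        while hi - lo + 1 > max_len:
            # trim the side farther from the anchor; ties drop the right
            if -lo > hi - 2:
                lo += 1
            else:
                hi -= 1
        run = list(range(lo, hi + 1))
        originals = [orig for orig, _, _ in supporters]
        if len(run) < min_len:
            results.append(
                ExtendedMotif(
                    consensus=anchor,
                    anchor=anchor,
                    supporters=originals,
                    column_support=[consensus_cols[c][1] for c in (0, 1, 2)],
                    unextended=True,
                )
            )
        else:
            results.append(
                ExtendedMotif(
                    consensus="".join(consensus_cols[c][0] for c in run),
                    anchor=anchor,
                    supporters=originals,
                    column_support=[consensus_cols[c][1] for c in run],
                    unextended=False,
                )
            )
    return results


def write_motif_table(stats: Iterable[TripeptideStat], path) -> None:
    """TSV: motif, n_forward, n_reverse, abundance, p_raw, p_adj, selected, reason."""
    rows = [
        {
            "motif": s.motif,
            "n_forward": s.n_forward,
            "n_reverse": s.n_reverse,
            "abundance": s.abundance,
            "p_raw": s.p_raw if s.p_raw is not None else "",
            "p_adj": s.p_adj if s.p_adj is not None else "",
            "selected": s.selected,
            "reason": ";".join(sorted(s.selection_reason)),
        }
        for s in stats
    ]
    pd.DataFrame(
        rows,
        columns=[
            "motif",
            "n_forward",
            "n_reverse",
            "abundance",
            "p_raw",
            "p_adj",
            "selected",
            "reason",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_extended_table(motifs: Iterable[ExtendedMotif], path) -> None:
    rows = [
        {
            "anchor": m.anchor,
            "consensus": m.consensus,
            "unextended": m.unextended,
            "n_supporters": len(m.supporters),
            "column_support": ",".join(f"{v:.3f}" for v in m.column_support),
            "supporters": ",".join(m.supporters),
        }
        for m in motifs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "anchor",
            "consensus",
            "unextended",
            "n_supporters",
            "column_support",
            "supporters",
        ],
    ).to_csv(path, sep="\t", index=False)
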