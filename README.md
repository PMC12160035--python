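# panmotif

Analysis pipeline for *in vivo* phage-display biopanning screens that
use an NNK-encoded disulfide-constrained 7-mer library (Ph.D.-C7C-style,
Cys-X7-Cys displayed on pIII). Given amplicon reads of the insert
region, the package decodes and validates the random region, collapses
the peptide pool, and finds enriched tripeptide motifs and their 4–6
residue consensus extensions — the computation that turns a pile of
sequenced phage clones into a short list of candidate targeting
peptides. It also covers the screen's bookkeeping: plaque-titer
arithmetic, round-wise recovery and enrichment, saturation detection,
and ELISA positive-clone classification.

## The method

1. **Insert decoding** (`seqio`). Each read is searched on both strands
   for the fixed vector anchors flanking the 21-nt random region; the
   enclosed insert is recorded with its strand. Codons translate with
   the standard genetic code, reading the amber codon TAG as Gln
   (libraries are propagated in supE hosts such as ER2738, where TAG is
   a sense codon); TAA/TGA are hard stops.
2. **NNK validation** (`library_qc`). The random region is synthesised
   from NNK codons (N = any base, K = G/T), so the third base of every
   codon must be G or T. Codon *i* fails iff its third base is A or C;
   any failing codon excludes the clone (wild-type contamination or
   sequencing error). Survivors become the heptapeptide pool.
3. **Dereplication** (`dereplication`). Identical 7-mers collapse into
   non-redundant representatives with multiplicities.
4. **Motif statistics** (`motif_discovery`). Every 7-mer is segmented
   into overlapping tripeptide windows in both reading directions
   (5 + 5 = 10 windows); the *abundance* of a tripeptide *t* is its
   total occurrence count over all windows of the pool, with *t* and
   its reversal kept as distinct motifs. Significance comes from a
   random permutation test: all residues of the pool are shuffled
   jointly and re-dealt into peptides of the original lengths, the null
   abundance of each observed motif is recomputed per replicate, and

       p_raw(t) = (1 + #{replicates with null abundance ≥ observed}) / (1 + n_permutations)

   followed by Bonferroni correction `p_adj = min(1, m · p_raw)` over
   the `m` observed motifs. Motifs with abundance > 20 or p_adj < 0.05
   are selected, then extended into 4–6 residue consensus motifs by an
   anchor-pinned ungapped star alignment of their parent heptapeptides.
5. **Panning metrics** (`panning_metrics`). Titer = plaques ×
   dilution / plated volume (pfu/ml); recovery rate = recovered/input
   titer per round; enrichment is reported against round 1 and a
   plateau between the last two rounds flags saturation. ELISA clones
   are positive when stretched/static OD450 ≥ 3-fold.
6. **Simulation** (`simlib`). Generates NNK libraries with optional
   spiked motifs (back-translated through NNK-compatible codons),
   exact numbers of rule-violating or wild-type reads, ELISA plates
   with an exact positive count, and round-wise panning titer tables —
   each with a ground-truth table, so every stage is testable offline.

## Worked example

```python
import panmotif as pm
from panmotif.simlib import DEFAULT_FLANK5, DEFAULT_FLANK3

spec = pm.SimulationSpec(n_clones=723, rng_seed=11,
                         spikes={"SPFPT": 0.12}, n_invalid=16)
reads, truth = pm.generate_nnk_library(spec)
reads, truth = pm.corrupt_library(reads, truth, spec.n_invalid,
                                  spec.n_wildtype, seed=12)

inserts = [pm.extract_insert(r, DEFAULT_FLANK5, DEFAULT_FLANK3) for r in reads]
peptides, report = pm.filter_library(inserts)
print(f"{report.n_input} reads -> {report.n_excluded} excluded -> "
      f"{report.n_passed} heptapeptides")

pool = pm.dereplicate(peptides)
cfg = pm.DiscoveryConfig(abundance_threshold=20, n_permutations=10_000,
                         rng_seed=13)
stats = pm.count_abundance(pool, cfg)
stats = pm.bonferroni_adjust(pm.permutation_test(stats, pool, cfg), cfg)
selected = pm.select_motifs(stats, cfg)
for s in selected[:5]:
    print(f"{s.motif}  abundance={s.abundance}  p_adj={s.p_adj:.3g}  "
          f"{sorted(s.selection_reason)}")
for m in pm.extend_motifs(selected, pool)[:3]:
    print(f"anchor {m.anchor} -> consensus {m.consensus} "
          f"({len(m.supporters)} supporters)")
```

prints

```
723 reads -> 16 excluded -> 707 heptapeptides
PFP  abundance=168  p_adj=0.367  ['abundant']
FPS  abundance=86  p_adj=0.367  ['abundant']
SPF  abundance=86  p_adj=0.367  ['abundant']
FPT  abundance=84  p_adj=0.367  ['abundant']
TPF  abundance=84  p_adj=0.367  ['abundant']
anchor PFP -> consensus SPFPT (84 supporters)
anchor FPS -> consensus TPFPS (86 supporters)
anchor SPF -> consensus SPFPT (86 supporters)
```

Of the 723 simulated clones, the 16 carrying a third-base violation are
excluded and 707 peptides survive. The pentapeptide SPFPT, spiked into
12 % of clones, dominates the abundance ranking through its constituent
tripeptides — PFP is a palindrome, so it accrues counts from both
reading directions — and the extension step reassembles the full 5-mer
(TPFPS is its reverse-orientation mirror). With 10,000 permutations and
~3,700 tested motifs, Bonferroni-adjusted p-values cannot drop below
≈ 0.37, so selection here is carried by the abundance channel (see
`docs/methods.md`).

The same pipeline runs from the shell:

```sh
panmotif simulate --spec spec.yaml --out-dir sim/
panmotif discover sim/reads.fastq --seed 13 --out-dir discovery/
panmotif panning titers.tsv
panmotif elisa od_table.tsv --fold-threshold 3
```

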