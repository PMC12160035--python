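# Methods

## Model and assumptions

The pipeline analyses a biopanning screen of an NNK-encoded,
disulfide-constrained 7-mer display library. Its units of inference are
tripeptides: three residues are the minimal framework for a
protein-protein recognition epitope, so enrichment is measured on
3-mers and only afterwards grown back into longer consensus motifs.

Assumptions baked into the defaults:

- **Amplicon structure.** Each read is vector + 21-nt random region +
  vector, sequenced from either strand. The vector anchors are exact:
  amplicon sequencing of a fixed vector should reproduce the anchors
  perfectly, so no mismatches are tolerated and a read whose anchors
  cannot be found on either strand is excluded rather than guessed at.
  A read containing N inside the insert is likewise excluded.
- **Amber suppression.** TAG is translated as Gln because display
  libraries of this architecture are propagated in supE hosts (ER2738),
  where TAG is read-through as glutamine. This is configurable
  (`translate_codons(..., amber_as=...)`); TAA/TGA always terminate.
- **NNK rule.** The random region is synthesised from NNK codons, so a
  third base of A or C in any codon is physically impossible in a
  correct clone. The rule is applied strictly per codon with no
  tolerance: one off-design codon excludes the clone. A record failing
  for several reasons (e.g. a third-base flip that also creates a TAA
  stop) is counted once, with all reasons listed — exclusions count
  clones, not codons.
- **Non-redundant counting.** Motif statistics run on the dereplicated
  pool, each distinct peptide counted once. Sequencing the same clone
  twice is evidence about sampling depth, not about motif enrichment; a
  `weight_by_multiplicity` flag exists for sensitivity analysis only.
  Dereplication itself is exact-string grouping: at seven residues
  there is no meaningful sub-identity clustering, and requesting
  identity < 1.0 raises `NotImplementedError` rather than silently
  approximating.

## The motif statistic

Each 7-mer yields 5 forward windows and 5 windows of the reversed
string (10 per peptide; a 638-peptide pool yields 6,380 windows).
A motif and its reversal are distinct keys — both orientations of a
binding epitope are biologically distinct — which means palindromic
3-mers (e.g. PFP) accrue counts from both directions and sit roughly
twice as high in the abundance ranking as their non-palindromic
companions from the same parent motif. The conservation identity
`sum of abundances == 10 x pool size` holds before and inside every
permutation replicate and is asserted in the tests.

**Null model.** The permutation null shuffles all residues of the pool
jointly and re-deals them into peptides of the original lengths. This
preserves the pool's overall amino-acid composition and the
peptide-count/length structure while destroying residue co-occurrence —
the weakest assumption that targets motif clustering rather than
composition bias. A `within-peptide` shuffle variant (preserving each
peptide's own composition) is exposed as a config option for
sensitivity analysis. The estimator is add-one
(`p = (1 + b)/(1 + n)`), so p-values are strictly positive and the test
is exact-level.

**Multiplicity of testing.** Bonferroni `m` defaults to the number of
distinct observed tripeptides (typically ≈ 3,700 for a ~640-peptide
pool) rather than all 20³ = 8,000 possible 3-mers: only observed motifs
are tested. An `all-8000` mode exists for the more conservative
reading.

**Resolution caveat.** With the add-one estimator the smallest
achievable p_raw is 1/(n_permutations + 1), so the smallest achievable
p_adj is m/(n_permutations + 1). At the default 10,000 permutations and
m ≈ 3,700 no motif can reach p_adj < 0.05; the significance channel of
the selection rule only becomes attainable at n_permutations ≳ 20·m
(e.g. ≥ 10⁵ for screen-scale pools). The default keeps routine runs
fast; users who want the significance channel to carry should raise
`n_permutations`. The abundance channel (> 20) is unaffected. This is
also why the type-I-error property test observes an empirical
family-wise rate of essentially zero: Bonferroni at permutation
resolution is conservative by construction.

**Selection.** `abundance > 20 OR p_adj < 0.05`, with the abundance
bound strict (a motif at exactly 20 is not selected). All rankings
break ties deterministically: abundance descending, adjusted p
ascending, then lexicographic.

## Motif extension

For each selected tripeptide, all pool peptides containing it forward —
or containing its reversal, in which case the peptide is flipped so the
anchor reads forward — are stacked in an ungapped alignment pinned on
the anchor's leftmost occurrence. A column is consensus when it has a
unique modal residue whose agreement fraction (among supporters
covering that column) is ≥ `column_support_min` (default 0.5); an exact
tie between residues is never consensus. The reported motif is the
longest contiguous consensus run containing the anchor, trimmed to
`max_len` (6) by dropping the columns farthest from the anchor (ties
trim the right); runs shorter than `min_len` (4) are reported
anchor-only and flagged `unextended`. Anchors with fewer than two
supporters are skipped with a logged notice. This anchor-star procedure
replaces a general multiple aligner: 7-mers sharing an exact 3-mer have
a unique gap-free anchoring, and a gapped aligner would only introduce
implementation-dependent nondeterminism. Reports from reverse-oriented
anchors are mirror images of their forward counterparts (SPFPT vs
TPFPS), reflecting the same underlying motif.

## Panning and affinity metrics

- Titer: `pfu/ml = plaques × dilution_factor / volume_plated_ml`;
  counts above 300 are outside a plate's countable range and warn.
- Recovery rate: recovered/input titer, dimensionless and
  scale-invariant.
- Enrichment is reported versus round 1 (the convention used for a
  screen's final enrichment figure); saturation is decided from the
  relative change between the last two rounds only, with
  `saturation_tol` defaulting to 0.10 (no published value exists; 10 %
  is within plaque-counting noise at typical plate counts). Fewer than
  two rounds → verdict unknown.
- ELISA positives: stretched/static OD450 ratio ≥ `fold_threshold`
  (default 3.0, boundary inclusive — "3-fold higher" is read as meeting
  the fold). Non-positive static ODs make a record unevaluable: it is
  excluded from the summary with a warning rather than crashing or
  silently counting as negative. No background-OD subtraction is
  performed; inputs are assumed blank-corrected upstream.

## Synthetic data: what it does and does not emulate

`simlib` emulates the data regimes the pipeline assumes: NNK-codon
inserts (N uniform over four bases, K uniform over G/T) between fixed
anchors, half the reads reverse-complemented, Phred qualities in the
36–40 band; spiked motifs back-translated by sampling uniformly among
NNK-compatible codons, so a spike is invisible at the DNA-composition
level and only detectable as peptide-level co-occurrence; exact-count
corruption (exactly `n_invalid` third-base flips to A/C, exactly
`n_wildtype` anchor-free reads) so fixture compositions are
deterministic; ELISA plates with an exact number of positives whose
ratio margins are wide relative to the noise SD (draws that would flip
a label are rejection-resampled, and a noise SD exceeding the minimal
label margin is rejected up front); and panning trajectories with
geometric recovery-rate growth to a plateau and Poisson plaque counts.

Real screens differ in ways the simulator deliberately ignores:
amplification bias between rounds, host-range and propagation
differences among clones, position-dependent residue preferences in the
library, sequencing error inside the anchors, and chimeric reads.
Passing tests therefore demonstrate the correctness of the
computation — extraction, validation, counting, the permutation null,
the selection and extension rules — not robustness to those real-data
artefacts.

## Numerical and design choices

- Seeds: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); the permutation test is bitwise
  reproducible given `rng_seed`, and the CLI refuses to run discovery
  without a seed.
- Permutations are evaluated in a vectorised integer encoding (residues
  0–19, window code `400·a + 20·b + c`, per-replicate `bincount` over
  the 8,000-cell motif space); 10,000 replicates on a ~700-peptide pool
  take a few seconds on one core.
- Problem sizes in the test suite mirror the screen's own scale (723
  clones, 638-peptide pools) wherever counts are asserted exactly;
  distributional properties use 20 replicate pools at 1,000–2,000
  permutations, which is ample for assertions about a family-wise
  error bound that is structurally conservative.
- Degenerate inputs: empty read files parse to empty lists; an empty
  pool yields empty statistics; a single panning round yields an
  unknown saturation verdict; extraction failures and rule violations
  are records, not exceptions — only malformed files, impossible
  configurations and domain errors (zero dilution, zero input titer)
  raise.

## Known limitations

- Sub-identity dereplication is intentionally unsupported (see above).
- The extension step reports one consensus per anchor; co-occurring
  distinct motifs sharing an anchor would be merged into whichever
  consensus the majority supports.
- The permutation test treats the non-redundant pool as exchangeable;
  if clone multiplicities carry real enrichment signal, the
  multiplicity-weighted mode changes both the statistic and the null in
  ways that have not been calibrated here.
- Recovery-rate arithmetic assumes titers measured in the same volume
  units throughout; no unit conversion is attempted.
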