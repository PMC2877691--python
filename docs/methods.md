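# Methods

## Data model and assumptions

The package analyzes subcloned bisulfite-PCR sequencing reads under the
standard mammalian CpG-centred model: bisulfite converts unmethylated
cytosine to uracil (sequenced as T) while 5-methylcytosine remains C, so
after conversion a CpG cytosine legitimately reads C (methylated) or T
(unmethylated), and every non-CpG cytosine should read T. A residual C at
a non-CpG position is treated as a conversion artifact, never as non-CpG
methylation; samples where non-CpG methylation is biologically expected
need the conversion threshold lowered manually and are outside the scope
of the statistics computed here.

The in-silico converted reference replaces every C not followed by G with
T (a terminal C has no following G and converts). CpG and non-CpG
cytosine positions are indexed once on the original sequence; the two
sets partition all cytosines.

## Alignment

Reads are globally aligned to the converted reference with an affine-gap
scheme (match +1, mismatch −1, gap open −4, gap extend −1; a gap of
length L costs 4 + L). End gaps are free on both sequences: a read
covering part of the reference is not penalised, and read bases extending
past the reference (cloning vector, adapters) hang off the ends and are
trimmed. The substitution matrix scores a read T opposite a reference C
as a match — after conversion the only reference Cs are CpG cytosines, so
this single rule makes alignment insensitive to methylation state. N
scores 0 against everything. Both the read and its reverse complement are
aligned; the higher score decides orientation (forward on ties), and a
read whose best score falls below 0.25 · min(read length, reference
length) is flagged unalignable and excluded with a logged reason. For
random unrelated sequence this overlap score hovers near zero while a
genuine read scores close to its length, so the floor separates the two
regimes by a wide margin.

Ties between co-optimal alignments are broken deterministically: fewest
gap columns first (equivalently, mismatch preferred over gap), then
leftmost gap placement, evaluated over the first 32 co-optimal candidates
the aligner enumerates. The brute-force enumeration oracle in the test
suite checks both the score and the tie rule on small inputs.

### Shared coordinate frame

Per-read pairwise alignments are merged into one gapped frame. The
*stitched* strategy opens, after each reference position, the longest
insertion any read carries there, left-aligning each read's inserted
bases within the block. The *msa* strategy is a centre-star progressive
merge with the converted reference as the hub under the same scoring.
Because the reference is the centre of every pairwise comparison, the two
strategies produce the same frame; the configured mode is recorded in the
run summary, and the distinction is kept because the automatic fallback
rule is part of the analysis contract: mode `auto` selects `msa` when a
CpG lies within 30 bp (`end_window`) of a reference end and is
immediately preceded, 5' in the converted reference, by a T-homopolymer
of ≥ 4 bases (`tstretch_min`). Both ends are checked by default
(`check_both_ends`). These two constants are package choices — "close to
the end" and "T-stretch" have no published values — sized to cover the
range over which polymerase slippage in terminal T-stretches misplaces
indels. The calling algorithm (below) is itself indel-robust, so frame
choice does not affect calls on indel-free reads; the equivalence is
asserted in the acceptance suite.

## Quality metrics and filtering

Within a read's aligned span (first to last non-gap column, skipping
columns where both the read and reference rows are gaps — padding opened
by other reads):

* **identity** = matching columns / columns where both rows are non-gap,
  counting C-or-T at a reference CpG cytosine as a match and excluding
  columns with N in either row;
* **conversion rate** = (non-CpG reference C positions read as T) /
  (those read as C or T); undefined when no position is assessable, in
  which case the conversion criterion is skipped rather than failed;
* **unconverted per 100 bp** = 100 · (non-CpG reference C positions read
  as C) / aligned reference bp — a global rate rather than fixed windows,
  since window phase would be arbitrary;
* **gap fraction** = gap columns / span columns, insertions and
  deletions counted jointly;
* **N at cytosine** = N basecalls at reference cytosine positions (CpG
  and non-CpG).

Unique-mode defaults are identity ≥ 90 %, conversion ≥ 95 %, gaps ≤ 20 %;
repeat-mode defaults are identity ≥ 70 %, gaps ≤ 20 %, and exclusion at
≥ 3 unconverted cytosines per 100 bp. Boundaries are inclusive for
passing (a read at exactly 90 % identity passes) except the repeat
unconverted rule, which by its "3 and more" formulation excludes at the
stated count; comparisons carry a 1e-9 slack so exact-boundary floating
point values behave as stated. The N-site threshold (≤ 3) has no
published default and is this package's configurable choice. Every failed
criterion is listed in the filter log; the filter is a pure function of
(metrics, config).

## CpG calling

For a read and a reference CpG at position *i*: locate the column of
reference position *i*+1 (the guanine). If the read base there is not G —
including gap, N, or any substitution — the call is *unknown*. Otherwise
the read's previous non-gap base before that column (read coordinates,
skipping alignment gaps) decides: C → methylated, T → unmethylated; A, G,
N or no preceding base → unknown. The truth table over all base pairs is
exhaustive: only C·G and T·G are informative. Taking the previous *read*
base rather than the base in the reference-C column makes the call
invariant to T-stretch insertions and deletions, which otherwise shift
the C out of its reference column.

Per-site averages are reported only where at least `min_site_n` = 5 reads
are informative (M or U; unknowns carry no information), avoiding
propagation of weak data points. Per-clone means have no minimum-site
threshold; a clone with zero informative sites reports NA. The overall
percentage is 100 · M / (M + U) over all matrix cells and the informative
percentage is 100 · (M + U) / cells; per-column informative counts are
also emitted. Optional sorting orders clones by descending per-clone
methylation, stable on ties, NA last; direction is a fixed package choice
(no published convention) and sorting can be disabled.

## Clonal duplicate filtering

Each read's cytosine pattern holds one symbol per reference cytosine:
M/U/X at CpGs, converted/artifact/other at non-CpG cytosines. Positions
where the read base is N are masked: N marks sequencing quality, not
molecular identity, so two patterns match iff they agree at every
position outside the union of their N-masks. An X arising from a mutation
(not from an N) is compared as an ordinary symbol.

N-wildcard matching is not transitive, so duplicate groups are the
connected components of the match graph (union–find); the representative
is the earliest read in input order, which keeps the kept-set size
independent of representative choice and makes runs order-stable. In
*strict* mode every non-representative is removed. In *suggested* mode a
member is removed only when it shares at least one artifact symbol with
the representative at a position unmasked in both — a shared conversion
failure is strong evidence of clonal PCR, whereas identical CpG-only
patterns are expected in highly methylated or unmethylated regions and
are kept. User include/exclude lists override either decision.

Strict removals always contain suggested removals. Strict and off modes
are idempotent on any input; suggested mode is idempotent whenever no
N-masked position links otherwise-distinct patterns (removing the linking
read can split a component, re-exposing a shared artifact within the
remainder). The property suite scopes its idempotence checks accordingly.

## Repeat-element analysis

Repeat reads align to a family consensus with the lower repeat-mode
identity threshold, always using the stitched frame (the fallback rule
addresses unique PCR products). Two outputs are produced in one run:

1. **Methylated-CpG extraction**: every read C whose next non-gap read
   base is G is a methylated CpG, flagged as consensus or novel by
   whether its column aligns to a consensus CpG cytosine — read-space
   adjacency so that CpGs inserted relative to the consensus are counted.
   Per-read counts, per-100-bp rates (normalised by aligned read length;
   consensus-length normalisation is available), the count histogram and
   a count-sorted read order summarise the set.
2. **Mutation-corrected estimation**: at each consensus CpG of each read
   the (5'-of-G base, G-column base) pair is tallied as CG, TG, CA, TA,
   or other (N, gap, or any other combination). A consensus CpG mutated
   to TG on the sequenced strand is indistinguishable from an
   unmethylated site, but the same mutation on the opposite strand shows
   up as CA; assuming symmetric strand mutation rates, the unmethylated
   count is corrected to u = max(0, n_TG − n_CA) and overall methylation
   is 100 · n_CG / (n_CG + u). Clamping at zero triggers a warning. TA
   pairs (opposite-strand mutation of an unmethylated or converted site)
   are tallied and reported but deliberately not used in the correction,
   which follows the published description exactly; a TA-aware variant
   would subtract mutation from both states and is left to the caller via
   the reported tallies.

The correction removes the first-order bias of the naive CG/(CG+TG)
ratio (which underestimates methylation by roughly the per-strand
mutation rate) at the cost of a smaller second-order residual, visible in
the simulation tests.

## Synthetic data generator

`simulate_reference` draws a CG-free random sequence, plants exactly
`n_cpg` CpG dinucleotides in jittered evenly-spaced slots (spacing ≥ 3 so
sites cannot interact) and, when T-stretch indels are enabled, one 5-T
homopolymer clear of all CpGs. `simulate_reads` then, per clone: samples
per-site methylation from `per_site_p`; applies conversion (methylated C
kept, unmethylated CpG C → T, non-CpG C → T except conversion failures at
rate `conv_failure` that leave an artifact C); optionally mutates each
consensus CpG per strand at `mutation_rate` (sequenced-strand mutation →
TG regardless of methylation; opposite-strand mutation → G reads A, so
the site reads CA if methylated, TA if not); and finally applies
sequencing-level noise per read — single-T insertions/deletions at
T-homopolymers ≥ 4 with probability `tstretch_indel`, substitutions at
`seq_error`, N basecalls at `n_rate`, random vector flanks of
`vector_flank` bp, and reverse-complementation with probability
`revcomp_fraction`. A clonal duplicate (probability `clonal_fraction`)
copies an earlier clone's *converted molecule* — methylation pattern and
conversion artifacts included — while sequencing noise stays independent,
exactly the signature the suggested filter keys on.

Defaults model a typical experiment: 400 bp amplicon, 20 CpGs, 50 clones,
30 % methylation, 2 % conversion failure, 0.1 % substitution and N rates,
5 % T-stretch indel rate, 20 bp flanks, random orientation. The
repeat-mode test bed uses 90 % methylation with 6 % per-strand CpG
mutation — a highly methylated family with moderate divergence, enough
for the naive estimator's bias to be well resolved against binomial
sampling error at 50 × 20 observations. All draws derive from one integer
seed via numpy's PCG64 and are recorded in a truth manifest.

What the generator does not emulate: basecall quality profiles and
chromatogram artifacts, position-dependent error rates, chimeric PCR
products, real repeat-family divergence outside CpG sites, and biased
subcloning. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every failure
mode of real trace data — the quality filters and the visual artifacts
log exist precisely because real data are messier.

## Numerical and design choices

* Deterministic outputs: TSVs use tab/'.'/"NA" conventions, JSON is
  written with sorted keys, floats at fixed precision; repeated runs on
  identical inputs are byte-identical.
* Problem sizes in the test and acceptance runs (50 clones × 400 bp, 20
  CpGs) match the generator's default study conditions and keep each
  scenario's binomial standard error small enough for 3-SE recovery
  checks to be meaningful.
* Undefined quantities (conversion rate with no assessable cytosine,
  overall percentage with no informative call, per-clone mean with no
  informative site) propagate as None/NA rather than 0, so empty results
  are distinguishable from unmethylated ones.
* The AB1/ABIF reader prefers the user-edited basecall record (PBAS 1)
  over the primary one (PBAS 2), honouring manual trace edits; trace
  input is an opt-in convenience and the core pipeline never requires it.
* Per-file read ids come from file stems, multi-FASTA ids from headers up
  to the first whitespace; duplicate ids are rejected rather than
  renamed, since silent renaming would corrupt the clonal report.

## Known limitations

* The centre-star MSA and the stitched merge coincide by construction;
  neither reproduces the gap placement of a full progressive aligner on
  heavily indel-laden data. The indel-robust calling rule compensates at
  CpG sites, which is where it matters for this analysis.
* The unalignable-score floor is a heuristic; reads consisting mostly of
  vector with a short genuine insert may fall below it and must be
  rescued by manual trimming.
* The mutation correction assumes strand-symmetric CG→TG mutation and
  treats CA sites as methylated-and-mutated; deviations from symmetry
  bias the estimate by the asymmetry times the site fraction.
* Non-CpG methylation is not analyzed; heavily non-CpG-methylated
  samples will fail the conversion filter unless its threshold is
  lowered.
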