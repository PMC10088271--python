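# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward axis of the
reference sequence; strand is `+`, `-` or `.`. GFF3 (1-based inclusive) is
converted only at the `read_features`/`write_features` boundary; BED passes
through unchanged. Sequences are uppercased on ingest and restricted to
`{A,C,G,T,N}`; soft-masking case is discarded — masking analyses are driven
by explicit feature files, not letter case. The GFF3 writer is exactly
inverse to the reader (coordinates, strand, score, attributes), which the
suite checks as a round-trip property.

## Quadruplex scanner

A PQS candidate is four G-runs separated by three loops. Constraints
(defaults in parentheses): each run holds `min_run` (3) to `max_run` (7)
guanines; at most `max_defective_runs` (1) of the four runs may carry
exactly one interior single-base non-G bulge while still containing
`min_run` G's; loops span `loop_min` (1) to `loop_max` (12) bases; the
whole candidate is at most `max_len` (50) bp and never spans an `N`
(assembly gaps must not masquerade as loops). With `t` the minimum over
runs of the longest contiguous G-stretch and `l_i` the loop lengths,

    score = 30·(t − 1) − 2·Σ max(0, l_i − 3) − 10·n_defects

and candidates below `min_score` (47) are dropped. The weights are chosen
so a canonical three-tetrad motif (`GGGTGGGTGGGTGGG`) scores 60 and clears
the threshold while a perfect two-tetrad motif (30) does not; the threshold
itself sits at the score below which predicted quadruplexes agree poorly
with G4-seq evidence. The scheme is deliberately simple and fully stated:
scores are reproducible within this package, and the qualitative contract
(more tetrads up, longer loops and bulges down) matches the established
scanners without claiming score-for-score compatibility with any of them.

Enumeration is exhaustive over all (run-start, run-length) placements, so
an independent brute-force enumerator can (and does, in the tests) verify
it exactly. Overlapping candidates are resolved greedily per strand — keep
the best score, discard same-strand overlaps, ties broken by leftmost
start, then shortest, then lexicographically smallest motif. Tie-breaking
operates in each strand's own 5'→3' frame (minus-strand candidates are
resolved in reverse-complement coordinates before mapping back): this is
the only convention under which scanning the reverse complement mirrors the
forward scan exactly, which the suite asserts. Hits on opposite strands may
overlap and are both kept, since sense and antisense PQS are counted
separately downstream. The scanner contains no randomness.

## Repeat intersection and densities

`intersect` follows bedtools semantics: one record per (PQS, repeat) pair
with ≥1 bp overlap, so a PQS straddling two element copies is counted for
both; hits touching no repeat are reported separately. Orientation is
`sense` when the G-rich strand equals the element's coding strand.

Two counting conventions coexist deliberately:

- **midpoint rule** for density and genome-partition fractions — a PQS
  belongs to the region containing its midpoint, so region tilings count
  each hit exactly once;
- **overlap base pairs** for `bp_proportion`, which normalises PQS *size*
  by fragment length, restricted to fragments that contain at least one
  PQS (PQS-free fragments are excluded from the denominator, and families
  with no PQS-containing fragment are omitted rather than reported as 0).

Density is `10⁴ · hits / (region length − N bases)`; a zero effective
length is an error, not a zero.

## Conservation bias

Protein alignments are consumed, never computed. `thread_codons` maps each
in-frame CDS back through its aligned protein row (one terminal stop codon
is trimmed if present; `X` matches any codon; every other residue must
translate exactly), giving DNA rows in which each protein column occupies
three DNA columns. Pairwise identity is the percent of columns identical
among columns where neither row has a gap (pairwise deletion, matching the
"average pairwise identity" convention of alignment viewers); similarity is
the percent of gap-free columns with strictly positive BLOSUM62 score.
Columns containing `X` are excluded from both statistics — stating the rule
once for identity and similarity keeps the two defined over the same column
set. BLOSUM62 and the standard genetic code come from Biopython.

`report` averages the three pairwise statistics over all unordered row
pairs; `diff_identity = DNA − AA` identity is negative when DNA is the less
conserved level (synonymous changes hit DNA only) and rises where DNA
conservation overrides the protein. Region reports slice both levels
through the 3× column mapping so DNA and AA cover identical residues.
PQS counted per CDS region use ≥1 bp overlap, and a boundary-straddling
PQS counts for every region it touches — the double counting is
intentional and reported.

## Nei–Gojobori dN/dS

Per codon, the synonymous site fraction at each position is (synonymous
single-base changes)/(changes not creating a stop); changes to stops are
excluded from numerator and denominator, so S + N = 3 exactly. Between two
codons differing at k positions, all k! mutational orderings are weighted
equally, orderings passing through a stop are dropped and the rest
re-weighted; if every ordering hits a stop, the k changes are counted as
nonsynonymous. Proportions ps = Sd/S and pn = Nd/N (site counts averaged
over the two sequences, gap/N codon pairs skipped) are corrected with
Jukes–Cantor, `d = −(3/4)·ln(1 − (4/3)p)`, which raises a saturation error
at p ≥ 3/4. The ratio dn/ds is NaN when both distances are zero and +inf
when only ds is; alignment-level means exclude such pairs and report how
many were excluded. This is plain NG86 — no Ota–Nei variants, no
maximum-likelihood codon models.

One subtlety the tests document: under a purely synonymous substitution
history, pathway averaging can still attribute a small nonsynonymous
fraction to codon pairs connected by serial synonymous steps (Leu
`TTA↔CTA`, then third-position changes), so dn is near zero rather than
identically zero.

## Codon composition

ΔGC of a codon is its GC content minus the mean GC of its full synonymous
family (so the family-wide mean ΔGC is exactly zero; the proline family
{CCT,CCC,CCA,CCG} has mean GC 10/12). `partition_by_pqs` assigns a codon to
the PQS set iff it overlaps any PQS interval by ≥1 bp — the same
boundary-inclusive rule used for regions. `codon_position_stats` reports
third-position cytosine fractions per partition, their ratio, and
amino-acid usage ratios (PQS over non-PQS frequency).

## Enrichment statistics

Quartiles use linear interpolation on order statistics (quantile q at rank
(n−1)·q — numpy's default); the upper fence is Q3 + 1.5·IQR and percentile
ranks accompany the flags so the outlier claim can be audited under other
conventions. Strand asymmetry uses the exact two-sided binomial test at
p = 0.5 (sum of outcome probabilities no larger than the observed one);
per-family counts are small enough that a normal approximation would be
inappropriate.

## Synthetic data

The generators emulate the structure of retrotransposon telomeres, not
their sequence content:

- **Background** draws i.i.d. bases with P(G)=P(C)=gc/2 (default GC 0.42,
  a typical euchromatic value for drosophilid genomes) and then locally
  resamples any window containing a PQS at the reporting threshold until
  the sequence is clean. A fully PQS-free background makes recovery tests
  exact: every hit in a simulated array is a planted hit. At extreme GC the
  rejection loop cannot converge and can be disabled.
- **Elements** are 5'UTR–gag–pol–3'UTR–poly(A) (defaults 300/1500/1500/300/
  20 bp). Motifs are planted at non-overlapping positions in the requested
  gene region; antisense motifs are inserted as reverse complements, so
  their G-runs lie on the template strand. One A/T base flanks each plant
  to stop run merging, loops never contain G, and the assembled element is
  rescanned: generation only succeeds when the scan returns exactly the
  planted set (stray candidates arising from background context are
  resampled away).
- **Arrays** concatenate n identical copies head-to-tail; the poly(A)
  tract, required to exceed the maximum loop length, insulates junctions so
  no candidate can span two copies. A minus-strand array is the reverse
  complement of the whole concatenation with all features mirrored — which
  is precisely why all antisense PQS of a one-orientation array occupy a
  single genomic strand.
- **Tandem repeats** are n copies of a monomer with i.i.d. substitutions at
  a stated per-base rate.
- **CDS families** start from a codon-wise sampled ancestor (uniform amino
  acids, uniform synonymous codons). Inside designated PQS loci the proline
  weight is multiplied (default experiments: 3×) and the probability of a
  C-ending codon within its family is the multiplier times the family's
  base C-fraction, capped at 1 (2×) — the cap formulation makes the
  *measured* C3 ratio track the planted multiplier across 2-, 3-, 4- and
  6-fold families, which a plain weight multiplication would not.
  Descendants evolve independently from the ancestor: per codon a Poisson
  number of proposed single-base changes (default expectation 0.3/codon),
  accepted with probability 1 if synonymous, ω of the codon's region if
  nonsynonymous, and rejected if creating a stop. No indels. This
  acceptance scheme is not a full codon rate matrix; it is sufficient to
  plant a recoverable dN/dS ordering and simple enough to verify directly.

What passing recovery tests show — and what they do not: the generators
produce clonal element copies, indel-free alignments, uniform amino-acid
usage and composition-clean background, so perfect sensitivity and exact
ratio recovery here demonstrate correctness of the bookkeeping and the
statistics, not performance on diverged real elements with fragmentary
annotations. Real-genome magnitudes (per-assembly PQS counts and
densities, published element accessions) depend on external databases and
third-party scanner engines and are intentionally out of scope.

## Problem sizes

The shipped analyses use 2-kb scanner-oracle sequences (100 replicates),
a 100-kb / 50-element array, dN/dS families of 20 sequences × 300 codons
(50 replicates), codon-bias families of 6 × 600 codons (20 replicates) and
conservation families of 8 × 200 codons (50 replicates) — sizes at which
every brute-force cross-check still runs exhaustively while each recovery
statistic is comfortably separated from its null.

## Known limitations

- Scores are internal to this package; no bit-for-bit compatibility with
  pqsfinder, G4Hunter or thermodynamic predictors is claimed or intended.
- One bulge of length 1 in at most one run is the only run defect modelled;
  two-defect and long-bulge quadruplexes are outside the search space.
- dN/dS means over pairs of a star-shaped family are correlated (shared
  ancestor); the recovery tests rely on ordering, not on the absolute mean.
- The Tukey-fence outlier convention and the exact binomial test are
  package choices where the field often reports bare counts; both report
  enough intermediate numbers to re-evaluate under other conventions.
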