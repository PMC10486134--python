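# Methods

## Scope and data model

The package analyzes single-segment positive-sense RNA virus genomes with
one long polyprotein ORF flanked by UTRs, the genome organization of the
flavivirus genus. All coordinates are 1-based inclusive in the data model
and TSV reports; BED exports convert to 0-based half-open and VCF exports
stay 1-based (each format keeps its native convention). Sequences are
normalized to the DNA alphabet at ingest (U→T); the frameshift module
re-displays RNA. IUPAC ambiguity codes are accepted but any alignment
column containing one is excluded from SNV calling and from identity
denominators — the alternative would fabricate variants from uncertainty.

The mature-peptide partition is carried as a `RegionTable`: contiguous,
non-overlapping regions tiling the ORF. The packaged VN180 partition
(AC+C 113..520 through NS5 7523..10189) spans 10,077 nt = 3,359 codons;
the ORF's stop codon lies after the last region, which reconciles the
3,359-residue polyprotein with a 10,080-nt coding sequence. The generator
uses the same convention (region lengths must sum to `cds_len − 3`).

## Pairwise alignment

Queries are ≥ 84% identical to the reference, so pairwise global alignment
to the reference replaces multiple alignment throughout: every downstream
statistic (SNVs, identities, region transfer, pseudo-alignments for
distances) needs only reference coordinates. The aligner is a banded Gotoh
three-state DP (match +1, mismatch −1, gap open −4, gap extend −1; the
first gap base costs the open score). The band covers diagonal offsets
around the main diagonal (default width 600 ≫ any plausible indel
imbalance at this divergence); within the band the result is exactly the
full-DP optimum, and `band_width=None` runs the full DP. Traceback ties
prefer diagonal over vertical over horizontal moves, making output
deterministic. Tests check banded == full DP == an independent aligner
(Biopython's `PairwiseAligner`) on randomized instances.

Percent identity is blastn-style: over the aligned core (terminal
overhangs excluded), matches divided by all columns whose reference
position falls in the requested interval, internal gap columns counted
against identity, ambiguity columns excluded, reported half-up to one
decimal. With this definition the whole-CDS identity of an isolate with
1,050 substitutions over a 10,080-nt ORF is 89.6%; published whole-genome
homology figures that round to 90% used an unspecified denominator, so
exact agreement there is not forced — per-region values (e.g. E 90.4%,
NS2A 95.9%, NS4A 85.9%) follow directly from counts and region lengths and
are reproduced exactly.

## SNV classification

SNVs are substitution columns only (indels are not called; the analysis
contract is substitutions). Each coding SNV is classified by substituting
the alternate base into the *reference* codon at its codon position and
translating with the standard code — per-variant annotation in the style
of ANNOVAR. Co-occurring substitutions in the same codon are deliberately
not combined; such codons are flagged `MULTIHIT` in the VCF INFO field.
The codon frame derives from the single ORF
(`codon_index = ⌈(pos − orf_start + 1)/3⌉`), so regions that split codons
(the 69-nt 2K peptide) classify correctly in the global frame. Region
summaries report per-isolate SNV and nonsynonymous counts, cross-isolate
means rounded half-up to one decimal (so (17+18+18)/3 prints as 17.7), and
a totals row summing the coding regions; UTR rows are listed but not
totalled. Classification is oracle-tested against an exhaustive
enumeration of all nine single-base substitutions per codon with an
independently transcribed codon table.

## Distances, trees, bootstrap

Distances use pairwise deletion: a column enters a pair's comparison only
when both bases are unambiguous. TN93 is the closed form over the two
transition proportions and the transversion proportion with empirical base
frequencies (averaged over both sequences); the gamma variant applies the
standard correction `a(w^(−1/a) − 1)` per term. Saturation (a log argument
≤ 0) yields an infinite distance, flagged in the matrix. The study's tree
used MEGA's maximum-composite-likelihood distance; that estimator's exact
procedure is not reproducible from its description, so TN93 — the same
substitution-model family in closed form — stands in for it, and
topology-level conclusions are checked rather than branch lengths.

Neighbor joining is the classical Saitou–Nei agglomeration: minimize
Q(i,j) = (m−2)d(i,j) − r(i) − r(j), join, update distances by the
reduction formula, finish with the closed-form three-taxon star. Ties in Q
are broken by the lexicographically smallest pair of canonical labels
(an internal node's canonical label is the smallest leaf label beneath
it), making the algorithm deterministic. Negative branch-length estimates
are clamped to zero and counted. NJ output is checked against exhaustive
least-squares topology search (≤ 6 taxa) and against dendropy's NJ.

Bootstrap resamples alignment columns with replacement (explicit seed),
re-runs distance + NJ per replicate, and reports the percentage of
replicates containing each split of the full-data tree. Replicates with a
saturated pair are skipped and removed from the denominator. For unaligned
input the CLI builds a pseudo-alignment by stacking each query's base at
every reference position (insertions relative to the reference are
dropped) — adequate at the divergences involved, and the aligned-FASTA
path accepts an externally built MSA when insertions matter.

## −1 PRF detection

The scan reports every exact occurrence (T ≡ U) of the five slippery
heptamers known from insect-specific flaviviruses, including overlaps. For
each match the 150 nt 3′ of the heptamer are folded and the structure is
searched for a hairpin: a helix of ≥ 4 pairs (single-base bulges allowed
between stacks) closing a terminal loop of 3–10 nt, with the helix 5′ end
within the first 60 nt of the window. All matches are reported;
`stem_loop_found` marks the verified ones, and matches whose window is cut
short by the genome end are flagged.

Folding is nested-structure dynamic programming with Watson–Crick + GU
pairs and hairpin loops ≥ 3 nt, with two objectives. `objective="pairs"`
maximizes pair count (the Nussinov objective; stacked pairs only break
ties) and is exhaustively oracle-tested on short windows.
`objective="stacks"` maximizes stacked pairs first and pair count second,
and is what the detector uses: on arbitrary sequence the pure-cardinality
optimum routinely dismembers even a perfect 8-bp hairpin to pair its arms
with spare partners elsewhere in the window, whereas the stacking-primary
objective prefers contiguous helices the way a thermodynamic folder does.
This choice was made after measuring planted-hairpin recovery under both
objectives (13/20 seeds versus 40/40). A thermodynamic MFE folder can be
substituted through the `fold_fn` hook of `detect_prf`.

Two properties of the stem-loop filter are worth knowing. First, on fully
random 150-nt windows the filter's criteria are met by chance most of the
time — real RNA almost always contains a small hairpin — so the filter
discriminates only among the handful of heptamer-matched sites, not as a
genome-wide structure test. Second, when a planted hairpin sits in a
random window, a competing helix occasionally absorbs one outer arm base,
reading an 8-bp stem as 7; detection of the site is unaffected, and exact
dimension recovery is asserted on isolated constructions.

## Synthetic data

The generator's defaults emulate the study system: 98-nt 5′UTR, 10,080-nt
ORF partitioned into the 11 mature-peptide regions at their published
lengths, 653-nt 3′UTR (10,831 nt total), GC 0.5, ATG start, single
in-frame stop at the end, no ATG upstream of the start in the ORF's frame
(so ORF finding is exact). SNV planting is site-wise rejection sampling:
draw a position in the region, draw an alternate base with
transition:transversion weight 2:1, verify the desired effect by codon
translation, retry up to 1,000 times; codon double-hits are avoided by
default and nonsense changes are never planted, so every nonsynonymous SNV
changes exactly one residue. Slippery-site planting writes the heptamer
plus a downstream hairpin with a GC-only stem, an unpairable A/C loop, and
unpairable A flanks, then removes any accidentally created heptamer match
from non-feature bases. Tree evolution simulates sites independently along
a Newick tree under JC or a single-kappa transition-bias model via the
matrix exponential of a normalized rate matrix.

What the generator does not emulate: indels, recombination, codon-level
selection (dN/dS), realistic RNA secondary-structure landscapes, and
real sequencing error. Passing the recovery suite therefore shows the
pipeline is exact on substitution-only divergence with known truth, not
that it is robust to assembly artifacts or alignment ambiguity in real
data.

## Numerical conventions and problem sizes

All user-facing percentages and means round half-up to one decimal
(`decimal` module; Python's built-in banker's rounding would print
(17+18+18)/3 as 17.6). Randomness always flows from explicit integer
seeds through `numpy.random.default_rng`.

The test suite runs the planted-truth recovery on 1.3-kb three-region
genomes (20 random trios) and the full 10.8-kb published-count geometry
once; oracle suites use ≤ 500-nt alignments, ≤ 18-nt folding windows and
≤ 6-taxon trees — sizes chosen so the whole suite completes in well under
a minute while still exercising every code path at full scale at least
once. `scripts/acceptance.py` runs the complete 10.8-kb trio pipeline.

## Known limitations

- Branch lengths (and hence exact published tree figures) are not
  reproduced: the distance model stands in for MEGA's MCL estimator.
- Whole-CDS identity depends on the denominator convention; this package's
  definition is stated above and applied uniformly.
- The PRF stem-loop filter is a structure plausibility check, not a
  thermodynamic or comparative-genomics test of frameshifting.
- GenBank accession handling is out of scope; all inputs are local FASTA/
  TSV/CSV, and the synthetic generator supplies test data.
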