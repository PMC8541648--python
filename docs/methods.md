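# Methods

This note records the models, procedures, numerical choices and known
limitations behind `mirtwin`, in the order a reader meets them in the
pipeline.

## Coordinates, alphabet, formats

All coordinates are 1-based inclusive (GFF3 convention); this fixes one
convention for the MS region ("nucleotides 2–13"), flank extents and
cleavage positions throughout. The internal alphabet is RNA
(`A C G U N`); DNA input is accepted and `T` is converted to `U`, since
miRBase and genome FASTA files mix conventions. Minus-strand loci keep
forward-strand coordinates; sequence retrieval returns the reverse
complement. FASTA/FASTQ are read by small line-level readers so that parse
errors can name the offending line; alignments (aligned FASTA or Clustal)
go through Bio.AlignIO and trees through Bio.Phylo.

## Family classification

**5'-motif rule.** Within the miR156/miR529 superfamily, a mature starting
`UGAC`/`CGAC` is MIR156 and anything else is MIR529. The rule is total and
never returns UNKNOWN — but it is only meaningful for sequences already
established to be in the superfamily. Membership itself is checked by
precursor similarity (below); applying the motif rule to arbitrary small
RNAs would misfire, hence the two-step contract.

**Overlap identity.** "Shared identical nucleotides" between two matures is
operationalized as the maximum count of matching positions over all
ungapped registers, with ties broken by smallest absolute offset, then
negative before positive offset. This is deterministic, symmetric in the
count, and reproduces the family-level ~13–16 nt overlap; whether gapped
registers should ever be allowed is left out (they change nothing on real
mature pairs, which differ by substitutions and end-shifts, not indels).

**Precursor-similarity assignment.** A candidate precursor is aligned
against reference pre-miR156/pre-miR529 sets with match +1, mismatch −1,
gap open −2, gap extend −1 — conventional nucleotide-BLAST-like weights —
and free end gaps, so candidates and references of unequal extent compare
on their shared core. The best-scoring reference's family wins; a best
score below 0.4 × candidate length yields UNKNOWN. miR535, a third
SPL-targeting family with a very different MS region, deliberately has no
class of its own and falls to UNKNOWN here.

**Frequency matrix.** The per-position A/C/G/U frequency table over
5'-anchored matures, with information content 2 − H bits per position
(no small-sample correction), is the tabular stand-in for a sequence logo.

## Locus discovery

**Homology scan.** Queries are mature miRNAs (19–24 nt), so instead of a
seeded heuristic the scan is exhaustive and exact: every window on both
strands with ≤ 4 mismatches (default) is reported, vectorized over the
genome as shifted byte comparisons. Duplicate loci found by several
queries collapse to the fewest-mismatch hit.

**Folding.** The default backend maximizes Watson–Crick + G:U base pairs
with a minimum hairpin loop of 3 unpaired nt — a Nussinov-style dynamic
program, chosen because it is deterministic and exactly checkable against
exhaustive enumeration. Among co-optimal structures the traceback prefers
the one maximizing stacked pair adjacencies (a lexicographic secondary
objective, implemented as combined score 1024·pairs + stacks), which
favours long helices over scattered isolated pairs and makes the recovered
structures far more hairpin-like; the pair *count* is exactly the
maximization optimum regardless. The table is computed
diagonal-by-diagonal with vectorized bifurcation so a 521-nt excerpt folds
in well under a second. A thermodynamic folder can be substituted through
the `backend` seam (`"rnafold"` shells out to ViennaRNA's RNAfold when
present; any callable works).

**Hairpin validation.** A candidate is accepted when the mature sits in
the duplex region of a single stem-loop. The check is duplex-centric:

1. the mature's pairing partners must predominantly lie on one side of it
   (the side capturing most pairs is the duplex side; a mature whose
   pairing splits substantially across both sides is branched —
   `multiloop`);
2. ≥ 60% of mature nucleotides must be paired into that duplex
   (`low_pairing`);
3. no run of > 4 consecutive unpaired nucleotides between the outermost
   duplex-paired mature positions (`big_bulge`); unpaired mature termini
   are end-fraying, not bulges;
4. a substantial helix (≥ 8 bp after smoothing away helices < 3 bp)
   interleaved between two partner runs of the mature means the stem
   passes over a branch point (`multiloop`);
5. walking inward from the innermost mature pair must reach a single
   terminal loop; ≥ 2 substantial branches on the way is a multiloop,
   smaller helices are treated as loop decoration;
6. the mature may poke into the terminal loop by at most the bulge
   allowance; more overlap — or a mature wholly inside the loop — is
   rejected (`in_loop`).

The smoothing and dominance rules exist because pair-maximization folds of
excerpts with 250-nt random flanks decorate real hairpins with stray 1–2 bp
helices and occasional distal pairs; requiring literal single-stem-loop
topology of the smallest enclosing pair rejects many true precursors. The
thresholds (60% pairing, 4-nt bulge, 3-bp smoothing, 8-bp branch cutoff)
follow common miRNA-annotation practice, are config-exposed, and were
validated against construction-known planted hairpins. On accepted loci
the star span is the duplex region paired to the mature extended by the
conventional 2-nt 3' overhang, and the arm (5p/3p) is recorded. Matures on
the 3' arm are accepted but flagged, not filtered.

**Multi-scale evaluation.** The precursor extent is unknown a priori, so
each hit is folded and validated at nested flank sizes (250, then 150, 100,
60 nt) and accepted at the first scale that validates. A short hairpin
inside a long excerpt can be folded away by global pair maximization yet
resolve cleanly in a tighter window; trying several windows is standard
practice in miRNA annotation. With these choices, planted-locus recall on
synthetic genomes is 1.0 across every generator seed tried (200/200 loci
over 20 seeds).

**Family cross-check.** Each accepted locus is classified twice: the
5'-motif rule on the hit's mature, and precursor similarity on the hairpin
region (stem ± 40 nt, which is length-comparable to reference precursors).
Disagreements are emitted with both calls and a `conflict` flag — this is
precisely the signature of database misannotations, where a "miR529" whose
precursor and 5' end both look like miR156 surfaces as a conflict.

## Conservation profiling

Alignment columns are mapped into the 40bp-5p/loop/3p-40bp frame using
per-row 5p/3p anchors: each column takes the frame label of the majority of
its non-gap residues (ties resolve by region order, then smaller position),
and columns with > 50% gaps are dropped. Conservation at a retained column
is the fraction of all rows carrying the modal non-gap nucleotide — gaps
count in the denominator — a transparent, row-order-invariant statistic.
Bands follow the four-class scheme <20% / [20,40)% / [40,70]% / >70%
(the middle boundaries are half-open so the classes partition [0,1]).
Conserved blocks are maximal runs of ≥ 5 consecutive frame positions at or
above a chosen band; runs never cross region boundaries (the flanks, arms
and loop are biologically distinct units), and a flag chooses whether
dropped gap-heavy columns break runs (`contiguity="frame"`, default) or
not (`"retained"`).

## Expression quantification

Reads are truncated at the leftmost exact occurrence of the 3' adapter
(`TGGAATTCTCGGG`; a ≥ 8-nt adapter prefix reaching the read's 3' end also
counts); reads without adapter evidence pass through flagged, and trimmed
reads < 18 nt are rejected. A read is assigned to a mature if it equals the
mature's sequence up to a 1-nt shift at each end; with precursor context
the read may also extend 1 nt into the precursor, without it only
end-trimmed variants can match. Reads compatible with several matures are
split fractionally and equally — the paper's procedure is silent on
multi-family reads, which are rare between miR156 and miR529 given their
MS-region difference but possible on shared 3' portions. RPM normalizes
each sample to 10⁶ over assigned reads (so per-sample RPM sums to 10⁶
whenever anything is assigned and is invariant under read duplication);
genome-wide mapped totals would require a mapping stage that is out of
scope. Tissue contrasts are descriptive: per-group mean RPM and
log2((a+1)/(b+1)); count-based differential testing belongs to dedicated
tools and is not re-implemented.

## Degradome analysis

Target sites are ungapped antisense windows satisfying < 3 weighted
mismatches opposite miRNA positions 1–10 and < 6 opposite positions
11–end, with G:U wobble counted as 0.5 (psRNATarget/Allen-style weighting;
the 1–10/11–end split puts the cleavage-determining pairing in the 5'
region). The cleavage position is the transcript nucleotide paired to
miRNA position 10 (slicing across the 10/11 bond); profile reads tolerate
±1 nt of PARE 5'-end jitter. Tags map by exact full-length sense match;
multi-position tags split equally across their occurrences.

Cleavage categories follow the CleaveLand-style ladder, reconstructed in
full here: with c = signal at the cleavage position (±1 nt window max),
M = transcript maximum and med = median of positive positions —
category 4 if c ≤ 1; 0 if c = M attained at exactly one position;
1 if c = M attained more than once; 2 if c > med; else 3.

Significance is a permutation p-value standing in for an E-value:
p = (1 + k)/(1 + n) over n dinucleotide-preserving shuffles of the miRNA
(random Eulerian walks on the dinucleotide multigraph), where k counts
shuffles achieving, anywhere on the transcript with PARE signal at the
implied cleavage position, a qualifying site with total weighted mismatch
≤ the observed site's. The scan over shuffled miRNAs is vectorized, so
n = 1000 on a 1-kb transcript takes ~1 s. With no signal anywhere, or
n = 0, p = 1 by convention. The default significance threshold is 0.05.

## Phylogenetics

p-distance (differing sites / comparable sites, gap-free column pairs
only) feeds Saitou–Nei neighbor joining with the standard Q-criterion.
Ties in Q resolve by the lexicographically smallest pair of subtree labels
— a deterministic convention, since agglomeration order is otherwise
arbitrary. Additive matrices are recovered exactly (path lengths within
1e-9 up to 8 taxa in the test suite); negative branch lengths are clamped
to zero and flagged on the input matrix object. Bootstrap support is the
percentage of column-resampled replicates (seeded, reproducible
bit-for-bit) whose NJ tree contains each internal bipartition of the
full-data tree. Alignment construction is out of scope; the module
consumes any MSA.

## Synthetic data

The generators produce data with exactly the structure the analyses
assume, plus recorded ground truth:

* `make_precursor` — 5' flank + mature + loop (8 nt) + star + 3' flank
  (60-nt flanks), star = reverse complement of the mature with a default
  2 substitutions (kept ≥ 3 nt apart while possible, so mismatches stay
  isolated bulges) and the 2-nt 3' overhang convention; the intended duplex
  structure is recorded so validation can be scored without re-folding.
* `make_genome` — uniform-random background (GC-skew knob available) with
  precursors inserted non-overlapping on random strands; truth GFF3-style
  coordinates recorded.
* `make_sra_reads` — multinomial sampling at a given depth from per-sample
  expression profiles; 10% of reads carry a 1-nt end trim (exercising the
  shift rule) and every read carries the adapter.
* `make_pare` — 20-nt tags with 5' ends at planted cleavage positions
  (weighted) or uniform background positions.
* `make_msa` — per-column independent draws whose expected modal fraction
  tracks a per-region (or per-column) conservation target; anchors emitted.
  The realized modal fraction tracks the target closely for targets ≥ ~0.4;
  below that the expected maximum of a multinomial inflates the realized
  value, so low-conservation regions are specified around 0.3 and asserted
  by band, not by exact fraction.

Every generator is a pure function of its arguments and seed. What the
fixtures do **not** model: sequencing errors, ligation and PCR biases,
non-uniform genomic base composition, indel evolution in alignments, and
RNA-structure-aware sequence evolution. Passing the recovery tests
therefore demonstrates that the algorithms are correct and well-calibrated
on data matching their assumptions — not that they are robust to every
artefact of real libraries.

## Problem sizes in the test and acceptance runs

The shipped checks use a 100-kb genome with 10 planted hairpins for
discovery recall, depth 10⁵ reads per duplicated-tissue comparison, 500
PARE tags on a 1-kb transcript with 1000 permutation shuffles, 50-sequence
alignments for conservation, and 10-taxon alignments with 1000 bootstrap
replicates — sizes at which every statistic of interest is stable across
seeds while the whole suite runs in a couple of minutes on one CPU.
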