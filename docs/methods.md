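# Methods

This note describes the models and numerical choices behind `satarch`: how
reads are annotated, how array periodicity and LINE insertion geometry are
estimated, what the simulator emulates, and where the design was genuinely
open.

## Read filtering and statistics

Reads pass the filter when their length is at least `min_length`
(default 30,000 bp; "shorter than" is discarded, so a read exactly at the
threshold is kept) and their arithmetic mean Phred score is at least
`min_mean_q` (default 8). The arithmetic-mean convention matches BBDuk's
`maq` filter; it is *not* the mean error probability, which would weight
low-quality bases more heavily. FASTA input has no qualities and passes the
quality criterion unconditionally — all downstream stages are
sequence-only. N50 is the largest length present in the set such that
reads at least that long contain half of all bases; when half the total
falls exactly on a cumulative boundary the larger length wins.

## Annotation

### Similarity engine

The built-in engine finds local similarities between each read and each
reference consensus on both strands:

1. **Seeding.** Read positions sharing an exact k-mer (k = 12) with the
   reference are merged into candidate regions; seed gaps over 100 bp
   split regions, so foreign insertions inside an array (SSR expansions,
   elements) separate its pieces.
2. **Tandem-tiled alignment.** Each region is aligned semi-globally
   (edlib, bit-parallel edit distance) against a head-to-tail tiling of
   the reference long enough to cover it. Tiling lets tandem arrays —
   including truncated terminal monomers — align contiguously and lets a
   region land anywhere in monomer phase.
3. **Path splitting.** The alignment path is cut at reference-copy
   boundaries and at indels ≥ 20 bp, so each emitted hit spans at most one
   reference copy; coordinates are folded back to the single consensus,
   always reported in its forward orientation. Per-hit identity and a
   bitscore-like score (2·matches − 3·mismatches − 4·gap bases) come from
   the path segment. Hits shorter than 30 bp or below 65% identity are
   dropped.
4. **Boundary extension.** Seed regions end at the last exact k-mer, so
   under sequencing error the terminal bases of an array would be lost
   (about 10–30 bp at 5% error). Terminal hits are extended past the
   region edge by anchored free-end alignment (≤ 40 bp); a minimum score
   gain of 8 keeps error-free boundaries exact, because chance matches
   into flanking sequence rarely reach it.

Scores, not engine internals, are the downstream contract: pre-computed
hits in the LASTZ general format (`name1,size1,start1,length1,strand1,
name2,size2,start2,length2,strand2,identity,score`) can be imported
bit-exactly, and `engine="external"` shells out to `lastz` with its
standard search parameters (`--ambiguous=iupac --xdrop=10
--hspthresh=1000`) when
the binary is installed, raising a configuration error otherwise.

### SSR scanner

SSRs are degenerate under alignment scoring, so they are detected by a
motif scanner: a position supports motif m when the k-mer starting there
is a cyclic rotation of m (forward) or of its reverse complement (minus
strand). Perfect runs merge across gaps ≤ 6 bp while the run's mismatch
fraction stays ≤ 0.2; runs ≥ 60 bp are reported. Scanner segments compete
in hit resolution with a perfect-match-equivalent score (2 per matching
base), commensurate with engine scores.

### Resolution

Every base takes the (family, strand) of the highest-scoring covering hit;
exact ties break toward the earlier reference in database order, then the
lower read start, making the result independent of hit input order.
Same-label segments separated by ≤ `merge_gap` (50 bp) unannotated bases
merge; segments < `min_segment_length` (100 bp) are dropped. Both defaults
are small relative to the 389 bp monomer and CLI-overridable. Base-wise
resolution (rather than whole-hit rejection) is order-independent and
lets a short SSR expansion win its own interval against a long
surrounding satellite hit — possible only because the engine splits hits
at monomer boundaries and long indels, keeping competing hits comparable
in span.

## Satellite arrays and periodicity

Arrays are maximal runs of same-family segments (either strand — inverted
blocks occur), merging across unannotated gaps ≤ `split_gap` (100 bp);
any intervening annotation of another class splits the run. Arrays
reaching within `edge_tol` (10 bp) of a read end are flagged truncated:
their lengths are lower bounds, so histograms tally them separately.
Histograms weight each array by its length in bp by default (bars then
reflect the genomic fraction per length class); `--weight count` switches
to plain counts.

### Periodicity fit

Array lengths concentrate on the lattice `n·L` (complete terminal
monomers) and `n·L + t` (arrays ending in a partial monomer of t bp).
The fit recovers (L, t) in two stages:

1. **Candidates** come from the autocorrelation of the 1 bp-resolution
   length distribution (box-smoothed ± 3 bp): shifting the distribution by
   the monomer length maps every peak family onto its n+1 counterpart, so
   the autocorrelation peaks at L and its multiples, and rational-fraction
   aliases of L never surface. The top local maxima (≤ 12) are rescored;
   a flat autocorrelation falls back to the full grid.
2. **Scoring.** For each candidate L, residues `length mod L` are reduced
   to their two dominant circular modes (windowed argmax refined by the
   circular centroid of raw counts within ± tol). The concentration — the
   fraction of residues within tol (default 20 bp) of either mode — is
   scored *in excess of the chance window coverage* `min(2(2·tol+1), L)/L`
   (two wide windows on a short period cover most of the circle), with
   three corrections: a sharpness penalty (mean capped distance to the
   nearest mode), a drift penalty (|correlation| of signed mode deviation
   with array length, weighted by the fraction of deviating residues —
   near-miss periods turn residues into a length-correlated ladder), and
   a lattice-support factor (fraction of predicted lattice cells actually
   occupied — sub-periods and offset-reparametrized half-periods predict
   peaks the data never shows). Exact ties go to the smallest L, so a
   period always beats its in-range multiples.

The offset is the circular lag from the base mode (the mode circularly
closest to residue 0, i.e. complete-monomer arrays) to the secondary mode,
in [0, L); a secondary mode covering no additional residues means a
unimodal distribution and offset 0. This recovers any t in [0, L) on
clean data, including offsets above L/2, where a minimal circular
distance would fold the answer.

The pipeline fits periodicity on complete arrays *not* directly adjacent
to a LINE segment (`periodicity_lengths`). An element insertion cuts an
array at the insertion site, so the cut pieces' lengths encode the target
position, not the termination process the lattice models; with a single
conserved target site those pieces even form a rival periodic family.
`fit_periodicity` itself accepts any length collection.

Junction truncation lengths at array/SSR junctions are measured from the
reference extent of the similarity hit spanning the junction-side array
boundary (modulo the monomer length; a full terminal monomer reports 0),
falling back to `array length mod monomer length` when hit-level detail
is unavailable.

## Flank interspersion

For each focal feature the ±`window` (10 kb) flanks are read out in
focal-forward coordinates: minus-strand features have upstream/downstream
swapped and neighbor orientations flipped (relative orientation = neighbor
strand XOR focal strand). Each offset is labeled by the annotation
covering that base; offsets beyond the read end are excluded from the
denominator rather than counted as unannotated, so read-length truncation
does not dilute the profile. Pooling is per focal feature; the plotting
threshold (0.05) only filters the exported/plotted labels. Adjacency
summaries score each array side not at a read end and tally the nearest
annotated segment within `adjacency_gap` (50 bp — necessarily far below
the monomer length for "terminated by" to be meaningful).

## LINE analysis

Lineage assignment aligns each element sequence (both orientations,
semi-global) against every full-length reference; the single
highest-scoring hit's lineage wins, exact ties resolving to database
order. Association with a satellite family is gap-wise: a segment is
associated when end-to-start distance to the nearest array on the same
read is ≤ `assoc_dist` (10 kb), 0 for overlap. Elements scored include
fragments down to `min_segment_length`.

Insertion-site mapping takes, for each full-length (5,000–7,000 bp)
element, up to 200 bp of flank per side in *element orientation*
(minus-strand elements have windows swapped and reverse-complemented);
windows shorter than 190 bp, or with fewer than 190 bp annotated as the
satellite family, are discarded. Surviving windows align to a head-to-tail
monomer dimer — so alignments spanning the monomer origin stay
contiguous — in both orientations; the better alignment (then the lower
dimer start) wins, and windows with edit distance above 35% of their
length are discarded as unalignable. The recorded site is the half-open
junction coordinate (just past the last 5′-flank base; the first 3′-flank
base), folded modulo the monomer length. With a TSD of d bp the two end
profiles are then shifted by exactly d; recording the abutting base
instead would give d − 1. The TSD estimate is the circular
cross-correlation lag of the two profiles, reported as its circular
magnitude `min(lag, L − lag)` because the shift direction depends on
element orientation relative to the monomer. Target-motif calling flags
positions with pooled frequency ≥ 5× the uniform expectation, clusters
peaks within 3 bp, and reports the monomer subsequence spanning each
cluster ± 5 bp (circularly).

## Simulator

The generator emulates the inferred locus-evolution model: satellite
array blocks of 1–10 units (uniform), each ending in a 120 bp partial
monomer with probability 0.5; SSR expansions — (TAA)n or (TGA)n,
25–100 copies — follow an array junction with probability 0.4; spacers of
2–8 kb with probability 0.3; per locus, 5 LINE elements are drawn from
three lineages (weights 0.7/0.1/0.2), full-length with probability 0.5
(fragments are 5′-truncated, as target-primed reverse transcription
produces), and placed *inside* an array at the planted target motif with
an exact TSD of 13–16 bp with lineage-specific probability (0.9 for the
dominant lineage) or else buried in 12 kb spacers guaranteeing > 10 kb
distance from satellite sequence. Array blocks invert or duplicate with
probability 0.05 each. Inserted elements keep one fixed orientation
relative to the monomer (reverse, the observed bias): motif-targeted
insertion fixes the orientation, and a random mixture would make each
end-profile bimodal.

The default monomer is generated (389 bp, four short (TAA)₂ hotspot
islands, one planted `TTCTA` target motif at 58% of the monomer), so no
figure transcription is needed; a user monomer FASTA is accepted
everywhere (the consensus' own target motif is located by search). Two
placement constraints matter: hotspot islands avoid the ~0.31 fraction
where the 120 bp truncation cuts (an island at the cut lets SSR runs
chain into the partial monomer and erode boundaries), and the target
motif avoids half-monomer positions (cut array pieces ending near L/2
would lend spurious support to half-period aliases).

Reads of 30–100 kb are sampled uniformly from both strands with i.i.d.
per-base substitution/insertion/deletion errors (defaults 3%/1%/1%); truth
coordinates are lifted through the indel map and strand flips, and
qualities are synthesized from the total error rate. The error model is
deliberately simple — no homopolymer-aware or signal-level behavior — so
passing tests demonstrate robustness to uniform noise, not to
nanopore-specific error structure. Real data also differ in having
diffuse, historically accumulated junction variation where the simulator
plants exact repeated coordinates; this makes some simulated recovery
tasks *harder* (coherent rival lattices) and some easier (no basecalling
artifacts).

All randomness derives from one integer seed through `numpy`
`SeedSequence` spawning; runs are bit-identical across repetitions, and
derived seeds stay below 2³¹.

## Problem sizes

The test suite runs the full pipeline end-to-end on the default
simulation (200 reads of 30–100 kb at 5% error, ~12.5 Mbp) and the
per-stage suites on 500+ arrays, 300+ insertions and 1,000+ classified
elements — sizes at which the binomial sampling error of every recovered
fraction is well inside the asserted tolerances. The acceptance script
uses 120 error-free 50 kb reads carrying ~900 arrays.

## Known limitations

- The engine assumes one orientation convention per reference family and
  does not model nested insertions (an element inside an element).
- Base-wise resolution can split a weak hit around a stronger overlapping
  one, leaving sub-`min_segment_length` slivers that are dropped.
- The periodicity fit assumes at most two dominant residue families; a
  satellite with three or more characteristic termination offsets would
  need a larger mode set.
- Association distance is measured within single reads; elements whose
  nearest array lies just beyond a read end are conservatively classified
  as not associated.
- The external-engine path is exercised only for its error contract in
  environments without `lastz`.
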