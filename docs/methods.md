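# Methods

This note records the models, parameter choices, and numerical conventions
behind the package, and what the synthetic fixtures do and do not establish.

## Problem setting

PhIP-Seq (phage immunoprecipitation sequencing) profiles serum antibody
reactivity against a programmable peptide library displayed on phage.
Classic libraries tile each protein with 56-aa peptides overlapping by 28 aa
(~2x proteome coverage), which is intractable for metaproteome-scale inputs
such as gut phage protein sets, and most tiles are never reactive. The
package implements a compressed alternative: predict which 15-aa windows of
each protein are likely to contain a *public* linear epitope (one recognized
by many unrelated individuals), keep only high-probability windows, and
stitch three of them into each synthesized peptide.

## Epitope classifier

A 15-mer is represented by 556 raw composition counts: 20 amino-acid counts,
400 ordered contiguous amino-acid digrams, 11 counts over the DIAMOND
reduced alphabet ({K,R,E,D,Q,N}, {S,T,A}, {I,L,V}, and the eight remaining
singletons {C},{G},{H},{M},{F},{Y},{W},{P}), 121 ordered DIAMOND digrams,
and 4 side-chain class counts (positive K/R/H, negative D/E, polar-uncharged
S/T/N/Q/Y/C, nonpolar A/V/L/I/P/F/M/W/G). Positions are deliberately
ignored: composition alone carries the signal for public epitopes. Counts
rather than frequencies are used — equivalent at fixed length and exactly
representable as integers. Digrams are ordered pairs of adjacent residues;
that is the only reading under which the block sizes sum to 556. Histidine
is assigned to the positive class and C/Y to polar-uncharged on standard
side-chain chemistry; the schema is a value object, so alternative
assignments are a one-line change and serializable to YAML.

The classifier is a scikit-learn random forest with default parameters
(100 trees, `random_state` 42 by default) and out-of-bag scoring retained
for evaluation. Training sets are built from scan reactivity tables: a
15-mer is positive when at least two serum samples show a positive log2 hit
fold change; negative candidates show no reactivity in any sample and are
ranked by descending mean mock-IP (beads-only) count — peptides abundant on
empty beads but never enriched are the safest true negatives, since
a peptide absent from the library cannot score — taking the top N to balance
the classes (ties broken lexicographically by sequence). Because scan
windows of one wildtype are near-duplicates, train/test splits operate on
whole wildtypes: shuffled wildtypes accumulate into the test side until at
least the requested fraction (default 5%) of peptides is covered, so the
realized fraction is the closest achievable under the disjointness
constraint. Peptides longer than the model window are scored by the mean
window probability over all stride-1 windows (42 windows for a 56-mer).

## Library designers

**Uniform tiling.** Tiles of `tile_len` (56) start every
`tile_len − overlap` (28) positions; when the protein length is not a
multiple of the step, a final full-length tile is placed flush with the
C-terminus (overlapping the previous tile by more than the nominal overlap),
so every residue of a ≥56-aa protein is covered. Proteins shorter than a
tile yield one short tile; bringing it to synthesis length is the encoder's
job, keeping tiling pure.

**Selection and stitching.** Every 15-mer window is scored; windows with
probability strictly above the cutoff (0.5) are accepted greedily in
descending-probability order, skipping overlaps; ties prefer the smaller
start, which makes the design deterministic. With n accepted windows,
`np = floor(n/3)` stitched peptides are built; peptide *i* holds probability
ranks *i*, *i+np*, *i+2np*, joined by GGGGS linkers (55 aa total; the stop
codon is appended at encoding). The interleaving puts the strongest
candidate first on every peptide, spreading the best epitopes across
independently testable constructs. Proteins with fewer than three accepted
windows are omitted and counted in `n_proteins_skipped` — the accepted cost
of compression. Proteins whose entire selected epitope sets are identical
(homologs, cluster members) are grouped and stitched once with merged
protein/phage provenance; this is the most conservative reading of
"shared epitopes", and partially overlapping sets stay separate (their
shared 15-mers are still deduplicated in the flat epitope list).

**Coverage bookkeeping.** Coverage = protein-derived amino acids in the
library / total proteome length. A tile credits its own length (56); a
stitched peptide credits 45 (3 x 15 — linkers are synthesis overhead, not
proteome content); a lone epitope credits 15. With the published pilot
numbers (23,745 tiles vs 5,266 stitched peptides over 750,776 aa) this
yields coverages 1.77 and 0.32 and a compression ratio of 0.22 — a 78%
library size reduction.

## Oligo encoding

Reverse translation samples codons from a bundled approximate E. coli K-12
usage table after dropping codons with usage < 0.1 and renormalizing (every
residue keeps at least one codon; the rare stop TAG drops out, leaving
TAA/TGA sampled by renormalized usage — stops are sampled like any residue).
Layouts (all pilot oligos are 200 nt = 16-nt prefix `AGGAATTCCGCTGCGT` +
168-nt insert + 16-nt suffix `ATGGTCACAGCTGTGC`):

* stitched 55-mer: 165 nt coding + 1 stop = 168-nt insert (56 codons);
* single 15-mer: 114 nt seeded random filler, then three stop codons, then
  the 45-nt coding region — 5' padding so the displayed fusion is the
  15-mer and all sub-libraries share one oligo length;
* 56-aa tile: 168 nt coding, no stop;
* variable-length dialect: coding + stop padded 3' with a fixed GS-linker
  sequence to a 120-nt insert, suffix `GTCGTGACTGGGAAAC`.

EcoRI (GAATTC) and HindIII (AAGCTT) sites are used for cloning, so they may
appear only in the designed adapter context (the prefix itself contains the
EcoRI site). Everywhere else they are removed: sites overlapping coding
sequence by synonymous codon swaps tried in descending-usage order
(translation provably unchanged), sites in random filler by local
resampling. Because a fix can create a new site, the scan iterates to a
fixed point (cap 100 passes); a site with no synonymous escape raises an
error naming the position. The filler/stop ordering and the filler generator
are versioned package conventions, not claims about any particular
historical byte stream.

## Reactivity scoring

**Hits.** A peptide x sample cell is a hit iff count > 15 AND fold change
> 5 AND p < 0.001 — all strict. Hits carry log2(fold change) ("log hit fold
change"); all other cells are exactly 0. Fold-change logs are base 2
throughout.

**PhARscore.** For each phage with ≥ 25 peptides in a sublibrary, per
sample: the observed mean log2 fold change of the phage's peptides is
compared with the mean of `n_draws` (default 10,000) random draws of equally
many peptides (without replacement within a draw) from the sublibrary pool,
excluding the phage's own peptides; the score is the observed excess over
the resampled null expectation divided by the null pool's peptide-level
standard deviation. An exchangeable phage therefore scores near 0, and
score > 1 demands a full pool-SD of aggregate enrichment (~two-fold at the
pool SD of 1 log2 unit typical of these data). Normalizing by the spread of
*draw means* instead would make the score a unit-variance z under the null,
so the fixed cutoff of 1 would flag ~16% of null phages and the iterative
removal would cascade; the pool-SD denominator keeps the cutoff meaningful
across phages of different peptide counts and calibrates cleanly (see the
acceptance suite). Scoring iterates: peptides of phages scoring > 1 leave
the null pool, then unflagged phages are rescored, until no new phage
crosses the cutoff or seven rounds have run. Flagged phages keep the score
and iteration at which they were flagged. The null pool is kept sorted by
peptide id, which makes results exactly invariant to the row order of the
input matrix under a fixed seed; per-sample generators are spawned from the
master seed. A degenerate null (pool SD 0) scores 0 with a warning.

**Protein discovery.** A protein is reactive in a sample when any of its
peptides is a hit; comparing one design's protein x sample calls against
another's as ground truth gives precision/recall/accuracy with NaN where
undefined (no predicted or no true positives).

## Scan generators and the epitope footprint

The k-mer scan tiles a 56-aa wildtype with sub-peptides of lengths 15–45
(step 5 between lengths) starting every 5 aa: 9+8+7+6+5+4+3 = 42
sub-peptides. The alanine scan substitutes AAA into successive triplets
(wildtype A → G so every scanned position always changes); the default step
is 1, with step 3 available.

The footprint analysis takes per-position reactivity-difference curves
(variant minus wildtype). A curve qualifies when a 3-point moving average
shows exactly one negative-to-positive sign-change pair (a single contiguous
dip); its dip center is the smoothed minimum, ties resolved to the middle of
the tied run so flat-bottomed dips center correctly. Qualifying curves are
aligned on their dip centers and averaged; the baseline is the median of the
outermost ten aggregated positions; `span80` is the width of the shortest
center-containing interval holding 80% of the baseline-subtracted dip mass.
The statistic is invariant to translating all curves. On a width-20
rectangular dip span80 is 16; on a unit delta it is 1; on a discrete
triangular dip of half-width 9 it is 10 (brute-force oracle in the test
suite).

## Synthetic fixtures

Generators are pure functions of a `FixtureSpec` (seed included). The
synthetic "epitope" rule is compositional, not biological: a 15-mer is
epitope-like when its K/R/H count lies in [5, 8], the band where real public
epitopes are enriched; background sequence is uniform over the 20 amino
acids, making the rule rare by chance (~6% of windows). This makes
classifier tests interpretable — the positive-side-chain count feature is
the planted ground truth, so parameter recovery (that feature ranking in
the top importances) is a meaningful check. Default sizes: proteomes of 30
proteins (90–250 aa, 3 planted epitopes each), training scans of 60
wildtypes x 9 windows with 8 serum + 2 bead samples, phage screens of 12
phages x 30 peptides plus 300 background peptides (peptides mapping to no
scored phage, as in real sublibraries where many peptides belong only to
phages below the 25-peptide scoring floor) over N(0,1) log2 fold changes,
spike-ins shifted by +2.

What passing these tests shows: the pipeline's combinatorics, contracts,
and statistical calibration are correct, and the classifier recovers a
planted compositional signal. What it does not show: real-data AUCs,
reactive fractions, or footprint widths — those depend on cohort data the
package accepts as optional input but does not ship.

## Problem sizes and tolerances

The test suite and acceptance script run on one CPU in well under a minute
apiece. Sizes chosen for that footprint: classifier calibration at 2,000
examples / 100 trees; PhARscore checks at 2,000 resampling draws (package
default stays 10,000; the Monte-Carlo error of a null mean at 2,000 draws is
already far below the assertion tolerances); bulk encoding contracts at
2,000–10,000 oligos. Null-AUC assertions use ±0.05–0.07 under fixed seeds;
PhARscore null mean uses ±0.1 over 48 phage x sample scores. Degenerate
inputs (single-class training data, single-wildtype splits, empty null
pools, proteins shorter than a window, all-flat footprint curves) raise
typed validation errors rather than propagating numerics.

## Known limitations

* The grouping rule collapses only exactly identical epitope sets; mixed
  provenance peptides across partially homologous proteins are not built.
* Epitopes of rank ≥ 3·floor(n/3) are never carried into a partially filled
  peptide; proteins contributing fewer than three accepted windows are
  invisible to the stitched library.
* The bundled codon usage table is approximate K-12 usage; substitute a
  measured table for production synthesis.
* The footprint dip detector assumes curves with a single dominant dip and
  modest noise; heavily multi-epitope curves must be excluded upstream, and
  the detector will exclude (with a warning) anything without a clean
  negative-to-positive transition.
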