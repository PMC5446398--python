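# Methods

## Problem and model

ATAC-seq measures chromatin accessibility by sequencing fragments created by
the Tn5 transposase, but in many cell types a large share of those fragments
— commonly 20–80% of sequenced reads — derives from mitochondrial DNA, which
is abundant, unprotected by nucleosomes, and analytically useless. One
post-library remedy is to digest the finished sequencing library with
SpCas9 loaded with a panel of guide RNAs tiled across the mitochondrial
chromosome. A cleaved fragment retains only one adapter-bearing end, cannot
bridge-amplify on an Illumina flow cell, and is therefore never sequenced,
freeing that sequencing capacity for nuclear reads. `mitocleave` implements
the computational side of this approach: panel design, oligo/reagent
generation, an in-silico digestion simulator, and the evaluation metrics
used to compare library-preparation treatments.

## Guide discovery and panel design

SpCas9 requires a 20-nt protospacer followed on its own strand by an NGG
PAM. The scanner enumerates every such 23-bp footprint on both strands of
the (circular) target, wrapping through the origin; on the reference the
footprint occupies `[proto_start, proto_start + 23)` for both strands, with
the PAM at the reference-left end for minus-strand guides (where it reads
CCN on the plus strand). The blunt cut is placed 3 bp 5′ of the PAM —
between protospacer positions 17 and 18 — the canonical SpCas9 geometry.

Candidate quality is enforced by explicit, deterministic, offline filters
rather than a web-service activity score:

- seed GC fraction within [0.25, 0.80] (defaults; configurable) — outside
  this range guides transcribe or anneal poorly;
- no `TTTT` run in the seed — a T7 polymerase terminator risk for
  in-vitro-transcribed guides;
- no N in the footprint;
- nuclear specificity: the exact 23-mer (seed+PAM, either orientation) must
  not occur in the background genome. The screen is an exact-match k-mer
  index at k = 23; mismatch- or bulge-tolerant off-target search is out of
  scope by design (the screen's purpose here is specificity on the supplied
  background, not genome-wide activity prediction).

Panel selection partitions the circle into `target_n` equal arcs anchored
at position 0 and picks, per arc, the unflagged candidate whose cut
position is nearest the arc midpoint (ties: smaller cut position, then plus
strand). This is deterministic — the same genome and configuration always
yield a byte-identical panel — and on a PAM-dense mitochondrial-sized
genome it achieves a maximum circular gap below twice the mean gap. Arcs
with no usable candidate are reported as gaps, not errors. Note that a
100-guide panel on 16,569 bp has a mean cut spacing of 165.69 bp; the
panel size, not a nominal per-250-bp density, is the controlling parameter,
and the spacing report makes the realized density explicit.

## Oligos and stoichiometry

Each guide's transcription template is `T7 promoter (18 nt) + seed (20 nt)
+ sgRNA scaffold (93 nt)` = 131 nt; the PAM is never included (it is a
genomic recognition requirement, not part of the RNA). The PCR primer pair
used to double-strand templates is the T7 promoter (forward) and the
reverse complement of the scaffold's 3′ terminus (reverse); this identity
is asserted at import time.

Reagent amounts follow molarity bookkeeping: a library at `c` nM of which a
fraction `m` is assumed mitochondrial contains a `c·m` nM target, so the
target amount in a reaction receiving `v` µL of library is `c·m·v·10⁻³`
pmol, and Cas9/gRNA amounts are fold excesses over that (defaults: 8 µL of
a 20 nM library assumed 50% mitochondrial in a 30 µL reaction, 100× each →
0.08 pmol target, 8 pmol Cas9 and gRNA). The 50% assumption is a
configurable default, not a constant. Incubation length and "Cas9 boost"
are recorded as metadata only; they alter no computed quantity. The cost
model amortizes a one-time panel cost over samples against the per-sample
sequencing saving implied by a higher usable-read fraction; every price is
a user input and the break-even sample count is found by direct scan.

## Library simulator

The generator is first-class, tested code and defines the study conditions:

- chromosomes: a 16,569-bp circular mitochondrial-sized chromosome
  (GC ≈ 0.44) and a 1-Mb nuclear chromosome (GC ≈ 0.41) with 200
  non-overlapping truth peaks (width ~ N(500, 100²) bp, floored at 50 bp),
  placed by distributing the free space between peaks uniformly at random;
- mitochondrial load: the fragment split per chromosome is set so the
  expected sequenced-read mitochondrial fraction equals
  `mito_read_fraction` (default 0.5, the midpoint of the 20–80% range seen
  across cell types; tests sweep 0.2–0.8);
- nuclear fragment starts: a peak/background mixture whose in-peak start
  density exceeds background by `peak_enrichment`-fold (default 20);
  enrichment 1 reduces exactly to uniform;
- fragment lengths: a three-component normal mixture (80±20 ×0.6,
  200±40 ×0.3, 400±60 ×0.1 bp, floored at 10 bp) emulating the
  sub-nucleosomal/mono-/di-nucleosomal Tn5 ladder;
- PCR duplicates: per-fragment multiplicity `1 + Geometric(dup_rate)`
  extra copies (default dup_rate 0.15); sampling reads with replacement
  proportional to multiplicity makes duplicates re-emerge as
  identical-coordinate reads, which deduplication later removes.

Digestion: a fragment is susceptible to a guide iff it fully contains the
guide's 23-bp footprint (circular containment honored); each susceptible
(fragment, guide) pair is cut independently with probability `efficiency`
(default 0.65 — a round mid-range value chosen because partial depletion is
what is observed in practice; per-site efficiencies are not identifiable
from sequencing data, so the simulator exposes both efficiency and panel
density and claims nothing about their real-world values). Cut fragments
are never deleted — they stay in the library with `amplifiable = False` —
mirroring bridge-amplification dropout, which the model treats as absolute.
Sequencing is sampling `depth` reads with replacement from amplifiable
fragments. Under this model the expected post-digestion mitochondrial read
fraction follows f′ = f·s / (f·s + (1 − f)), where f is the pre-digestion
fraction and s the multiplicity-weighted survival of mitochondrial
fragments; the test suite verifies this identity within 3 Monte-Carlo SDs
at f ∈ {0.2, 0.5, 0.8}.

What the simulator does **not** model: sequence errors and base qualities,
Tn5 insertion bias, mate-level coordinates (reads are fragment-spanning
intervals), residual sequencing of cleaved fragments, or off-target
cleavage of nuclear fragments. Passing tests therefore demonstrate the
internal consistency of design, digestion and metrics under these idealized
conditions — not the depletion fold a wet-lab treatment will achieve on a
real library.

The naive Poisson-window peak caller (fixed windows by read midpoint,
Benjamini–Hochberg-adjusted upper-tail flags at FDR 0.05, adjacent flagged
windows merged, score = −log10 best adjusted p) exists solely so the
end-to-end loop runs without an external caller; MACS2/HOMER BED or
narrowPeak files are first-class inputs and take precedence in real
analyses.

## Evaluation metrics

- Samples are compared at a fixed sequenced depth (uniform downsampling
  without replacement).
- Read accounting: mitochondrial reads are removed first as one bucket;
  among the remainder, every occurrence beyond the first at an identical
  (chrom, start, end, strand) key is a duplicate; the rest are usable. The
  partition is exact by construction. Strand participation in the
  duplicate key is configurable (default on, matching common practice).
- Signal/noise: usable reads inside the merged union of all samples' peaks
  vs outside; zero background yields an infinity marker.
- Peak concordance uses the top-N peaks per sample (default 20,000) ranked
  by score with (chrom, start) tie-breaks. The common-peak fraction
  (≥ 1 bp overlap) is asymmetric; both directions are available and group
  matrices average over ordered pairs excluding self-pairs.
- Read-count reproducibility: all peaks are merged, usable reads counted
  per merged peak per sample (a read spanning two merged peaks counts in
  each), and squared Pearson correlations reported per pair or as group
  means.
- Feature overlap: point features (TSSs) are expanded to ±flank windows
  (default 1 kb); interval features (enhancers) are used as-is; the
  fraction counts each feature at most once, the `bedtools intersect -u`
  contract.
- Fold-differences: matched treated/untreated halves use the median of
  per-pair ratios ("pairwise-median"); unmatched groups use the ratio of
  group medians ("ratio-of-medians"). Values are reported at 2 significant
  figures (3 on request) with full precision stored alongside, and the
  convention is always recorded.
- Hypothesis tests: one-sided Wilcoxon signed-rank (paired) or rank-sum
  (unpaired), exact small-sample null when sizes permit (and, for the
  rank-sum, the data are tie-free), otherwise normal approximation with
  continuity correction; the test identity and method are recorded, and
  P-values are explicitly unadjusted.

## Reproducibility and numerical choices

All coordinates are 0-based half-open; overlap is computed on half-open
intervals, so book-ended intervals do not overlap. Circularity is assigned
by chromosome name (FASTA carries no flag). The end-to-end workflow derives
every stage's generator from one top-level seed via spawned seed sequences,
so a fixed seed fixes every output byte; tests assert byte-identical
reports across runs. Degenerate inputs produce markers, not exceptions:
empty peak sets give NaN fractions, zero background gives an infinite
signal/noise, a panel shortfall is a report field.

Default problem sizes in the test and acceptance suites — 16,569 bp + 1 Mb
genomes, 12,000–50,000-fragment libraries, 8,000–40,000-read depths, three
replicates per arm — are desk-scale choices that keep every stochastic
check inside 3-SD Monte-Carlo bands while the whole suite runs in well
under a minute; all sizes are configurable upward.

## Known limitations

The off-target screen is exact-match only; the digestion model ignores
partial-footprint nicking and chromatinized-substrate effects; the
simulator's uniform-background nuclear model understates the structured
background of real libraries, so absolute signal/noise values are not
comparable to real data; and the cost model is a linear amortization with
user-supplied placeholder prices.
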