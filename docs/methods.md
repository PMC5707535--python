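# Methods

This note documents the models, parameter choices and numerical decisions
behind `cocktailscope`, and what the synthetic validation does and does not
demonstrate about real data.

## Synthetic cocktails (`seq_synth`)

Phage genomes are emitted from independent order-3 Markov chains whose 64
transition rows are drawn from a uniform Dirichlet. This gives every genome
its own low-order compositional signature — between-genome tetranucleotide
vectors sit several-fold farther apart than 5-kb windows of one genome —
which is precisely the signal composition-based binning exploits. Default
genome lengths are 20–60 kb (typical tailed-phage range); hosts are assigned
round-robin over a configurable number of synthetic species.

Relatives are derived by i.i.d. per-site substitution at a chosen rate
(optionally single-base indels); the realized substitution fraction is
binomial around the nominal rate. Cocktail abundance weights are log-uniform
over a configurable span (default cap 1000-fold, the scale of the spread
between most- and least-abundant members seen in real therapeutic
cocktails).

Reads are 250-bp paired-end with uniform substitution errors (default 1%)
and no indels: the alignment engine, not the simulator, is the object under
test, and substitution-only reads keep every downstream expectation
computable in closed form. Base qualities are deterministic per position — a
Q37 core with a linear 25-base 3' decay to Q5 — so quality trimming removes
a predictable suffix. Contigs are produced by walking each genome and
alternating emitted fragments (uniform length in a configured range) with
exponential gaps whose mean is set so the expected uncovered fraction equals
the dropout parameter.

What the generator does **not** emulate: assembly artifacts (chimeras,
repeat collapse), indel sequencing errors, GC-coverage bias, strand bias,
and RNA/ssDNA genomes. Passing recovery tests therefore demonstrates
correctness of the algorithms under clean composition/coverage signal, not
robustness to assembler pathology.

## Preprocessing (`preprocess`)

Order of operations per read: fixed 5' trim (20 bp) → fixed 3' trim (10 bp)
→ per-base 3' trimming while quality < Q20 (window size 1) → discard if mean
quality < Q20 or length < 35 → dereplication (exact duplicates and exact
reverse-complement duplicates, per mate file, first occurrence kept) → mate
re-synchronization with orphan routing. Spike-in control matching uses
21-mer seeds every 7 bp (an error-free word survives up to three errors per
42 bp) and calls a read control-derived when any diagonal shows ≥ 50 bp at
≥ 90% identity on either strand; at 1% error this removes ≥ 99% of genuine
control pairs with no false positives observed on unrelated reads.

## Binning (`binning`)

Features are canonical tetranucleotide frequencies: 256 tetramers pooled to
136 reverse-complement classes (16 palindromes + 120 pairs), counted over
all sliding windows on one strand and normalized; windows containing non-
ACGT bases are skipped. Clustering is single linkage with a Euclidean
distance cut (`link_threshold`). The default 0.045 was calibrated once on
the synthetic suite: across seeds, the largest within-genome nearest-
neighbour distance among 2–10-kb fragments was ≤ 0.027 and the smallest
between-genome fragment distance ≥ 0.066, so 0.045 sits mid-gap. Contigs
< 2000 bp are excluded before clustering and clusters < 10,000 bp are
reported unbinned — the conventional thresholds for phage-scale draft
genomes. Coverage is deliberately not a binning feature: with only two
samples co-abundance is uninformative, and depth is instead used downstream
for curation. Ties and ordering are fixed (contigs processed sorted by id;
bins numbered by descending size) so binning is invariant to input order.

## Alignment and ANI (`ani`, `_align`)

Scoring: match +2, mismatch −3, gap open 5, gap extend 2 (a gap of length L
costs 5 + 2L), word size 11 — ordinary nucleotide-BLAST-style parameters.
Two routes share this scheme:

* **Exact route** (product of sequence lengths ≤ 4·10⁵): affine-gap
  Smith–Waterman with traceback. Its scores equal Biopython's optimal
  local-alignment scores, which the validation uses as an independent
  oracle.
* **Seeded route** (longer sequences): shared 11-mer words nominate
  (subject, diagonal) candidates; on each diagonal the optimal *ungapped*
  local segment is found exactly as a maximum-sum subarray over the +2/−3
  profile. Words whose overlapping 3-mers take ≤ 3 distinct values
  (homopolymers, period ≤ 3 repeats) are masked at indexing time — the role
  DUST masking plays in nucleotide BLAST; without it, poly-A runs in
  Markov-emitted genomes seed spurious micro-hits that depress self-ANI by
  ~1.5 points. The route is gap-free, which is exact for the substitution-
  only simulator and an approximation for indel-bearing real data (a
  12-column tabular ingestion path accepts externally computed hits when
  tool-identical alignments are wanted).

Significance uses a Karlin–Altschul e-value with the ungapped λ for this
scoring scheme (λ ≈ 0.634 at uniform composition, solved numerically) and
K = 0.41, applied to both routes; the default cutoff is e ≤ 0.05. On random
5-kb sequence pairs this admits a spurious hit in roughly 5% of pairs — the
expected behaviour of the threshold, not a defect.

Integrated ANI follows the hit-integration formula in the README; `mcov` is
computed from the **union** of query hit intervals so overlapping hits are
not double-counted. Multi-contig bins combine per-contig ANIs length-
weighted. Conventions: the best-reference search runs with each reference as
the query against the bin's contigs as database (the tables report "ANI of
the reference toward the bin"); the phage/non-phage call runs the other
direction (bin contigs as queries against the full reference set), with the
10% threshold inclusive. Reciprocal ANI cuts both sequence sets into
1020-bp fragments, identifies reciprocal best-hit fragment pairs, and
averages the two directions' identities per pair — symmetric by
construction (fragment sets are compared in a fixed orientation).

Host prediction ranks database phages by the fraction of the bin's distinct
canonical 16-mers they share; the host most represented among the top 10
qualifying hits wins, with score = mean shared fraction of the winning
host's phages among those hits (clipped to [0,1]) and reliability requiring
score > 0.1. Chance matching is excluded by a shared-fraction floor of
10⁻³: unrelated tens-of-kb genomes collide on ~10⁻⁴ of their 16-mers,
whereas genuine homology retains (1−d)¹⁶ ≈ 0.03 even at 20% divergence.

## Curation and classification (`curation`)

Depth comes from an internal mapper (31-mer seeds at half-word stride, both
strands, best placement by identity ≥ 0.9, ties broken by a seeded RNG) or
from SAM/BAM via pysam. Bin splitting triggers when the coefficient of
variation of member-contig depths exceeds `cv_threshold` (default **0.10**)
and cuts at the largest gap in sorted depth, recursively; sub-bins below
10 kb re-attach to the nearest-depth sibling. The 0.10 default follows from
the design requirement that a balanced mix of two genomes at depth ratio
1.3 (CV ≈ 0.13) must split while within-genome contig-depth scatter (a few
percent) must not. Merging requires a shared best reference, mean depths
within 25% (relative), and no contig-contig alignment ≥ 500 bp at ≥ 95%
identity between the bins; it is a transitive closure over qualifying
pairs. "Overlapping contigs" is operationalized by that same alignment
rule.

Cross-sample pairing computes the length-weighted ANI of each bin's contigs
against each counterpart bin as database, in both directions; for each
database bin the best query is a candidate, candidates above 70% in at
least one direction survive, and a one-to-one matching is enforced greedily
by descending ANI. Classification precedence: special case (ANI < 10% or
> 20 contigs all < 7000 bp) → collapsed (> 10% longer than the best
reference with internal overlap) → the near-complete/partial ×
counterpart/no-counterpart grid. Near-complete means bin length ≥ 0.9 ×
reference length; the 0.9 respects the precedent that a bin at 80% of its
reference remains partial despite high ANI. Abundance is mean depth divided
by the sample's total read count; zero depth is missing on the log scale.

## Sketch distances (`sketch`)

Sketches are the 400 smallest seeded-splitmix64 hashes of canonical 16-mers
seen ≥ 2 times (the multiplicity floor suppresses error k-mers, which at
≥ 5× coverage are almost all singletons). Jaccard uses the merged bottom-s
estimator; distance is D = −ln(2j/(1+j))/k with D(0) capped at 1. Hash
values are implementation-defined, so cross-tool comparisons should use the
recovery and ordering properties, not raw sketch contents.

The bootstrap resamples read pairs with replacement per sample and rebuilds
all sketches per replicate. Two uncertainty figures are reported:
`bootstrap_sd` (replicate standard deviation — the bootstrap estimate of
the point estimator's sampling error) and `bootstrap_se` (sd/√reps, the
small ± conventionally printed beside the bootstrap mean). Two design
choices deserve note. First, with a fixed hash function the replicate
spread at high coverage reflects only read-sampling noise and understates
bottom-s sketch sampling error (~√(j(1−j)/s) on j); `vary_hash=True`
re-draws the hash seed per replicate (shared across samples) and makes the
spread variance-complete — validation against a known mutation rate uses
this mode, while the classic fixed-hash mode remains the default for
between-sample tables. Second, each sample's resampling stream is seeded
from (global seed, content digest), so byte-identical samples resample
identically and D(x,x) = 0 holds in every replicate, not just on average.
The bootstrap mean sits slightly above the point estimate at moderate
coverage (resampling pushes k-mers below the multiplicity floor); the point
estimate is the headline value.

## Validation experiments (`validation`, `scripts/acceptance.py`)

All experiments regenerate their inputs from the seed at run time. Problem
sizes: 50 random pairs ≤ 200 bp for aligner-oracle agreement; six 20–60-kb
genomes, 2–10-kb fragments, 10% dropout for binning recovery; 20 engineered
three-genome scenarios (depth ratio 1.35 mixed bin, three same-depth
fragment bins) for split/merge recovery scored by adjusted Rand index;
seven classification fixtures; two 8-member cocktails sharing 5 members (2%
between-batch divergence on the shared members) for pairing; 100k read
pairs over a 1000-fold abundance span for abundance recovery; 800-pair
(~10×) read sets for mutation-distance recovery at d ∈ {0.01, 0.05, 0.1};
and three 50k-pair cocktails for the full bootstrap and distance-ordering
check. The ordering experiment uses a 20-fold abundance span: at a 50k-pair
budget a 1000-fold span drops rare members below the sketch multiplicity
floor, a regime the full-size data (two orders of magnitude more reads)
does not enter, and the distance would then rank abundance dropout rather
than membership. The abundance experiment, whose subject *is* coverage
linearity, keeps the full 1000-fold span.

## Known limitations

* The seeded alignment route reports ungapped hits; indel-rich real
  divergence will fragment hits and lower mcov slightly relative to a
  gapped aligner. The tabular ingestion path is the escape hatch.
* The binner is intentionally simple; it requires the compositional
  separation that distinct Markov sources provide and will under-perform on
  closely related genomes co-occurring in one sample.
* E-values are calibrated analytically, not against any external tool
  version; only the ≤ 0.05 significance regime is exercised.
* Host prediction transfers the host of compositionally similar phages; it
  cannot discover hosts absent from the annotated database.
* RNA and ssDNA phages are out of scope end to end.
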