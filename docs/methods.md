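# Methods

## Coordinates and site identity

Internally everything is 0-based, half-open; VCF and the tabular dialects
convert at the I/O boundary (their positions are 1-based). Two platforms
"agree" at a location when they call a variant at the same (chromosome,
position), regardless of the alternate allele: concordance is about variant
*locations*. An allele mismatch at a shared location is rare and visible in
the per-site output, but it does not move the site between Venn cells.
Chromosome classes (autosome / sex / mitochondrion) come from configuration
rather than name heuristics, so nothing assumes a human karyotype.

## Retention filters

A call is retained iff its post-deduplication depth d satisfies
d_min ≤ d ≤ d_max(class), its call quality meets the platform minimum (when
the platform defines one — the pyrosequencing-like profile does not), and on
sex chromosomes and the mitochondrion it is homozygous. Both depth bounds
are read inclusively ("between 2 and 30" keeps 2 and 30; "minimum coverage
of 4" keeps 4); boundary tests lock this down. Zygosity is homozygous iff
*strictly more* than 80 % of covering reads support the alternate allele.
Rules are evaluated in the fixed order depth-low, depth-high, quality,
zygosity-class, and the rejection log cites the first failure only, which
makes the log deterministic and the filter idempotent.

Default profiles: pyrosequencing-like d ∈ [2, 30] (all classes), no quality
rule, no mapping quality; Illumina-like d ∈ [4, 60] (45 on sex chromosomes,
10 000 on the mitochondrion), quality ≥ 20; SOLiD-like the same with
autosomal ceiling 100 and 60 on sex chromosomes. As an alternative to fixed
bounds, limits can be derived from the Poisson model: autosomes from a
two-tailed Poisson(λ) interval at tail mass α, sex chromosomes from
Poisson(λ/2) (haploid coverage), mitochondrion capped at 10 000.

## Poisson depth machinery

`poisson_expected` evaluates the pmf through the scipy log-space
implementation, stable to λ ≈ 10⁴. `poisson_depth_bounds(λ, α)` returns
(d_min, d_max) with d_max the smallest d whose CDF reaches 1−α and d_min the
largest d with CDF(d−1) ≤ α (0 when no positive depth qualifies); bounds are
monotone in α and always bracket ⌊λ⌋. Depth-0 bases are part of the
histogram denominator — the histogram is over fractions of the reference,
not of covered bases.

## GC windows

Non-overlapping windows (default 50 000 bp; desk-scale analyses here use
1 000 bp) tile each chromosome left to right; the trailing short window is
kept but flagged partial. GC is computed over non-N bases only and all-N
windows are dropped; mean depth is over the full window length so
Σ length·mean over windows recovers the chromosome's aligned base count.
The bias fit regresses log(window mean depth) on (GC − 0.5) by ordinary
least squares, excluding zero-depth windows.

## Duplicate marking

Putative PCR duplicates are records sharing identical alignment coordinates:
(chromosome, start, strand), plus mate chromosome and mate start when
present. Within each identical group of size g the first-seen record is
retained and g−1 are flagged. On the small simulated genomes used in tests,
random coordinate collisions also count as duplicates — coordinate identity
is the criterion, and collisions are negligible only at real-genome scale.

## Uniqueome

Fragments of the read length L start at 0, L/2, L, …; if the last regular
start leaves a tail, one extra fragment is anchored at (length − L).
Matching is gapless and mismatch-only with budget k = ⌊divergence·L⌋
(default divergence 5 %): a full alignment scoring scheme would add
parameters that cannot be checked against an exact oracle, while the
mismatch contract admits a brute-force all-placement reference
implementation that the tests and the acceptance script both use. Both
strands are searched — reads align to either strand. A base is uniquely
mappable iff its placement counter is at most its tile multiplicity (2 in
the interior, 1 where only one tile covers it near chromosome ends), i.e.
only the home placements hit it.

The production search uses a pigeonhole seed filter: any placement with ≤ k
mismatches must contain one of k+1 disjoint exact ⌊L/(k+1)⌋-grams, so exact
seed lookup plus Hamming verification enumerates every qualifying placement
— it is exhaustive, not heuristic. Dynamic soft-masking of over-counted
bases (a performance shortcut for genome-scale runs) is deliberately not
implemented; plain counting is the contract.

## Miss classification

Categories and precedence: (1) no coverage, (2) low coverage, (3) excess
coverage, (4) alternate allele not seen, (5) seen once, (6) SNP cluster,
(7) near a high-quality indel, (8) low RMS mapping quality, (9) low call
quality, else UNEXPLAINED. Precedence follows the three-group structure
(coverage → allele → calling filters) with the listed order inside the
third group; a deterministic single label per (site, platform) requires
*some* fixed order, and this is the documented choice. For platforms whose
aligner has no mapping quality, rule 8 instead asks whether the site lies in
the uniquely-mappable region (category NON_UNIQUE, reported in slot 8):
such aligners discard multiply-placed reads outright, which is the
analogous failure mode. Classifier defaults, all configurable per platform:
cluster = more than 2 other candidate SNPs within a 10-bp window;
near-indel = within 3 bp of an indel of quality ≥ 50; RMS mapping-quality
threshold 25. These are conventional short-read-caller filter settings.

The false-positive rule treats the coverage clause and the allele clause as
alternatives evaluated per other-platform: a singleton is plausibly true
iff each other platform is coverage-compromised *or* saw the alternate
allele ≥ 1 time. The underlying prose criterion is ambiguous between this
and requiring both; the per-platform OR reading is implemented and tested,
not asserted as the only possible one.

## Indel matching

Indel calls are compared as reference-footprint intervals. Each interval in
A is matched to its nearest interval in B by gap (bases strictly between
the two half-open intervals; 0 when they overlap), leftmost on ties: an
exact match at gap 0, a slop-only match at 0 < gap ≤ slop (default 10 bp,
i.e. they would intersect after ± slop expansion), unmatched beyond. The
three categories are disjoint and cover A.

## Synthetic data

The generator emulates what the analysis assumes about real multi-platform
data, not reads: there is no FASTQ, no quality-score model, no mate-pair
geometry.

* **Reference.** Bases are drawn with a GC probability that oscillates
  sinusoidally around the target (period 3 kb, amplitude 0.08), so that
  1-kb analysis windows span a usable range of GC fractions while the
  overall GC stays within ±2 points of the target from 10 kb up. Planted
  repeats are exact copies of one random segment at recorded,
  non-overlapping coordinates.
* **Truth.** Substitutions at 10⁻³ per bp and short indels (1–5 bp) at
  2×10⁻⁴ per bp in the bundled 200-kb demo — human-scale heterozygosity —
  with a 2:1 het:hom ratio and at least 1 bp between variants.
* **Depth.** Per-base Poisson with window rate λ(w) = mean_depth ·
  exp(gc_beta·(gc(w) − 0.5)). The log-linear form keeps rates positive with
  one interpretable coefficient. No quantitative bias magnitude is
  established for these platforms, so the defaults (−0.2 for the
  pyrosequencing-like archetype, −2.0 for the short-read archetypes) are
  illustrative: they reproduce the qualitative picture of GC-rich coverage
  loss on short-read platforms.
* **Archetypes.** Mean depths 10 / 59 / 79; duplicate fractions 0.027 /
  0.066 / 0.27 (duplicates re-emit alignment coordinates and never inflate
  the evidence depth, which is post-deduplication); the pyrosequencing-like
  archetype has no mapping quality and injects false substitution calls
  adjacent to homopolymer runs ≥ 4 bp (threshold configurable) at 0.02 per
  run; the short-read archetypes inject genome-wide false substitutions at
  4×10⁻⁵ and 1.5×10⁻⁵ per bp. Per-platform miss rates (0.18 / 0.11 / 0.21)
  and miss-category weights echo the relative prevalence each platform
  class shows for coverage, allele and filter causes.
* **Planted miss causes.** Truth sites inside planted repeats are always
  missed with the mapping-ambiguity cause; other misses draw a category and
  get evidence engineered to satisfy exactly that rule, keeping ≥ 2 units
  of margin from integer thresholds and 5 from quality thresholds so the
  classifier recovers every planted label. One unavoidable exception: with
  a minimum depth of 2, LOW_COVERAGE can only be planted at depth 1
  (margin 1); the comparison is exact integer arithmetic, so recovery is
  still deterministic. Evidence at called sites has depth clamped into the
  retention band so the simulated callsets survive their own filters.

What passing tests therefore show: the pipeline's bookkeeping, rules and
estimators are correct against engineered evidence and exact oracles. What
they do not show: performance on real pileups, where evidence fields are
noisy and correlated, miss causes overlap, and alignment artifacts are not
limited to planted repeats and homopolymer-adjacent errors.

## Problem sizes and numerics

The demo and recovery analyses use a 200-kb single-chromosome genome with
1-kb GC windows (200 windows), chosen so every stage — including the
brute-force mappability oracle on ≤ 20-kb fixtures and a 10⁶-base depth
marginal — runs in seconds while leaving the statistical checks
well-powered (GC-slope standard error ≈ 0.01; total-variation distance to
the Poisson pmf ≈ 0.002 at 10⁶ bases). Histogram fractions must sum to 1
within 10⁻⁹; the Poisson pmf table is tested to sum to 1 within 10⁻⁶ at
support λ + 10√λ. Ties in indel matching go to the leftmost candidate;
degenerate inputs (empty callsets, empty interval lists, all-N windows,
zero-depth histograms) are either well-defined or rejected with a specific
error, as exercised in the tests.

## Known limitations

* Gapless mismatch-only mappability: no indel-tolerant placement, and each
  read length requires its own run.
* The Poisson coverage model understates the heavy tails real short-read
  data show; a gamma model would fit better but is not implemented.
* Miss-cause classification assigns exactly one label; real misses can have
  several contributing causes, and the precedence order decides which one
  is reported.
* The false-positive estimate is a plausibility argument, not a calibrated
  probability; its OR-reading of the excusing conditions is a documented
  interpretation choice.
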