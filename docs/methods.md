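# Methods

## The transform

`panelmix` resamples a phased reference panel of N haplotypes × L sites
into the haplotypes of hypothetical descendants after K generations of
meiosis. Crossovers over the whole panel are modelled as one homogeneous
Poisson process on the genetic (centimorgan) scale with intensity
(N/2)·K per Morgan: each of the N/2 diploid individuals undergoes one
meiosis per generation, and one Morgan is one expected crossover per
meiosis. With ℓ the chromosome's genetic length in Morgans, the event
count is M ~ Poisson(λ), λ = ℓ·(N/2)·K.

The realisation draws M first and then places M i.i.d. Uniform(0, ℓ)
genetic positions, sorting afterwards. This is law-identical to drawing
exponential inter-arrival distances sequentially, but it fixes the number
and order of RNG draws, which the reverse transform depends on. Genetic
positions are converted to base pairs by inverting the genetic map's
piecewise-linear cM(bp) function, so breakpoints concentrate where the
map says recombination happens (hotspots) and never fall strictly inside
zero-rate segments.

Haplotype slots get one uniform random relabelling (a Fisher–Yates
permutation, performed for every K including K = 0), then the chromosome
is streamed site by site: at each breakpoint two slots drawn uniformly
**with replacement** are swapped, and every emitted row is the input row
re-indexed by the current slot order. Consequences:

* per-site allele counts — hence frequencies, the number of segregating
  sites and the full site-frequency spectrum — are exactly invariant;
* a given haplotype is involved in a given event with probability
  1 − ((N−1)/N)² = (2N−1)/N², so by Poisson thinning its hit count is
  Poisson with rate ℓK(2N−1)/(2N) and it recombines at least once with
  probability 1 − exp(−ℓK(2N−1)/(2N)); the with-replacement self-swap
  (a no-op) is what makes this correction exact;
* memory is O(N) per emitted site and total work O(NL): the row pipeline
  is a generator and never holds more than one site.

Crossover interference is deliberately not modelled, and a single
(sex-averaged) map is used.

## Reversibility and the RNG contract

The entire event sequence is a pure function of (seed, K, N, genetic map).
Per chromosome, a fresh numpy PCG64 generator is seeded from
SeedSequence([seed, crc32(chromosome)]) and consumed in a fixed order:
(1) the Poisson count M, (2) M uniform positions, (3) the slot
permutation, (4) an (M, 2) block of uniform slot indices, row m being the
swap at the m-th breakpoint in ascending position order. The reverse
transform replays this sequence and applies the inverse permutation per
segment, restoring the genotype matrix exactly (integer arithmetic only —
byte-identical, verified across K ∈ {0, 1, 8, 128}).

Outputs are self-describing: seed, K, N, RNG identifier, tool version and
a per-chromosome SHA-256 of the map table travel as `##panelmix_*` VCF
header lines and optionally as sidecar JSON. Reversal verifies the map
fingerprint first and refuses on mismatch, since a different map would
silently replay a different event sequence.

## Tie-breaks and edge rules

* **Breakpoint/variant boundary.** An event at real-valued position r is
  applied before the first variant with position > r; an event exactly at
  a variant's position takes effect after that variant. Half-open,
  deterministic, and immaterial in practice (breakpoints are continuous).
* **Events between the same pair of variants, or past the last variant,**
  are all applied in order even when unobservable, keeping replay exact.
* **Map extrapolation.** Positions outside the mapped interval get the
  boundary cM value (zero recombination rate off the map) — conservative,
  since the map asserts nothing there.
* **Flat map segments.** Inverting cM→bp on a zero-rate segment returns
  the leftmost bp; such points carry zero probability mass anyway.
* **K = 0.** The initial shuffle still runs, so a K = 0 output is the
  original panel under one global column relabelling — nothing measurable
  changes (LD scores are invariant in exact arithmetic; in floats the dot
  products merely reorder terms, so tests compare at machine precision).
* **Sample identity.** Output haplotypes are re-paired consecutively into
  samples named SYN0001…; original IDs are never emitted, since breaking
  the genome–individual link is the point.

## LD metrics

The LD score of a variant is Σ r² against every other variant within
±100 kb (inclusive bound, 1-based positions) on the same chromosome; r²
is the squared Pearson correlation of phased 0/1 haplotype columns, not
genotypes. Monomorphic columns have undefined correlation: they score
over polymorphic neighbours only (hence 0 with none) and are excluded
from cross-panel comparisons.

Two panels over the same variants are compared by Pearson ρ between their
LD-score vectors and by the OLS slope β (with intercept) of synthetic
scores regressed on original scores. The orientation is chosen so that a
uniform loss of LD in the synthetic panel gives β < 1; the intercept
absorbs additive offsets so β isolates the proportional change. The
windowed engine is tested for exact agreement against a brute-force
all-pairs oracle on small panels.

## Synthetic fixtures

The fixture generator is a founder mosaic, not a coalescent: n_founders
haplotypes are drawn i.i.d. per site (alt probability 0.3), and each
panel haplotype copies a founder, switching to a uniform founder between
consecutive sites with probability 1 − exp(−switch_rate·Δbp). Defaults —
100 haplotypes, 500 sites over 1 Mb, 8 founders, switch rate 1e-5/bp
(mean founder tract 100 kb) — give pronounced block LD on the scale of
the ±100 kb window. Toy maps are constant-rate (1 cM over 1 Mb by
default, the genome-wide average rate) or "hotspot" (90% of the genetic
length in the central 10% of the span).

What the mosaic emulates: tunable local LD, block structure, shared
segments (plus an explicit `plant_duplicate_haplotype` for IBD-tracing
tests). What it does not: realistic allele-frequency spectra, LD decay
shaped by a true genealogy, mutation/gene-conversion, population
structure. Tests passing on these fixtures therefore demonstrate the
transform's exact properties (reversibility, conservation, the Poisson
law, LD invariance at K = 0) on any input, and the *qualitative*
LD-vs-K behaviour — not quantitative LD numbers for any real cohort.

## Problem sizes and statistical tolerances

The default suite runs panels up to 200 haplotypes × 2,000 sites and
chromosome-scale quantities on toy maps (λ ≈ 20 for goodness-of-fit
checks), sizes at which every property is either exact or has ample
Monte-Carlo resolution. Stochastic checks are seeded and use 3-standard-
error bands (binomial or replicate-level) or goodness-of-fit tests at
α = 0.01 (χ² against Poisson(λ) with pooled tails; Kolmogorov–Smirnov
against the uniform). The LD-decay trend uses 10 seeded replicates per K
over K ∈ {1, 32, 128} and compares means.

## Known limitations

* Single-threaded reference implementation; `--threads` would only ever
  affect I/O compression, never RNG order, but is currently a no-op.
* BCF and bgzipped VCF are supported through pysam/htslib; streaming VCF
  input is loaded per chromosome into an int8 matrix, which is compact
  (one byte per allele) but not constant-memory in L like the row
  pipeline itself — genuinely biobank-scale panels would want the
  generator path wired directly to the VCF reader.
* The per-haplotype probability formula assumes every event swaps two
  slots of the same chromosome's panel; with multiple chromosomes each is
  handled independently, so probabilities are per chromosome.
* Monomorphic and multiallelic sites pass through (the permutation is
  allele-agnostic) and are only reported by validation; imputation-side
  filtering is out of scope.
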