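# Methods

## Small-RNA processing chain

**Trimming.** A raw library read is insert + 3′-linker, sequenced to a
fixed length. The insert is everything left of the *first* perfect
occurrence of the linker's 5′-terminal 6-mer; reads without an
occurrence are discarded and counted. Matching is case-insensitive and
literal — an `N` never matches, and there is no mismatch tolerance or
full-linker alignment, because downstream mapping is exact and a
fuzzily trimmed insert would silently fail there anyway. An insert in
which the 6-mer happens to occur at position 0 becomes an empty insert
and is removed by the length filter (default bounds 18–30 nt, chosen
to bracket the 19–29 nt range analyzed; both bounds are configurable),
keeping the accounting exact:

```
reads_in = inserts_out + discarded_no_linker + discarded_length
```

This ledger is checked at run time and propagated across stage
boundaries by the pipeline driver.

**Mapping.** Inserts are placed wherever they match the genome
perfectly over their whole length, on either strand. The matcher
indexes forward-strand k-mers (k = 18 by default, shrunk to the query
length for shorter queries) and verifies candidate slices, which is
exactly equivalent to a brute-force both-strand substring scan (a
property test asserts this on random genomes). Minus-strand placements
are found by searching the reverse complement against the forward
genome, so all coordinates are forward-genome, 0-based, half-open.
Multi-mappers retain all placements with `n_hits` recorded; an
optional cap (`max_hits`) discards reads above it, off by default. A
chromosome blocklist applied before mapping models the exclusion of
unassembled heterochromatic scaffolds. Palindromic (self-reverse-
complementary) inserts report each interval on both strands; they are
vanishingly rare at these lengths and deterministic either way.

**ncRNA filtering.** A read is removed — all placements — when any
placement overlaps any interval of the ncRNA/pre-miRNA tracks by ≥ 1
nt, strand-agnostically: removal is defined on sequences, not
placements. Abutting half-open intervals do not overlap. The number of
distinct reads surviving with ≥ 1 placement is the library's
normalization depth.

**Cluster histogram.** A read contributes once to bin
(strand, length) if at least one placement overlaps the cluster span;
strand and length come from its leftmost cluster placement, and a
counter records reads whose cluster placements disagree on strand
(determinism over ambiguity; the counter makes the choice visible).
Abundances are reported raw and as reads per million mapped non-ncRNA
reads (RPM). Zero depth is an error, not a NaN.

**Size classes and fold change.** The short class sums lengths
{19, 20, 22}; the entire 21 nt bin is excluded as the endo-siRNA peak —
no mixture modelling, the bin is simply dropped. The long class sums
23–29 nt inclusive. Fold changes are elementwise mutant/wild-type
ratios of RPM values (per-library scaling cancels in the ratio); a
zero wild-type class yields a flagged undefined ratio, never a crash
or a silent drop.

**Cluster attribution.** Of the reads with ≥ 1 placement on a
telomeric-element interval (genome-wide track), the reported fraction
also has ≥ 1 placement inside the cluster. Undefined (flagged) when no
read touches the track.

**Ping-pong signature.** For every plus/minus placement pair on one
chromosome, the 5′-to-5′ overlap is `(minus.end − 1) − plus.start + 1`
(inclusive, in plus-read coordinates; the minus read's 5′ end is its
rightmost base). Overlaps 1–30 are histogrammed per placement pair via
position counters — algebraically identical to the O(n²) all-pairs
enumeration a test checks against — and the 10 nt bin gets a z-score
against the mean/SD of the other bins.

## qPCR quantification

Primer efficiency is `E = 10^(−1/slope)` from an ordinary
least-squares fit of Ct on log10(dilution) over ≥ 3 distinct dilution
points (≥ 4 ten-fold points in generated plates); a non-negative slope
is a data-orientation error, and fitted efficiencies outside (1, 2.2]
are flagged. Replicate Cts are always averaged on the cycle scale
before exponentiation (geometric averaging of quantities); Ct ≥ 40 is
treated as a non-detect and excluded with a warning.

Percent input corrects the input aliquot to its whole-chromatin
equivalent: for input fraction `f`, the adjusted input Ct is
`mean_input_Ct − log_E(1/f)` (more template, fewer cycles), and
`%input = 100 · E^(adjusted − mean_IP_Ct) = 100 · f · E^(ΔCt)`. The
sanity anchor for the sign convention: an IP that recovers exactly the
fraction `f` of the chromatin gives Cts equal to the input aliquot's
and must report `100·f` percent. The SD combines both replicate
standard errors by the delta method on the log scale. Fold change vs
wild type is the ratio of percent-input values per primer pair.

Relative copy number per sample is `E_t^(−Ct_t) / E_r^(−Ct_r)`
(element primer over single-copy reference primer), divided by the
same quantity in the control sample; with both efficiencies 2 this is
exactly the textbook `2^(−ΔΔCt)` (asserted to 1e-12).

## Cytology statistics

Each embryo is one independent observation: its bridge frequency is
bridged/total anaphase–telophase figures. Genotype summaries are the
mean of per-embryo ratios with SEM (never pooled figures — a test
exhibits a counterexample where the two differ), a one-way ANOVA on
the ratios across genotypes, and two-tailed pairwise t-tests at
α = 0.05. Welch's unequal-variance test is the default (binomial
ratio variances differ whenever the underlying probabilities do); a
pooled Student's option exists. Ratios are untransformed and pairwise
p-values are raw; a Bonferroni flag is available. A genotype with one
embryo gets a flagged NaN SEM.

## Synthetic data: what it emulates, and what it does not

The default toy genome is a 100 kb "chromosome-4-like" sequence with a
71 kb cluster span (matching the size of the real profiled span) and a
50 kb background chromosome. Six telomeric-element fragments lie
inside the cluster and one outside, all annotated on the minus genomic
strand — the elements' sense strand — and all drawn as independent
random sequence, i.e. *diverged* copies: each read then has one true
origin, which keeps planted-truth attribution exact. Small ncRNA
intervals sit off-cluster.

Libraries are mixtures over six read classes (defaults in
parentheses): minus-strand 23–29 nt piRNAs from the fragments (0.30),
plus-strand 23–29 nt piRNAs from the cluster span (0.18), the 21 nt
minus-strand endo-siRNA peak (0.10), the short minus-strand species
with length support {19, 20, 22} (0.20), off-cluster background
(0.17), and linker-free junk that trimming must discard (0.05). piRNA
lengths peak at 25–26 nt. Reads are insert + linker truncated to 36 nt
with dummy qualities; the linker is a fixed arbitrary 20-mer
(`CTGTAGGCACCATCAATCGT`) — the original linker sequence is not public,
and only its leading 6-mer matters. Reads carry no sequencing errors
by default because the mapper is exact-match; an error-rate knob
exists. Mutant genotypes divide a class weight by a planted factor and
move the freed mass into the background class, which preserves the
mappable fraction so the planted RPM ratio is exactly 1/factor. The
rhi/ago3-like condition depletes the long classes (minus 2.5×, plus
5×) and sets the short minus class to 90% of wild type — inside the
80–95% regime reported for those genotypes. Forced ping-pong pairs
place a plus-strand partner whose 5′ end overlaps a minus read's 5′
end by exactly 10 nt.

Ground truth (class, origin, strand per read) is always emitted
alongside the reads; tests compare against it and never
reverse-engineer truth from outputs. All generators are bit-
reproducible given (spec, seed); a test asserts byte-identical FASTA
across runs.

What the generator does *not* model: sequencing errors and quality
artifacts by default, true repeat homology between fragments (so
multi-mapping is rarer than in real telomeric arrays and is exercised
by dedicated small tests instead), ChIP enrichment or chromatin
biology, and Piwi-IP selectivity. Passing recovery tests therefore
demonstrates correctness of the analysis arithmetic under the stated
mixture model, not robustness to real-library artifacts.

qPCR plates follow `Ct = intercept + log_E(1/quantity) + N(0, σ)` with
σ = 0.1 cycles by default and technical triplicates, plus a five-point
ten-fold dilution series per primer. Embryo tables are binomial draws
per embryo, 10–30 embryos per genotype (the regime the scoring scheme
assumes), 20 figures per embryo by default.

## Problem sizes and numerical choices

Recovery experiments use 200,000 reads per library (short-class
counts ≈ 4·10⁴ give a relative sampling error well below the 15%
recovery band); attribution uses 50,000 reads, ping-pong 2,000 planted
pairs over 10,000 background reads, efficiency recovery 100 plates,
copy-number recovery the geometric mean over 10 plates, and the bridge
power estimate 200 simulated datasets. Region strings like
`chr4:1280000-1350999` are parsed as 1-based inclusive and converted
to 0-based half-open on ingest (that span is exactly 71,000 nt).
Interval overlap everywhere is half-open, ≥ 1 nt. Ties in histogram
strand assignment go to the leftmost cluster placement. The ping-pong
z-score uses the sample SD (ddof = 1) of the non-signature bins and is
NaN when that SD is zero.

## Known limitations

The exact-match mapper is quadratic-free but holds the k-mer index in
memory; it is sized for cluster-scale toy genomes (≤ a few Mb), not
whole genomes. The ncRNA filter is by-read and strand-agnostic by
design, which can discard a multi-mapper whose only ncRNA overlap is a
secondary placement. Percent-input SDs propagate technical-replicate
Ct variance only; biological-replicate spread should be summarized
over repeated runs. The bridge ANOVA assumes per-embryo ratios are
approximately normal, which is adequate at ≥ 10 embryos × 20 figures
but fragile for probabilities near 0 or 1.
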