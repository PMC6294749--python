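# Methods

## Model

A ZW genome is modelled as scaffolds tiled by copy-number segments. Per sex,
a segment carries an integer copy number: autosomal and pseudoautosomal
sequence is 2/2 (female/male), W-specific sequence 1/0, Z-hemizygous
sequence (present on Z, lost from W) 1/2. Collapsed repeats keep 2/2 copies
but multiply apparent depth by a family-size factor, reflecting reads from
many near-identical genomic copies piling onto one reference locus — this is
how repeat-driven false positives arise in practice, so repeats are
simulated as depth multipliers, not literal extra sequence. Sex-independent
structural polymorphism is modelled as deletion loci where each individual
draws a diploid copy number Binomial(2, 1 − q), q the deletion frequency.

Per-base depth for one individual is an independent Poisson draw with mean

    target_depth × copy_number(sex)/2 × repeat_multiplier.

Poisson is the natural counting-process choice for shotgun coverage and
makes pooled tracks analytically tractable (a pool of n individuals at a
2-copy locus is Poisson(n × target_depth)); the variance structure of real
pooled data is not otherwise constrained, so overdispersion (GC bias,
mappability, index hopping) is deliberately out of scope. The read-emission
path places single-end reads segment-by-segment with Poisson counts of mean
(segment depth × length / read_length), so recomputed unfiltered depth
equals the depth model in expectation and the total of aligned bases equals
the sum of record-aligned lengths exactly (conservation). Flagged-secondary
and both-side-clipped records are injected at configurable fractions purely
to exercise the alignment filters.

One master seed expands to per-individual seeds via
`SeedSequence([master, index])` reduced mod 2^31, so partial re-runs of a
panel are reproducible individual by individual.

## The scan

Pooled per-sex tracks are summarised by modal non-zero depth, with ties
broken toward the smaller depth. Validity limits per sex are
`min = floor(modal/3)` (flooring, not rounding — rounding would break the
canonical 29 → 9 lower limit) and `max = 3 × modal`. A base is valid iff
`(C_f < max_f and C_m < max_m) and (C_f > min_f or C_m > min_m)`, all
inequalities strict. Male coverage is rescaled by `modal_f / modal_m` before
ratio formation; a total-throughput ratio is available as a config
alternative for libraries with very different insert profiles.

Intervals are exactly-V runs of valid bases (V defaults to 1000), with a
shorter terminal interval per scaffold; "approximately V" is read as
exactly-V because the downstream short-interval filter exists precisely to
remove scaffold-end remainders. Interval boundaries are trimmed to the
first/last valid base so spans reflect assayable sequence. Means are
computed over valid bases only (invalid bases are by definition repeats or
dropout); averaging over every base of the span is available via
`scan_intervals(..., means_over="all")` for sensitivity checks, but it
reintroduces exactly the signal the mask removed and is not the default.
The enrichment score is
`log2(mean_f / (adjustment × mean_m))`. A zero male mean is replaced by
`(read_length/2)/span` — the depth contribution of half of one aligned read,
the dimensionally consistent reading of a half-read pseudocount — with
read_length defaulting to 125 bp. Filters: span ≥ 500 bp and ≥ 200 valid
bases (inclusive, since the exclusion rule is "fewer than"); candidate calls
require score strictly > 2.

Degenerate inputs: an all-zero pooled track has no mode and is an error; an
interval with zero coverage in both sexes cannot exist (every valid base
exceeds a lower limit in one sex) and is asserted against; a panel missing
either sex cannot form a ratio and is rejected at pooling.

## Supporting procedures

*Chromosome assignment*: only primary, properly-paired records with edit
distance 0 on both mates count; records lacking the NM tag are excluded
(conservative — an unknown edit distance is not zero). A pair contributes
the outer span of its two mates (physical, fragment-level coverage), and a
scaffold is assigned when the union of spans covers ≥ 5% of it (inclusive).

*Synteny enrichment*: tabular (12-column) protein alignments are kept at
alignment length ≥ 50 aa and identity ≥ 60% (percent scale), reduced to the
best hit per query (identity, then length, then first seen) to avoid double
counting; enrichment is observed homologs / annotated genes per chromosome.

*Sex typing*: a marker is sex-specific only when present in every female and
no male; exactly one discordant animal demotes it to near-specific; any
other partial pattern is polymorphic. The panel false-positive probability
uses a null in which a segregating dominant marker is present in any animal
with p = 1/2, giving `p^nf (1−p)^nm` = 2^−12 ≈ 2e-4 for a 6+6 panel — the
natural model for that printed figure. Cross expectations enumerate gametes
uniformly with a viability map and the sex rule ZZ → male, ZW/WW → female.
Biplex band calls require the 486-bp internal control within a ±10-bp gel
tolerance before the 219-bp female band is read.

*Paralog divergence*: the ancestral state at each column is the strict
majority of non-gap outgroup bases. A substitution is attributed to the
paralog that departs from that state while the other retains it; columns
where both paralogs depart are unresolvable and reported, not guessed, and
columns where both share the same non-ancestral base are pre-duplication
changes attributed to neither. Amino-acid impact is counted per codon by
translating the paralog's codon against the same codon with attributed sites
reverted. Identity is computed over columns gap-free in both sequences.

## Synthetic study conditions and what the tests show

The generator's defaults are the conditions the recovery experiment uses: a
10-Mb genome in 50 × 200-kb scaffolds; 20 W-specific and 20 Z-hemizygous
segments of 2 kb; 10 collapsed repeats (2 kb, 10× multiplier); 20 deletion
polymorphisms (2 kb, frequency 0.3); 22 females and 26 males at 1X each;
master seed 0. The 10-Mb scale keeps the full pipeline — 48 simulated
individuals, pooling, scan — within tens of seconds while leaving every
planted feature hundreds of intervals of background to be confused with.
On these conditions the suite checks ≥ 95% of planted W segments overlap a
candidate, Z-hemizygous intervals sit near score −1 (half female coverage,
full male coverage) and are never called, and no candidate falls outside
the W truth (< 1 false call per 10 Mb).

Passing these tests shows the interval arithmetic, masking, scoring and
substitution rules behave as specified under Poisson sampling with known
truth. It does not demonstrate robustness to real-data features the
generator omits: mapping ambiguity, GC- and mappability-driven
overdispersion, reference errors, library-size imbalance beyond a modal
rescaling, or assembly fragmentation (real W candidates often terminate
scaffolds, which changes interval geometry). A known consequence of
embedding W segments mid-scaffold is boundary dilution: a 2-kb segment whose
valid bases straddle two scan intervals with substantial flanking sequence
on both sides can fail the score threshold on each; at the default
conditions this costs at most about one segment in twenty.

## Numerical choices

Modal ties break to the smaller depth; lower limits floor after adding 1e-9
to guard float division; scores are finite by construction (the zero-male
substitution bounds the denominator); interval means use float64
accumulations over valid positions. Scan output order is scaffold order then
coordinate, so results are byte-stable for a fixed seed.
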