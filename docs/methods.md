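# Methods

## The analysis model

`satquant` treats satellite-DNA quantification as a weighting problem.
A read from a tandem array has a set of *best hits* — alignments sharing
the minimal mismatch count (NM tag; negated alignment score as a
fallback) — and every statistic downstream is a function of the weights
placed on those hits. Three policies are implemented. `fractional`
(default) gives each of the n best hits weight 1/n; it is deterministic
and conserves mass exactly: summed feature counts plus the unannotated
row equal the mapped-read total to 1e-9 for any input. `random` draws
one hit per read, uniformly, from a seeded stream over hits sorted by
(contig, position, strand), so results reproduce across platforms; its
per-family expectation equals the fractional counts. `unique` keeps
only single-best-hit reads and is enforced for ChIP scoring at
heterochromatic satellite loci, where multimapper placement cannot be
trusted. A hit is attributed to the feature containing its 5′-most
genomic coordinate (for minus-strand reads, the rightmost aligned base);
this single-point rule makes window tiling and boundary behaviour
unambiguous and avoids double counting.

Normalisation is multiplicative: RPM (counts × 10⁶ / total mapped) for
within-library comparisons, or counts × 10⁶ / reference-mapped where the
reference (miRNA-class features, or the *flamenco*-like uni-strand
cluster) is unaffected by the pathway under study. Because
normalisation is a per-library constant, log2 ratios between samples are
invariant to the 10⁶ scale, and mutant-vs-control fold changes agree
between the two references whenever both are genuinely unaffected.

### Ping-pong statistic

On 0-based coordinates with the minus-strand 5′ end defined as the
rightmost aligned base, a plus read at p and a minus read at q overlap
by o = q − p + 1. The histogram c_o counts pairs for o in 1..30 (each
read pair once, or each distinct position pair once under "species"
weighting, which is never larger). The score is
z10 = (c_10 − mean of the other 29 bins) / sample SD of those bins
(n − 1 denominator). A perfectly flat histogram scores 0; any other
zero-SD background leaves the score undefined (reported as a flag, never
an exception or ±∞, so tabular output stays finite).

### Consensus folding

Reads are aligned to a multimer — monomer doubled, or Left+Right+Left
for a dimer family, so that any alignment of up to one unit length fits
without crossing the sequence end — and every aligned base at multimer
position x adds depth at x mod L_f, where L_f is the monomer length (or
|Left| + |Right|). Folding is idempotent and conserves bases exactly;
junction-spanning hits produce contiguous wrapped footprints. The
Left+Right+Left unit order of the trimer is a documented assumption; a
5′-end-only pileup mode is available alongside the default full-footprint
mode. The internal ungapped aligner (exhaustive scan, maximal identity,
all ties, both strands) is a toy-scale stand-in with the same output
type as the BLAST outfmt-6 reader; note a multimer contains each unit
twice, so an exact unit-internal query legitimately returns two
placements that fold identically.

### Enrichment and differential statistics

ChIP enrichment is E = RPM_ChIP / RPM_input per feature (undefined when
input RPM is 0), never input-subtracted coverage; the RPM constant
cancels, so E is invariant to library depth. Class summaries average E
over loci per class (heterochromatic satellite loci only for the satDNA
class — euchromatic insertions are excluded) and compare classes with
Welch's unequal-variance t, BH-adjusted across the comparisons in a
call. The euchromatic baseline is the median E of genes whose midpoint
is at least 5 Mb (configurable) from every heterochromatin boundary;
the midpoint anchor is a documented choice. Knockdown changes are
log2(E_kd / E_ctrl) per feature with per-class one-sample t-tests
against 0. Fold changes of normalised counts use
log2(mutant + pc) − log2(control + pc) with pc = 0.5 applied only when
either value is zero, making the statistic exactly antisymmetric and
finite. qPCR quantities use replicate-mean Ct values, base
(1 + efficiency) with efficiency in (0, 1], ΔCt = Ct_target − Ct_reference,
and ΔΔCt = ΔCt(wild type) − ΔCt(mutant), so negative values mean lower
expression in the mutant. Degenerate zero-variance groups in t-tests
yield t = 0, p = 1 when means agree (identical groups are never called
significant) and p = 0 otherwise.

## The simulator: what it emulates

The generator reproduces the statistical structure the analysis relies
on, with exact ground truth per read:

- **Genome.** One contig: random background with auto-placed loci
  separated by even background gaps (explicit offsets are honoured and
  collisions reported). Satellite arrays are concatenated consensus
  units — Left then Right per copy for dimers — mutated by substitutions
  only (always to a different base), so truth intervals tile the array
  exactly; indels are out of scope by design. The shipped consensus set
  is synthetic, generated once from a fixed internal stream with the
  real families' unit lengths and ~10% Left/Right divergence.
- **Expression.** Each read samples its source locus with probability
  proportional to a configured abundance coefficient (satellites:
  proportional to copy number), so per-locus counts are exactly
  multinomial and knockdowns act multiplicatively. Dual-strand loci emit
  both strands at 1:1; uni-strand loci one strand.
- **piRNA pool.** Lengths are integer draws from a truncated normal
  (mean 25, sd 1.5, bounds 23–28 — the canonical 24–26-nt peak; all four
  parameters exposed, bounds constrained to 18–35). Primary reads carry
  5′ U with probability `u1_bias` (0.75 default), otherwise a uniform
  other base, so the observed 1U fraction estimates the bias directly.
  At dual-strand loci a fraction `pingpong_fraction` of reads are
  responders, each paired with a primary actually emitted at the same
  locus (an independent virtual template only if the locus emitted
  none): opposite strand, 5′ ends exactly 10 nt apart, position 10
  complementary to the template's first base. Making the responder
  decision per locus rather than per library keeps locus read counts
  proportional to abundance under knockdown — the property the fold
  change analysis measures — while still planting the 10-nt overlap
  excess.
- **ChIP.** Input 5′ positions are uniform over the contig; ChIP
  positions are drawn per segment with weight length × E_f (background
  E = 1). Plain RPM-ratio scoring then recovers E_f up to a factor
  Σ(length × E)/G; the default study configuration keeps annotated
  features a small fraction of a 4-Mb background — as in a real assembly
  — so that bias stays within a few percent.
- **Knockdown.** The `rdc` regulatory class multiplies the abundance of
  satDNA loci and dual-strand clusters by a factor in (0, 1]; miRNA,
  uni-strand clusters and genes are untouched.
- **qPCR.** Ct = intercept − log2(q)/log2(1 + efficiency) + N(0, sd),
  replicated; references are targets with constant quantity.

Every stochastic operation draws from `default_rng([seed, crc32(name)])`
— one stream per operation (per-locus qualified where needed) — so a
single integer seed reproduces all outputs byte-for-byte and adding a
generator never perturbs existing ones. FASTQ qualities are constant
("I") and never consumed.

**What the simulator does not model:** sequencing error, indels,
paired-end reads, PCR/GC bias, adapter artefacts, chromatin-shear
profiles, isoform structure, or cross-mapping between diverged
subfamilies beyond what the mutated arrays induce. Passing tests
therefore demonstrate that the implementation recovers configured truth
under the stated statistical structure — conservation, geometry,
normalisation and estimator behaviour — not that any particular
biological dataset would yield the same numbers.

## Default study configuration and problem sizes

The packaged configuration mirrors the study system's shape: three
heterochromatic satellite arrays (an Rsp-like dimer and two 1.688-like
subfamilies), a 12-copy euchromatic Rsp insertion (the intronic-copies
analogue), two dual-strand and two uni-strand piRNA clusters (one
*flamenco*-like), three miRNA loci as normalisers, and eight euchromatic
genes, on a 4-Mb background. ChIP enrichment factors are 9.0 (dual),
4.7 (heterochromatic satDNA), 1.7 (uni), 1.55 (genes), 1.0 elsewhere —
the dual > satDNA > uni ≈ euchromatin regime. The test suite and the
acceptance script run at 2 × 10⁴–2 × 10⁵ reads per library and 20–50
seeds per property — sizes chosen so binomial error is well inside each
tolerance (e.g. class enrichment recovery within ±15% needs only a few
hundred input reads per locus) while a full run stays in the minutes
range on one CPU.

## Known limitations

- The counting path interprets alignments through their 5′ coordinate
  only; spliced/gapped alignments and paired-end fragments are not
  modelled.
- The brute-force mapper is guarded to toy scale (≤ 10 Mb genomes and a
  genome × reads product cap); real libraries should be aligned
  externally and ingested as SAM/BAM.
- Plain ChIP RPM-ratio scoring carries a global factor set by overall
  feature enrichment density; configurations where enriched features are
  a large genome fraction will show proportionally deflated E.
- The combined family row (e.g. `1.688` over its subfamilies) duplicates
  subfamily mass by construction and is marked as derived; conservation
  sums exclude derived rows.
- DESeq2-style dispersion modelling, shrinkage and covariates are
  deliberately not reimplemented; the fold-change definition here is the
  explicit normalised log2 ratio.
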