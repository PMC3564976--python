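# Methods

## The compatibility model

The package models a tetrapolar mating system: a mating between two
monokaryons succeeds if and only if they carry different alleles at
MAT A *and* at MAT B. Observed crossings are reduced to a binary clamp
formation signal — compatible (`+`), incompatible (`-`) — with `?`
reserved for crosses that produced no scorable confrontation.
Predictions on complete genotypes are always decided; `unresolved` can
only enter through observation. Self-crossings are incompatible by the
rule itself (identical alleles at both loci); because the bundled
crossing sheet leaves the diagonal blank, concordance scoring excludes
the diagonal by default. Replicate crossings are not represented: the
input format takes one consensus symbol per pair, and conflicting
replicates should be encoded as `?` upstream.

A dikaryon heteroallelic at both loci (alleles {a1,a2}, {b1,b2})
segregates exactly four progeny classes — the Cartesian product — and
under equifrequent classes the probability that two random sibs are
compatible is exactly 1/4 (4 of the 16 ordered class pairs differ at
both loci). Restricting the rule to one locus gives the bipolar value
1/2; these two rates are what the polarity caller uses.

### Compatibility-class inference

From crossing data alone, strains are grouped by identical
compatibility profiles (rows of the matrix), with unresolved cells
treated as wildcards and the constraint that same-class members are
mutually incompatible. Polarity is called tetrapolar when four classes
emerge and the resolved compatible-pair fraction lies within ±0.10 of
1/4, bipolar for two classes near 1/2, otherwise undetermined. The
±0.10 band is a pragmatic default (block structure over 16 strains
gives 32/120 ≈ 0.27); it is a parameter, not a fitted constant. Fewer
than four strains returns undetermined rather than an error.

## Allele calling

Marker amplicons are short and allele assignment in the source data
rests on sequence identity, so the default clustering merges reads only
on exact identity (`min_identity = 1.0`). A configurable threshold with
single-linkage clustering absorbs simulated sequencing error; single
linkage was chosen for its simplicity at the scale of tens of reads and
is documented as replaceable. Pairwise identity is computed gap-free on
the trimmed, nominally equal-length amplicons; a length mismatch is
end-padded and padded positions count as mismatches (no alignment rule
is defined for the marker, and indel-bearing reads should be resolved
upstream). Cluster representatives are the most frequent exact
sequence, ties broken lexicographically; labels are assigned by
descending cluster size, which makes the result invariant to input
order. `map_catalog_labels` pins de-novo clusters to an external
nomenclature; unmatched clusters keep their auto-label with an `_auto`
suffix.

A dikaryon observed with a single allele at a locus is flagged
(`*_SINGLE`) and never promoted to a homoallelic genotype: under the
mating model dikaryons are heteroallelic at both loci, so a single
observation means an unsampled second allele. Three or more alleles at
a locus are flagged `*_EXCESS` and left for interpretation
(contamination, three nuclei, and locus duplication are all consistent
with the data; the package only flags).

## Population statistics

**Richness** counts distinct labels per locus over all strains; a
flagged `*_EXCESS` strain still contributes all observed alleles,
because richness asks what alleles exist.

**Frequencies** (gene-count mode) give monokaryons one slot and
dikaryons two slots per locus; the unobserved slot of a single-allele
dikaryon is excluded from the denominator rather than imputed, and
excess strains are capped at their two most population-frequent alleles
with a warning. Strain-presence mode counts each distinct allele once
per strain. Both modes normalise to 1 per locus.

**Single-allele counts** are reported under two conventions — every
flagged strain, and only strains with data at the other locus — because
a companion locus that failed entirely makes the single-allele reading
ambiguous. The audit reports both rather than forcing either.

**Outcrossing potential** is `(1 − Σp²)(1 − Σq²)`, the probability two
random monokaryons differ at both loci under independence of the loci.

**Minimal founders**: n dikaryons carry at most 2n distinct alleles per
locus, and a pairing that reuses already-covered alleles always exists,
so the minimum is `max(⌈n_A/2⌉, ⌈n_B/2⌉)`. A brute-force search over
pair assignments ships alongside as an oracle for small allele sets.
Founders are constrained to be valid dikaryons: heteroallelic wherever
two distinct alleles are available, a repeated slot only for a
singleton locus.

**Marker-resolution audit**: per locus, a map functional factor →
proxy allele is built from strains with both labels. A proxy hit by k
functional factors leaves k−1 of them unresolved; within a collision
the most frequently observed functional factor is taken as the one the
proxy "sees", ties broken lexicographically. A functional factor
observed with two different proxies is reported separately as an
inconsistency.

## Segregation statistics

Goodness-of-fit is a plain Pearson χ² against an expected ratio
(default uniform), df = classes − 1, no continuity correction — at
family sizes around 23 the χ² approximation is slightly conservative
to slightly liberal depending on the split, which the test suite
quantifies (type-I error within [0.02, 0.09] at α = 0.05). Expected
classes come from the parent genotype, not the observed progeny, so a
missing class is detected as a zero count. Locus independence uses the
2×2 table of parental A allele × B allele with χ² (Yates optional,
default off) or Fisher's exact test; the recombination fraction is
estimated as the minority-diagonal proportion, 0.5 meaning free
recombination.

## Pheromone-precursor scan

Candidates are single-exon ATG→stop ORFs (standard genetic code, both
strands, nested starts included, 0-based half-open forward-strand
coordinates) whose protein falls within 30–120 aa and ends in a CaaX
motif: C, then two residues from the aliphatic set {A, V, L, I}
(configurable; some definitions include M), then any residue. The
30–120 aa window brackets known basidiomycete precursor sizes and is
overridable. The postulated N-terminal cleavage site is *not* modeled —
no usable rule exists — and every candidate carries a note saying so.
Splicing is ignored: intron-containing precursors are a documented
false-negative class of this scanner.

## Synthetic data

The generator defaults mirror the sampling design of the analysed
study: 26 dikaryotic strains, 3 MAT A / 4 MAT B alleles at equal
frequencies, 500 bp markers at 5% inter-allele divergence, 8 clones
sequenced per dikaryon marker, families of 23 spores, unlinked loci
(r = 0.5), error-free crossing scores with a 1/120 unresolved rate.
Allele sequences descend from a random ancestor per locus (first allele
= ancestor, the rest mutated independently; collisions resampled).
Dikaryons are drawn as compatible nucleus pairs, so truth tables are
heteroallelic at both loci by construction. Clone sampling picks one of
the two alleles uniformly per clone and drops the read with probability
`clone_dropout` (default 0.1 — no rate is known; this value produces
occasional single-allele dikaryons, matching what the real table
shows). With k clones and dropout d, a given allele stays unseen with
probability ((1+d)/2)^k, giving the closed-form single-allele rate the
tests check. What the generator does **not** emulate: PCR chimeras and
recombinant clones, allele-specific amplification bias, and
chromatogram-level error — so passing recovery tests show correctness
of the calling logic, not robustness to those artefacts.

### Wright–Fisher bottleneck simulator

A haploid population of N individuals carries one allele at MAT A,
MAT B, and a neutral control locus. Each offspring draws a parent pair
uniformly with replacement and the pair is rejected unless it differs
at both MAT loci (up to `max_mate_retries = 100`, after which the pair
is accepted anyway and counted as a failed mating); the offspring
inherits one allele per locus independently from either parent. This
rejection step is the entire selection model: carriers of rare MAT
alleles are rejected less often, an implicit negative
frequency-dependent selection with no explicit fitness function. The
life cycle is abstracted to haploid generations (no persistent
dikaryotic phase), which is sufficient for the richness-retention
question but not for, e.g., somatic incompatibility dynamics. The
neutral locus segregates identically minus the rejection step, making
it the matched drift control.

The default scenario is a severe founder bottleneck with matched
initial richness: N = 200, downsampled without replacement to 6
individuals at generation 20, recovery to N afterwards, 80 generations
total, 3 alleles at each locus. Retention experiments run 100
replicates (seeds derived from the master seed) and compare, per
replicate, whether each locus kept its full allele complement; the
MAT-vs-neutral contrast is tested with a one-sided sign test on
discordant replicates. Under these conditions the MAT loci retain all
alleles in roughly 0.6–0.8 of replicates versus roughly 0.3 for the
neutral locus. Selection intensity is emergent from the rejection
mechanism, not calibrated to any empirical estimate.

## Numerical and formatting choices

- All simulators take explicit integer seeds (numpy `default_rng`);
  fixed seed ⇒ byte-identical output, and the deterministic analysis
  path contains no randomness at all.
- Interval outputs use 0-based half-open coordinates everywhere; the
  GFF3 writer converts to 1-based inclusive at the boundary.
- Writers are atomic (temp file + rename): a failure leaves nothing
  partial.
- Blank genotype cells are explicit missing data, distinct from
  observed-single; the bundled tables preserve every ambiguous cell
  (including the one unresolved crossing) as-is.
- Test problem sizes (e.g. 1,000 random count vectors, 10⁵ Monte-Carlo
  pairs, 100 Wright–Fisher replicates, 2,000 small-family type-I
  replicates) were chosen to give stable statistical verdicts at
  interactive runtimes.

## Known limitations

- The exact-identity default makes allele calls sensitive to any
  uncorrected sequencing error; lower `min_identity` for noisy reads.
- Compatibility is binary; flat/intermediate mating reactions and
  nuclear-migration phenotypes are out of scope.
- The founder bound assumes founders are ordinary dikaryons; vegetative
  spread or multiple introductions of identical genotypes do not change
  the bound but are indistinguishable within it.
- The marker proxies themselves under-resolve functional mating types
  (the audit quantifies this); richness figures from proxies are
  therefore lower bounds.
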