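# Methods

This note documents the models, parameter choices and numerical
conventions behind `ysubtract`: what each component assumes, why the
defaults are what they are, and what validation on simulated data does and
does not establish.

## The subtraction model

The cascade treats Y-linkage as an inference by exclusion. Its premise is
that a transcript residing on the male-limited Y (i) cannot be explained
by the female genome assembly, (ii) attracts no female RNA-seq reads,
(iii) shows high male and negligible female genomic read coverage, and
(iv) is expressed substantially more in males. Each stage removes
transcripts violating one of these expectations; the thresholds are
deliberately strict, so the output is a conservative candidate set. The
design consequence is a known blind spot: a Y gene whose closest relative
in the female genome is nearly identical (a very recent duplication, ~98%
nucleotide identity) is removed by the female-genome subtraction — this
miss is a property of the method, reproduced and tested here rather than
patched around.

A second, subtler blind spot emerges from the coverage stage. Female
genomic reads map onto a Y transcript wherever a read-length window of the
paralogous locus carries at most two divergent sites. With 100-bp reads, a
gene below roughly 12% paralog divergence accumulates enough such windows
that its female breadth exceeds the 10% ceiling, even though it clears the
98%-identity subtraction comfortably. The detectability floor of the whole
cascade is therefore set by the coverage filter, not the identity filter;
the simulator's default world places its detectable diverged genes at
≥ 15% divergence and additionally plants two low-divergence probes (5% and
8%) that are expected to pass stage 3 and fail stage 6, so both behaviors
are pinned by tests.

### Thresholds

All cascade thresholds live in `PipelineConfig` with the published
defaults: 90% length / 98% identity and score floor 50 for the
female-genome subtraction; 50% breadth at ≤ 2 mismatches for the
female-RNA subtraction; 30 bp merge overlap; > 60% male and < 10% female
genomic breadth; > 2× expression ratio; > 60% effective-length fraction;
k = 25 (transcriptome) and k = 31 (genome) k-mer sizes; and the
more-than-twofold sex-swap inclusion rule. Inequalities are strict or
non-strict exactly as the stage contracts state ("greater than", "50% or
more"). All stages treat records independently except stage 7, whose RPKM
normalization uses per-library mapped-fragment totals over the current
record set.

## Internal engines and their contracts

The mapper, assembler, merger, repeat-library builder and aligners are
small internal engines with explicit contracts, chosen so that every
filter consumes exactly the quantity its threshold is defined on.

**Read mapping** is end-to-end and substitution-only (no indels, no
splicing): candidate placements come from a pigeonhole seed index (a read
with ≤ m mismatches must contain one of m+1 exact segments), verified by
bounded Hamming distance. Ties are broken by fewest mismatches, then
lowest target id, then leftmost position, then forward strand. Splicing is
unnecessary because transcripts are intron-free in the simulated regime;
on real data this mapper understates coverage for spliced genes.

**Assembly** is a greedy de Bruijn traversal over canonical k-mers with
count ≥ 2 (dropping singleton error k-mers), reporting maximal
non-branching paths; both orientations of every solid k-mer enter the
graph and mirror-image unitigs collapse afterwards, each contig reported
on the strand with the longest ORF. Three standard graph-cleanup moves
precede traversal — fork-edge plucking (a fork edge with < 0.2× the
support of its strongest sibling), bubble popping (parallel unitigs
sharing both junctions; the better-covered survives) and tip clipping
(dead-end unitigs < 2k with < 0.3× the coverage of their junction
siblings). All three are no-ops on error-free data, which keeps the exact
assembly contracts testable; they exist because two reads sharing a
sequencing error defeat the count threshold and would otherwise fragment
transcripts. Fragments whose ends fall below the count threshold lose a
few terminal bases; uniformly sampled fragments cannot cover terminal
k-mers at calibrated depth, so "full-length" reconstruction is asserted
with explicitly tiled reads, and end-to-end recovery by alignment
matching.

**Local nucleotide alignment** (stages 3 and 8) is seeded ungapped
extension: exact 16-mer seeds define diagonals, and the best segment per
diagonal is found by a maximum-subarray scan at +1/−1, which *is* the
matches − mismatches score the thresholds are written on. Ungapped is
sufficient because paralog divergence in the simulated regime is
substitution-only; on real data indels would fragment hits and make stage
3 slightly more permissive.

**The repeat library** is assembled from male genomic k-mers whose count
is ≥ 10 × the median count of solid (count ≥ 2) k-mers. The median over
solid k-mers estimates single-copy depth; including singletons would let
sequencing-error k-mers drag the median to 1 and misclassify the whole
genome as repeat.

**The translated paralog search** runs the candidate peptide against all
six frames of every female scaffold with Biopython's Smith–Waterman
(BLOSUM62, gap open −11, extend −1). The score floor of 50 is interpreted
on the BLAST bit-score scale via the Karlin–Altschul conversion
(λ = 0.267, K = 0.041 for gapped BLOSUM62): a raw-score floor of 50 admits
the chance hits any genome-sized search produces, which would invent
paralogs for genes that have none. The identity floor (40%) applies to the
aligned columns. Codon alignments for Ka/Ks are obtained by back-threading
the protein alignment and dropping gap and stop columns pairwise.

## Ka/Ks (Nei–Gojobori 1986)

Synonymous sites per codon are the degeneracy-weighted count
s = Σᵢ (synonymous one-step changes at position i)/3, with mutations to
stop codons counted as nonsynonymous; sites are averaged over the two
sequences. Differences per codon pair are averaged over all substitution
orderings, excluding orderings that pass through a stop codon unless every
ordering does. Both proportions receive the Jukes–Cantor correction
d = −¾ ln(1 − 4p/3); p ≥ ¾ yields an infinite estimate, and Ka/Ks is
reported as undefined (missing) whenever Ks is zero or non-finite, never
as infinity. For display, Ka/Ks values above 3 are truncated at 3 while
raw values are preserved in the tables. The per-codon-pair pathway
averages are precomputed once; tests check them against an independent
exhaustive enumeration, exactly on counts and to 1e−12 after correction.

A caveat inherent to the method: synonymous sites with two-fold degeneracy
saturate faster than the Jukes–Cantor model assumes, so Ks is mildly
biased at high divergence; recovery within 15% is verified for synonymous
divergence up to 0.3.

## Coverage-based sex-linkage classification

A scaffold's log2(male/female) depth ratio is normalized by per-library
totals. For classification the totals are the *sequenced* bases of each
library, not the aligned bases: male libraries contain a Y-derived
fraction that cannot align to a female assembly, and normalizing by
aligned bases would shift every scaffold's ratio upward by that fraction
(≈ +0.25 under default conditions, enough to push autosomes out of their
expected band). With effort normalization, X-linked scaffolds (one copy in
males, two in females) sit near −1 and autosomes near 0; the classifier
calls X below −0.5, autosome within ±0.5 of 0, male-only when female depth
is zero, ambiguous otherwise, and only accepts scaffolds ≥ 1000 bp.
Scaffolds carrying high-copy repeats attract multi-mapped reads and can
drift toward the band edges — visible in the simulation as a mild positive
shift of the repeat-bearing autosome.

## Expression statistics

TPM_i = (cᵢ/elᵢ) × 10⁶ / Σⱼ(cⱼ/elⱼ) with el the effective length
(L − μ_frag + 1, floored at 0; zero-el transcripts get zero TPM). A read
pair counts once, assigned to the target of its first mapped mate. Row
z-scores use the n−1 denominator; constant rows are returned as zeros and
flagged. The enrichment test is a one-sided exact binomial upper tail at
p₀ = k_bg/n_bg — one-sided because only overrepresentation is of
interest — and the two planned tests are reported raw, without
multiple-testing correction. "Expressed" for the exclusivity flag means
TPM > 1, a conventional presence threshold the analysis does not otherwise
depend on.

## The simulator

The generator emulates the study design the cascade assumes: separately
sequenced male and female individuals of an XY species. Its fixed
structural assumptions are a diploid autosomal complement, a hemizygous X
(two copies in females, one in males) and a male-limited Y carrying
planted genes of five origin classes — unique (no paralog anywhere),
X escapee and autosomal acquisition (paralog planted on an X or autosomal
scaffold at a specified divergence), recent duplicate (≤ 2% divergence,
the designed stage-3 miss) and repeat-embedded (a diverged repeat-monomer
copy transcribed as a tail, the designed stage-8 catch).

Sequence model: i.i.d. uniform nucleotide backbones; every gene is a
transcription unit (50-bp UTR + single-ORF CDS + 50-bp UTR) so the ORF
stays interior when assembly trims transcript ends. Paralogs are created
by copying the whole unit and substituting at exactly
round(divergence × L) distinct sites — nucleotide identity is exactly
1 − divergence, keeping alignment oracles sharp. In the CDS, start/stop
codons are protected, substitutions creating in-frame stops are resampled,
and amino-acid-changing proposals are accepted with relative probability
ω = 0.3, mimicking purifying selection: surviving gene copies in real
genomes keep protein identity far above what uniform substitution would
leave, and without this bias a 40%-diverged paralog would fall below the
translated search's own 40% identity floor by construction. Repeats are a
150-bp motif tandem-repeated 12 times, planted on an autosome and between
Y genes.

Reads are paired-end (100 bp, fragment length ~ Normal(250, 25) clipped to
[read length, template length]) with uniform per-base substitution errors
(default 0.002). Genomic libraries sample a copy-number-expanded pool so
autosomal depth equals the configured value (20×) and the male X sits at
half; RNA libraries sample each expressed transcript at
depth × profile[tissue] (50× baseline; Y genes default to a 10:1
gonad:head bias). One RNG stream per (sex, datatype, tissue), each seeded
from the master seed, makes every library reproducible independently —
adding a tissue never perturbs another library — and gzip output is
written with a fixed timestamp so repeated runs are byte-identical.

Default problem sizes — six autosomal, four X and four Y scaffolds of
~8 kb, 26 Y genes of 780–1200 bp, ≈ 16 k genomic read pairs and ≈ 17 k RNA
pairs per sex — are chosen so one full cascade runs in a few seconds while
every per-scaffold and per-gene statistic stays well-powered (e.g. the
log2 ratio of an 8-kb scaffold at 20× has σ ≈ 0.1 against a ±0.3
acceptance band).

What the simulator does **not** emulate, and what passing tests therefore
do not show: indel and structural divergence (alignment and mapping on
real data must tolerate gaps), splicing, heterozygosity beyond X
hemizygosity, GC- or machine-dependent error profiles, realistic repeat
landscapes (one satellite family vs. nested transposon hierarchies),
partial Y degeneration (pseudogenes, truncated copies), and
multi-isoform transcription. Results on real data will be noisier at
every stage; the simulation validates the logic and the thresholds'
interplay, not field performance.

## Degenerate inputs and conventions

Coordinates are 0-based half-open throughout. Empty read streams yield
empty mapping results, not errors; an empty record list passes through
every filter; a world without Y scaffolds yields an empty candidate list.
`kaks` rejects sequences whose length is not a multiple of three or that
contain internal stops. `classify_scaffold` rejects scaffolds under
1000 bp. Records discarded by a stage carry the discarding stage and the
measured metric in their audit trail and are never re-examined; every
discarded record names exactly one stage.

## Known limitations

- The stage-3 score clause is interpreted so that sub-floor alignments
  count as *no hit* (retaining the transcript): reading the discard rule
  literally would discard transcripts with no female-genome hit at all,
  inverting the pipeline's purpose.
- The effective-length correction uses the mean fragment length; a
  quantifier integrating over the fragment-length distribution would give
  slightly different values near the stage-9 boundary, though the
  pass/fail contract (> 0.6 × length) is unchanged.
- Stage 4's "50% of their sequence" is computed as per-transcript breadth
  of female-RNA coverage; a per-read-fraction reading is possible but less
  consistent with the coverage semantics of stage 6.
- NG86 with equal pathway weighting is the simplest of the counting
  Ka/Ks estimators; maximum-likelihood dN/dS is out of scope.
- The greedy merger is order-stabilized but not globally optimal; inputs
  engineered into chains of pairwise-compatible overlaps can merge
  differently under permutation.
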