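# Methods

## Model and rationale

In an F1 hybrid of two closely related species, both parental alleles are
transcribed in the same nucleus under the same *trans*-acting machinery, so
the ratio of allele-resolved read counts for a gene estimates the relative
*cis*-regulatory activity of the two parental haplotypes. Two confounders
dominate this design and drive the pipeline's structure:

- **Reference mapping bias.** Reads carrying the non-reference allele
  mismatch the reference at divergent sites and are lost or penalized more
  often. hybridase maps (or accepts mappings) against both the reference and
  a pseudogenome in which every fixed divergent site (FDS) carries the other
  species' base. Substitutions preserve length, so both mappings share one
  coordinate system; fragments unique in both with identical coordinates are
  kept once, fragments unique in exactly one are taken from it, and per-gene
  counts are the mean of the two mappings' counts (hence possibly
  half-integral; they are rounded nearest-ties-to-even before testing, which
  is immaterial above the 20-read filter).
- **Genomic imprinting.** A parent-of-origin effect mimics cis divergence in
  a single cross. With reciprocal crosses the species allele favoured by an
  imprinted gene flips between directions, so requiring concordance of the
  *species* ratio across all replicates of both directions excludes imprinted
  genes from ASE calls, and requiring concordance of the *parental* ratio
  (after relabelling counts by each sample's cross direction) identifies them
  separately. The two definitions are mutually exclusive under relabelling,
  which the separation experiment confirms empirically.

## Statistical tests

**Storer–Kim exact unconditional test.** For pooled allele counts
(x1, x2) with n = x1 + x2 the test evaluates H0: p1 = p2 by summing
Bin(y1; n, p̂)·Bin(y2; n, p̂) over all outcome pairs whose proportion
difference is at least the observed one, with p̂ the pooled proportion and an
ε = 1e-12 guard against floating ties in the |difference| statistic.
Unlike the conditional (Fisher) test it does not condition on the table
margin, which preserves power at moderate counts. The implementation is
vectorized over the outcome grid; `storer_kim_grid` computes all outcomes for
fixed sample sizes at once by sorting the outcome surface per pooled count
and suffix-summing. A p-value of exactly 1 is returned when the observed
difference is 0, where the tail is the whole sample space.

**Calling rules.** Genes enter testing when they have ≥ 3 exonic FDSs, a
mean of ≥ 20 assigned reads per biological replicate, and mean FPKM ≥ 1.
Significance (BH-adjusted q < 0.05, family = eligible genes of one tissue)
comes from replicate-pooled counts; the effect-size cutoffs (ratio > 0.65
and < 0.35, strict inequalities; 0.6/0.4 in permissive mode) must hold in
the pooled estimate and in every replicate. Pooling for significance plus
per-replicate concordance for effect is the reading that satisfies both the
depth filter and the all-replicates requirement; a per-replicate significance
test would be underpowered at exactly the depths the filter admits.

**Splicing LRT.** Per event the inclusion-read count is modelled binomial
with inclusion probability p = ψ·l_inc / (ψ·l_inc + (1−ψ)·l_exc); ψ ↔ p is a
monotone bijection, so the MLEs are observed count fractions and the
likelihood ratio 2(ℓ1 − ℓ0) for H0: ψ_A = ψ_B is referred to χ² with 1 df.
Replicates are pooled per allele before testing (the allele split already
halves depth); a hierarchical replicate model is deliberately out of scope.
Significance additionally requires support ≥ 100 reads (all four counts
summed; switchable to per-allele), |Δψ| > 0.10, and FDR ≤ 1% across all
tested events of a sample/tissue.

**Effective lengths.** l_inc and l_exc count the distinct read start
positions on the local inclusion/exclusion isoform that the read classifier
would score for that form, computed by sliding a read-length window over the
isoform blocks and applying the same classifier used for real reads. This
guarantees estimator/counting consistency; a config option (l_inc = l_exc =
1) gives raw-count ψ. Junction evidence requires an exact intron match
(donor and acceptor both equal); reads consistent with both or neither form
are uncounted. Each mate of a pair is classified independently ("reads", not
fragments, support events).

**Allele assignment.** Fragments (read pairs) are the assignment unit: a
pair is alleleA iff it shows ≥ 1 species-A base and 0 species-B bases at
covered FDSs (symmetrically for B); both kinds → ambiguous; none →
uninformative. A base matching neither allele (sequencing error) is tallied
but does not force ambiguity; a mate disagreement at one site is marked as a
non-allele observation at that site. "Uniquely mapped" means primary
alignments only, no secondary/supplementary records for the read name, and
MAPQ ≥ 30 (configurable). Fragments overlapping the exon unions of several
genes count for each (tallied; a drop mode is available).

## Synthetic data

The generator lays out multi-exon genes (3–8 exons of 80–300 bp, introns
100–400 bp) of three biotypes (80% protein-coding, 15% lncRNA, 5%
pseudogene) on one chromosome, draws FDSs per-position Bernoulli (1.0%
exonic, 1.2% non-exonic — roughly the fixed divergence of equid or bovine
species pairs that separated a few million years ago), and derives the
second haplotype by substitution, so the two genomes differ exactly at the
site list. Per sample and gene, fragment totals are negative-binomial
(default mean 100, dispersion 0.1 — typical biological variability between
bulk-tissue replicates); each fragment's allele is Bernoulli with the gene's
sample-specific species-A probability (0.5 for balanced genes, 0.8/0.2 for
the ~10% imbalanced genes; imprinted genes override this with a ratio of 0.9
toward the favoured *parent*, flipping the species direction between
reciprocal crosses). Genes designated for splicing carry two transcripts
realizing one event type (60% SE, 10% each of the others); the isoform of
each fragment is chosen with probability proportional to molecule fraction ×
eligible start positions, which makes length-normalized PSI estimation
unbiased. Reads are 100 bp pairs from ~N(300, 30) fragments with
per-base substitution errors at 0.001, emitted as truth-aligned SAM (tags
record the true allele, gene, and error positions) plus FASTQ; identical
config + seed reproduces byte-identical files.

What the generator does **not** model: indels and structural divergence,
quality-score and position-dependent error profiles, intron-spanning
mis-splicing, trans-regulatory divergence (irrelevant in a hybrid by
design), multi-mapping ambiguity and alignment errors (records are
truth-placed), and expression-level differences between parental species
beyond the allelic ratio. Passing tests therefore demonstrate correctness of
the statistical machinery and the assignment logic under ideal mapping, not
robustness to aligner artefacts.

## Calibration experiments

`hybridase.calibration` (exercised by the test suite and
`scripts/acceptance.py`) runs seeded experiments at the study's operating
conditions; problem sizes are chosen so every experiment completes in
seconds at desk scale:

- **ASE error/power**: 500 balanced + 50 genes at true ratio 0.8, three
  replicates, mean 100 assigned fragments. Measures the false-call rate on
  balanced genes (≈ 0 — the 0.65 effect cutoff is ~3 binomial SDs from 0.5
  at this depth), sensitivity on imbalanced genes, and the accuracy of the
  pooled ratio (±0.05 is ≈ 2 standard errors at ~300 pooled reads, so the
  expected within-tolerance fraction is ~95%).
- **Imprinting separation**: 20 imprinted (ratio 0.9 to the favoured parent)
  + 20 cis (0.8) + 60 balanced genes across both cross directions; measures
  recovery of each class, direction correctness, and call-set overlap.
- **Splicing LRT**: 500 null events (ψ_A = ψ_B = 0.5, ~300 reads) for
  null-uniformity (KS test), plus 10 planted Δψ = 0.3 events at ~400
  supporting reads — above the 100-read floor and far enough from the
  detection margin that the binomial power bound predicts ≥ 9/10 detections
  robustly. Raw-count ψ (l_inc = l_exc) is used here since the experiment is
  a plain two-binomial comparison.
- **Assignment soundness / mock hybrid**: with error rate 0, every assigned
  fragment must match its truth label and the call classes partition the
  fragments exactly; an equal in-silico mixture of the two parental
  libraries (≥ 10⁴ assigned fragments) must pass a two-sided binomial test
  against 0.5/0.5 at α = 0.01.
- **FDS density contrast**: a 2× exonic FDS rate planted in one gene class
  must be recovered within 3 Poisson standard errors of the site counts.

## Numerical and design choices

- Exact-test tie guard ε = 1e-12; p-values clamped to (0, 1].
- BH step-up via statsmodels; Storey-π0 rescaling available as an option.
- Averaged counts rounded nearest-ties-to-even before exact testing.
- Thresholds exposed in `RunConfig`; defaults: QUAL ≥ 30, MAPQ ≥ 30,
  RNA-filter coverage ≥ 10 with concordance ≥ 0.9 (the refinement thresholds
  are this package's choices), ≥ 3 exonic FDSs, ≥ 20 mean reads, FPKM ≥ 1,
  α = 0.05 with 0.65/0.35 (or 0.6/0.4) cutoffs, support ≥ 100, |Δψ| > 0.10,
  FDR ≤ 1%, promoter = 2 kb upstream of the TSS.
- Region precedence for FDS annotation: exonic > promoter > intronic >
  intergenic; sites on chromosomes absent from the models are intergenic.
- Gene length for FPKM is the exon-union length; CV uses the sample (n−1)
  standard deviation; group contrasts use the two-sided Wilcoxon rank-sum
  test.
- "Mean 20 reads" is interpreted as total assigned reads per replicate
  (config-switchable to per-allele).
- The pipeline accepts the same alignment file for the reference- and
  pseudogenome-mapping inputs (as with simulator output, where coordinates
  are identical by construction); with two files, merge semantics are
  one-entry-per-name with position-conflict dropping, as described above.

## Known limitations

Single-nucleotide divergence only (no indel-aware pseudogenome); no
aligner-level validation (alignments are consumed, not produced); the
splicing test pools replicates and ignores overdispersion between them;
event enumeration is annotation-driven (no novel-junction discovery); FPKM
uses exon-union counting rather than transcript-resolved quantification.
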