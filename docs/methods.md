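# Methods

## Rearrangement detection model

The caller consumes paired-end alignments and emits confirmed breakpoint
pairs in five steps.

**Discordant-pair collection.** A mate pair is discordant when the two ends
map to different chromosomes, or when the outer insert — the span from the
leftmost start to the rightmost end of the pair, the SAM `TLEN` convention —
strictly exceeds `insert_threshold` (default 2000 bp). Pairs are keyed by
read id; unpaired ids and records without mate coordinates are skipped with
a warning.

**Clustering.** Discordant pairs sharing (chromosome A, chromosome B,
strand orientation) are linked when both their A-side and B-side start
positions differ by strictly less than `cluster_distance` (default 500 bp);
clusters are the connected components of this link graph (single linkage on
both junction sides), so the result is independent of input order. The
500 bp rule is applied to read start positions, not fragment midpoints.

**Assembly.** Each cluster's reads (both mates) are assembled by a bundled
greedy assembler: repeatedly merge the fragment pair with the longest exact
suffix–prefix overlap ≥ `min_overlap` (default 20 bp), either orientation,
absorbing contained fragments. Mate reads typically tile two disjoint
intervals plus the junction, so assembly legitimately yields several
contigs; all are retained, longest first. A cluster in which nothing merges
is dropped and logged.

**Confirmation.** A contig is confirmed by split realignment against
reference windows around the cluster's two loci (window pad 1000 bp): the
longest contig prefix and suffix are each anchored by an exact
`min_flank`-base seed (default 25 bp) and extended under a mismatch budget
(`max_mismatch`, default 2), strand-aware with reverse complements
considered, and the contig is confirmed when both flanks are ≥ `min_flank`
and jointly cover it. Two subtleties matter numerically:

* the extension endpoint maximizes a local score (match +1, mismatch −4)
  rather than running to the mismatch budget, so chance matches beyond the
  true junction cannot drag the alignment edge outward;
* when the two flank alignments overlap (junction microhomology or residual
  chance agreement), every junction offset inside the overlap describes the
  same event; the reported offset is the overlap midpoint, bounding the
  coordinate bias at half the overlap length. Breakpoint recovery is
  therefore evaluated at a ±5 bp tolerance.

Reported calls are canonicalized so (chromosome, position) of side A sorts
first; a side swap reverses the contig and flips both strands. Strand `+`
on side A means the retained segment lies genomically left of the
breakpoint and reads toward the junction; strand `+` on side B means the
retained segment lies right of it. Positions are 0-based half-open
internally (the breakpoint is one past the last retained base); TSV reports
are 1-based.

**Support filter.** Unique support is the number of distinct
(A-start, B-start) coordinate tuples in the cluster — a PCR-duplicate-style
deduplication — counted before assembly; calls below `min_support` (default
5) are never emitted, and clusters below it are never assembled.

## Fusion annotation and classification

Each breakpoint is assigned to the unique overlapping gene model (intergenic
breakpoints make the call non-reportable; two overlapping genes raise an
ambiguity error). One canonical transcript per gene is assumed; exon
ordinals are 1-based in transcript order, and an intron *k* separates exons
*k* and *k*+1. The NTRK side of a call is the gene carrying a kinase-domain
annotation.

*In-strand* requires the partner's retained segment to contain its
transcription start and the NTRK retained segment its 3′ end, so both
transcripts read 5′→3′ contiguously across the junction given the genomic
strands. *In-frame* additionally requires the retained partner CDS length
to be congruent modulo 3 with the NTRK CDS length removed upstream of its
breakpoint (the junction acceptor phase); a non-coding gene on either side
is never in frame. *Kinase-domain retention* means every CDS base of the
annotated kinase interval lies 3′ of the NTRK breakpoint. Classification is
then: Definite iff in-strand ∧ in-frame ∧ kinase-retained; else Likely iff
kinase-retained and (partner in the reported-partner knowledge base ∨
breakpoint in a hot NTRK exon/intron); else NotReportable.

Two curated inputs are deliberately configurable rather than inferred:

* **Hot regions.** The recurrently rearranged regions default to NTRK3
  exons/introns 13–15 and NTRK1 8–17 — the breakpoint ranges observed in
  the transcribed cohort — because no formal definition of a "hot exon"
  exists; the set is carried as a GFF3 gene attribute and can be replaced.
* **Partner knowledge base.** A packaged TSV of partner genes with
  previously reported NTRK fusions (ETV6, TPM3, LMNA, TPR, RBPMS, IRF2BP2,
  PHF20, AMOTL2, COL8A1, PEAR1), matched case-insensitively and
  user-extensible; no external fusion registry is consulted.

The packaged toy gene models (GFF3) place NTRK1 with partner genes TPM3 and
LMNA on one chromosome (so intrachromosomal events are simulable), ETV6,
NTRK3/MORF4L1, and C7orf69 on three others, mirroring the real genes'
chromosome relationships. Exon CDS lengths are multiples of three except
C7orf69's (301 bases over three exons), so the canonical reported fusions
annotate as in-frame Definite while C7orf69→NTRK3 is out-of-frame and
rescued as Likely by the hot-intron rule — matching the transcribed
classifications. These are toys for pipeline demonstration; unit tests
construct gene models programmatically for the frame algebra.

## Panel metrics

**TMB** = (coding SNVs + insertions + deletions) / panel megabases,
reported to one decimal (half-up). Synonymous and non-synonymous variants
count alike and drivers are not subtracted — the simplest faithful reading
of "coding SNVs and indels per megabase". The denominator is a parameter
(`panel_coding_mb`), not a constant, because the capture footprint is
panel-specific.

**MSI.** Per locus, tumor and matched-normal allele-length profiles are
compared: a locus is *uncovered* below `min_locus_depth` (default 10×) in
either sample, *unstable* when the tumor carries an allele length with ≥
`min_allele_reads` (default 3) reads that is absent from the normal, else
*stable*. The per-locus rule is this package's operationalization — only
the panel-level threshold is externally specified. Panel status over the
572-locus marker set: MSI-H iff unstable/evaluated > 0.15 strictly
(86/572 = 15.03% is MSI-H; 85/572 is MSS), Unknown below `min_evaluated`
(default 20) evaluable loci, else MSS. "Unknown" is modeled as insufficient
evaluable loci.

## Cohort statistics

Fixtures transcribe the printed clinical tables: full-cohort marginals
(variable/level/overall/positive/negative; tumor-type totals sum exactly to
10,194 and positives to 40), the 41-fusion table of 40 patients (one
patient carries both MORF4L1→NTRK3 and PPFIA2→NTRK3), and the 13-patient
DNA/RNA/IHC concordance table. Prevalence percentages are recomputed as
100·positive/total, rounded half-up to one decimal; strata with zero totals
are omitted. Per-fusion statistics use the 41 denominator and per-patient
statistics 40; both are exposed because the source usage mixes them.

Associations use Fisher's exact test, two-sided by summing hypergeometric
probabilities ≤ the observed table's, with chi-square available on request;
'Unknown' levels are excluded pairwise. Continuous group comparisons use
the Wilcoxon rank-sum test with midrank ties. The fusion × MSI enrichment
table is (6, 180 / 32, 9429), giving rates 3.2% vs 0.34% and p ≈ 8×10⁻⁵.
Significance is read at p < 0.05. Two transcription-level inconsistencies
are retained rather than repaired: recomputing the positive-cohort age
median from the per-patient table gives 43.5 (the marginal table prints
45.0), and the IHC detection rate among evaluated samples is 7/9 = 77.8%
(an 87.5% figure appears elsewhere with an unstated 7/8 denominator); the
package reports the fixture-derived counts.

The per-patient co-mutation matrix of the source figure is not recomputable
from any printed table, so co-occurrence analysis is exposed only as a
generic counter over boolean per-patient flags for use on simulated
cohorts.

## Synthetic data

The generators define the test conditions; all are deterministic given a
seed (NumPy `default_rng`).

* **Reference**: uniform-random ACGT chromosomes (GC ≈ 0.5), ≥ 2
  chromosomes of ≥ 10 kb (default 50 kb) — a coordinate-generic stand-in
  for a real genome, since nothing in the algorithms depends on sequence
  provenance.
* **Reads**: 100 bp reads, 300 bp median insert, SD 30 — typical
  hybrid-capture short-read values. Supporting fragments span the planted
  junction at unique 10 bp-staggered offsets (30 bp minimum margin), so the
  pooled cluster reads tile across the junction and assembly can bridge it;
  each read is anchored to the fragment-end side it starts from, the
  soft-clipped-alignment abstraction without explicit CIGAR clips.
  Requesting more supporting pairs than staggered starts fit in one
  fragment length is an error. Background pairs are concordant with insert
  ~ Normal(300, 30) truncated above 2·read length; at SD ≤ median/10 the
  probability of a background insert crossing the 2000 bp threshold is
  below 10⁻¹⁰⁰, so background read sets are discordance-free by
  construction and specificity tests measure the caller, not the generator.
  No sequencing-error, base-quality, or duplicate model is included — the
  planted-recovery results therefore demonstrate algorithmic correctness,
  not robustness to real-data artifacts.
* **Microsatellites**: a 572-locus panel; a planted-unstable locus gains
  one novel tumor allele (depth/4 reads, ≥ 3) absent from the normal,
  all other loci have identical tumor/normal profiles; the planted count is
  round(fraction × panel size), half-up. The planted count equals what the
  MSI caller recovers at default thresholds, by construction.
* **Cohorts**: per-patient fusion status ~ Bernoulli(fusion rate) and MSI
  status drawn conditionally on it; tumor types follow the transcribed
  overall frequency vector.

## Verification strategy and problem sizes

Independent oracles back the core computations: clustering is checked
against a brute-force connected-components oracle on the pairwise link
graph (property-based, up to 40 pairs); the exact test against full
hypergeometric enumeration (exhaustive for small tables plus a seeded
sample up to N = 60, agreement within 10⁻⁹); the rank-sum p against exact
permutation on a 3-vs-3 example; breakpoint recovery against planted truth
(20 replicates of 1000 background pairs each for recall, 5000 for
specificity, on 50 kb × 4 chromosomes). These sizes keep the full suite
under ~10 s while leaving every decision threshold (2000 bp / 500 bp /
5 pairs / 15%) covered by strict boundary cases on both sides.

## Known limitations

* Split-read (single-end) evidence, copy-number events, and
  somatic-vs-germline subtraction are out of scope; so are the external
  mapper/assembler/realigner tools the bundled stand-ins replace.
* The confirmation step requires an exact 25 bp seed at each flank end;
  heavily degraded flanks would realign in a real pipeline but fail here.
* One transcript per gene: isoform-aware exon numbering is a curation
  problem deliberately left outside the annotator.
* RNA-level fusion detection is consumed only as a fixture (the concordance
  table); no RNA caller is included.
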