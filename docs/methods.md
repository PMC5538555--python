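# Methods

This note documents the models, rules and numerical choices behind
`retroped`: what the synthetic-data generator emulates, how each analysis
stage is defined, which parameters matter, and what the passing test
suite does and does not demonstrate about real sequencing data.

## The biological model

Mouse L1 elements integrate by target-primed reverse transcription
(TPRT). The endonuclease nicks AT-rich DNA at sites resembling
5'-TTTT/AA-3'; the staggered second nick produces a short direct repeat —
the target-site duplication (TSD) — flanking the new copy, and
reverse transcription of the polyadenylated mRNA leaves a 3' poly(A)
tract. If transcription of the donor element read through its own
polyadenylation signal, the new insertion carries a 3' transduction: a
tag of genomic DNA downstream of the donor that uniquely identifies it.

Where in development the insertion happened determines its distribution
across the animal and its heritability:

| archetype | soma | gonad/germ cells | offspring |
|---|---|---|---|
| heterozygous (late germline / zygote) | 1 allele everywhere | 1 allele | Mendelian (50%) |
| germline-restricted mosaic (early PGC) | absent | fraction f | each carrier with prob. f |
| somatic + germline mosaic (pluripotent embryo) | low fractions | fraction g | each carrier with prob. g |
| somatic-restricted mosaic (embryo, soma only) | sub-het fractions | absent | never |
| polymorphic (ancestral) | per genotype | per genotype | Mendelian |

The classifier's job is to invert this table from sequencing read support
and tissue qPCR.

## Synthetic-data generator

**Consensus library.** Seven deterministic synthetic stand-ins (L1 T_F,
G_F, A; SINE B1, B2; LTR IAP, ETn) generated once from a fixed internal
seed. The L1 subfamilies share one body at ~5% divergence but carry
distinct 212-bp 5' UTR monomers (3 tandem copies), so subfamily
assignment by identity and monomer counting are meaningful. Each L1 ends
in a GC-rich segment (the property blamed for poor sequencing of real L1
3' ends), whose last three bases are pinned to non-A so the element /
poly(A) boundary of a TPRT product is exact, followed by a 25-bp A-tail
so 3'-junction read segments are terminal-anchored on the consensus.
These are not Repbase sequences; every test that "recovers" a subfamily
is exercising the machinery, not mouse biology.

**Reference.** Random AT-biased chromosomes (GC 0.42) seeded with
mutated (2–10%) decoy TE copies — L1 decoys are 3'-anchored truncations,
as most genomic copies are — plus exact full-length L1 T_F donor copies,
each with a unique 300-bp downstream tag region for transduction
tracing, and a catalogue of known polymorphic-insertion loci.

**Insertions.** Nick sites are drawn uniformly from positions matching
the EN motif within a configurable mismatch budget (default 1). TSD
length ~ U{13..17}; poly(A) ~ round(N(64, 15)) truncated at 10;
transductions with probability 0.25, length U[50, 200], copied from a
donor tag. The modified haplotype is
`ref[:nick+tsd] + cassette + ref[nick:]`, so both flanks retain the TSD;
minus-strand events insert the reverse complement (the poly(A) reads as
poly(T) at the left junction). Full-length-only by default, matching the
observation motivating this design that de novo T_F insertions are
5'-intact; a truncation probability knob exists.

**Pedigree.** The demo pedigree is two founders and 20 F1 offspring
(the size of the study design this emulates). Founders carry the full
tissue panel; mRC-seq libraries are simulated for founder pooled soma and
germ-cell fractions and for offspring soma. Mosaic fractions:
germline-restricted f ~ U(0.20, 0.35); somatic+germline events have
somatic fractions U(0.001, 0.015) (the "1–2 reads upon deep sequencing"
regime) with germ fraction g ~ U(0.20, 0.35) — low somatic prevalence
coexisting with substantial germline contribution is exactly the
surprising pattern the pedigree design detects; somatic-restricted
events use U(0.20, 0.40) across soma, since such events are discovered by
sequencing the carrier's own tissues. Offspring carrier draws are
i.i.d. Bernoulli at the germ fraction.

**Reads.** `coverage_target` (default 30×) is the mean read depth over
capture-targeted bases — annotated TE intervals and insertion alleles —
with off-target background at `coverage_target / capture_enrichment`
(enrichment default 20×). This is the natural depth model for a
hybridization-capture assay and keeps the 5-Mb demo tractable. Mosaicism
is modeled by sampling the insertion haplotype per fragment at the tissue
allele fraction (no overdispersion). Germ-cell-fraction libraries get 3×
depth and founder soma 2× (parental tissues received the deep-sequencing
treatment in the emulated design). Fragments spanning the element-3' /
poly(A) junction are dropped with probability 0.8 (the observed depletion
of mouse L1 3' termini); insert sizes 450/550 bp, 150-bp reads, 0.2%
substitution error, 3% PCR duplicates, 1% chimeric fragments (spliced
from two loci, biased into TE sequence because capture enriches
TE-containing molecules; truth-tagged in read names).

**qPCR.** Ct = base − log2(template fraction) + N(0, sd) at 100%
efficiency; a zero fraction emits a no-amplification sentinel. Four
technical replicates per reaction by default, as in the emulated assay.

## Analysis stages

**Read prep.** End-trimming to the longest span whose terminal bases have
Phred ≥ 10 (interior low-quality bases retained). Pair merging scans all
overlaps ≥ 10 nt between read 1 and the reverse complement of read 2 and
accepts the lowest mismatch-density overlap if ≤ 0.25 — the documented
defaults of the overlap-merging tools this stage replaces. Disagreeing
overlap bases take the higher-quality call. 450/550-bp inserts with
150-bp reads cannot overlap; both mates are then analyzed independently
and evidence is unified at clustering.

**Genome alignment.** Seed-and-extend with 15-mer seeds (stride 4),
diagonal voting, and gapped verification scored match +1 / mismatch −2 /
gap open −4 / gap extend −1. The banded DP inside candidate verification
is delegated to `edlib`; seeding, candidate selection, scoring, and the
retained-read contracts are local code. A hit is reported only at ≥ 0.94
identity (mirroring a 2-mismatch tolerance on short reads), and is
*unique* only if the best score beats the runner-up at a distinct locus
by ≥ 5. Reads straddling an insertion junction fail the identity floor
and flow to the consensus pass, which is exactly how a two-pass unique
aligner behaves. A batched implementation performs the k-mer lookups for
a whole library at once and resolves the common single-candidate case in
a vectorized pass; it is contract-identical to the per-contig mapper up
to score ties between exact repeat copies (both are non-unique and
discarded either way). PCR duplicates are removed per identical
(reference, span, strand), keeping the highest-quality read, ties broken
by read id.

**Consensus pass.** Terminal-anchored, gap-free extensions along seeded
diagonals (8-mers; any alignment that can pass the filter at > 90%
identity over ≥ 33 nt must contain an exact 8-mer, so seeding loses no
passing hit). A hit passes iff identity > 0.90 and the alignment spans
≥ 33 nt from one contig end. Extensions whose inner endpoint reaches an
element terminus get a small selection bonus: the tandem 5' UTR monomers
make the diagonal ambiguous by one monomer unit, and parsimony anchors a
junction segment at the element 5' start / 3' end. Gap-free extension
reflects the substitution-only error model of the simulator; indel-rich
real data would need a gapped variant here.

**Junction calling.** The non-TE remainder of a passing contig must map
uniquely with ≥ 25 nt anchor (the TE side already requires 33 nt; the
genome-side minimum is a documented package choice). For 3'-side
junctions the poly(A)/poly(T) homopolymer between element and genome is
stripped before anchoring, which can eat leading TSD A's — junction
coordinates on the 3' side are therefore exact only to a few bases,
while 5' junctions are exact. Junction reads deduplicate per (sample,
anchor coordinates, side), then cluster by single linkage within 100 bp
per (chrom, side, orientation, subfamily); 100 bp exceeds the maximum
TSD with margin. Clusters with ≥ 3 reads across the cohort are primary
calls; 1–2-read clusters are retained as low-evidence records because
parental mosaicism lives there. 5'/3' clusters within 50 bp merge;
many-to-many ambiguity resolves by nearest-position greedy matching.

Calls are annotated, never deleted: `known_polymorphic` (within 100 bp of
a catalogue locus), `founder_polymorphic` (robust in every library of
some founder), `chimera_suspect` (rules: (a) anchors split across locus
groups; (b) consensus-orientation disagreement within a cluster; (c) pure
PCR stack; (d) junction-adjacent TE boundary interior to the consensus —
valid in full-length-only mode, where genuine junctions abut the element
termini), and `reference_te` (junction within 350 bp of an annotated
reference TE copy — such clusters are the reference copy's own termini
or, notably, transduction-carrying reads anchoring in the donor's
downstream tag, and are kept for donor tracing but excluded from primary
reporting).

**Hallmarks.** Annotation runs on the validated insertion cassette (the
generator truth stands in for capillary-sequenced junctions; assembling
full insertions from 150-bp reads is out of scope). TSD = reference
between the two junction coordinates (refused beyond 50 bp); EN site
read on the priming strand with the slash at the nick; poly(A) = maximal
terminal A-tract allowing isolated single-base interruptions flanked by
≥ 5 A on both sides (a strict-contiguous mode exists); subfamily by best
NW identity against the library with non-overlapping monomer matches
≥ 80% identity in the 5' region; transduction = segment between consensus
match end and terminal poly(A), ≥ 20 nt, mapped uniquely, with the donor
the annotated element whose 3' end lies within 200 bp upstream on the
matching strand; GC in 50-bp and 20-kb windows clipped at chromosome
ends.

**Origin classification.** Deterministic rules applied in order, using
read support plus optional per-tissue qPCR prevalence (the package
simulates the tracing qPCRs for candidate de novo calls, mirroring the
genotyping workflow of the emulated study):

1. known/founder polymorphic flags → `polymorphic`;
2. no parental somatic positivity (reads or qPCR) and germline evidence
   positive (germ-fraction reads or gonad qPCR) →
   `germline_restricted_mosaic`; with ≥ 2 carrier siblings and fully
   negative parents the class is inferred without a positive germ
   sample; a germ-positive parent with no carrier offspring also
   classifies here (deep germ-fraction discovery);
3. carrier offspring plus low (1–2-read) or sub-heterozygous qPCR
   somatic signal in a parent → `somatic_germline_mosaic`;
4. robust in every library of exactly one animal with fully negative
   parents → `heterozygous_de_novo`;
5. qPCR-backed sub-heterozygous somatic signal, no germline evidence, no
   carrier offspring → `somatic_restricted_mosaic` if the animal has
   offspring (germline contribution noted as not excludable), else
   `unresolved`.

Rule 5 requires qPCR evidence because read counts alone cannot separate
heterozygous from broadly mosaic tissue. Rule 2 differs from a
read-only formulation in accepting gonad qPCR as the germline-positive
signal: bulk gonads are genotyped, not capture-sequenced, in the design
this package emulates.

**Statistics.** Transmission: chi2 = Σ(obs−exp)²/exp over carrier and
non-carrier cells; the two-tailed p for this 1-df statistic is the upper
tail of chi-square(1) (documented because "two-tailed" is ambiguous for a
one-sided statistic). Insertion rate: events/genomes with Clopper–Pearson
95% bounds; an exact Poisson interval (flagged) when events exceed
genomes. qPCR: ΔΔCt with efficiency fixed at 2.0;
prevalence% = 100·2^−ΔΔCt against a heterozygous calibrator; replicate
SDs propagate in quadrature on the Ct scale. Copy number sets the mean
ΔCt of heterozygous calibrators to copy = 1 per assay.

## Problem sizes and determinism

The end-to-end demonstration runs a 5-Mb, 2-chromosome genome, 40 decoys,
2 donors, 12 insertions across all archetypes, 2 founders + 20 offspring
(30 libraries, ~1.1 M read pairs), on-target coverage 30×, enrichment
20×, error 0.2% — sized so a single-CPU run completes in minutes. A
master seed derives independent sub-streams for genome, planning,
pedigree, reads and qPCR, so any stage can be regenerated in isolation;
fixed seeds give byte-identical FASTA/FASTQ/BED/TSV outputs.

## Limitations

* Substitution-only error model; no indels, no quality-dependent errors,
  no GC-coverage bias beyond the explicit 3'-junction depletion.
* The consensus pass is gap-free; the genome pass tolerates indels only
  inside edlib verification.
* Hallmark annotation consumes validated insertion sequences; it does not
  assemble insertions from reads.
* Synthetic consensus sequences: subfamily assignment and monomer counts
  validate the algorithms, not real mouse L1 phylogeny.
* Carrier draws are independent Bernoulli; real litters share gamete
  pools, so sibling carrier counts can be over-dispersed relative to this
  model.
* The classifier assumes the tissue panel of the demo design (pooled
  soma, gonads, germ fractions); sparser panels push events to
  `unresolved` rather than to a wrong class, by construction of the rule
  order.
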