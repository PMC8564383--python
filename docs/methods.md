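# Methods

## What the synthetic loci emulate

The generator (`figmark.forge`) fabricates the two fig sex-linked loci
with their documented structure, so that the discovery stages have
something real to rediscover. Hard structural facts are layout
constants; the seed only fills background sequence (uniform A/C/G/T),
intron lengths, panel shuffles and which cultivars violate the invalid
SNP sites. Identical seeds therefore give byte-identical fixtures.

**AG locus.** The female gene is 5230 bp with 7 CDS-exons concatenating
to a 744-bp CDS. The two male-specific alleles (AG2/AG3) are the female
CDS plus a 15-bp insertion (`CAGGAGGAGGAAGCT`, the AG-Marker forward
primer) at CDS offset 613 (0-based), inside exon 7; their CDS is 759 bp.
AG3 differs from AG2 at exactly 9 CDS positions, of which exactly 2
change the encoded amino acid — enforced by construction (seven edits at
third positions of four-fold-degenerate codons, two first-position edits
verified to change the residue) and re-verified by translation in the
tests. Exons are CDS-exons: UTRs are not modelled because every
published length refers to the start-to-stop region.

The marker geometry deserves a note. The published rule takes the 15-mer
as the forward primer and "20 bp before the termination site" as the
reverse primer, with a 146-bp product. The reverse-primer binding site
(revcomp of `TTACACTAATTGGAGGGCCA`) itself ends in TAA. Placing that
site strictly *before* the stop codon would put an in-frame TAA three
codons from the end — an internal stop — and would make the full-length
AG primer pair produce 756 bp instead of its catalogued 759. We
therefore read the rule inclusively: the reverse-primer site is the
**terminal 20 bp of the CDS and its final TAA is the stop codon**. With
the insertion at offset 613 the product runs to the CDS end:
759 − 613 = 146 bp, and the full-length AG pair amplifies exactly
759 bp from male cDNA. `design_presence_marker` implements the same
inclusive rule (revcomp of the last 20 CDS bp), which reproduces the
published reverse primer verbatim.

**RAN1 locus.** Nine CDS-exons (250, 650, 400, 800, 500, 150, 120, 90,
55 bp) concatenate to 3015 bp. Four primer windows are embedded wholly
inside single exons so the same product sizes arise from genomic DNA
and cDNA: the 608-bp RAN1-Marker in exon 2, the 371-bp 1-SNP and the
766-bp 6SNP-2 / 156-bp qPCR windows (exon 3 and 4), and the 444-bp
2-SNP window in exon 5. The qPCR reverse primer shares 16 bases with
the 6SNP-2 reverse primer, so one 25-bp segment realises both sites —
a property of the published oligo sequences, not an invention. The
full-length FcRAN1 primer pair spans the CDS (3015 bp from cDNA).

**SNP catalogue.** Fifteen labelled sites; 12 discriminating, 3 invalid
(seq000259_9823, _9855, _10377). Six discriminating sites fall inside
the marker window, and the four amplicons partition the catalogue
6 + 1 + 6 + 2. Only 14 distinct labels are published (seq000259_12722
appears in both the missense and synonymous lists); we keep 12722 as a
single missense site by default (a `snp12722_effect` switch flips it)
and complete the catalogue with one synthetic label,
`seq000259_12800` (synonymous, discriminating). Labels are identifiers
only: the published scaffold offsets cannot be reconciled with a 608-bp
window (the valid labels span far more than 608 bp), so each label maps
to a generator-chosen CDS offset. Effects are real: a synonymous site
occupies the third position of a four-fold codon, a missense site the
first position of a codon pair verified to change the residue; the
tests re-derive every effect by translating the female and
male-haplotype CDS.

**Panels.** The cultivar panel holds 27 males and 24 females. Males
carry the conserved female AG allele plus both male alleles and show the
heterozygote IUPAC code at all 15 RAN1 sites (the cloned male haplotype
is variant everywhere); females are homozygous everywhere and carry no
male allele. At each invalid site, 1–3 seeded males are made homozygous
and 1–3 seeded females heterozygous, which is what "not sex-specific"
means operationally. F1 families model the female (ga/ga) x male
(GA/ga) cross: a seedling inherits the male haplotype (one of the two
male AG alleles, chosen per seedling, plus heterozygosity at the 12
discriminating sites) with probability 0.5, or in the exact
(female, male) split when fixture counts (110, 132) and (49, 36) are
requested. Invalid-site noise is not modelled inside F1 families. A
350-bp actin locus with a 250-bp amplicon serves as the positive
control in every sample.

**What is not emulated** — and hence what passing tests do not show
about real data: chromatogram traces and base-calling error,
recombination inside the sex-linked region, population polymorphism
beyond the modelled sites, paralogous off-target priming, and PCR
chemistry (melting temperatures, dimers). The generator proves the
pipeline's logic, not the wet-lab robustness of the assays.

## In-silico PCR

A primer base matches a template base when their IUPAC sets intersect;
this is deliberately permissive on the template side so markers amplify
heterozygous consensus sequences (primer C anneals to template Y).
Matching is compiled to character-class regexes (overlap-safe via
lookahead). `amplify` enumerates every (plus-strand hit, downstream
minus-strand hit) combination of the pair in both orientations up to
`max_len` (default 5000 bp), so the output is symmetric under
reverse-complementing the template and is exhaustive rather than
"shortest product only" — fixtures guarantee uniqueness instead.
Mismatch tolerance defaults to 0 (the reproduced results are clean
presence/absence); an optional 3'-anchor mode forbids mismatches in the
last three bases. Restriction scanning reports plus-strand motif hits,
flagging hits that exist only on one haplotype of an ambiguous consensus
as conditional; PciI (A^CATGT) and HpyCH4IV (A^CGT) are the catalogued
CAPS enzymes.

## Alignment and structure

`global_align` is affine-gap global alignment (match +2, mismatch −3,
gap open −5, gap extend −2 per base), backed by Bio.Align's Gotoh
implementation; the defaults make one contiguous 15-bp gap strongly
preferable to scattered gaps, which is what resolves the male/female
difference as a single clean indel. Ties are broken by taking the
aligner's first optimal alignment, a fixed deterministic order; all
fixture-level results have unique optima. The test suite cross-checks
the optimal score against an independent pure-Python affine DP on 1000
random pairs up to 12 bp. `diff_alignment` merges maximal gap runs into
single indels and reports substitutions in both coordinate frames.

`splice_map` recovers CDS-exon structure by greedy longest-exon-first
matching with backtracking over candidate GT..AG introns (minimum
60 bp, 15-bp anchor for intron-end candidates). The generator patches
exon-start bases so they cannot extend into an intron's GT, making the
mapping's answer unique on every fixture; mapping failure raises,
which is the in-silico signature of an assembly inconsistency. Exact
matching only: fixtures are error-free, and a mismatch-tolerant mode is
out of scope.

## Screening and calling rules

The SNP screen is strict universality, matching the all-or-nothing
published verdicts: discriminating iff every male is heterozygous and
every female homozygous at the site; one exception invalidates it (a
tolerance knob exists, default 0). Screening a single-sex panel warns
that the empty class is vacuously satisfied. The presence caller
requires the actin control to amplify before a female (absence-of-band)
call — the original assay implies but never states this control, so it
is an explicit assumption and can be disabled. Mixed RAN1 zygosity
yields "ambiguous", not a majority vote; consensus between markers is
unanimity, with failures abstaining rather than vetoing.

## Statistics

Sex ratios are formatted "1:x" with x = males/females to two
significant figures, trailing zeros stripped — the only simple rule
that reproduces both published strings (1:1.2 and 1:0.73). The 1:1
goodness-of-fit is a df=1 chi-square without continuity correction
(Yates optional); p-values come from the chi-square survival function.
A vectorised Monte-Carlo check confirms the test rejects ~5% of
Bernoulli(0.5) populations of n=242 at alpha=0.05. The 2^-ddCt helper
normalises Ct values to a reference gene and calibrator sample; the
calibrator reports 1.0 by construction.

## Numerical and design choices

* Coordinates 0-based half-open internally, 1-based inclusive in GFF3.
* All randomness flows through named, seeded substreams
  (numpy `SeedSequence`); generation retries with a perturbed substream
  (up to 25 attempts) if a random background happens to collide with a
  primer site, and an exhaustive scan of all 18 catalogued primers over
  all generated sequences verifies that every hit is at its intended
  location — silent constraint violation is never allowed.
* Problem sizes in the tests are the study's own: 51 cultivars, F1
  families of 242 and 85, 1000 alignment oracle pairs, 2000 simulated
  populations. The full suite runs in a few seconds.

## Known limitations

* SNP label offsets are synthetic by construction (see above); any
  analysis that depended on true scaffold coordinates would not
  transfer.
* The alignment tie-break differs from a substitution-preferred policy
  some tools use; only degenerate-optimum inputs could notice.
* Heterozygous indel carriers are not representable in a single IUPAC
  consensus; indel discovery therefore assumes clean per-haplotype
  sequences, which the fixtures provide.
* `concordance` cannot estimate recombination between the two markers:
  the fixtures are fully concordant, so discordance is unidentifiable.
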