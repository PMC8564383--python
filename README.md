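# figmark

PCR-based early sex identification for fig (*Ficus carica*), as a tested,
fully in-silico pipeline.

Fig is gynodioecious: female trees bear the commercial fruit, while
"male" trees (caprifigs) carry stamens and gall flowers. Seedlings take
years to flower, so breeders want a DNA marker that calls sex at the
seedling stage. Two sex-linked loci make this possible:

* **AGAMOUS (AG)** — male figs carry two extra *AG* alleles whose 759-bp
  coding sequence includes a 15-bp stretch in exon 7 that the conserved
  744-bp *FcAG* lacks. Using the 15-mer itself as a forward primer and
  the reverse complement of the terminal 20 bp of the CDS as the reverse
  primer gives a presence/absence (SCAR-style) marker: a 146-bp band in
  males, nothing in females (the **AG-Marker**).
* **RAN1 (HMA7)** — the sex-determining candidate region carries 15
  labelled SNP sites in the 3015-bp, 9-exon *FcRAN1* CDS. Twelve of them
  are sex-discriminating: heterozygous double-base peaks (IUPAC ambiguity
  codes in a Sanger consensus) tag the males, a single homozygous base
  the females. Six of the twelve sit inside one 608-bp exon-2 amplicon,
  the **RAN1-Marker**, which works on both genomic DNA and cDNA.

`figmark` builds seeded synthetic versions of these loci and panels with
exactly the documented structure (the generator is first-class, tested
code), then rediscovers everything downstream from scratch: it aligns
female against male coding sequences to find the diagnostic indel,
derives the marker primers by the published rule, screens the SNP
catalogue over a 51-cultivar panel, calls sex on two F1 populations with
both markers, and checks segregation against the 1:1 Mendelian
expectation of the female (ga/ga) x male (GA/ga) cross with a df=1
chi-square.

## Worked example

```python
from figmark import forge
from figmark.primers import default_primer_pairs
from figmark.screen import find_diagnostic_indels, design_presence_marker, screen_snp_sites
from figmark.call import call_panel
from figmark.stats import tally_population, concordance

pairs = {p.name: p for p in default_primer_pairs()}
ag = forge.build_ag_models(seed=1)
ran1 = forge.build_ran1_model(seed=1)
panel = forge.build_cultivar_panel(seed=1)          # 27 male + 24 female

indel = find_diagnostic_indels(panel, "AG")[0]
marker = design_presence_marker(indel, ag["male_ag2"])
verdicts = screen_snp_sites(panel, ran1["sites"])

pop1 = forge.build_f1_population(seed=1, fixed_counts=(110, 132), population="pop1")
calls = call_panel(pop1, marker, pairs["RAN1-Marker"], ran1["sites"],
                   control=pairs["Actin"])
summary = tally_population(calls["AG"], population="pop1")
frac, _ = concordance(calls["AG"], calls["RAN1"])
```

This prints (via the example script in the docstrings):

```
diagnostic indel: CAGGAGGAGGAAGCT (15 bp, male-specific)
designed marker: F=CAGGAGGAGGAAGCT R=TTACACTAATTGGAGGGCCA expected 146 bp
SNP screen: 12/15 discriminating; invalid: seq000259_10377, seq000259_9823, seq000259_9855
pop1: 110 female / 132 male (ratio 1:1.2), chi2 vs 1:1 = 2.00 (p = 0.157); AG/RAN1 concordance = 1.00
```

Reading it: the screen rediscovered the 15-bp male-specific insertion
and turned it into the AG-Marker primer pair with its 146-bp product;
12 of the 15 RAN1 SNPs discriminate sex over the cultivar panel (the
three known non-sex-specific sites are rejected with named
counterexamples); both markers call all 242 seedlings of population 1
identically, the sex ratio formats as 1:1.2, and the chi-square of 2.0
(p ≈ 0.16) does not reject 1:1 segregation.

## Command line

```sh
figmark forge --seed 1 --out fixtures/          # write panels + models (FASTA/GFF3/TSV)
figmark amplify --fasta fixtures/cultivars/genes.fasta --pair AG-Marker --out amps.tsv
figmark screen --panel fixtures/cultivars --out verdicts.tsv
figmark call --panel fixtures/pop1 --out calls.tsv
figmark report --calls calls.tsv --out report.json
```

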