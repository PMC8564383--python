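"""Deterministic synthetic fig loci and plant panels.

This module fabricates the two sex-linked loci of *Ficus carica* with the
documented structure, so every downstream stage (alignment, marker
discovery, in-silico PCR, sex calling, segregation statistics) can
rediscover the published features from first principles:

* a female *AG* (AGAMOUS) gene: 5230 bp, 7 CDS-exons, 744-bp CDS;
* two male-specific *AG* alleles (AG2/AG3): 759-bp CDS carrying a 15-bp
  insertion in exon 7 whose sequence is the AG-Marker forward primer,
  differing from each other at 9 CDS positions (2 amino-acid changes);
* a *RAN1* (HMA7 copper-transporting ATPase) gene: 9 CDS-exons, 3015-bp
  CDS, carrying 15 labelled SNP sites of which 12 are sex-discriminating
  and 3 (seq000259_9823/_9855/_10377) are invalid, with 6 discriminating
  sites inside a 608-bp exon-2 amplicon (the RAN1-Marker);
* a small actin locus providing the 250-bp positive-control amplicon.

Only 14 distinct SNP labels are published (seq000259_12722 is listed as
both missense and synonymous); the generator treats 12722 as a single
missense site by default (switchable) and adds one synthetic label,
``seq000259_12800`` (synonymous, discriminating), to complete the
15/12/3 accounting.  SNP labels are identifiers, not coordinates: each
is mapped to a generator-chosen CDS offset.

All randomness flows from a single integer seed through named
substreams, so identical seeds give byte-identical fixtures.  Hard
layout facts (exon sizes, primer placements, SNP offsets) are constants;
randomness only fills background sequence, intron lengths, panel
shuffles and which panel individuals violate the invalid SNP sites.
"""
from __future__ import annotations

import functools
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import reverse_complement

from . import io as fio
from .models import (
    ConstraintError,
    GeneModel,
    HET_CODES,
    Panel,
    Sample,
    SnpSite,
    STOP_CODONS,
    het_code_for,
)
from .pcr import find_primer_sites
from .primers import default_primer_pairs, primer_by_name

# ---------------------------------------------------------------------------
# layout constants (lengths in bp, coordinates 0-based in the CDS)

AG_FEMALE_CDS_LEN = 744
AG_MALE_CDS_LEN = 759
AG_FEMALE_GENE_LEN = 5230
AG_EXON_LENS = (110, 120, 90, 100, 95, 79, 150)        # female CDS-exons
AG_MARKER_INSERTION = "CAGGAGGAGGAAGCT"                 # AG-Marker-F, exon 7
AG_INSERTION_CDS_POS = 613                              # insert before this female offset
#: concrete expansion of the degenerate AG-F primer used as the CDS start
AG_START_EMBED = "ATGGCGTACCAAAACAAGGAGAAGA"
#: concrete expansion of revcomp(AG-R); its final 20 bp are
#: revcomp(AG-Marker-R) and its last codon is the stop codon
AG_END_EMBED = "TTCCATGGCCCTCCAATTAGTGTAA"
AG_N_DIFFS = 9                                          # AG2 vs AG3
AG_N_MISSENSE_DIFFS = 2

RAN1_CDS_LEN = 3015
RAN1_EXON_LENS = (250, 650, 400, 800, 500, 150, 120, 90, 55)
RAN1_MARKER_WINDOW_CDS = (270, 878)     # 608 bp, inside exon 2
RAN1_1SNP_WINDOW_CDS = (911, 1282)      # 371 bp, inside exon 3
RAN1_6SNP2_WINDOW_CDS = (1310, 2076)    # 766 bp, inside exon 4
RAN1_QPCR_WINDOW_CDS = (1915, 2071)     # 156 bp, inside exon 4
RAN1_2SNP_WINDOW_CDS = (2103, 2547)     # 444 bp, inside exon 5

INVALID_SITE_LABELS = ("seq000259_9823", "seq000259_9855", "seq000259_10377")
SYNTHETIC_SITE_LABEL = "seq000259_12800"  # completes the 15-site catalogue

#: (label, default CDS offset, effect, validity); offsets chosen so a
#: synonymous site sits at a third codon position and a missense site at
#: a first codon position, in regions free of primer footprints.
RAN1_SITE_LAYOUT: Tuple[Tuple[str, int, str, str], ...] = (
    ("seq000259_10431", 320, "synonymous", "discriminating"),
    ("seq000259_11760", 401, "synonymous", "discriminating"),
    ("seq000259_12314", 480, "missense", "discriminating"),
    ("seq000259_12388", 560, "synonymous", "discriminating"),
    ("seq000259_12646", 701, "synonymous", "discriminating"),
    ("seq000259_12722", 801, "missense", "discriminating"),
    ("seq000259_10377", 1100, "synonymous", "invalid"),
    ("seq000259_8998", 1400, "synonymous", "discriminating"),
    ("seq000259_9166", 1502, "synonymous", "discriminating"),
    ("seq000259_9823", 1601, "synonymous", "invalid"),
    ("seq000259_9855", 1701, "missense", "invalid"),
    ("seq000259_9876", 1800, "missense", "discriminating"),
    ("seq000259_9900", 1902, "missense", "discriminating"),
    ("seq000259_12743", 2202, "missense", "discriminating"),
    (SYNTHETIC_SITE_LABEL, 2300, "synonymous", "discriminating"),
)

ACTIN_LOCUS_LEN = 350
ACTIN_F_POS = 50
ACTIN_PRODUCT_LEN = 250

AG_LOCUS, RAN1_LOCUS, ACTIN_LOCUS = "AG", "RAN1", "ACT"

MIN_INTRON = 60

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_FOURFOLD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
#: (female codon, alternative first base) pairs, all missense, no stops
_MISSENSE_CODON_OPTIONS = (
    ("GAA", "A"), ("AAA", "G"), ("CGT", "G"), ("GGT", "C"), ("CTG", "A"), ("GAC", "C"),
)


def _rng(seed: int, tag: str, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(tag.encode()), attempt])
    )


def _random_codons(rng: np.random.Generator, n_codons: int) -> List[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return list("".join(_NONSTOP_CODONS[i] for i in idx))


def _embed(seq: List[str], mask: List[bool], pos: int, text: str) -> None:
    for i, ch in enumerate(text):
        seq[pos + i] = ch
        mask[pos + i] = True


def _fix_internal_stops(seq: List[str], mask: List[bool]) -> None:
    """Rewrite one free base of every internal stop codon to C (no stop
    codon contains a C, so this always resolves it)."""
    for i in range(0, len(seq) - 3, 3):
        if "".join(seq[i: i + 3]) in STOP_CODONS:
            for j in range(i, i + 3):
                if not mask[j]:
                    seq[j] = "C"
                    break
            else:
                raise ConstraintError(f"stop codon locked by embeds at CDS {i}")


def _avoid_g(seq: List[str], mask: List[bool], pos: int) -> None:
    """Force a non-G base at an exon-start position so spliced mapping
    cannot extend the previous exon into the GT intron start."""
    if seq[pos] != "G":
        return
    if mask[pos]:
        raise ConstraintError(f"exon-start position {pos} locked to G by an embed")
    codon_start = pos - pos % 3
    for base in "ACT":
        seq[pos] = base
        if "".join(seq[codon_start: codon_start + 3]) not in STOP_CODONS:
            return
    raise ConstraintError(f"cannot patch exon-start base at {pos}")


def _exon_intervals(exon_lens: Sequence[int], intron_lens: Sequence[int]) -> Tuple[Tuple[int, int], ...]:
    out, g = [], 0
    for i, L in enumerate(exon_lens):
        out.append((g, g + L))
        g += L
        if i < len(intron_lens):
            g += intron_lens[i]
    return tuple(out)


def _assemble_genomic(cds: str, exon_lens: Sequence[int], intron_seqs: Sequence[str]) -> str:
    parts, c = [], 0
    for i, L in enumerate(exon_lens):
        parts.append(cds[c: c + L])
        c += L
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
    return "".join(parts)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length - 4))
    return "GT" + body + "AG"


# ---------------------------------------------------------------------------
# AG locus


def _build_ag(seed: int, attempt: int) -> Dict[str, GeneModel]:
    rng = _rng(seed, "ag", attempt)
    cds = _random_codons(rng, AG_FEMALE_CDS_LEN // 3)
    mask = [False] * AG_FEMALE_CDS_LEN
    _embed(cds, mask, 0, AG_START_EMBED)
    _embed(cds, mask, AG_FEMALE_CDS_LEN - len(AG_END_EMBED), AG_END_EMBED)
    # the two bases after the insertion point must not turn the T that
    # ends the inserted 15-mer into a stop codon in the male frame
    if "".join(cds[613:615]) in ("AA", "AG", "GA"):
        cds[613] = "C"
    starts = np.cumsum((0,) + AG_EXON_LENS[:-1])
    for pos in starts[1:]:
        _avoid_g(cds, mask, int(pos))
    _fix_internal_stops(cds, mask)
    female_cds = "".join(cds)

    male_cds = (
        female_cds[:AG_INSERTION_CDS_POS]
        + AG_MARKER_INSERTION
        + female_cds[AG_INSERTION_CDS_POS:]
    )

    # AG3 = AG2 with 9 substitutions, exactly 2 of them missense
    ag3 = list(male_cds)
    codon_pool = list(range(14, 200))
    rng.shuffle(codon_pool)
    syn_done = mis_done = 0
    used = []
    for ci in codon_pool:
        if syn_done == AG_N_DIFFS - AG_N_MISSENSE_DIFFS and mis_done == AG_N_MISSENSE_DIFFS:
            break
        codon = male_cds[ci * 3: ci * 3 + 3]
        if syn_done < AG_N_DIFFS - AG_N_MISSENSE_DIFFS and codon[:2] in _FOURFOLD_PREFIXES:
            alt = "ACGT"[(("ACGT".index(codon[2])) + 1 + int(rng.integers(0, 3))) % 4]
            if alt != codon[2]:
                ag3[ci * 3 + 2] = alt
                syn_done += 1
                used.append(ci)
                continue
        if mis_done < AG_N_MISSENSE_DIFFS:
            from .align import translate as _tr
            for alt in "ACG":
                if alt == codon[0]:
                    continue
                new = alt + codon[1:]
                if new in STOP_CODONS:
                    continue
                if _tr(new + "TAA") != _tr(codon + "TAA"):
                    ag3[ci * 3] = alt
                    mis_done += 1
                    used.append(ci)
                    break
    if syn_done + mis_done != AG_N_DIFFS:
        raise ConstraintError("could not place the 9 AG2/AG3 differences")
    ag3_cds = "".join(ag3)

    total_intron = AG_FEMALE_GENE_LEN - AG_FEMALE_CDS_LEN
    extra = rng.multinomial(total_intron - 6 * MIN_INTRON, [1 / 6] * 6)
    intron_lens = [MIN_INTRON + int(e) for e in extra]
    introns = [_random_intron(rng, L) for L in intron_lens]

    male_exon_lens = AG_EXON_LENS[:-1] + (AG_EXON_LENS[-1] + 15,)
    female = GeneModel(
        name="FcAG_female",
        genomic_seq=_assemble_genomic(female_cds, AG_EXON_LENS, introns),
        exons=_exon_intervals(AG_EXON_LENS, intron_lens),
        cds_seq=female_cds,
    )
    male2 = GeneModel(
        name="FcAG2_male",
        genomic_seq=_assemble_genomic(male_cds, male_exon_lens, introns),
        exons=_exon_intervals(male_exon_lens, intron_lens),
        cds_seq=male_cds,
    )
    male3 = GeneModel(
        name="FcAG3_male",
        genomic_seq=_assemble_genomic(ag3_cds, male_exon_lens, introns),
        exons=_exon_intervals(male_exon_lens, intron_lens),
        cds_seq=ag3_cds,
    )
    return {"female": female, "male_ag2": male2, "male_ag3": male3}


# ---------------------------------------------------------------------------
# RAN1 locus


def _build_ran1(seed: int, attempt: int, snp12722_effect: str) -> Dict[str, object]:
    rng = _rng(seed, "ran1", attempt)
    cds = _random_codons(rng, RAN1_CDS_LEN // 3)
    mask = [False] * RAN1_CDS_LEN

    rc = reverse_complement
    p = primer_by_name
    qpcr_r_site = rc(p("qPCR-R").seq)
    snp6_r_site = rc(p("6SNP-2-R").seq)
    assert qpcr_r_site[4:] == snp6_r_site[:16]  # published primers overlap
    merged_tail = qpcr_r_site + snp6_r_site[16:]

    _embed(cds, mask, 0, p("FcRAN1-F").seq)
    _embed(cds, mask, RAN1_MARKER_WINDOW_CDS[0], p("RAN1-Marker-F").seq)
    _embed(cds, mask, RAN1_MARKER_WINDOW_CDS[1] - 22, rc(p("RAN1-Marker-R").seq))
    _embed(cds, mask, RAN1_1SNP_WINDOW_CDS[0], p("1-SNP-F").seq)
    _embed(cds, mask, RAN1_1SNP_WINDOW_CDS[1] - 20, rc(p("1-SNP-R").seq))
    _embed(cds, mask, RAN1_6SNP2_WINDOW_CDS[0], p("6SNP-2-F").seq)
    _embed(cds, mask, RAN1_QPCR_WINDOW_CDS[0], p("qPCR-F").seq)
    _embed(cds, mask, RAN1_QPCR_WINDOW_CDS[1] - 20, merged_tail)
    _embed(cds, mask, RAN1_2SNP_WINDOW_CDS[0], p("2-SNP-F").seq)
    _embed(cds, mask, RAN1_2SNP_WINDOW_CDS[1] - 21, rc(p("2-SNP-R").seq))
    _embed(cds, mask, RAN1_CDS_LEN - 25, rc(p("FcRAN1-R").seq))

    if "".join(cds[1260:1262]) == "TA":  # would form TAG with the 1-SNP-R site
        cds[1260] = "C"
    starts = np.cumsum((0,) + RAN1_EXON_LENS[:-1])
    for pos in starts[1:]:
        _avoid_g(cds, mask, int(pos))
    _fix_internal_stops(cds, mask)

    # plant the SNP codons
    from .align import translate as _tr
    site_defs = []
    for label, pos, effect, validity in RAN1_SITE_LAYOUT:
        if label == "seq000259_12722" and snp12722_effect == "synonymous":
            effect, pos = "synonymous", 803  # shift to a third codon position
        if effect == "synonymous":
            codon_start = pos - 2
            assert pos % 3 == 2
            prefix = _FOURFOLD_PREFIXES[int(rng.integers(0, len(_FOURFOLD_PREFIXES)))]
            female_base = "ACGT"[int(rng.integers(0, 4))]
            codon = prefix + female_base
            alt = "ACGT"[("ACGT".index(female_base) + 1 + int(rng.integers(0, 3))) % 4]
        else:
            codon_start = pos
            assert pos % 3 == 0
            codon, alt = _MISSENSE_CODON_OPTIONS[int(rng.integers(0, len(_MISSENSE_CODON_OPTIONS)))]
            female_base = codon[0]
        if any(mask[codon_start + k] for k in range(3)):
            raise ConstraintError(f"SNP codon for {label} overlaps a primer footprint")
        for k in range(3):
            cds[codon_start + k] = codon[k]
            mask[codon_start + k] = True
        site_defs.append((label, pos, female_base, alt, effect, validity))

    female_cds = "".join(cds)
    male_cds = list(female_cds)
    for _, pos, _, alt, _, _ in site_defs:
        male_cds[pos] = alt
    male_cds = "".join(male_cds)
    n_missense = sum(
        1 for a, b in zip(_tr(female_cds), _tr(male_cds)) if a != b
    )
    declared = sum(1 for d in site_defs if d[4] == "missense")
    if n_missense != declared:
        raise ConstraintError("RAN1 SNP effects do not verify under translation")

    intron_lens = [int(x) for x in rng.integers(MIN_INTRON, 121, size=8)]
    introns = [_random_intron(rng, L) for L in intron_lens]
    gene = GeneModel(
        name="FcRAN1",
        genomic_seq=_assemble_genomic(female_cds, RAN1_EXON_LENS, introns),
        exons=_exon_intervals(RAN1_EXON_LENS, intron_lens),
        cds_seq=female_cds,
    )
    sites = tuple(
        SnpSite(
            label=label,
            genomic_pos=gene.cds_to_genomic(pos),
            female_base=female_base,
            male_alt_base=alt,
            het_code=het_code_for(female_base, alt),
            validity=validity,
            effect=effect,
            cds_pos=pos,
        )
        for label, pos, female_base, alt, effect, validity in site_defs
    )
    sites = tuple(sorted(sites, key=lambda s: s.genomic_pos))
    window = (
        gene.cds_to_genomic(RAN1_MARKER_WINDOW_CDS[0]),
        gene.cds_to_genomic(RAN1_MARKER_WINDOW_CDS[1] - 1) + 1,
    )
    return {"gene": gene, "sites": sites, "marker_window": window, "male_cds": male_cds}


def _build_actin(seed: int, attempt: int) -> str:
    rng = _rng(seed, "actin", attempt)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=ACTIN_LOCUS_LEN)))
    mask = [False] * ACTIN_LOCUS_LEN
    f = primer_by_name("Actin-F")
    r = primer_by_name("Actin-R")
    _embed(seq, mask, ACTIN_F_POS, f.seq)
    _embed(seq, mask, ACTIN_F_POS + ACTIN_PRODUCT_LEN - len(r.seq), reverse_complement(r.seq))
    return "".join(seq)


# ---------------------------------------------------------------------------
# joint build with primer-uniqueness validation


def _intended_hits(models: Dict[str, object]) -> Dict[str, Dict[str, set]]:
    """Expected (position, strand) primer sites per generated sequence."""
    ag_f, ag2, ag3 = models["female"], models["male_ag2"], models["male_ag3"]
    ran1 = models["ran1"]["gene"]

    def g(model, cds_pos):
        return model.cds_to_genomic(cds_pos)

    female_hits = {
        "AG-F": {(0, "+")},
        "AG-R": {(g(ag_f, 719), "-")},
        "AG-Marker-R": {(g(ag_f, 724), "-")},
    }
    male_hits = {
        "AG-F": {(0, "+")},
        "AG-Marker-F": {(g(ag2, AG_INSERTION_CDS_POS), "+")},
        "AG-R": {(g(ag2, 734), "-")},
        "AG-Marker-R": {(g(ag2, 739), "-")},
    }
    ran1_hits = {
        "FcRAN1-F": {(0, "+")},
        "RAN1-Marker-F": {(g(ran1, RAN1_MARKER_WINDOW_CDS[0]), "+")},
        "RAN1-Marker-R": {(g(ran1, RAN1_MARKER_WINDOW_CDS[1] - 22), "-")},
        "1-SNP-F": {(g(ran1, RAN1_1SNP_WINDOW_CDS[0]), "+")},
        "1-SNP-R": {(g(ran1, RAN1_1SNP_WINDOW_CDS[1] - 20), "-")},
        "6SNP-2-F": {(g(ran1, RAN1_6SNP2_WINDOW_CDS[0]), "+")},
        "qPCR-F": {(g(ran1, RAN1_QPCR_WINDOW_CDS[0]), "+")},
        "qPCR-R": {(g(ran1, RAN1_QPCR_WINDOW_CDS[1] - 20), "-")},
        "6SNP-2-R": {(g(ran1, RAN1_6SNP2_WINDOW_CDS[1] - 21), "-")},
        "2-SNP-F": {(g(ran1, RAN1_2SNP_WINDOW_CDS[0]), "+")},
        "2-SNP-R": {(g(ran1, RAN1_2SNP_WINDOW_CDS[1] - 21), "-")},
        "FcRAN1-R": {(g(ran1, RAN1_CDS_LEN - 25), "-")},
    }
    actin_hits = {
        "Actin-F": {(ACTIN_F_POS, "+")},
        "Actin-R": {(ACTIN_F_POS + ACTIN_PRODUCT_LEN - 21, "-")},
    }
    return {
        ag_f.name: female_hits,
        ag2.name: male_hits,
        ag3.name: male_hits,
        "FcRAN1": ran1_hits,
        "Actin": actin_hits,
    }


def validate_primer_uniqueness(sequences: Dict[str, str], intended: Dict[str, Dict[str, set]]) -> None:
    """Exhaustively scan every catalogued primer against every sequence and
    raise if any hit is not at its intended location."""
    primers = {}
    for pair in default_primer_pairs():
        primers[pair.forward.name] = pair.forward
        primers[pair.reverse.name] = pair.reverse
    for seq_name, seq in sequences.items():
        expected_for_seq = intended.get(seq_name, {})
        for pname, primer in primers.items():
            hits = {(h.position, h.strand) for h in find_primer_sites(seq, primer)}
            expected = expected_for_seq.get(pname, set())
            if hits != expected:
                raise ConstraintError(
                    f"primer {pname} on {seq_name}: found {sorted(hits)}, intended {sorted(expected)}"
                )


@functools.lru_cache(maxsize=8)
def _build_all(seed: int, snp12722_effect: str = "missense") -> Dict[str, object]:
    last_err: Optional[Exception] = None
    for attempt in range(25):
        try:
            ag = _build_ag(seed, attempt)
            ran1 = _build_ran1(seed, attempt, snp12722_effect)
            actin = _build_actin(seed, attempt)
            models = {**ag, "ran1": ran1, "actin": actin}
            seqs = {
                ag["female"].name: ag["female"].genomic_seq,
                ag["male_ag2"].name: ag["male_ag2"].genomic_seq,
                ag["male_ag3"].name: ag["male_ag3"].genomic_seq,
                "FcRAN1": ran1["gene"].genomic_seq,
                "Actin": actin,
            }
            validate_primer_uniqueness(seqs, _intended_hits(models))
            return models
        except ConstraintError as err:  # collision with random background: redraw
            last_err = err
    raise ConstraintError(f"could not satisfy locus constraints after 25 attempts: {last_err}")


def build_ag_models(seed: int) -> Dict[str, GeneModel]:
    """Female *FcAG* plus the two male-specific alleles (seeded)."""
    built = _build_all(seed)
    return {k: built[k] for k in ("female", "male_ag2", "male_ag3")}


def build_ran1_model(seed: int, snp12722_effect: str = "missense") -> Dict[str, object]:
    """The *FcRAN1* gene model, its 15 labelled SNP sites, and the
    genomic interval of the 608-bp RAN1-Marker amplicon."""
    built = _build_all(seed, snp12722_effect)
    r = built["ran1"]
    return {"gene": r["gene"], "sites": list(r["sites"]), "marker_window": r["marker_window"]}


def build_actin_locus(seed: int) -> str:
    return _build_all(seed)["actin"]


# ---------------------------------------------------------------------------
# panels


def _het_consensus(base_seq: str, sites: Iterable[SnpSite], het_at: Iterable[str]) -> str:
    """RAN1 consensus with the heterozygote code at the given labels."""
    het_at = set(het_at)
    out = list(base_seq)
    for s in sites:
        if s.label in het_at:
            out[s.genomic_pos] = s.het_code
    return "".join(out)


def _make_sample(
    sample_id: str,
    sex: str,
    models: Dict[str, object],
    population: str,
    ran1_consensus: str,
    male_ag_alleles: Tuple[str, ...] = ("male_ag2", "male_ag3"),
) -> Sample:
    ag_seqs = [models["female"].genomic_seq]
    if sex == "male":
        ag_seqs += [models[k].genomic_seq for k in male_ag_alleles]
    return Sample(
        sample_id=sample_id,
        true_sex=sex,
        locus_seqs={
            AG_LOCUS: tuple(ag_seqs),
            RAN1_LOCUS: (ran1_consensus,),
            ACTIN_LOCUS: (models["actin"],),
        },
        population=population,
    )


def build_cultivar_panel(n_male: int = 27, n_female: int = 24, seed: int = 1) -> Panel:
    """The known-sex cultivar survey: every male heterozygous at all 12
    discriminating RAN1 sites and carrying both male AG alleles; at each
    invalid site at least one cultivar of each sex violates the
    het-male/hom-female rule."""
    models = _build_all(seed)
    sites: Tuple[SnpSite, ...] = models["ran1"]["sites"]
    base = models["ran1"]["gene"].genomic_seq
    disc = [s.label for s in sites if s.validity == "discriminating"]
    invalid = [s for s in sites if s.validity == "invalid"]

    rng = _rng(seed, "cultivars")
    # default zygosity: males het everywhere (incl. invalid sites, as in
    # the cloned male haplotype), females hom everywhere
    male_het: Dict[int, set] = {i: set(s.label for s in sites) for i in range(n_male)}
    female_het: Dict[int, set] = {i: set() for i in range(n_female)}
    for s in invalid:
        k_m = int(rng.integers(1, 4))
        k_f = int(rng.integers(1, 4))
        for i in rng.choice(n_male, size=k_m, replace=False):
            male_het[int(i)].discard(s.label)      # a homozygous male
        for i in rng.choice(n_female, size=k_f, replace=False):
            female_het[int(i)].add(s.label)        # a heterozygous female
    samples: List[Sample] = []
    for i in range(n_male):
        samples.append(
            _make_sample(
                f"CV-M{i + 1:02d}", "male", models, "cultivars",
                _het_consensus(base, sites, male_het[i]),
            )
        )
    for i in range(n_female):
        samples.append(
            _make_sample(
                f"CV-F{i + 1:02d}", "female", models, "cultivars",
                _het_consensus(base, sites, female_het[i]),
            )
        )
    order = rng.permutation(len(samples))
    return Panel(samples=[samples[int(i)] for i in order], name="cultivars")


def build_f1_population(
    n: Optional[int] = None,
    seed: int = 1,
    fixed_counts: Optional[Tuple[int, int]] = None,
    population: str = "F1",
) -> Panel:
    """An F1 family from a female (ga/ga) x male (GA/ga) cross: each
    seedling inherits the male haplotype with probability 0.5, or with
    the exact (n_female, n_male) split when ``fixed_counts`` is given."""
    models = _build_all(seed)
    sites: Tuple[SnpSite, ...] = models["ran1"]["sites"]
    base = models["ran1"]["gene"].genomic_seq
    disc = [s.label for s in sites if s.validity == "discriminating"]
    rng = _rng(seed, f"f1-{population}")

    if fixed_counts is not None:
        n_female, n_male = fixed_counts
        if n is not None and n_female + n_male != n:
            raise ValueError(f"fixed_counts {fixed_counts} do not sum to n={n}")
        sexes = ["female"] * n_female + ["male"] * n_male
        order = rng.permutation(len(sexes))
        sexes = [sexes[int(i)] for i in order]
    else:
        if n is None:
            raise ValueError("either n or fixed_counts is required")
        sexes = ["male" if b else "female" for b in rng.random(n) < 0.5]

    male_consensus = _het_consensus(base, sites, disc)
    samples = []
    for i, sex in enumerate(sexes):
        allele = ("male_ag2",) if rng.random() < 0.5 else ("male_ag3",)
        samples.append(
            _make_sample(
                f"{population}-{i + 1:03d}", sex, models, population,
                male_consensus if sex == "male" else base,
                male_ag_alleles=allele,
            )
        )
    return Panel(samples=samples, name=population)


# ---------------------------------------------------------------------------
# fixture I/O (delegates to figmark.io)


def write_fixtures(
    panel: Panel,
    outdir,
    seed: Optional[int] = None,
    models: Optional[Dict[str, object]] = None,
    sites: Optional[Sequence[SnpSite]] = None,
) -> None:
    """Write a panel (plus gene models and the SNP catalogue when given)
    as FASTA/GFF3/TSV/JSON; re-reading reproduces the panel exactly."""
    fio.write_panel(panel, outdir, seed=seed, models=models, sites=sites)


def read_fixtures(indir) -> Panel:
    return fio.read_panel(indir)
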