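"""Shared domain types for the fig sex-marker pipeline.

Coordinates are 0-based half-open everywhere in memory; report writers
convert to 1-based inclusive (GFF3) at the boundary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

DNA_ALPHABET = set("ACGT")
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
#: IUPAC code for each two-base heterozygote, e.g. {"A","G"} -> "R"
HET_CODES: Dict[frozenset, str] = {
    v: k for k, v in IUPAC_SETS.items() if len(v) == 2
}

STOP_CODONS = ("TAA", "TAG", "TGA")


class ConstraintError(RuntimeError):
    """A synthetic-locus constraint could not be satisfied."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as genomic sequence plus ordered CDS-exon intervals.

    Exons are CDS-exons: UTRs are not modelled, so concatenating the exon
    subsequences reproduces ``cds_seq`` exactly and the genomic sequence
    runs from the first base of the start codon to the last base of the
    stop codon.
    """

    name: str
    genomic_seq: str
    exons: Tuple[Tuple[int, int], ...]
    cds_seq: str
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.genomic_seq)):
                raise ValueError(f"exon [{s},{e}) outside genomic sequence")
            if s <= prev_end - 1 or s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if self.spliced_seq() != self.cds_seq:
            raise ValueError("exon concatenation does not equal cds_seq")
        if len(self.cds_seq) % 3:
            raise ValueError("CDS length not a multiple of 3")
        if not self.cds_seq.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if self.cds_seq[-3:] not in STOP_CODONS:
            raise ValueError("CDS does not end with a stop codon")

    def spliced_seq(self) -> str:
        return "".join(self.genomic_seq[s:e] for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a CDS offset to a genomic offset (plus strand)."""
        if not 0 <= cds_pos < len(self.cds_seq):
            raise IndexError(f"CDS position {cds_pos} out of range")
        off = cds_pos
        for s, e in self.exons:
            if off < e - s:
                return s + off
            off -= e - s
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class SnpSite:
    """A labelled SNP with the female base, the male-specific alternative
    and the IUPAC code a heterozygote shows in a Sanger consensus."""

    label: str
    genomic_pos: int
    female_base: str
    male_alt_base: str
    het_code: str
    validity: str  # "discriminating" | "invalid"
    effect: str    # "missense" | "synonymous"
    cds_pos: int = -1

    def __post_init__(self):
        pair = frozenset((self.female_base, self.male_alt_base))
        if len(pair) != 2 or not pair <= DNA_ALPHABET:
            raise ValueError(f"{self.label}: bases must be two distinct A/C/G/T")
        if HET_CODES[pair] != self.het_code:
            raise ValueError(
                f"{self.label}: het code {self.het_code} is not the IUPAC code for {sorted(pair)}"
            )
        if self.validity not in ("discriminating", "invalid"):
            raise ValueError(f"{self.label}: bad validity {self.validity!r}")
        if self.effect not in ("missense", "synonymous"):
            raise ValueError(f"{self.label}: bad effect {self.effect!r}")


@dataclass
class Sample:
    """One plant: per-locus sequences, heterozygosity as IUPAC consensus.

    ``locus_seqs`` maps a locus name to one or more sequences: separate
    haplotypes for the AG locus (male plants carry the conserved allele
    plus the male-specific allele(s)) and a single IUPAC consensus for
    RAN1 and the actin control.
    """

    sample_id: str
    true_sex: str  # "male" | "female" | "unknown"
    locus_seqs: Dict[str, Tuple[str, ...]]
    population: str = ""

    def consensus(self, locus: str) -> str:
        return self.locus_seqs[locus][0]


@dataclass
class Panel:
    """A labelled collection of samples (cultivar survey or F1 family)."""

    samples: List[Sample]
    name: str = "panel"

    @property
    def truth_table(self) -> Dict[str, str]:
        return {s.sample_id: s.true_sex for s in self.samples}

    def by_sex(self, sex: str) -> List[Sample]:
        return [s for s in self.samples if s.true_sex == sex]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.name}: empty primer sequence")
        for i, b in enumerate(self.seq):
            if b not in IUPAC_SETS:
                raise ValueError(f"{self.name}: invalid IUPAC character {b!r} at position {i}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.name}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: Primer
    reverse: Primer
    expected_length: Optional[int] = None

    def __post_init__(self):
        if self.forward.orientation != "forward" or self.reverse.orientation != "reverse":
            raise ValueError(f"{self.name}: pair must hold one forward and one reverse primer")
        if self.expected_length is not None and self.expected_length <= 0:
            raise ValueError(f"{self.name}: expected_length must be positive")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    product_seq: str
    fwd_site: Tuple[int, int]
    rev_site: Tuple[int, int]

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.length != len(self.product_seq):
            raise ValueError("amplicon length inconsistent with product sequence")


@dataclass(frozen=True)
class DiagnosticIndel:
    """An indel carried by every sample of one sex class and absent from
    every sample of the other."""

    sequence: str
    length: int
    present_in: str
    locus: str
    position: int  # offset in the reference of the class lacking the indel


@dataclass
class SiteVerdict:
    site_label: str
    verdict: str  # "discriminating" | "invalid"
    counterexamples: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if (self.verdict == "discriminating") != (len(self.counterexamples) == 0):
            raise ValueError("verdict inconsistent with counterexamples")


@dataclass
class SexCall:
    sample_id: str
    marker: str  # "AG" | "RAN1" | "consensus"
    call: str    # "male" | "female" | "ambiguous" | "failed"
    evidence: Dict[str, object] = field(default_factory=dict)


@dataclass
class PopulationSummary:
    population: str
    n_female: int
    n_male: int
    n_ambiguous: int
    n_failed: int
    ratio_text: str
    chi2: float
    p_value: float


def het_code_for(a: str, b: str) -> str:
    """IUPAC code for the unordered base pair {a, b}."""
    return HET_CODES[frozenset((a, b))]
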