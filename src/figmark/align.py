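"""Global alignment, variant extraction, spliced CDS-to-genome mapping
and translation.

``global_align`` wraps Bio.Align.PairwiseAligner in global mode with
affine gap costs.  A gap of length k costs ``gap_open + k * gap_extend``;
the defaults make one contiguous 15-bp gap strongly preferable to
scattered single-base gaps, which is what resolves the male/female AG
difference as a single clean indel.  Ties are broken by the aligner's
deterministic enumeration order (the first optimal alignment is taken),
so alignments are reproducible byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from Bio import Align
from Bio.Seq import Seq

from .models import GeneModel, STOP_CODONS

DEFAULT_SCORING: Dict[str, float] = {
    "match": 2.0,
    "mismatch": -3.0,
    "gap_open": -5.0,
    "gap_extend": -2.0,
}


@dataclass(frozen=True)
class Alignment:
    seq_a_gapped: str
    seq_b_gapped: str
    score: float

    def __post_init__(self):
        if len(self.seq_a_gapped) != len(self.seq_b_gapped):
            raise ValueError("gapped sequences differ in length")
        if any(a == b == "-" for a, b in zip(self.seq_a_gapped, self.seq_b_gapped)):
            raise ValueError("gap/gap column")

    @property
    def seq_a(self) -> str:
        return self.seq_a_gapped.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.seq_b_gapped.replace("-", "")


@dataclass
class VariantList:
    #: (a_pos, b_pos, a_base, b_base)
    substitutions: List[Tuple[int, int, str, str]] = field(default_factory=list)
    #: (pos_in_carrier, length, inserted_in {"a","b"}, sequence)
    indels: List[Tuple[int, int, str, str]] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    def is_empty(self) -> bool:
        return not self.substitutions and not self.indels


def _aligner(scoring: Optional[Dict[str, float]]) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = s["match"]
    al.mismatch_score = s["mismatch"]
    # biopython charges open_gap_score for the first gap base and
    # extend_gap_score for each further base; our convention charges
    # gap_open once plus gap_extend per base.
    al.open_gap_score = s["gap_open"] + s["gap_extend"]
    al.extend_gap_score = s["gap_extend"]
    return al


def global_align(a: str, b: str, scoring: Optional[Dict[str, float]] = None) -> Alignment:
    """Optimal global alignment of two DNA sequences under affine gaps."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(scoring).align(a.upper(), b.upper())
    best = aln[0]
    return Alignment(seq_a_gapped=str(best[0]), seq_b_gapped=str(best[1]), score=best.score)


def diff_alignment(aln: Alignment) -> VariantList:
    """Substitutions and (gap-run-merged) indels of an alignment."""
    out = VariantList()
    a_pos = b_pos = 0
    run_in: Optional[str] = None  # which sequence carries the inserted bases
    run_start = 0
    run_seq: List[str] = []

    def flush():
        nonlocal run_in, run_seq
        if run_in is not None:
            out.indels.append((run_start, len(run_seq), run_in, "".join(run_seq)))
        run_in = None
        run_seq = []

    for ca, cb in zip(aln.seq_a_gapped, aln.seq_b_gapped):
        if ca != "-" and cb != "-":
            flush()
            if ca != cb:
                out.substitutions.append((a_pos, b_pos, ca, cb))
            a_pos += 1
            b_pos += 1
        elif cb == "-":  # base present only in a
            if run_in != "a":
                flush()
                run_in, run_start = "a", a_pos
            run_seq.append(ca)
            a_pos += 1
        else:  # base present only in b
            if run_in != "b":
                flush()
                run_in, run_start = "b", b_pos
            run_seq.append(cb)
            b_pos += 1
    flush()
    return out


def translate(cds: str) -> str:
    """Translate a CDS with the standard code; the terminal stop is
    consumed, an internal stop is an error."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at residue {protein.index('*')}")
    return protein


class SpliceError(ValueError):
    """No GT..AG exon chain reconciles the CDS with the genomic sequence
    (the signature of an assembly inconsistency)."""


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def splice_map(
    cds: str,
    genomic: str,
    name: str = "gene",
    min_intron: int = 60,
    anchor: int = 15,
) -> GeneModel:
    """Recover the CDS-exon structure of ``genomic`` given its spliced
    product ``cds``.

    The CDS must be an exact spliced subsequence; introns must begin GT
    and end AG and be at least ``min_intron`` long.  Exons are matched
    greedily longest-first with backtracking over candidate intron ends.
    """
    cds, genomic = cds.upper(), genomic.upper()
    if not genomic.startswith(cds[: min(8, len(cds))]):
        raise SpliceError("genomic sequence does not begin with the CDS start")

    def solve(ci: int, gi: int) -> Optional[List[Tuple[int, int]]]:
        rest_c = len(cds) - ci
        rest_g = len(genomic) - gi
        if rest_c == rest_g and genomic[gi:] == cds[ci:]:
            return [(gi, len(genomic))]  # final exon
        lmax = _common_prefix_len(genomic[gi:], cds[ci:])
        for L in range(lmax, 0, -1):
            intron_start = gi + L
            if genomic[intron_start: intron_start + 2] != "GT":
                continue
            nxt = cds[ci + L: ci + L + anchor]
            if not nxt:
                continue
            j = genomic.find(nxt, intron_start + min_intron)
            while j != -1:
                if genomic[j - 2: j] == "AG":
                    tail = solve(ci + L, j)
                    if tail is not None:
                        return [(gi, intron_start)] + tail
                j = genomic.find(nxt, j + 1)
        return None

    exons = solve(0, 0)
    if exons is None:
        raise SpliceError(f"{name}: no consistent GT..AG exon chain found")
    return GeneModel(name=name, genomic_seq=genomic, exons=tuple(exons), cds_seq=cds)
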