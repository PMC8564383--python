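"""In-silico PCR with IUPAC-degenerate primers, plus restriction-site
scanning for CAPS-style genotyping.

Matching semantics: a primer base matches a template base when their
IUPAC base sets intersect.  This is deliberately permissive on the
template side so that markers amplify heterozygous Sanger consensus
sequences (a primer C anneals to a template Y, which is C on one of the
two chromatids).
"""
from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from Bio.Seq import reverse_complement

from .models import IUPAC_SETS, Amplicon, Primer, PrimerPair

#: Recognition motifs for the enzymes used in the published CAPS assay.
ENZYME_MOTIFS: Dict[str, str] = {"PciI": "ACATGT", "HpyCH4IV": "ACGT"}
#: Cut offset from motif start (A^CATGT, A^CGT).
ENZYME_CUT_OFFSETS: Dict[str, int] = {"PciI": 1, "HpyCH4IV": 1}


@dataclass(frozen=True)
class PrimerHit:
    position: int      # start on the plus strand
    strand: str        # "+" | "-"
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.position + self.length


def expand_degenerate(primer) -> List[str]:
    """All concrete A/C/G/T strings matching a degenerate primer.

    The result size is the product of the per-position degeneracies.
    """
    seq = primer.seq if isinstance(primer, Primer) else str(primer)
    choices = []
    for i, b in enumerate(seq.upper()):
        if b not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {b!r} at position {i}")
        choices.append(sorted(IUPAC_SETS[b]))
    return ["".join(p) for p in itertools.product(*choices)]


def _compat_class(primer_base: str) -> str:
    """Regex character class of template letters whose IUPAC set
    intersects the primer base's set."""
    pset = IUPAC_SETS[primer_base]
    letters = [t for t, tset in IUPAC_SETS.items() if tset & pset]
    return "[" + "".join(letters) + "]"


@functools.lru_cache(maxsize=256)
def _compiled(seq: str):
    pattern = "".join(_compat_class(b) for b in seq)
    return re.compile(f"(?=({pattern}))")


def _scan_exact(template: str, seq: str) -> List[int]:
    return [m.start() for m in _compiled(seq).finditer(template)]


def _scan_mismatch(template: str, seq: str, max_mismatch: int, anchor3: bool) -> List[Tuple[int, int]]:
    sets = [IUPAC_SETS[b] for b in seq]
    n, k = len(template), len(seq)
    out = []
    anchored = range(k - 3, k) if anchor3 else ()
    for i in range(n - k + 1):
        mm = 0
        ok = True
        for j in range(k):
            if not (IUPAC_SETS.get(template[i + j], frozenset()) & sets[j]):
                if j in anchored:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            out.append((i, mm))
    return out


def find_primer_sites(
    template: str,
    primer,
    max_mismatch: int = 0,
    anchor3: bool = False,
) -> List[PrimerHit]:
    """All binding sites of a primer on both strands of a template.

    Returns hits sorted by plus-strand position; a minus-strand hit is the
    plus-strand interval covered by the reverse-complement of the primer.
    """
    seq = (primer.seq if isinstance(primer, Primer) else str(primer)).upper()
    template = template.upper()
    if not template:
        return []
    hits: List[PrimerHit] = []
    for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
        if max_mismatch == 0 and not anchor3:
            found = [(p, 0) for p in _scan_exact(template, probe)]
        else:
            found = _scan_mismatch(template, probe, max_mismatch, anchor3)
        hits.extend(PrimerHit(p, strand, mm, len(seq)) for p, mm in found)
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def amplify(
    template: str,
    pair: PrimerPair,
    max_len: int = 5000,
    template_id: str = "template",
    max_mismatch: int = 0,
) -> List[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Every combination of a plus-strand hit of one primer with a
    downstream minus-strand hit of the other yields a product, provided
    the product is at most ``max_len``.  Both pair orientations are
    enumerated so the result is symmetric under reverse-complementing
    the template.
    """
    template = template.upper()
    products: List[Amplicon] = []
    fwd_hits = find_primer_sites(template, pair.forward, max_mismatch)
    rev_hits = find_primer_sites(template, pair.reverse, max_mismatch)
    for left, right in ((fwd_hits, rev_hits), (rev_hits, fwd_hits)):
        for a in (h for h in left if h.strand == "+"):
            for b in (h for h in right if h.strand == "-"):
                if b.position < a.end:
                    continue
                length = b.end - a.position
                if length > max_len:
                    continue
                products.append(
                    Amplicon(
                        template_id=template_id,
                        start=a.position,
                        end=b.end,
                        product_seq=template[a.position:b.end],
                        fwd_site=(a.position, a.end),
                        rev_site=(b.position, b.end),
                    )
                )
    products.sort(key=lambda p: (p.start, p.length))
    return products


def restriction_scan(seq: str, enzyme_motif: str, include_conditional: bool = True) -> List[int]:
    """Plus-strand occurrences of a concrete restriction motif.

    Template ambiguity codes match when at least one of their expansions
    matches the motif; such occurrences are "conditional" (they exist on
    one haplotype only) and are included unless switched off.
    """
    detailed = restriction_scan_detailed(seq, enzyme_motif)
    return [p for p, cond in detailed if include_conditional or not cond]


def restriction_scan_detailed(seq: str, enzyme_motif: str) -> List[Tuple[int, bool]]:
    """Like :func:`restriction_scan` but returns (position, conditional)."""
    motif = enzyme_motif.upper()
    for b in motif:
        if b not in "ACGT":
            raise ValueError(f"motif must be concrete A/C/G/T, got {b!r}")
    seq = seq.upper()
    out: List[Tuple[int, bool]] = []
    # template char matches motif base if its expansion can produce it
    classes = ["[" + "".join(t for t, s in IUPAC_SETS.items() if b in s) + "]" for b in motif]
    rx = re.compile("(?=(" + "".join(classes) + "))")
    for m in rx.finditer(seq):
        window = seq[m.start(): m.start() + len(motif)]
        out.append((m.start(), window != motif))
    return out


def caps_fragments(seq: str, enzyme: str) -> List[int]:
    """Fragment lengths after a complete digest with a named enzyme."""
    motif = ENZYME_MOTIFS[enzyme]
    offset = ENZYME_CUT_OFFSETS[enzyme]
    cuts = sorted(p + offset for p, cond in restriction_scan_detailed(seq, motif) if not cond)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
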