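"""Sex genotyping: the AG presence/absence rule, the RAN1 zygosity rule,
and their consensus.

Absence of a band is the female signal for the AG marker, so a female
call requires the positive control (actin, 250 bp) to have amplified;
without it the call is "failed".  Mixed zygosity across RAN1 sites
yields "ambiguous" rather than a majority vote.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import Panel, PrimerPair, Sample, SexCall, SnpSite, DNA_ALPHABET
from .pcr import amplify

AG_LOCUS, RAN1_LOCUS = "AG", "RAN1"


def _product_lengths(sample: Sample, pair: PrimerPair, max_len: int) -> List[int]:
    lengths = []
    for locus, seqs in sorted(sample.locus_seqs.items()):
        for i, seq in enumerate(seqs):
            for amp in amplify(seq, pair, max_len=max_len, template_id=f"{locus}|{i}"):
                lengths.append(amp.length)
    return sorted(lengths)


def call_by_presence(
    sample: Sample,
    marker: PrimerPair,
    control: Optional[PrimerPair] = None,
    max_len: int = 5000,
    marker_name: str = "AG",
) -> SexCall:
    """Male iff the marker yields a product of the expected length;
    female iff no product at all (given an amplifying control)."""
    evidence: Dict[str, object] = {}
    if control is not None:
        control_lengths = _product_lengths(sample, control, max_len)
        evidence["control_products"] = control_lengths
        ok = (
            control.expected_length in control_lengths
            if control.expected_length is not None
            else bool(control_lengths)
        )
        if not ok:
            return SexCall(sample.sample_id, marker_name, "failed", evidence)
    lengths = _product_lengths(sample, marker, max_len)
    evidence["marker_products"] = lengths
    if not lengths:
        call = "female"
    elif marker.expected_length is None or marker.expected_length in lengths:
        call = "male"
    else:
        call = "ambiguous"
    return SexCall(sample.sample_id, marker_name, call, evidence)


def genotype_snp_sites(
    sample: Sample,
    marker: PrimerPair,
    sites: Sequence[SnpSite],
    locus: str = RAN1_LOCUS,
    max_len: int = 5000,
) -> Optional[Dict[str, str]]:
    """Zygosity at every site covered by the marker amplicon on the
    sample's consensus: het (the site's ambiguity code), hom (a concrete
    base) or missing (N).  None when the marker fails to amplify."""
    consensus = sample.consensus(locus)
    products = amplify(consensus, marker, max_len=max_len, template_id=locus)
    if not products:
        return None
    amp = products[0]
    zygosity: Dict[str, str] = {}
    for site in sites:
        if not amp.start <= site.genomic_pos < amp.end:
            continue
        base = consensus[site.genomic_pos]
        if base == "N":
            zygosity[site.label] = "missing"
        elif base == site.het_code:
            zygosity[site.label] = "het"
        elif base in DNA_ALPHABET:
            zygosity[site.label] = "hom"
        else:
            zygosity[site.label] = "het"  # some other ambiguity code: two bases present
    return zygosity


def call_by_snp(
    zygosity: Optional[Dict[str, str]],
    sample_id: str = "",
    marker_name: str = "RAN1",
) -> SexCall:
    """All-heterozygous is male, all-homozygous is female; a mixture is
    ambiguous, and no informative site (or no amplification) fails."""
    if zygosity is None:
        return SexCall(sample_id, marker_name, "failed", {"reason": "no amplification"})
    informative = [z for z in zygosity.values() if z != "missing"]
    evidence = {"zygosity": dict(sorted(zygosity.items()))}
    if not informative:
        return SexCall(sample_id, marker_name, "failed", evidence)
    if all(z == "het" for z in informative):
        call = "male"
    elif all(z == "hom" for z in informative):
        call = "female"
    else:
        call = "ambiguous"
    return SexCall(sample_id, marker_name, call, evidence)


def call_by_ran1(
    sample: Sample,
    marker: PrimerPair,
    sites: Sequence[SnpSite],
    max_len: int = 5000,
) -> SexCall:
    return call_by_snp(
        genotype_snp_sites(sample, marker, sites, max_len=max_len), sample.sample_id
    )


def consensus_call(calls: Sequence[SexCall]) -> SexCall:
    """Unanimous per-marker calls carry over; any disagreement between
    non-failed calls is ambiguous, with both evidences retained."""
    if not calls:
        raise ValueError("consensus requires at least one marker call")
    sample_id = calls[0].sample_id
    evidence = {c.marker: {"call": c.call, **c.evidence} for c in calls}
    informative = [c.call for c in calls if c.call != "failed"]
    if not informative:
        return SexCall(sample_id, "consensus", "failed", evidence)
    call = informative[0] if len(set(informative)) == 1 else "ambiguous"
    return SexCall(sample_id, "consensus", call, evidence)


def call_panel(
    panel: Panel,
    ag_marker: PrimerPair,
    ran1_marker: PrimerPair,
    sites: Sequence[SnpSite],
    control: Optional[PrimerPair] = None,
    max_len: int = 5000,
) -> Dict[str, List[SexCall]]:
    """Run both markers plus the consensus over a whole panel."""
    ag_calls, ran1_calls, cons = [], [], []
    for s in panel.samples:
        a = call_by_presence(s, ag_marker, control=control, max_len=max_len)
        r = call_by_ran1(s, ran1_marker, sites, max_len=max_len)
        ag_calls.append(a)
        ran1_calls.append(r)
        cons.append(consensus_call([a, r]))
    return {"AG": ag_calls, "RAN1": ran1_calls, "consensus": cons}
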