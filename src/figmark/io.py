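"""Readers and writers for the formats the pipeline touches.

FASTA via Bio.SeqIO, GFF3 written by a byte-stable emitter and read back
through gffutils, tables as UTF-8 TSV with Unix newlines.  Internal
coordinates are 0-based half-open; GFF3 output is 1-based inclusive.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    GeneModel,
    IUPAC_SETS,
    Panel,
    Primer,
    PrimerPair,
    Sample,
    SexCall,
    SnpSite,
)

LOCUS_ORDER = ("AG", "RAN1", "ACT")


@dataclasses.dataclass
class RunConfig:
    """Options shared by the CLI subcommands; unknown keys are rejected."""

    seed: int = 1
    max_mismatch: int = 0
    max_len: int = 5000
    control_enabled: bool = True
    yates: bool = False

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _line_of(path, predicate, occurrence: int = 1) -> int:
    """1-based number of the n-th line satisfying a predicate."""
    seen = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if predicate(line.rstrip("\n")):
                seen += 1
                if seen == occurrence:
                    return i
    return -1


def read_fasta(path) -> List[Tuple[str, str]]:
    """Parse FASTA into (id, upper-cased sequence) pairs, validating ids
    and the IUPAC alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            ln = _line_of(
                path,
                lambda l, rid=rec.id: l.startswith(">") and l[1:].split()[0] == rid,
                occurrence=2,
            )
            raise ValueError(f"{path}: duplicate record id {rec.id!r} (line {ln})")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = next((b for b in seq if b not in IUPAC_SETS), None)
        if bad is not None:
            ln = _line_of(path, lambda l, b=bad: not l.startswith(">") and b in l.upper())
            raise ValueError(f"{path}: illegal character {bad!r} in record {rec.id!r} (line {ln})")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path, wrap: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# gene models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"##sequence-region {m.name} 1 {len(m.genomic_seq)}\n")
        for m in models:
            gid = m.name
            fh.write(
                f"{m.name}\tfigmark\tgene\t1\t{len(m.genomic_seq)}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.name}\tfigmark\tmRNA\t1\t{len(m.genomic_seq)}\t.\t{m.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                for ftype in ("exon", "CDS"):
                    phase = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{m.name}\tfigmark\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                        f"ID={gid}.{ftype}{i};Parent={gid}.t1\n"
                    )


def read_gene_models(gff_path, fasta_path) -> Dict[str, GeneModel]:
    seqs = dict(read_fasta(fasta_path))
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    out: Dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(f"{gene.id}.t1", featuretype="CDS")
        )
        genomic = seqs[gene.seqid]
        cds = "".join(genomic[s:e] for s, e in exons)
        out[gene.id] = GeneModel(
            name=gene.id, genomic_seq=genomic, exons=tuple(exons), cds_seq=cds, strand=gene.strand
        )
    return out


# ---------------------------------------------------------------------------
# tables


def read_primer_table(path) -> List[PrimerPair]:
    """Assemble primer pairs from a TSV with columns
    name/sequence/orientation/expected_length; -F and -R rows sharing a
    prefix form a pair."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "sequence", "orientation", "expected_length"}
    if not required <= set(df.columns):
        raise ValueError(f"primer table must have columns {sorted(required)}")
    groups: Dict[str, Dict[str, Tuple[Primer, Optional[int]]]] = {}
    order: List[str] = []
    for _, row in df.iterrows():
        name = row["name"]
        if name.endswith("-F"):
            base, orient = name[:-2], "forward"
        elif name.endswith("-R"):
            base, orient = name[:-2], "reverse"
        else:
            raise ValueError(f"primer name {name!r} lacks an -F/-R suffix")
        if row["orientation"] != orient:
            raise ValueError(f"{name}: orientation column disagrees with the -F/-R suffix")
        length = None
        if isinstance(row["expected_length"], str) and row["expected_length"].strip():
            length = int(row["expected_length"])
            if length <= 0:
                raise ValueError(f"{name}: expected_length must be positive")
        if base not in groups:
            order.append(base)
        groups.setdefault(base, {})[orient] = (Primer(name, row["sequence"].upper(), orient), length)
    pairs = []
    for base in order:
        g = groups[base]
        if "forward" not in g or "reverse" not in g:
            missing = "-R" if "forward" in g else "-F"
            raise ValueError(f"primer {base}{missing} is missing: unpaired primer {base!r}")
        length = g["forward"][1] if g["forward"][1] is not None else g["reverse"][1]
        pairs.append(PrimerPair(base, g["forward"][0], g["reverse"][0], expected_length=length))
    return pairs


def write_sites_tsv(sites: Sequence[SnpSite], path) -> None:
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "genomic_pos": s.genomic_pos,
                "cds_pos": s.cds_pos,
                "female_base": s.female_base,
                "male_alt_base": s.male_alt_base,
                "het_code": s.het_code,
                "validity": s.validity,
                "effect": s.effect,
            }
            for s in sites
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sites_tsv(path) -> List[SnpSite]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    return [
        SnpSite(
            label=r.label,
            genomic_pos=int(r.genomic_pos),
            female_base=r.female_base,
            male_alt_base=r.male_alt_base,
            het_code=r.het_code,
            validity=r.validity,
            effect=r.effect,
            cds_pos=int(r.cds_pos),
        )
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: Sequence[SexCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "marker": c.marker,
                "call": c.call,
                "evidence_json": json.dumps(c.evidence, sort_keys=True),
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_calls_tsv(path) -> List[SexCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SexCall(
            sample_id=r.sample_id,
            marker=r.marker,
            call=r.call,
            evidence=json.loads(r.evidence_json) if r.evidence_json else {},
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# panel directories


def write_panel(
    panel: Panel,
    outdir,
    seed: Optional[int] = None,
    models=None,
    sites: Optional[Sequence[SnpSite]] = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for s in panel.samples:
        for locus in LOCUS_ORDER:
            if locus not in s.locus_seqs:
                continue
            for i, seq in enumerate(s.locus_seqs[locus]):
                records.append((f"{s.sample_id}|{locus}|{i}", seq))
    write_fasta(records, outdir / "samples.fasta")
    truth = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "population": s.population, "true_sex": s.true_sex}
            for s in panel.samples
        ]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    if sites is not None:
        write_sites_tsv(sites, outdir / "snp_sites.tsv")
    if models is not None:
        gene_models = _collect_gene_models(models)
        write_gff3(gene_models, outdir / "genes.gff3")
        write_fasta([(m.name, m.genomic_seq) for m in gene_models], outdir / "genes.fasta")
    manifest = {
        "panel": panel.name,
        "n_samples": len(panel),
        "n_male": sum(1 for s in panel.samples if s.true_sex == "male"),
        "n_female": sum(1 for s in panel.samples if s.true_sex == "female"),
        "seed": seed,
        "format_version": 1,
    }
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _collect_gene_models(models) -> List[GeneModel]:
    if isinstance(models, dict):
        out = []
        for v in models.values():
            if isinstance(v, GeneModel):
                out.append(v)
            elif isinstance(v, dict) and isinstance(v.get("gene"), GeneModel):
                out.append(v["gene"])
        return out
    return list(models)


def read_panel(indir) -> Panel:
    indir = Path(indir)
    truth = pd.read_csv(indir / "truth.tsv", sep="\t", dtype=str)
    seqs = read_fasta(indir / "samples.fasta")
    per_sample: Dict[str, Dict[str, Dict[int, str]]] = {}
    for rec_id, seq in seqs:
        sample_id, locus, idx = rec_id.rsplit("|", 2)
        per_sample.setdefault(sample_id, {}).setdefault(locus, {})[int(idx)] = seq
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    samples = []
    for r in truth.itertuples():
        loci = per_sample.get(r.sample_id, {})
        samples.append(
            Sample(
                sample_id=r.sample_id,
                true_sex=r.true_sex,
                locus_seqs={
                    locus: tuple(loci[locus][i] for i in sorted(loci[locus]))
                    for locus in LOCUS_ORDER
                    if locus in loci
                },
                population=r.population,
            )
        )
    return Panel(samples=samples, name=manifest.get("panel", indir.name))
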